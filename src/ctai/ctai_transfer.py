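"""Calibration transfer by affine invariance (CTAI), without transfer standards.

The method adapts a master-instrument PLS1 model to a slave instrument
using only unlabeled slave calibration spectra — no samples measured on
both instruments and no slave reference values.

Idea.  For each latent variable i, the master model yields a score vector
t_i and a prediction vector yhat on the master calibration spectra, and a
*pseudo* score vector and pseudo prediction vector on the slave
calibration spectra (the same W, P, beta are applied to the slave
spectra).  After min–max normalization of each vector to [0, 1], the
per-component relationship between score and prediction is a straight
line on each instrument:

    yhat_norm = t_norm * tan(theta_i) + b_i

The instruments are assumed to differ, component-wise, only by a rotation
Delta_theta_i = theta_i^m - theta_i^s and a translation
Delta_b_i = b_i^m - b_i^s of that line (affine invariance).  At prediction
time each slave test sample's normalized (score, prediction) point is
rotated and translated accordingly:

    y' = t_n * sin(Delta_theta_i) + (y_n - b_i^s) * cos(Delta_theta_i) + b_i^m

then mapped back to property units, and the A per-component corrections
are averaged.

The rotation is carried out entirely in normalized coordinates; the
scaling factors that mix raw and normalized units in the original
formulation are treated as the denormalization step.  A
``denorm_reference`` switch selects whose prediction bounds (master or
slave) rescale the corrected value; the default ``master`` is the reading
under which a pure prediction offset is corrected exactly and the
identity case (slave == master) reproduces the master model.

Test batches are normalized with the *calibration* bounds, so
single-sample prediction is well-defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .pls_core import PLS1Model, fit_pls1, pls_predict, pls_scores, select_lv

__all__ = [
    "ComponentRegression",
    "CTAIModel",
    "SlaveCoefficients",
    "minmax_normalize",
    "fit_component_regression",
    "fit_ctai",
    "ctai_predict",
    "slave_coefficients",
]

_RANGE_EPS = 1e-12


@dataclass
class ComponentRegression:
    """Per-component line between normalized scores and predictions.

    ``slope`` is tan(theta); ``theta = arctan(slope)`` lies in
    (-pi/2, pi/2).  ``t_min/t_max`` and ``y_min/y_max`` are the min–max
    normalization bounds of the calibration score column and prediction
    vector on this instrument.
    """

    slope: float
    intercept: float
    theta: float
    t_min: float
    t_max: float
    y_min: float
    y_max: float


@dataclass
class CTAIModel:
    """Fitted transfer model: master PLS1 plus per-component affine deltas."""

    master: PLS1Model
    master_regs: list[ComponentRegression]
    slave_regs: list[ComponentRegression]
    delta_theta: np.ndarray
    delta_b: np.ndarray
    denorm_reference: str = "master"
    lv_selection: object | None = field(default=None, repr=False)

    @property
    def A(self) -> int:
        return self.master.A


@dataclass
class SlaveCoefficients:
    """Equivalent slave-instrument coefficient view of the corrected predictor.

    ``beta`` (length p) and ``intercept`` satisfy
    ``X @ beta + intercept ~= ctai_predict(...)`` on the batch they were
    computed from, up to ``residual_norm``.  ``rank_deficient`` flags a
    minimum-norm solve on rank-deficient spectra.
    """

    beta: np.ndarray
    intercept: float
    residual_norm: float
    rank_deficient: bool


def minmax_normalize(v: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Scale ``v`` into [0, 1]; returns ``(normalized, min, max)``.

    Raises for near-degenerate ranges (max - min < 1e-12).
    """
    v = np.asarray(v, dtype=float).ravel()
    if v.size < 2:
        raise ValueError("need at least 2 elements to normalize")
    lo, hi = float(v.min()), float(v.max())
    if hi - lo < _RANGE_EPS:
        raise ValueError(f"degenerate range [{lo}, {hi}]: spread < {_RANGE_EPS}")
    return (v - lo) / (hi - lo), lo, hi


def fit_component_regression(
    t_norm: np.ndarray, y_norm: np.ndarray
) -> tuple[float, float]:
    """Ordinary least squares of ``y_norm`` on ``[t_norm, 1]``.

    Returns ``(slope, intercept)``.
    """
    t = np.asarray(t_norm, dtype=float).ravel()
    y = np.asarray(y_norm, dtype=float).ravel()
    if t.size != y.size or t.size < 2:
        raise ValueError("t_norm and y_norm must have equal length >= 2")
    var = float(np.var(t))
    if var < _RANGE_EPS:
        raise ValueError("constant predictor: cannot fit component regression")
    slope = float(np.cov(t, y, bias=True)[0, 1] / var)
    intercept = float(y.mean() - slope * t.mean())
    return slope, intercept


def _fit_instrument_regs(
    T: np.ndarray, yhat: np.ndarray, label: str
) -> list[ComponentRegression]:
    regs = []
    try:
        y_norm, y_lo, y_hi = minmax_normalize(yhat)
    except ValueError as exc:
        raise ValueError(f"{label} predictions: {exc}") from None
    for i in range(T.shape[1]):
        try:
            t_norm, t_lo, t_hi = minmax_normalize(T[:, i])
        except ValueError as exc:
            raise ValueError(f"{label} component {i + 1} scores: {exc}") from None
        slope, intercept = fit_component_regression(t_norm, y_norm)
        regs.append(
            ComponentRegression(
                slope=slope,
                intercept=intercept,
                theta=float(np.arctan(slope)),
                t_min=t_lo,
                t_max=t_hi,
                y_min=y_lo,
                y_max=y_hi,
            )
        )
    return regs


def fit_ctai(
    master_X: np.ndarray,
    master_y: np.ndarray,
    slave_X: np.ndarray,
    A: int | str = "auto",
    denorm_reference: str = "master",
    *,
    lv_range: tuple[int, int] = (1, 15),
    cv_folds: int = 10,
    seed: int = 0,
) -> CTAIModel:
    """Fit the transfer model from master (X, y) and unlabeled slave X.

    Slave reference values are not required and slave rows need not
    correspond to master rows.  ``A='auto'`` selects the latent-variable
    count by cross-validation on the master calibration set.
    """
    master_X = np.asarray(master_X, dtype=float)
    slave_X = np.asarray(slave_X, dtype=float)
    if master_X.shape[1] != slave_X.shape[1]:
        raise ValueError(
            f"channel mismatch: master has {master_X.shape[1]}, "
            f"slave has {slave_X.shape[1]}"
        )
    if denorm_reference not in ("master", "slave"):
        raise ValueError("denorm_reference must be 'master' or 'slave'")

    lv_sel = None
    if A == "auto":
        lv_sel = select_lv(
            master_X, master_y, lv_range[0], lv_range[1], folds=cv_folds, seed=seed
        )
        A = lv_sel.chosen_A
    master = fit_pls1(master_X, master_y, int(A))

    Tm = pls_scores(master, master_X)
    yhat_m = pls_predict(master, master_X)
    Ts = pls_scores(master, slave_X)
    yhat_s = pls_predict(master, slave_X)

    master_regs = _fit_instrument_regs(Tm, yhat_m, "master")
    slave_regs = _fit_instrument_regs(Ts, yhat_s, "slave")

    delta_theta = np.array(
        [m.theta - s.theta for m, s in zip(master_regs, slave_regs)]
    )
    delta_b = np.array(
        [m.intercept - s.intercept for m, s in zip(master_regs, slave_regs)]
    )
    if np.any(np.abs(np.cos(delta_theta)) < 1e-9):
        warnings.warn(
            "near-vertical rotation (|cos(delta_theta)| < 1e-9) in some "
            "component; corrected predictions may be unstable",
            RuntimeWarning,
        )
    return CTAIModel(
        master=master,
        master_regs=master_regs,
        slave_regs=slave_regs,
        delta_theta=delta_theta,
        delta_b=delta_b,
        denorm_reference=denorm_reference,
        lv_selection=lv_sel,
    )


def ctai_predict(
    m: CTAIModel, slave_X_test: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Correct slave-instrument predictions by per-component affine maps.

    Returns ``(predictions, per_component)`` where ``per_component`` is a
    ``(k, A)`` matrix of corrected predictions per latent variable and
    ``predictions`` is its row mean.
    """
    if not isinstance(m, CTAIModel) or not m.master_regs:
        raise ValueError("model is not fitted")
    slave_X_test = np.asarray(slave_X_test, dtype=float)
    if slave_X_test.ndim == 1:
        slave_X_test = slave_X_test[None, :]
    T = pls_scores(m.master, slave_X_test)
    yhat = pls_predict(m.master, slave_X_test)

    k = slave_X_test.shape[0]
    per_component = np.empty((k, m.A))
    for i in range(m.A):
        sreg = m.slave_regs[i]
        mreg = m.master_regs[i]
        # normalize with SLAVE CALIBRATION bounds (well-defined for 1 sample)
        t_n = (T[:, i] - sreg.t_min) / (sreg.t_max - sreg.t_min)
        y_n = (yhat - sreg.y_min) / (sreg.y_max - sreg.y_min)
        dth = m.delta_theta[i]
        y_corr = t_n * np.sin(dth) + (y_n - sreg.intercept) * np.cos(dth) + mreg.intercept
        ref = mreg if m.denorm_reference == "master" else sreg
        per_component[:, i] = y_corr * (ref.y_max - ref.y_min) + ref.y_min
    return per_component.mean(axis=1), per_component


def slave_coefficients(
    m: CTAIModel, slave_X_test: np.ndarray
) -> SlaveCoefficients:
    """Project corrected predictions back onto the slave spectra.

    Diagnostic equivalent-coefficient view: the least-squares (minimum-norm
    on rank-deficient batches) solution of the centered system
    ``(X - mean) beta = pred - mean(pred)``, with the intercept absorbing
    the means.  Applying the result to ``slave_X_test`` reproduces the
    corrected predictions up to the projection residual.
    """
    slave_X_test = np.asarray(slave_X_test, dtype=float)
    pred, _ = ctai_predict(m, slave_X_test)
    x_mean = slave_X_test.mean(axis=0)
    Xc = slave_X_test - x_mean
    yc = pred - pred.mean()
    beta, _, rank, _ = np.linalg.lstsq(Xc, yc, rcond=None)
    rank_deficient = rank < min(Xc.shape)
    if rank_deficient:
        warnings.warn(
            "rank-deficient slave spectra: returning minimum-norm coefficients",
            RuntimeWarning,
        )
    intercept = float(pred.mean() - x_mean @ beta)
    residual_norm = float(np.linalg.norm(Xc @ beta - yc))
    return SlaveCoefficients(
        beta=beta,
        intercept=intercept,
        residual_norm=residual_norm,
        rank_deficient=bool(rank_deficient),
    )
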
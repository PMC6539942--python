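"""Standard-sample calibration-transfer baselines: SBC, MSC and PDS.

These are the classical comparison methods.  Unlike the affine-invariance
transfer, SBC and PDS require *transfer standards*: samples measured on
both instruments.

* SBC (slope/bias correction) fits one line between the master and slave
  predictions of the standards and maps every slave prediction through it.
* MSC (multiplicative scatter correction) regresses each spectrum on a
  reference spectrum (mean master calibration spectrum) and removes the
  fitted additive and multiplicative terms; applied to slave spectra it
  acts as a standard-free transfer preprocessing.
* PDS (piecewise direct standardization) regresses each master channel on
  a window of slave channels around it, assembling a banded transfer
  matrix that maps slave spectra into master space; the per-window
  regressions here are PLS1 sub-models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .pls_core import PLS1Model, fit_pls1, pls_predict

__all__ = [
    "SBCModel",
    "MSCReference",
    "PDSModel",
    "HyperparamSelection",
    "fit_sbc",
    "apply_sbc",
    "make_msc_reference",
    "msc_correct",
    "fit_pds",
    "apply_pds",
    "select_hyperparams",
    "DEFAULT_PDS_WINDOWS",
    "DEFAULT_STANDARD_COUNTS",
]

# odd centered windows from the 3..16-by-2 search grid
DEFAULT_PDS_WINDOWS = (3, 5, 7, 9, 11, 13, 15)
DEFAULT_STANDARD_COUNTS = tuple(range(5, 31))


@dataclass
class SBCModel:
    """Univariate slope/bias map from slave predictions to master scale."""

    slope: float
    bias: float
    n_standards: int


@dataclass
class MSCReference:
    """Reference spectrum for multiplicative scatter correction."""

    ref_spectrum: np.ndarray


@dataclass
class PDSModel:
    """Banded transfer matrix mapping slave spectra to master space.

    ``transfer_matrix[j_slave, j_master]`` is zero outside the band
    ``|j_slave - j_master| <= (window - 1) / 2``.
    """

    window: int
    transfer_matrix: np.ndarray
    intercepts: np.ndarray
    inner_lv: int


@dataclass
class HyperparamSelection:
    """Result of a baseline hyperparameter search."""

    method: str
    window: int | None
    n_standards: int | None
    criterion_curve: dict
    folds: int
    seed: int


def fit_sbc(master_pred_std: np.ndarray, slave_pred_std: np.ndarray) -> SBCModel:
    """OLS of master predictions on slave predictions of paired standards."""
    a = np.asarray(master_pred_std, dtype=float).ravel()
    b = np.asarray(slave_pred_std, dtype=float).ravel()
    if a.size != b.size or a.size < 2:
        raise ValueError("need paired standard predictions of equal length >= 2")
    var = float(np.var(b))
    if var < 1e-12:
        raise ValueError("constant slave predictions: SBC slope undefined")
    slope = float(np.cov(b, a, bias=True)[0, 1] / var)
    bias = float(a.mean() - slope * b.mean())
    return SBCModel(slope=slope, bias=bias, n_standards=a.size)


def apply_sbc(m: SBCModel, slave_pred: np.ndarray) -> np.ndarray:
    return m.slope * np.asarray(slave_pred, dtype=float) + m.bias


def make_msc_reference(master_cal_spectra: np.ndarray) -> MSCReference:
    """Mean master calibration spectrum as the MSC reference."""
    X = np.asarray(master_cal_spectra, dtype=float)
    return MSCReference(ref_spectrum=X.mean(axis=0))


def msc_correct(X: np.ndarray, ref: MSCReference) -> np.ndarray:
    """Replace each row x by ``(x - a) / b`` where ``x = a + b*ref + e`` (OLS)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    r = ref.ref_spectrum
    if X.shape[1] != r.size:
        raise ValueError(
            f"channel mismatch: spectra have {X.shape[1]}, reference {r.size}"
        )
    rc = r - r.mean()
    denom = float(rc @ rc)
    out = np.empty_like(X)
    for i, x in enumerate(X):
        b = float(rc @ (x - x.mean())) / denom
        if abs(b) < 1e-12:
            raise ValueError(f"row {i}: zero MSC slope, correction undefined")
        a = float(x.mean() - b * r.mean())
        out[i] = (x - a) / b
    return out


def fit_pds(
    master_std: np.ndarray,
    slave_std: np.ndarray,
    window: int = 3,
    inner_lv: int = 1,
) -> PDSModel:
    """Fit piecewise direct standardization from paired standards.

    For each master channel j a PLS1 sub-model regresses the master
    standards' channel j on the slave standards' window centered at j
    (truncated symmetrically at the spectrum edges, so output length stays
    p).  ``inner_lv`` is capped by window width and standard count.
    """
    M = np.asarray(master_std, dtype=float)
    S = np.asarray(slave_std, dtype=float)
    if M.shape != S.shape:
        raise ValueError("master and slave standards must be paired (same shape)")
    n, p = M.shape
    if window % 2 != 1 or window < 3:
        raise ValueError("window must be an odd count >= 3")
    if window > p:
        raise ValueError(f"window {window} exceeds channel count {p}")
    if n < 2:
        raise ValueError("need at least 2 standards")
    half = (window - 1) // 2
    B = np.zeros((p, p))
    intercepts = np.zeros(p)
    for j in range(p):
        lo, hi = max(0, j - half), min(p, j + half + 1)
        Xw = S[:, lo:hi]
        yj = M[:, j]
        a = min(inner_lv, hi - lo, n - 1)
        if np.ptp(yj) == 0:
            # constant target channel: flat map
            intercepts[j] = yj[0]
            continue
        sub = fit_pls1(Xw, yj, a)
        B[lo:hi, j] = sub.beta
        intercepts[j] = sub.y_mean - float(sub.x_mean @ sub.beta)
    return PDSModel(
        window=window, transfer_matrix=B, intercepts=intercepts, inner_lv=inner_lv
    )


def apply_pds(m: PDSModel, slave_X: np.ndarray) -> np.ndarray:
    """Map slave spectra into master space with the banded transfer matrix."""
    X = np.atleast_2d(np.asarray(slave_X, dtype=float))
    if X.shape[1] != m.transfer_matrix.shape[0]:
        raise ValueError(
            f"channel mismatch: spectra have {X.shape[1]}, "
            f"model expects {m.transfer_matrix.shape[0]}"
        )
    return X @ m.transfer_matrix + m.intercepts


def _pds_cv_rmse(
    master_std, slave_std, reference, master_model, window, inner_lv, folds, seed
):
    """5-fold CV error of PDS at one window: held-out standards are mapped to
    master space and predicted with the master model against reference."""
    n = master_std.shape[0]
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    bounds = np.linspace(0, n, folds + 1).round().astype(int)
    sq = 0.0
    for f in range(folds):
        test_idx = order[bounds[f] : bounds[f + 1]]
        train_idx = np.setdiff1d(order, test_idx)
        model = fit_pds(
            master_std[train_idx], slave_std[train_idx], window, inner_lv
        )
        mapped = apply_pds(model, slave_std[test_idx])
        pred = pls_predict(master_model, mapped)
        sq += float(np.sum((reference[test_idx] - pred) ** 2))
    return float(np.sqrt(sq / n))


def select_hyperparams(
    method: str,
    master_std: np.ndarray,
    slave_std: np.ndarray,
    reference: np.ndarray,
    master_model: PLS1Model,
    *,
    windows=DEFAULT_PDS_WINDOWS,
    standard_counts=DEFAULT_STANDARD_COUNTS,
    inner_lv: int = 1,
    folds: int = 5,
    seed: int = 0,
) -> HyperparamSelection:
    """Search baseline hyperparameters on Kennard–Stone-ordered standards.

    ``master_std``/``slave_std`` rows must be paired and already in KS
    selection order, so the first k rows are the k standards.

    * ``method='pds'``: window chosen from the odd grid 3..15 by k-fold
      cross-validation of the mapped-and-predicted held-out standards.
    * ``method='sbc'``: standard count chosen from 5..30 by the smallest
      RMSE of the corrected standards against their reference values.
    """
    M = np.asarray(master_std, dtype=float)
    S = np.asarray(slave_std, dtype=float)
    reference = np.asarray(reference, dtype=float).ravel()
    if method == "pds":
        p = M.shape[1]
        curve = {}
        for w in windows:
            if w > p:
                warnings.warn(f"window {w} > channel count {p}: skipped")
                continue
            curve[w] = _pds_cv_rmse(
                M, S, reference, master_model, w, inner_lv, folds, seed
            )
        if not curve:
            raise ValueError("no feasible PDS window candidate")
        best = min(curve, key=lambda w: (curve[w], w))
        return HyperparamSelection(
            method="pds",
            window=int(best),
            n_standards=None,
            criterion_curve=curve,
            folds=folds,
            seed=seed,
        )
    if method == "sbc":
        n = M.shape[0]
        curve = {}
        for k in standard_counts:
            if k > n:
                warnings.warn(f"standard count {k} > available {n}: skipped")
                continue
            mp = pls_predict(master_model, M[:k])
            sp = pls_predict(master_model, S[:k])
            model = fit_sbc(mp, sp)
            corrected = apply_sbc(model, sp)
            curve[k] = float(np.sqrt(np.mean((reference[:k] - corrected) ** 2)))
        if not curve:
            raise ValueError("no feasible standard-count candidate")
        best = min(curve, key=lambda k: (curve[k], k))
        return HyperparamSelection(
            method="sbc",
            window=None,
            n_standards=int(best),
            criterion_curve=curve,
            folds=folds,
            seed=seed,
        )
    raise ValueError(f"unknown method {method!r}; expected 'pds' or 'sbc'")
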
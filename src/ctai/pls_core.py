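"""Bespoke PLS1 (single-response partial least squares) regression.

The calibration-transfer method in this package is defined in terms of the
internal quantities of a PLS1 model — the weight matrix W, the x-loading
matrix P, the y-loading vector q and the coefficient vector
``beta = W (P'W)^-1 q'`` — so the decomposition is implemented here rather
than delegated to a generic PLS library whose internals differ by
convention.

The algorithm is the classical NIPALS/deflation scheme for one response:
X and y are mean-centered, each weight vector is the (sign-fixed, unit
norm) direction ``X' y / ||X' y||`` of the current deflated X — i.e. the
dominant eigenvector of ``X' y y' X`` — X is deflated per component
(``X <- X - t p'``, y not deflated), and q_a = t'y / t't.  Successive score
vectors are mutually orthogonal by construction.  Predictions are
``(X - x_mean) beta + y_mean``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PLS1Model",
    "LVSelection",
    "fit_pls1",
    "pls_predict",
    "pls_scores",
    "select_lv",
]


@dataclass
class PLS1Model:
    """Fitted PLS1 decomposition.

    Attributes
    ----------
    x_mean, y_mean
        Centering offsets of the training data.
    W
        ``(p, A)`` weight matrix; unit-norm columns, sign fixed so the
        largest-magnitude element of each column is positive.
    P
        ``(p, A)`` x-loading matrix.
    q
        Length-``A`` y-loading vector.
    beta
        Length-``p`` regression coefficient vector on the centered scale.
    A
        Number of latent variables.
    rmsec
        Training root-mean-square error.
    residual_X, residual_y
        Training residuals after A components (the E and F matrices).
    """

    x_mean: np.ndarray
    y_mean: float
    W: np.ndarray
    P: np.ndarray
    q: np.ndarray
    beta: np.ndarray
    A: int
    rmsec: float
    residual_X: np.ndarray | None = None
    residual_y: np.ndarray | None = None

    @property
    def n_channels(self) -> int:
        return self.beta.size


@dataclass
class LVSelection:
    """Latent-variable count chosen by cross-validation.

    ``chosen_A`` attains the minimum of ``rmsecv_curve`` (smallest A on
    ties); ``rmsecv_curve[i]`` is the pooled held-out RMSE for
    ``candidates[i]`` components.
    """

    chosen_A: int
    candidates: np.ndarray
    rmsecv_curve: np.ndarray
    folds: int
    seed: int


def _check_Xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if y.size != X.shape[0]:
        raise ValueError(f"y length {y.size} != sample count {X.shape[0]}")
    return X, y


def fit_pls1(X: np.ndarray, y: np.ndarray, A: int) -> PLS1Model:
    """Fit a PLS1 model with ``A`` latent variables.

    Deterministic; raises for infeasible ``A`` or constant ``y``.
    """
    X, y = _check_Xy(X, y)
    n, p = X.shape
    if not 1 <= A <= min(n - 1, p):
        raise ValueError(f"A={A} outside feasible range [1, {min(n - 1, p)}]")
    if np.ptp(y) == 0:
        raise ValueError("y is constant; nothing to regress on")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean

    W = np.empty((p, A))
    P = np.empty((p, A))
    q = np.empty(A)
    Xd = Xc.copy()
    norm0 = np.linalg.norm(Xc.T @ yc)
    if norm0 < 1e-14:
        raise ValueError("degenerate input: X'y ~ 0, no predictive direction")
    a_eff = A
    for a in range(A):
        w = Xd.T @ yc
        norm = np.linalg.norm(w)
        if norm < 1e-12 * norm0:
            # fit already exact (deflated X carries no covariance with y);
            # truncate rather than extract numerically meaningless components
            a_eff = a
            break
        w /= norm
        # fix sign: largest-magnitude element positive (reproducible serialization)
        if w[np.argmax(np.abs(w))] < 0:
            w = -w
        t = Xd @ w
        tt = float(t @ t)
        pvec = Xd.T @ t / tt
        q[a] = float(t @ yc) / tt
        Xd -= np.outer(t, pvec)
        W[:, a] = w
        P[:, a] = pvec

    W, P, q = W[:, :a_eff], P[:, :a_eff], q[:a_eff]
    beta = W @ np.linalg.solve(P.T @ W, q)
    resid_y = yc - Xc @ beta
    rmsec = float(np.sqrt(np.mean(resid_y**2)))
    return PLS1Model(
        x_mean=x_mean,
        y_mean=y_mean,
        W=W,
        P=P,
        q=q,
        beta=beta,
        A=a_eff,
        rmsec=rmsec,
        residual_X=Xd,
        residual_y=resid_y,
    )


def pls_predict(m: PLS1Model, X: np.ndarray) -> np.ndarray:
    """Predict responses: ``(X - x_mean) beta + y_mean``."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != m.n_channels:
        raise ValueError(
            f"X has {X.shape[1]} channels, model expects {m.n_channels}"
        )
    return (X - m.x_mean) @ m.beta + m.y_mean


def pls_scores(m: PLS1Model, X: np.ndarray) -> np.ndarray:
    """Score matrix ``T = (X - x_mean) W (P'W)^-1`` (columns orthogonal on
    the training data)."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != m.n_channels:
        raise ValueError(
            f"X has {X.shape[1]} channels, model expects {m.n_channels}"
        )
    R = np.linalg.solve((m.P.T @ m.W).T, m.W.T).T  # W (P'W)^-1
    return (X - m.x_mean) @ R


def select_lv(
    X: np.ndarray,
    y: np.ndarray,
    a_min: int = 1,
    a_max: int = 15,
    folds: int = 10,
    seed: int = 0,
) -> LVSelection:
    """Choose the latent-variable count by k-fold cross-validation.

    Folds are formed by a seeded shuffle followed by contiguous
    partitioning; the RMSECV for each candidate A pools all held-out
    predictions.  The chosen A minimizes RMSECV, breaking ties toward the
    smaller (more parsimonious) count.  The default search range 1..15
    with 10 folds mirrors common chemometric practice.
    """
    X, y = _check_Xy(X, y)
    n = X.shape[0]
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if folds > n:
        raise ValueError(f"folds={folds} exceeds sample count {n}")
    min_train = n - (n // folds + (1 if n % folds else 0))
    feasible_max = min(a_max, min_train - 1, X.shape[1])
    if feasible_max < a_min:
        raise ValueError(
            f"no feasible candidate in [{a_min}, {a_max}] with {folds} folds "
            f"on {n} samples"
        )
    candidates = np.arange(a_min, feasible_max + 1)

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fold_ids = np.zeros(n, dtype=int)
    # contiguous blocks over the shuffled order, sizes differing by <= 1
    bounds = np.linspace(0, n, folds + 1).round().astype(int)
    for f in range(folds):
        fold_ids[order[bounds[f] : bounds[f + 1]]] = f

    press = np.zeros(candidates.size)
    for f in range(folds):
        test = fold_ids == f
        train = ~test
        model = fit_pls1(X[train], y[train], int(candidates[-1]))
        Xc = X[test] - model.x_mean
        # held-out predictions for every truncated component count at once
        T = Xc @ np.linalg.solve((model.P.T @ model.W).T, model.W.T).T
        cum = np.cumsum(T * model.q, axis=1) + model.y_mean
        for i, a in enumerate(candidates):
            # fits that converged early (A truncated) extend flat
            col = min(int(a), model.A) - 1
            press[i] += float(np.sum((y[test] - cum[:, col]) ** 2))
    rmsecv = np.sqrt(press / n)
    best = int(np.argmin(rmsecv))
    return LVSelection(
        chosen_A=int(candidates[best]),
        candidates=candidates,
        rmsecv_curve=rmsecv,
        folds=folds,
        seed=seed,
    )
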
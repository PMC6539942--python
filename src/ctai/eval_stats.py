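"""Evaluation statistics for calibration-transfer experiments.

Conventions:

* RMSE — root-mean-square error; RMSEC/RMSECV/RMSEP denote the same
  quantity on the calibration set, under cross-validation, and on the
  test set.
* bias — mean signed error, ``sum(y_i - yhat_i)/n``.
* SE — bias-corrected standard error of prediction,
  ``sqrt(sum((e_i - mean(e))^2)/(n-1))`` with ``e = y - yhat``, so that
  ``rmse^2 = bias^2 + se^2 (n-1)/n``.
* h — RMSEP improvement rate of one method over another,
  ``(1 - rmsep/rmsep_other) * 100`` percent.
* Wilcoxon signed-rank test — two-sided, on paired absolute residuals;
  exact null enumeration for small tie-free samples, else the
  tie-corrected normal approximation without continuity correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "EvaluationReport",
    "rmse",
    "bias_se",
    "improvement",
    "pearson_test",
    "one_sample_t",
    "wilcoxon_signed_rank",
    "evaluate_transfer",
]


@dataclass
class EvaluationReport:
    """Statistics for one method on one dataset."""

    method: str
    rmse: float
    bias: float
    se: float
    pearson_r: float
    pearson_p: float
    t_stat: float
    t_p: float
    t_critical: float
    wilcoxon_stat: float | None = None
    wilcoxon_p: float | None = None
    wilcoxon_degenerate: bool = False
    h_vs: dict = field(default_factory=dict)


def _paired(y, yhat):
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size != yhat.size:
        raise ValueError(f"length mismatch: {y.size} vs {yhat.size}")
    return y, yhat


def rmse(y, yhat) -> float:
    y, yhat = _paired(y, yhat)
    if y.size < 1:
        raise ValueError("need at least one observation")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def bias_se(y, yhat) -> tuple[float, float]:
    """Mean signed error and bias-corrected standard error of prediction."""
    y, yhat = _paired(y, yhat)
    if y.size < 2:
        raise ValueError("need at least 2 observations for SE")
    e = y - yhat
    b = float(e.mean())
    se = float(np.sqrt(np.sum((e - b) ** 2) / (e.size - 1)))
    return b, se


def improvement(rmsep: float, rmsep_other: float) -> float:
    """Improvement rate h in percent; positive when ``rmsep`` is smaller."""
    if rmsep_other <= 0:
        raise ValueError("rmsep_other must be positive")
    return (1.0 - rmsep / rmsep_other) * 100.0


def pearson_test(a, b) -> tuple[float, float]:
    """Sample Pearson r with the two-sided t-based significance test."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size or a.size < 3:
        raise ValueError("need paired vectors of equal length >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant input: correlation undefined")
    res = stats.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)


def one_sample_t(d, mu0: float = 0.0, alpha: float = 0.05) -> tuple[float, float, float]:
    """Two-sided one-sample t-test of ``mean(d) == mu0``.

    Returns ``(t, p, critical)`` where ``critical`` is the two-sided
    rejection quantile at ``alpha`` with ``n-1`` degrees of freedom.
    """
    d = np.asarray(d, dtype=float).ravel()
    if d.size < 2:
        raise ValueError("need at least 2 observations")
    if np.ptp(d) == 0 and d.size > 1 and np.std(d, ddof=1) == 0:
        if d[0] == mu0:
            # zero statistic by convention; p = 1
            crit = float(stats.t.ppf(1 - alpha / 2, d.size - 1))
            return 0.0, 1.0, crit
        raise ValueError("zero variance with nonzero mean offset: t undefined")
    res = stats.ttest_1samp(d, mu0)
    crit = float(stats.t.ppf(1 - alpha / 2, d.size - 1))
    return float(res.statistic), float(res.pvalue), crit


def _wilcoxon_exact_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p by enumerating the 2^n sign assignments.

    Ranks must be tie-free integers; the null distribution of W+ is built
    by the standard generating-polynomial recursion (equivalent to full
    enumeration but O(n * sum(ranks)))."""
    total = int(ranks.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks.astype(int):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w = int(round(w_plus))
    p_le = counts[: w + 1].sum()
    p_ge = counts[w:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(a, b, mode: str = "auto") -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped; the statistic is W+, the rank sum of
    positive differences.  ``mode='exact'`` enumerates the tie-free null
    distribution (n <= 25); ``mode='normal'`` uses the tie-corrected
    normal approximation without continuity correction; ``'auto'`` picks
    exact when valid.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n < 5:
        raise ValueError(
            f"need >= 5 nonzero differences, got {n} (all-zero or tiny sample)"
        )
    absd = np.abs(d)
    ranks = stats.rankdata(absd)
    has_ties = np.unique(absd).size < n
    w_plus = float(ranks[d > 0].sum())

    if mode == "auto":
        mode = "exact" if (n <= 25 and not has_ties) else "normal"
    if mode == "exact":
        if has_ties:
            raise ValueError("exact mode requires tie-free absolute differences")
        return w_plus, _wilcoxon_exact_p(ranks, w_plus)
    if mode == "normal":
        mean = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        # tie correction: subtract sum(t^3 - t)/48 over tie groups
        _, tie_counts = np.unique(absd, return_counts=True)
        var -= float(np.sum(tie_counts**3 - tie_counts)) / 48.0
        if var <= 0:
            raise ValueError("degenerate variance in normal approximation")
        z = (w_plus - mean) / math.sqrt(var)
        return w_plus, float(2.0 * stats.norm.sf(abs(z)))
    raise ValueError(f"unknown mode {mode!r}")


def evaluate_transfer(
    y_true,
    predictions: dict,
    reference_method: str,
    *,
    alpha: float = 0.05,
    wilcoxon_mode: str = "auto",
) -> dict:
    """Full per-method evaluation against a designated reference method.

    For each method: RMSE, bias, SE, Pearson correlation of predictions
    with the truth, a one-sample t-test of zero mean residual, and —
    versus the reference method — the Wilcoxon signed-rank test on paired
    absolute residuals and the RMSEP improvement rate h.

    Returns ``{method: EvaluationReport}``.
    """
    y_true = np.asarray(y_true, dtype=float).ravel()
    if reference_method not in predictions:
        raise KeyError(f"reference method {reference_method!r} not in predictions")
    resid = {m: y_true - np.asarray(p, dtype=float).ravel() for m, p in predictions.items()}
    rmses = {m: rmse(y_true, predictions[m]) for m in predictions}
    reports = {}
    for m, pred in predictions.items():
        b, se = bias_se(y_true, pred)
        r, rp = pearson_test(y_true, pred)
        t, tp, tc = one_sample_t(resid[m], 0.0, alpha)
        w_stat = w_p = None
        degenerate = False
        if m != reference_method:
            try:
                w_stat, w_p = wilcoxon_signed_rank(
                    np.abs(resid[reference_method]), np.abs(resid[m]), wilcoxon_mode
                )
            except ValueError:
                degenerate = True
        else:
            degenerate = True
        h_vs = {
            other: improvement(rmses[m], rmses[other])
            for other in predictions
            if other != m and rmses[other] > 0
        }
        reports[m] = EvaluationReport(
            method=m,
            rmse=rmses[m],
            bias=b,
            se=se,
            pearson_r=r,
            pearson_p=rp,
            t_stat=t,
            t_p=tp,
            t_critical=tc,
            wilcoxon_stat=w_stat,
            wilcoxon_p=w_p,
            wilcoxon_degenerate=degenerate,
            h_vs=h_vs,
        )
    return reports
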
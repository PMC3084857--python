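"""ROC curves, DeLong AUC inference, and analytic AUC from exact score laws.

The AUC is always the Mann-Whitney functional P(S_case > S_control) +
½P(S_case = S_control); ties carry half weight throughout (the count score is
integer-valued, so ties are common and material).  Standard errors and the
paired comparison of two correlated AUCs computed on the same subjects use
the DeLong structural-component estimator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .grs import ScoreDistribution

__all__ = ["RocCurve", "AucComparison", "empirical_auc", "delong_paired_test", "analytic_auc"]

_Z95 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC curve with DeLong AUC standard error."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    auc_se: float
    n_case: int
    n_control: int

    @property
    def auc_ci(self) -> tuple[float, float]:
        """Wald 95% CI on the DeLong SE, clipped to [0, 1]."""
        return (
            float(max(self.auc - _Z95 * self.auc_se, 0.0)),
            float(min(self.auc + _Z95 * self.auc_se, 1.0)),
        )


@dataclass(frozen=True)
class AucComparison:
    """Paired DeLong comparison of two AUCs on the same subjects."""

    auc_a: float
    auc_b: float
    difference: float
    variance: float  # Var(AUC_a − AUC_b), paired
    z: float
    p_value: float


def _split(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    if labels.dtype.kind in "OUS":
        is_case = labels == "case"
    else:
        is_case = labels.astype(bool)
    cases = scores[is_case]
    controls = scores[~is_case]
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("both classes must be present")
    return cases, controls


def _delong_components(cases: np.ndarray, controls: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and per-subject structural components (V10 per case, V01 per control).

    V10_i = mean_j ψ(x_i, y_j), V01_j = mean_i ψ(x_i, y_j) with ψ = 1, ½, 0
    for x>y, x=y, x<y.  Computed via midranks in O((m+n)log(m+n)).
    """
    m, n = len(cases), len(controls)
    combined = np.concatenate([cases, controls])
    rank_all = stats.rankdata(combined)  # midranks
    rank_cases = stats.rankdata(cases)
    rank_controls = stats.rankdata(controls)
    v10 = (rank_all[:m] - rank_cases) / n
    v01 = 1.0 - (rank_all[m:] - rank_controls) / m
    auc = float(v10.mean())
    return auc, v10, v01


def empirical_auc(scores: Sequence[float], labels: Sequence) -> RocCurve:
    """Empirical ROC curve and Mann-Whitney AUC with DeLong standard error."""
    s = np.asarray(scores, float)
    cases, controls = _split(s, np.asarray(labels))
    auc, v10, v01 = _delong_components(cases, controls)
    m, n = len(cases), len(controls)
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    y = np.concatenate([np.ones(m), np.zeros(n)])
    fpr, tpr, thresholds = _sk_roc_curve(y, np.concatenate([cases, controls]))
    return RocCurve(
        thresholds=thresholds,
        tpr=tpr,
        fpr=fpr,
        auc=auc,
        auc_se=float(np.sqrt(var)),
        n_case=m,
        n_control=n,
    )


def delong_paired_test(
    scores_a: Sequence[float], scores_b: Sequence[float], labels: Sequence
) -> AucComparison:
    """DeLong test for the difference of two correlated AUCs.

    Both score vectors must be computed on the same subjects in the same
    order.  Returns the paired variance of the AUC difference and a two-sided
    normal p-value; identical rankings give difference 0 and p = 1.
    """
    a = np.asarray(scores_a, float)
    b = np.asarray(scores_b, float)
    lab = np.asarray(labels)
    if a.shape != b.shape or a.shape[0] != lab.shape[0]:
        raise ValueError("scores_a, scores_b and labels must have equal length")
    ca, ka = _split(a, lab)
    cb, kb = _split(b, lab)
    auc_a, v10_a, v01_a = _delong_components(ca, ka)
    auc_b, v10_b, v01_b = _delong_components(cb, kb)
    m, n = len(ca), len(ka)
    # paired covariance of the two AUC estimators
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = float(cov[0, 0] + cov[1, 1] - 2 * cov[0, 1])
    diff = auc_a - auc_b
    if abs(diff) < 1e-15:
        z, p = 0.0, 1.0  # identical up to monotone transform
    elif var_diff <= 0:
        z, p = float(np.sign(diff)) * np.inf, 0.0
    else:
        z = diff / np.sqrt(var_diff)
        p = float(2 * stats.norm.sf(abs(z)))
    return AucComparison(auc_a, auc_b, diff, var_diff, float(z), float(min(p, 1.0)))


def analytic_auc(dist_case: ScoreDistribution, dist_control: ScoreDistribution) -> float:
    """Exact AUC between two finite score laws.

    P(S_case > S_control) + ½P(S_case = S_control) by summation over the
    product of supports (support points equal within 1e-9 count as ties).
    """
    for d in (dist_case, dist_control):
        if abs(d.mass.sum() - 1.0) > 1e-9:
            raise ValueError("distribution masses must sum to 1")
    sc, pc = dist_case.support, dist_case.mass
    sk, pk = dist_control.support, dist_control.mass
    cdf = np.cumsum(pk)
    lo = np.searchsorted(sk, sc - 1e-9, side="left")
    hi = np.searchsorted(sk, sc + 1e-9, side="right")
    below = np.where(lo > 0, cdf[np.maximum(lo - 1, 0)], 0.0)
    at = np.where(hi > lo, cdf[np.maximum(hi - 1, 0)] - below, 0.0)
    return float(pc @ (below + 0.5 * at))
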
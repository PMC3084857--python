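"""Case-control association statistics for risk scores and panel SNPs.

Logistic models (per-SNP additive trend, quartile indicators, subphenotype,
pairwise interaction) are maximum-likelihood fits via statsmodels with Wald
odds ratios, 95% CIs and two-sided p-values, optionally adjusted for an
arbitrary covariate matrix (typically sex plus ancestry principal
components).  The Cochran-Armitage trend test and the tie-corrected
Mann-Whitney comparison follow their textbook forms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .data_io import MISSING, GenotypeMatrix

__all__ = [
    "AssocResult",
    "QuartileAssoc",
    "additive_logistic",
    "quartile_or",
    "cochran_armitage_trend",
    "mann_whitney",
    "subphenotype_assoc",
    "pairwise_interactions",
]

_Z95 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class AssocResult:
    """One logistic-regression term: OR with Wald 95% CI and p-value."""

    term: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    beta: float
    se: float
    model: str
    n: int
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class QuartileAssoc:
    """Quartile odds ratios vs the first quartile plus the trend test."""

    quartile_results: list  # AssocResult per quartile; Q1 is the reference
    trend_z: float
    trend_p: float
    counts: pd.DataFrame  # status × quartile counts
    flags: tuple[str, ...] = ()


def _design(
    main: np.ndarray,
    covariates: np.ndarray | None,
    sex: np.ndarray | None,
    names: list[str],
) -> tuple[np.ndarray, list[str]]:
    main = np.asarray(main, float)
    main_cols = [main] if main.ndim == 1 else [main[:, k] for k in range(main.shape[1])]
    cols = [np.ones(len(main)), *main_cols]
    out_names = ["const", *names]
    if sex is not None:
        sex = np.asarray(sex)
        if sex.dtype.kind in "OUS":
            sex = (sex == "male").astype(float)
        cols.append(sex.astype(float))
        out_names.append("sex")
    if covariates is not None and np.size(covariates):
        cov = np.atleast_2d(np.asarray(covariates, float))
        if cov.shape[0] != len(main):
            cov = cov.T
        for k in range(cov.shape[1]):
            cols.append(cov[:, k])
            out_names.append(f"cov_{k + 1}")
    return np.column_stack(cols), out_names


def _fit_logit(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """ML logistic fit returning (beta, se, flags); separation is flagged."""
    flags: list[str] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            beta, se = np.asarray(res.params, float), np.asarray(res.bse, float)
            if not res.mle_retvals.get("converged", True):
                flags.append("non_convergent")
        except Exception:  # perfect separation or singular design
            beta = np.full(X.shape[1], np.nan)
            se = np.full(X.shape[1], np.inf)
            flags.append("separation")
    if np.any(~np.isfinite(se)) or np.any(np.abs(beta) > 25):
        flags.append("unstable")
        se = np.where(np.isfinite(se), se, np.inf)
    return beta, se, tuple(flags)


def _term_result(
    term: str, beta: float, se: float, model: str, n: int, flags: tuple[str, ...]
) -> AssocResult:
    if np.isfinite(se) and se > 0:
        p = 2 * stats.norm.sf(abs(beta / se))
        lo, hi = np.exp(beta - _Z95 * se), np.exp(beta + _Z95 * se)
    else:
        p, lo, hi = 1.0, 0.0, np.inf
    return AssocResult(
        term=term,
        odds_ratio=float(np.exp(beta)) if np.isfinite(beta) else np.nan,
        ci_low=float(lo),
        ci_high=float(hi),
        p_value=float(max(min(p, 1.0), np.nextafter(0, 1))),
        beta=float(beta),
        se=float(se),
        model=model,
        n=n,
        flags=flags,
    )


def _as_binary_status(status: Sequence) -> np.ndarray:
    s = np.asarray(status)
    if s.dtype.kind in "OUS":
        return (s == "case").astype(float)
    return s.astype(float)


def additive_logistic(
    dosage: Sequence[int],
    status: Sequence,
    covariates: np.ndarray | None = None,
    sex: Sequence | None = None,
) -> AssocResult:
    """Per-allele additive logistic association of one SNP with case status.

    Dosage enters as a numeric trend term; the returned OR is the per-allele
    odds ratio exp(β) with Wald CI and two-sided p.  Perfect separation is
    reported via an infinite-CI sentinel rather than an exception.
    """
    d = np.asarray(dosage, float)
    y = _as_binary_status(status)
    if (d == MISSING).any() or np.isnan(d).any():
        keep = (d != MISSING) & ~np.isnan(d)
        d, y = d[keep], y[keep]
        if covariates is not None:
            covariates = np.atleast_2d(np.asarray(covariates, float))[keep]
        if sex is not None:
            sex = np.asarray(sex)[keep]
    if len(np.unique(d)) < 2:
        raise ValueError("dosage has no variation")
    if min((y == 1).sum(), (y == 0).sum()) < 2:
        raise ValueError("need at least 2 subjects per status")
    X, names = _design(d, covariates, sex, ["dosage"])
    beta, se, flags = _fit_logit(y, X)
    model = "status ~ dosage" + (" + sex" if sex is not None else "") + (
        " + covariates" if covariates is not None and np.size(covariates) else ""
    )
    return _term_result("dosage", beta[1], se[1], model, len(y), flags)


def cochran_armitage_trend(
    counts: np.ndarray, scores: Sequence[float] | None = None
) -> tuple[float, float]:
    """Cochran-Armitage trend test on a 2×k table (row 1 = cases).

    With column scores s_j (default 1..k), the statistic is
    z = Σ s_j (a_j − n_j R/N) / sqrt((R/N)(1−R/N)(Σ s_j² n_j − (Σ s_j n_j)²/N))
    where a_j are case counts, n_j column totals, R total cases, N the grand
    total.  Returns (z, two-sided p).
    """
    tab = np.asarray(counts, float)
    if tab.ndim != 2 or tab.shape[0] != 2 or tab.shape[1] < 2:
        raise ValueError("counts must be a 2×k table with k ≥ 2")
    if (tab < 0).any():
        raise ValueError("counts must be nonnegative")
    n_j = tab.sum(axis=0)
    if (n_j == 0).any() or tab.sum(axis=1).min() == 0:
        raise ValueError("table has a zero margin")
    s = np.arange(1, tab.shape[1] + 1, dtype=float) if scores is None else np.asarray(
        scores, float
    )
    a_j = tab[0]
    N = tab.sum()
    R = a_j.sum()
    num = float(s @ (a_j - n_j * R / N))
    var = (R / N) * (1 - R / N) * float(s**2 @ n_j - (s @ n_j) ** 2 / N)
    if var <= 0:
        return 0.0, 1.0
    z = num / np.sqrt(var)
    return float(z), float(2 * stats.norm.sf(abs(z)))


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney comparison of two samples.

    Exact enumeration when min(n, m) ≤ 8; otherwise the tie-corrected normal
    approximation.  Returns (U for the first sample, p).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    if np.unique(np.concatenate([x, y])).size == 1:
        return float(len(x) * len(y) / 2), 1.0  # all values identical
    method = "exact" if min(len(x), len(y)) <= 8 else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def quartile_or(
    quartiles: Sequence[int],
    status: Sequence,
    covariates: np.ndarray | None = None,
    sex: Sequence | None = None,
) -> QuartileAssoc:
    """Quartile odds ratios relative to Q1 plus the Cochran-Armitage trend.

    Fits status ~ I(Q2) + I(Q3) + I(Q4) [+ sex + covariates]; the trend test
    runs on the unadjusted status × quartile counts with scores 1..4.
    """
    q = np.asarray(quartiles, int)
    y = _as_binary_status(status)
    flags: list[str] = []
    counts = pd.crosstab(pd.Series(y, name="case"), pd.Series(q, name="quartile"))
    for level in range(1, 5):
        if level not in counts.columns or (counts.get(level, pd.Series([0])) == 0).any():
            flags.append(f"empty_cell_Q{level}")
    dummies = np.column_stack([(q == k).astype(float) for k in (2, 3, 4)])
    X, _ = _design(dummies, covariates, sex, ["Q2", "Q3", "Q4"])
    beta, se, fit_flags = _fit_logit(y, X)
    flags.extend(fit_flags)
    model = "status ~ quartile indicators (Q1 ref)"
    results = [
        AssocResult("Q1", 1.0, 1.0, 1.0, 1.0, 0.0, 0.0, model, int((q == 1).sum()), ())
    ]
    for i, name in enumerate(("Q2", "Q3", "Q4")):
        results.append(
            _term_result(name, beta[1 + i], se[1 + i], model, int((q == i + 2).sum()), tuple(flags))
        )
    table = np.vstack(
        [[(y[q == k] == 1).sum() for k in (1, 2, 3, 4)],
         [(y[q == k] == 0).sum() for k in (1, 2, 3, 4)]]
    )
    z, p = cochran_armitage_trend(table)
    return QuartileAssoc(results, z, p, counts, tuple(flags))


def subphenotype_assoc(
    wgrs: Sequence[float],
    subpheno: Sequence,
    covariates: np.ndarray | None = None,
    sex: Sequence | None = None,
    per_sd: bool = False,
    test_level: str | None = None,
) -> AssocResult:
    """Association of the weighted score with a binary subphenotype (cases only).

    Fits subphenotype ~ wGRS [+ sex + covariates]; the OR is per wGRS unit by
    default, or per sample SD of the score when ``per_sd`` is set.  For string
    labels the modelled (non-reference) level is the lexically larger one
    unless ``test_level`` names it.  Fewer than 10 subjects in either class
    flags the result as low-power.
    """
    g = np.asarray(wgrs, float)
    lab = np.asarray(subpheno)
    if lab.dtype.kind in "OUS":
        levels = pd.unique(lab[~pd.isna(lab)])
        if len(levels) < 2:
            raise ValueError("subphenotype has no variation")
        if len(levels) > 2:
            raise ValueError(f"subphenotype must be binary, got levels {levels}")
        levels = np.sort(levels)
        if test_level is not None:
            if test_level not in levels:
                raise ValueError(f"test_level {test_level!r} not among {levels}")
            levels = np.array([l for l in levels if l != test_level] + [test_level])
        y = (lab == levels[1]).astype(float)
        term = str(levels[1])
    else:
        y = lab.astype(float)
        term = "subphenotype"
    if len(np.unique(y)) < 2:
        raise ValueError("subphenotype has no variation")
    scale = np.std(g, ddof=1) if per_sd else 1.0
    X, _ = _design(g / scale, covariates, sex, ["wgrs"])
    beta, se, flags = _fit_logit(y, X)
    if min((y == 1).sum(), (y == 0).sum()) < 10:
        flags = flags + ("low_power",)
    unit = "per-SD" if per_sd else "per-unit"
    return _term_result(term, beta[1], se[1], f"subpheno ~ wgrs ({unit})", len(y), flags)


def pairwise_interactions(
    gm: GenotypeMatrix,
    status: Sequence,
    covariates: np.ndarray | None = None,
    sex: Sequence | None = None,
    case_only: bool = False,
) -> pd.DataFrame:
    """Product-term logistic interaction scan over all SNP pairs.

    For each of the C(K,2) pairs fits status ~ dᵢ + dⱼ + dᵢ·dⱼ [+ adjustments]
    and reports the interaction Wald p with Bonferroni adjustment over the
    number of pairs.  With ``case_only``, status is instead a binary
    subphenotype and only case rows should be supplied.  Non-convergent pairs
    are flagged and excluded from min-p summaries by their NaN p-values.
    """
    if gm.n_snps < 2:
        raise ValueError("need at least 2 SNPs for an interaction scan")
    y = _as_binary_status(status)
    d = gm.dosage.astype(float)
    d[gm.missing_mask] = np.nan
    pairs = list(combinations(range(gm.n_snps), 2))
    m = len(pairs)
    rows = []
    for i, j in pairs:
        di, dj = d[:, i], d[:, j]
        keep = ~np.isnan(di) & ~np.isnan(dj)
        cov = None
        if covariates is not None and np.size(covariates):
            cov = np.atleast_2d(np.asarray(covariates, float))[keep]
        sx = np.asarray(sex)[keep] if sex is not None else None
        main = np.column_stack([di[keep], dj[keep], di[keep] * dj[keep]])
        X, _ = _design(main, cov, sx, ["d_i", "d_j", "d_ixd_j"])
        beta, se, flags = _fit_logit(y[keep], X)
        ok = np.isfinite(se[3]) and se[3] > 0 and "separation" not in flags
        p = 2 * stats.norm.sf(abs(beta[3] / se[3])) if ok else np.nan
        rows.append(
            {
                "snp_i": gm.snp_ids[i],
                "snp_j": gm.snp_ids[j],
                "beta_int": beta[3],
                "se_int": se[3],
                "p_int": p,
                "p_bonferroni": min(p * m, 1.0) if np.isfinite(p) else np.nan,
                "converged": ok and "non_convergent" not in flags,
                "n": int(keep.sum()),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["n_tests"] = m
    out.attrs["case_only"] = case_only
    return out
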
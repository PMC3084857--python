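"""Count and weighted genetic risk scores, quartiles, and exact score laws.

The count score (cGRS) is the number of risk alleles carried across the panel;
the weighted score (wGRS) weights each risk allele by the natural log of its
per-allele odds ratio, so a subject's wGRS is Σ_i d_i·ln(OR_i) over dosages
d_i ∈ {0,1,2}.  Subjects with any missing genotype are excluded from scoring
(complete-case rule) rather than rescaled.

``exact_score_distribution`` enumerates the full probability mass of either
score under Hardy-Weinberg genotype frequencies and between-SNP independence,
giving closed-form population distributions against which empirical results
can be checked analytically.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .data_io import MISSING, GenotypeMatrix, SnpPanel

__all__ = [
    "snp_weight",
    "count_grs",
    "weighted_grs",
    "complete_case_filter",
    "score_table",
    "assign_quartiles",
    "ScoreDistribution",
    "exact_score_distribution",
    "expected_score",
]

ScoreKind = Literal["cgrs", "wgrs"]

#: enumeration limit: 3^K genotype states
_MAX_ENUM_SNPS = 12
#: scores closer than this are merged into one support point
_MERGE_TOL = 1e-12


def snp_weight(odds_ratio: float) -> float:
    """Score weight of a SNP: the natural log of its per-allele odds ratio.

    A dosage-2 (homozygous risk) genotype at OR 1.59 therefore contributes
    2·ln(1.59) ≈ 0.927 to the weighted score.
    """
    if odds_ratio <= 0:
        raise ValueError(f"odds_ratio must be > 0, got {odds_ratio}")
    return math.log(odds_ratio)


def _check_complete(dosages: np.ndarray) -> np.ndarray:
    d = np.asarray(dosages)
    if (d == MISSING).any() or np.isnan(d.astype(float)).any():
        raise ValueError("incomplete subject: missing dosages are not scored")
    if not np.isin(d, [0, 1, 2]).all():
        raise ValueError("dosages must be 0, 1 or 2")
    return d


def count_grs(dosages: Sequence[int]) -> int:
    """Risk-allele count across the panel (complete dosage vector required)."""
    return int(_check_complete(np.asarray(dosages)).sum())


def weighted_grs(dosages: Sequence[int], panel: SnpPanel) -> float:
    """Weighted score Σ dᵢ·ln(ORᵢ) for a complete dosage vector."""
    d = _check_complete(np.asarray(dosages))
    if d.shape[-1] != panel.n_snps:
        raise ValueError(f"dosage length {d.shape[-1]} != panel size {panel.n_snps}")
    return float(d @ panel.weights)


def complete_case_filter(gm: GenotypeMatrix) -> tuple[GenotypeMatrix, int]:
    """Drop every subject with one or more missing dosages.

    Returns the reduced matrix and the number of subjects removed.  An empty
    result is allowed (with a warning); missing data are never imputed.
    """
    keep = gm.complete_mask
    n_removed = int((~keep).sum())
    if keep.sum() == 0:
        warnings.warn("complete-case filter removed every subject", stacklevel=2)
    return gm.take_subjects(np.where(keep)[0]), n_removed


def score_table(gm: GenotypeMatrix, panel: SnpPanel) -> pd.DataFrame:
    """Per-subject scores: columns subject_id, cgrs, wgrs, complete.

    Incomplete subjects keep their row with ``complete=False`` and NaN scores.
    """
    if list(gm.snp_ids) != panel.snp_ids:
        raise ValueError("genotype matrix SNP order does not match panel")
    complete = gm.complete_mask
    d = gm.dosage.astype(float)
    d[gm.missing_mask] = np.nan
    cgrs = np.where(complete, np.nansum(d, axis=1), np.nan)
    wgrs = np.where(complete, np.nansum(d * panel.weights, axis=1), np.nan)
    return pd.DataFrame(
        {
            "subject_id": gm.subject_ids,
            "cgrs": cgrs,
            "wgrs": wgrs,
            "complete": complete,
        }
    )


def assign_quartiles(scores: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Quartile labels 1..4 with the 25/50/75 empirical-percentile boundaries.

    Boundaries are percentiles of the pooled analyzed sample; a score equal to
    a boundary goes to the lower quartile.  Requires ≥4 distinct values.
    """
    s = np.asarray(scores, dtype=float)
    if np.isnan(s).any():
        raise ValueError("scores contain NaN; filter incomplete subjects first")
    if len(np.unique(s)) < 4:
        raise ValueError("need at least 4 distinct score values to form quartiles")
    boundaries = np.percentile(s, [25, 50, 75])
    labels = 1 + (s[:, None] > boundaries[None, :]).sum(axis=1)
    return labels.astype(int), boundaries


@dataclass(frozen=True)
class ScoreDistribution:
    """Exact probability mass of a score over its finite support."""

    support: np.ndarray
    mass: np.ndarray
    score_kind: str

    def __post_init__(self) -> None:
        s = np.asarray(self.support, float)
        m = np.asarray(self.mass, float)
        if s.shape != m.shape:
            raise ValueError("support and mass must have equal length")
        if (m < -_MERGE_TOL).any():
            raise ValueError("negative probability mass")
        if abs(m.sum() - 1.0) > 1e-9:
            raise ValueError(f"masses sum to {m.sum()}, not 1")
        if (np.diff(s) <= 0).any():
            raise ValueError("support must be strictly increasing")
        object.__setattr__(self, "support", s)
        object.__setattr__(self, "mass", m)

    @property
    def mean(self) -> float:
        return float(self.support @ self.mass)

    @property
    def var(self) -> float:
        return float((self.support**2) @ self.mass - self.mean**2)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.choice(self.support, size=n, p=self.mass)


def _convolve_dosage(
    support: np.ndarray, mass: np.ndarray, weight: float, freq: float
) -> tuple[np.ndarray, np.ndarray]:
    """Convolve a score law with one SNP's dosage law Binomial(2, freq)·weight."""
    probs = np.array([(1 - freq) ** 2, 2 * freq * (1 - freq), freq**2])
    s = (support[:, None] + weight * np.arange(3)[None, :]).ravel()
    m = (mass[:, None] * probs[None, :]).ravel()
    order = np.argsort(s, kind="stable")
    s, m = s[order], m[order]
    # merge support points equal within tolerance
    new_group = np.concatenate([[True], np.diff(s) > _MERGE_TOL])
    idx = np.cumsum(new_group) - 1
    out_s = s[new_group]
    out_m = np.zeros(len(out_s))
    np.add.at(out_m, idx, m)
    return out_s, out_m


def exact_score_distribution(
    freqs: Sequence[float], panel: SnpPanel, score_kind: ScoreKind = "wgrs"
) -> ScoreDistribution:
    """Exact score law under HWE and SNP independence at the given frequencies.

    Each SNP's dosage is Binomial(2, freq); the score is the weighted (wgrs)
    or unweighted (cgrs) dosage sum.  Full 3^K enumeration via sequential
    convolution; K ≤ 12.
    """
    f = np.asarray(freqs, float)
    if f.shape != (panel.n_snps,):
        raise ValueError("one frequency per panel SNP required")
    if ((f < 0) | (f > 1)).any():
        raise ValueError("frequencies must lie in [0, 1]")
    if panel.n_snps > _MAX_ENUM_SNPS:
        raise ValueError(
            f"{panel.n_snps} SNPs exceeds the 3^{_MAX_ENUM_SNPS} enumeration "
            "limit; use the simulation mode instead"
        )
    weights = panel.weights if score_kind == "wgrs" else np.ones(panel.n_snps)
    support = np.zeros(1)
    mass = np.ones(1)
    for q, w in zip(f, weights):
        support, mass = _convolve_dosage(support, mass, w, q)
    mass = mass / mass.sum()
    return ScoreDistribution(support, mass, score_kind)


def expected_score(
    freqs: Sequence[float], panel: SnpPanel, score_kind: ScoreKind = "wgrs"
) -> float:
    """Population mean score: 2·Σ freqᵢ·wᵢ (wgrs) or 2·Σ freqᵢ (cgrs)."""
    f = np.asarray(freqs, float)
    if f.shape != (panel.n_snps,):
        raise ValueError("one frequency per panel SNP required")
    w = panel.weights if score_kind == "wgrs" else np.ones(panel.n_snps)
    return float(2.0 * f @ w)
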
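"""Liability-threshold estimates of genetic variance explained per SNP.

Disease is modelled as a latent standard-normal liability exceeding a
threshold set by population prevalence K.  For a biallelic SNP with control
(≈ population) risk-allele frequency q and per-allele odds ratio OR, genotype
frequencies follow HWE, genotype relative risks are (1, OR, OR²), and the
baseline penetrance is solved so that Σ f_g·pen_g = K.  Each genotype's
penetrance maps to a liability threshold t_g = Φ⁻¹(1−pen_g); relative to the
population threshold T = Φ⁻¹(1−K), the genotype mean liabilities are
μ_g = T − t_g, and the variance explained is the between-genotype variance
Σ f_g μ_g² − (Σ f_g μ_g)².  Totals over a panel assume independent loci.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data_io import SnpPanel

__all__ = [
    "LiabilityResult",
    "genotype_penetrances",
    "snp_liability",
    "variance_explained",
    "total_variance_explained",
]


def _validate(q: float, odds_ratio: float, prevalence: float) -> None:
    if not 0.0 < q < 1.0:
        raise ValueError(f"control frequency must be in (0, 1), got {q}")
    if odds_ratio <= 0:
        raise ValueError(f"odds_ratio must be > 0, got {odds_ratio}")
    if not 0.0 < prevalence < 1.0:
        raise ValueError(f"prevalence must be in (0, 1), got {prevalence}")


def genotype_penetrances(
    q: float, odds_ratio: float, prevalence: float
) -> tuple[float, float, float]:
    """Penetrances (pen_0, pen_1, pen_2) for dosages 0/1/2.

    Multiplicative genotype relative risks (1, OR, OR²) with the baseline
    solved in closed form from prevalence conservation:
    pen_0 = K / (f_0 + f_1·OR + f_2·OR²) under HWE frequencies from q.
    """
    _validate(q, odds_ratio, prevalence)
    f = np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
    rr = np.array([1.0, odds_ratio, odds_ratio**2])
    pen0 = prevalence / float(f @ rr)
    pens = pen0 * rr
    if (pens >= 1.0).any() or (pens <= 0.0).any():
        raise ValueError(
            f"model inconsistent (OR {odds_ratio} too large for prevalence "
            f"{prevalence}): penetrance outside (0, 1)"
        )
    return tuple(float(p) for p in pens)


@dataclass(frozen=True)
class LiabilityResult:
    """Per-SNP liability-threshold decomposition."""

    snp_id: str
    prevalence: float
    control_freq: float
    genotype_freqs: np.ndarray
    penetrances: np.ndarray
    thresholds: np.ndarray  # t_g = Φ⁻¹(1 − pen_g)
    population_threshold: float  # T = Φ⁻¹(1 − K)
    liability_means: np.ndarray  # μ_g = T − t_g
    variance_explained: float


def snp_liability(
    q: float, odds_ratio: float, prevalence: float, snp_id: str = ""
) -> LiabilityResult:
    """Full liability-threshold decomposition for one SNP."""
    pens = np.array(genotype_penetrances(q, odds_ratio, prevalence))
    f = np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
    t = norm.isf(pens)
    T = norm.isf(prevalence)
    mu = T - t
    var = float(f @ mu**2 - (f @ mu) ** 2)
    return LiabilityResult(
        snp_id=snp_id,
        prevalence=prevalence,
        control_freq=q,
        genotype_freqs=f,
        penetrances=pens,
        thresholds=t,
        population_threshold=float(T),
        liability_means=mu,
        variance_explained=var,
    )


def variance_explained(q: float, odds_ratio: float, prevalence: float) -> float:
    """Proportion of liability variance explained by one SNP."""
    return snp_liability(q, odds_ratio, prevalence).variance_explained


def total_variance_explained(
    panel: SnpPanel, prevalence: float = 0.025
) -> tuple[float, pd.DataFrame]:
    """Sum of per-SNP liability variances over a panel (independent loci).

    Returns the total and a per-SNP breakdown table mirroring the panel order,
    with penetrances and thresholds alongside the variance explained.
    """
    rows = []
    for snp, gene, q, odds in zip(
        panel.snp_ids,
        panel.table["gene"],
        panel.control_freqs,
        panel.odds_ratios,
    ):
        res = snp_liability(q, odds, prevalence, snp_id=snp)
        rows.append(
            {
                "snp_id": snp,
                "gene": gene,
                "control_freq": q,
                "odds_ratio": odds,
                "pen_0": res.penetrances[0],
                "pen_1": res.penetrances[1],
                "pen_2": res.penetrances[2],
                "t_0": res.thresholds[0],
                "t_1": res.thresholds[1],
                "t_2": res.thresholds[2],
                "variance_explained": res.variance_explained,
            }
        )
    table = pd.DataFrame(rows)
    return float(table["variance_explained"].sum()), table
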
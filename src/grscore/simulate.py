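"""Synthetic case-control and nuclear-family genotype data.

Two generating models share the panel's published frequencies:

* **frequency mode** draws each SNP's dosage Binomial(2, freq) with the case
  and control risk-allele frequencies directly — the distributional structure
  the analytic score laws assume, with no latent disease model.

* **liability mode** draws genotypes at population (control) frequencies and
  assigns disease when a latent liability Σ dᵢβᵢ + ε (ε standard normal)
  exceeds the prevalence threshold.  Each βᵢ is calibrated numerically so
  that the *marginal* per-allele case-control odds ratio — what an additive
  logistic fit on the simulated data estimates — equals the panel's odds
  ratio at the configured prevalence.  Parameter recovery is therefore a
  closed loop: analysing the synthetic data should return the panel.

Nuclear families draw parents from the population, transmit alleles by
Mendelian segregation, determine affection through the same liability model
(plus a shared-family residual component with the marginal variance kept at
1), and are ascertained for at least one affected sibling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import norm

from .data_io import MISSING, GenotypeMatrix, SnpPanel, SubjectTable

__all__ = [
    "SimConfig",
    "LiabilityEffects",
    "calibrate_liability_effects",
    "simulate_case_control",
    "simulate_families",
    "inject_missingness",
]


@dataclass(frozen=True)
class SimConfig:
    """Generating conditions for synthetic case-control and family data.

    Defaults mirror the study being emulated: 724/1995 analyzed cases and
    controls, 2.5% prevalence, 281 ascertained families with sibship
    affected/unaffected means 2.32/1.24, four null ancestry covariates and a
    balanced sex ratio.
    """

    panel: SnpPanel
    mode: Literal["frequency", "liability"] = "liability"
    n_case: int = 724
    n_control: int = 1995
    prevalence: float = 0.025
    n_families: int = 281
    sibship_affected_mean: float = 2.32
    sibship_unaffected_mean: float = 1.24
    family_shared_var: float = 0.3
    n_covariates: int = 4
    sex_ratio: float = 0.5
    stratification_shift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")
        if not 0 <= self.family_shared_var < 1:
            raise ValueError("family_shared_var must be in [0, 1)")
        if self.mode not in ("frequency", "liability"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class LiabilityEffects:
    """Calibrated per-SNP liability effects and the prevalence threshold."""

    betas: np.ndarray
    threshold: float
    prevalence: float


# ---------------------------------------------------------------------------
# liability-effect calibration


def _dosage_law(q: float, beta: float) -> tuple[np.ndarray, np.ndarray]:
    vals = beta * np.arange(3.0)
    probs = np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
    return vals, probs


def _convolve(a: tuple[np.ndarray, np.ndarray], b: tuple[np.ndarray, np.ndarray]):
    s = (a[0][:, None] + b[0][None, :]).ravel()
    p = (a[1][:, None] * b[1][None, :]).ravel()
    return s, p


def _compress(s: np.ndarray, p: np.ndarray, h: float = 2e-3):
    """Merge support points falling in the same width-h bin (mass-weighted mean).

    Keeps the enumerated liability-score laws small during calibration; the
    ≤ h/2 displacement per point is far below the calibration tolerance.
    """
    if len(s) <= 256:
        return s, p
    bins = np.round(s / h).astype(np.int64)
    uniq, idx = np.unique(bins, return_inverse=True)
    mass = np.bincount(idx, weights=p)
    mean = np.bincount(idx, weights=p * s) / mass
    return mean, mass


def _expected_logit_slope(f_g: np.ndarray, p_case_g: np.ndarray) -> float:
    """Slope of the population logistic fit of case status on dosage 0/1/2.

    Solves the expected score equations of the two-parameter logistic model
    on the three dosage support points by Newton iteration.
    """
    g = np.arange(3.0)
    # initialise from empirical log-odds of the outer genotypes
    eps = 1e-12
    lo = np.log((p_case_g + eps) / (1 - p_case_g + eps))
    a, b = lo[0], (lo[2] - lo[0]) / 2.0
    for _ in range(50):
        eta = a + b * g
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = f_g * mu * (1 - mu)
        grad = np.array([f_g @ (p_case_g - mu), (f_g * g) @ (p_case_g - mu)])
        hess = np.array([[w.sum(), w @ g], [w @ g, w @ g**2]])
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        a, b = a + step[0], b + step[1]
        if np.abs(step).max() < 1e-12:
            break
    return float(b)


def calibrate_liability_effects(
    panel: SnpPanel, prevalence: float = 0.025, tol: float = 1e-5, max_sweeps: int = 8
) -> LiabilityEffects:
    """Solve per-SNP liability effects reproducing the panel's marginal ORs.

    Iteratively (Jacobi sweeps over SNPs) root-finds each βᵢ so that, with
    all other SNPs at their current effects, the marginal additive-logistic
    per-allele OR at the given prevalence equals the panel OR.  The marginal
    distribution over the other SNPs is enumerated exactly (3^(K−1) states),
    so the calibration involves no simulation error.
    """
    K = panel.n_snps
    q = panel.control_freqs
    w = panel.weights
    betas = w.copy()  # ln(OR) is an adequate starting point

    for _ in range(max_sweeps):
        laws = [_dosage_law(q[i], betas[i]) for i in range(K)]
        prefix: list = [(np.zeros(1), np.ones(1))]
        for law in laws:
            prefix.append(_compress(*_convolve(prefix[-1], law)))
        suffix: list = [(np.zeros(1), np.ones(1))]
        for law in reversed(laws):
            suffix.append(_compress(*_convolve(suffix[-1], law)))
        suffix = suffix[::-1]

        new_betas = betas.copy()
        for i in range(K):
            s_rest, p_rest = _compress(*_convolve(prefix[i], suffix[i + 1]))
            f_g = _dosage_law(q[i], 1.0)[1]

            def slope_error(beta_i: float) -> float:
                # threshold conserving prevalence for this candidate effect
                def prev(T: float) -> float:
                    tail = norm.sf(T - s_rest[None, :] - beta_i * np.arange(3.0)[:, None])
                    return float(f_g @ (tail @ p_rest)) - prevalence

                T = optimize.brentq(prev, -15.0, 15.0 + abs(beta_i) * 2 + s_rest.max())
                tail = norm.sf(T - s_rest[None, :] - beta_i * np.arange(3.0)[:, None])
                p_case_g = tail @ p_rest
                return _expected_logit_slope(f_g, p_case_g) - w[i]

            lo = min(0.0, 1.8 * w[i]) - 0.05
            hi = max(0.0, 1.8 * w[i]) + 0.05
            while slope_error(lo) * slope_error(hi) > 0:
                lo, hi = lo - 0.5, hi + 0.5
                if hi - lo > 20:
                    raise RuntimeError(f"calibration bracket failed for SNP {i}")
            new_betas[i] = optimize.brentq(slope_error, lo, hi, xtol=1e-10)
        delta = np.abs(new_betas - betas).max()
        betas = new_betas
        if delta < tol:
            break

    # final threshold under the calibrated effects
    laws = [_dosage_law(q[i], betas[i]) for i in range(K)]
    full = (np.zeros(1), np.ones(1))
    for law in laws:
        full = _convolve(full, law)

    def prev_full(T: float) -> float:
        return float(norm.sf(T - full[0]) @ full[1]) - prevalence

    T = optimize.brentq(prev_full, -15.0, 15.0 + full[0].max())
    return LiabilityEffects(betas=betas, threshold=float(T), prevalence=prevalence)


# ---------------------------------------------------------------------------
# generators


def _hwe_dosages(rng: np.random.Generator, freqs: np.ndarray, n: int) -> np.ndarray:
    return rng.binomial(2, freqs[None, :], size=(n, len(freqs))).astype(np.int8)


def _subject_frame(
    ids: list[str],
    status: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    n = len(ids)
    sex = np.where(rng.random(n) < cfg.sex_ratio, "female", "male")
    df = pd.DataFrame({"subject_id": ids, "status": status, "sex": sex})
    stratum = rng.integers(0, 2, size=n)
    for k in range(cfg.n_covariates):
        df[f"cov_{k + 1}"] = rng.standard_normal(n) + cfg.stratification_shift * stratum
    # null subphenotypes for cases: independent of genotype by construction
    is_case = status == "case"
    age = np.round(np.clip(rng.normal(24.6, 15.5, size=n), 1, 90)).astype(float)
    df["age_onset"] = np.where(is_case, age, np.nan)
    df["family_history"] = np.where(
        is_case, np.where(rng.random(n) < 0.767, "yes", "no"), None
    )
    df["psoriasis_type"] = np.where(
        is_case, np.where(rng.random(n) < 0.8, "plaque", "guttate"), None
    )
    df["psa"] = np.where(is_case, np.where(rng.random(n) < 0.25, "yes", "no"), None)
    return df


def simulate_case_control(
    cfg: SimConfig, effects: LiabilityEffects | None = None
) -> tuple[GenotypeMatrix, SubjectTable]:
    """Generate an unrelated case-control dataset under the configured model.

    Frequency mode draws case and control genotypes at their respective panel
    frequencies.  Liability mode draws genotypes at population frequencies
    and samples until the case and control quotas are met; ``effects`` may be
    passed to reuse a previous calibration.
    """
    rng = np.random.default_rng(cfg.seed)
    panel = cfg.panel
    if cfg.mode == "frequency":
        case_d = _hwe_dosages(rng, panel.case_freqs, cfg.n_case)
        control_d = _hwe_dosages(rng, panel.control_freqs, cfg.n_control)
        dosage = np.vstack([case_d, control_d])
        status = np.array(["case"] * cfg.n_case + ["control"] * cfg.n_control)
    else:
        if effects is None:
            effects = calibrate_liability_effects(panel, cfg.prevalence)
        need_case, need_control = cfg.n_case, cfg.n_control
        exp_rate = min(cfg.prevalence, 1 - cfg.prevalence)
        if (max(need_case / cfg.prevalence, need_control / (1 - cfg.prevalence))) > 5e8:
            raise ValueError(
                "quota unreachable at this prevalence; reduce n_case/n_control "
                "or move prevalence away from the boundary"
            )
        cases, controls = [], []
        got_case = got_control = 0
        batch = int(min(5e5, max(1e4, 4 * need_case / exp_rate)))
        while got_case < need_case or got_control < need_control:
            d = _hwe_dosages(rng, panel.control_freqs, batch)
            liab = d @ effects.betas + rng.standard_normal(batch)
            aff = liab > effects.threshold
            if got_case < need_case:
                take = d[aff][: need_case - got_case]
                cases.append(take)
                got_case += len(take)
            if got_control < need_control:
                take = d[~aff][: need_control - got_control]
                controls.append(take)
                got_control += len(take)
        dosage = np.vstack([*cases, *controls])
        status = np.array(["case"] * cfg.n_case + ["control"] * cfg.n_control)

    ids = [f"S{i + 1:06d}" for i in range(len(status))]
    gm = GenotypeMatrix(np.array(ids, object), np.array(panel.snp_ids, object), dosage)
    st = SubjectTable(_subject_frame(ids, status, cfg, rng))
    return gm, st


def _truncated_poisson(rng: np.random.Generator, mean: float, minimum: int, size: int) -> np.ndarray:
    """Poisson draws resampled until ≥ minimum (left truncation)."""
    out = rng.poisson(mean, size=size)
    bad = out < minimum
    while bad.any():
        out[bad] = rng.poisson(mean, size=int(bad.sum()))
        bad = out < minimum
    return out


def simulate_families(
    cfg: SimConfig, effects: LiabilityEffects | None = None
) -> tuple[GenotypeMatrix, SubjectTable]:
    """Generate ascertained two-generation nuclear families.

    Parents are drawn from the population under HWE; each offspring receives
    one allele per SNP from each parent by Mendelian segregation.  Affection
    follows the liability model with a shared within-family residual
    component (variance ``family_shared_var``; individual residual variance
    reduced so the marginal liability stays standard normal).  Families are
    retained only when at least one offspring is affected.
    """
    if effects is None:
        effects = calibrate_liability_effects(cfg.panel, cfg.prevalence)
    rng = np.random.default_rng(cfg.seed)
    panel = cfg.panel
    freqs = panel.control_freqs
    sig_f = np.sqrt(cfg.family_shared_var)
    sig_e = np.sqrt(1.0 - cfg.family_shared_var)

    rows_dosage: list[np.ndarray] = []
    rows_meta: list[dict] = []
    accepted = 0
    attempts = 0
    counter = 0
    while accepted < cfg.n_families:
        attempts += 1
        if attempts > 10000 and accepted == 0:
            raise RuntimeError(
                "family ascertainment acceptance rate below 1e-4; "
                "check effect sizes and prevalence"
            )
        n_sibs = int(
            _truncated_poisson(rng, cfg.sibship_affected_mean, 1, 1)[0]
            + rng.poisson(cfg.sibship_unaffected_mean)
        )
        father = rng.binomial(2, freqs).astype(np.int8)
        mother = rng.binomial(2, freqs).astype(np.int8)
        kids = (
            rng.binomial(1, np.tile(father / 2.0, (n_sibs, 1)))
            + rng.binomial(1, np.tile(mother / 2.0, (n_sibs, 1)))
        ).astype(np.int8)
        shared = sig_f * rng.standard_normal()
        members = np.vstack([father[None, :], mother[None, :], kids])
        liab = members @ effects.betas + shared + sig_e * rng.standard_normal(len(members))
        affected = liab > effects.threshold
        if not affected[2:].any():  # ascertain on ≥1 affected sibling
            continue
        accepted += 1
        fid = f"F{accepted:04d}"
        roles = ["father", "mother"] + ["child"] * n_sibs
        sexes = ["male", "female"] + [
            "female" if rng.random() < cfg.sex_ratio else "male" for _ in range(n_sibs)
        ]
        for m in range(len(members)):
            counter += 1
            rows_dosage.append(members[m])
            rows_meta.append(
                {
                    "subject_id": f"{fid}_{counter:05d}",
                    "status": "case" if affected[m] else "control",
                    "sex": sexes[m],
                    "family_id": fid,
                    "affected": "yes" if affected[m] else "no",
                    "role": roles[m],
                }
            )

    dosage = np.vstack(rows_dosage)
    meta = pd.DataFrame(rows_meta)
    for k in range(cfg.n_covariates):
        meta[f"cov_{k + 1}"] = rng.standard_normal(len(meta))
    gm = GenotypeMatrix(
        meta["subject_id"].to_numpy(object), np.array(panel.snp_ids, object), dosage
    )
    return gm, SubjectTable(meta)


def inject_missingness(
    gm: GenotypeMatrix, rate: float, seed: int | np.random.Generator = 0
) -> GenotypeMatrix:
    """Set each dosage independently to missing with the given probability."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    if rate == 0.0:
        return gm
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mask = rng.random(gm.dosage.shape) < rate
    dosage = gm.dosage.copy()
    dosage[mask] = MISSING
    return GenotypeMatrix(gm.subject_ids, gm.snp_ids, dosage)
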
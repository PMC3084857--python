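"""Genotype quality control: exact Hardy-Weinberg test, MAF/call-rate filters.

The HWE test is the standard exact test conditional on the observed allele
counts: the p-value is the total probability of all heterozygote counts whose
conditional probability does not exceed that of the observed table.  MAF and
HWE are computed in controls only; call rates over all retained subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import MISSING, GenotypeMatrix, SubjectTable

__all__ = ["QcThresholds", "QcReport", "hwe_exact_test", "qc_filter"]


def hwe_exact_test(n_hom_nonrisk: int, n_het: int, n_hom_risk: int) -> float:
    """Exact Hardy-Weinberg p-value for one biallelic SNP.

    Conditional on the observed allele counts, heterozygote counts follow the
    distribution p(h) ∝ C(n, (r−h)/2, h, (2n−r−h)/2) · 2^h; the two-sided
    p-value sums p(h) over all h with p(h) ≤ p(h_obs).  Computed with the
    usual stable recurrence from the modal heterozygote count.

    Parameters are genotype counts; the orientation of the alleles is
    irrelevant (the test is symmetric in allele labels).
    """
    counts = (n_hom_nonrisk, n_het, n_hom_risk)
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be nonnegative")
    n = sum(counts)
    if n == 0:
        raise ValueError("all genotype counts are zero")
    rare = 2 * min(n_hom_nonrisk, n_hom_risk) + n_het  # rarer allele count
    if rare == 0:
        return 1.0  # monomorphic: only one table possible

    # probabilities over het ∈ {rare mod 2, ..., rare} step 2, unnormalised
    hets = np.arange(rare % 2, rare + 1, 2)
    probs = np.zeros(len(hets))
    # start at the (approximate) mode and recurse outward
    mid = int(rare * (2 * n - rare) / (2 * n))
    if mid % 2 != rare % 2:
        mid += 1
    mid_idx = (mid - hets[0]) // 2
    probs[mid_idx] = 1.0
    # downward: p(h-2)/p(h) = h(h-1) / ((r-h+2)/2 * (2n-r-h+2)/2) inverse form
    for i in range(mid_idx, 0, -1):
        h = hets[i]
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        probs[i - 1] = probs[i] * h * (h - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
    for i in range(mid_idx, len(hets) - 1):
        h = hets[i]
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        probs[i + 1] = probs[i] * 4.0 * hom_r * hom_c / ((h + 1.0) * (h + 2.0))
    probs /= probs.sum()
    obs_idx = (n_het - hets[0]) // 2
    p = probs[probs <= probs[obs_idx] * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


@dataclass(frozen=True)
class QcThresholds:
    """Filter thresholds; defaults follow common GWAS practice for this panel."""

    maf_min: float = 0.01
    hwe_p_min: float = 1e-4
    snp_call_min: float = 0.9
    subject_call_min: float = 0.9

    def __post_init__(self) -> None:
        for name in ("maf_min", "hwe_p_min", "snp_call_min", "subject_call_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class QcReport:
    """Per-SNP and per-subject QC statistics with pass flags and reasons."""

    snp_report: pd.DataFrame
    subject_report: pd.DataFrame
    thresholds: QcThresholds

    def write_tsv(self, snp_path, subject_path) -> None:
        self.snp_report.to_csv(snp_path, sep="\t", index=False)
        self.subject_report.to_csv(subject_path, sep="\t", index=False)


def _snp_stats(gm: GenotypeMatrix, is_control: np.ndarray) -> pd.DataFrame:
    present = gm.dosage != MISSING
    call_rate = present.mean(axis=0) if gm.n_subjects else np.zeros(gm.n_snps)
    rows = []
    for j, snp in enumerate(gm.snp_ids):
        d = gm.dosage[is_control, j]
        d = d[d != MISSING]
        if len(d):
            q = d.mean() / 2.0  # control risk-allele frequency
            maf = min(q, 1 - q)
            hwe_p = hwe_exact_test(int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum()))
        else:
            q, maf, hwe_p = np.nan, np.nan, np.nan
        rows.append(
            {
                "snp_id": snp,
                "call_rate": call_rate[j],
                "control_freq": q,
                "maf": maf,
                "hwe_p": hwe_p,
            }
        )
    return pd.DataFrame(rows)


def qc_filter(
    gm: GenotypeMatrix,
    subjects: SubjectTable,
    thresholds: QcThresholds | None = None,
) -> tuple[GenotypeMatrix, QcReport]:
    """Apply subject call-rate then SNP MAF/HWE/call-rate filters.

    Subjects failing the call-rate threshold are removed first; SNP statistics
    (call rate over retained subjects, MAF and exact HWE in retained controls)
    are then computed on the reduced matrix.  Raises if no SNP survives.
    """
    thr = thresholds or QcThresholds()
    st = subjects.aligned_to(list(gm.subject_ids))

    present = gm.dosage != MISSING
    subj_call = present.mean(axis=1) if gm.n_snps else np.ones(gm.n_subjects)
    subj_pass = subj_call >= thr.subject_call_min
    subject_report = pd.DataFrame(
        {
            "subject_id": gm.subject_ids,
            "call_rate": subj_call,
            "pass": subj_pass,
            "reason": np.where(subj_pass, "", "call_rate"),
        }
    )

    gm2 = gm.take_subjects(np.where(subj_pass)[0])
    st2 = st.aligned_to(list(gm2.subject_ids))
    snp_stats = _snp_stats(gm2, ~st2.is_case)

    reasons = []
    for _, row in snp_stats.iterrows():
        why = []
        if row["call_rate"] < thr.snp_call_min:
            why.append("call_rate")
        if np.isnan(row["maf"]) or row["maf"] < thr.maf_min:
            why.append("MAF")
        if np.isnan(row["hwe_p"]) or row["hwe_p"] < thr.hwe_p_min:
            why.append("HWE")
        reasons.append(",".join(why))
    snp_stats["pass"] = [r == "" for r in reasons]
    snp_stats["reason"] = reasons

    keep = np.where(snp_stats["pass"].to_numpy())[0]
    if len(keep) == 0:
        raise ValueError("empty panel after QC: every SNP was removed")
    gm3 = gm2.take_snps(keep)
    report = QcReport(snp_stats, subject_report, thr)
    return gm3, report
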
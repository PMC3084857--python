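"""Panel, genotype and subject tables: readers, validation, risk-allele orientation.

The exchange formats are deliberately platform-neutral: a delimited SNP panel
(one row per locus with risk/non-risk alleles, per-allele odds ratio and
case/control risk-allele frequencies), a subjects-by-SNPs genotype table whose
entries are either two-character allele pairs ("TC") or integer risk-allele
dosages, and a subject table with status, covariates, subphenotypes and family
structure.  A VCF path is supported as an alternative genotype source.

Dosage is always oriented to count *risk* alleles, 0/1/2, with ``MISSING``
(-1) as the explicit missing sentinel.  Missing dosages are never imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "SnpPanel",
    "GenotypeMatrix",
    "SubjectTable",
    "load_snp_panel",
    "psoriasis_panel",
    "load_genotypes",
    "load_genotypes_vcf",
    "load_subjects",
]

#: sentinel for a missing dosage; distinct from every valid dosage {0, 1, 2}
MISSING: int = -1

_PANEL_COLUMNS = [
    "snp_id",
    "chrom",
    "gene",
    "risk_allele",
    "nonrisk_allele",
    "odds_ratio",
    "case_freq",
    "control_freq",
]

_NUCLEOTIDES = frozenset("ACGT")


@dataclass(frozen=True)
class SnpPanel:
    """Per-SNP metadata: risk-allele orientation, effect size, frequencies.

    ``odds_ratio`` is the per-allele (additive) odds ratio; the score weight
    of a SNP is its natural logarithm.  ``case_freq``/``control_freq`` are
    risk-allele frequencies.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        missing_cols = [c for c in _PANEL_COLUMNS if c not in df.columns]
        if missing_cols:
            raise ValueError(f"panel is missing columns: {missing_cols}")
        if len(df) == 0:
            raise ValueError("no records in panel")
        dup = df["snp_id"][df["snp_id"].duplicated()].tolist()
        if dup:
            raise ValueError(f"duplicate snp_ids in panel: {sorted(set(dup))}")
        if (df["odds_ratio"] <= 0).any():
            bad = df.loc[df["odds_ratio"] <= 0, "snp_id"].tolist()
            raise ValueError(f"odds_ratio must be > 0 (offending SNPs: {bad})")
        for col in ("case_freq", "control_freq"):
            if ((df[col] < 0) | (df[col] > 1)).any():
                raise ValueError(f"{col} must lie in [0, 1]")
        same = df["risk_allele"] == df["nonrisk_allele"]
        if same.any():
            raise ValueError(
                f"risk and nonrisk alleles identical for {df.loc[same, 'snp_id'].tolist()}"
            )
        object.__setattr__(self, "table", df.reset_index(drop=True))

    # -- convenience accessors -------------------------------------------
    @property
    def snp_ids(self) -> list[str]:
        return self.table["snp_id"].tolist()

    @property
    def n_snps(self) -> int:
        return len(self.table)

    @property
    def odds_ratios(self) -> np.ndarray:
        return self.table["odds_ratio"].to_numpy(float)

    @property
    def weights(self) -> np.ndarray:
        """Per-SNP score weights, ln(OR)."""
        return np.log(self.odds_ratios)

    @property
    def case_freqs(self) -> np.ndarray:
        return self.table["case_freq"].to_numpy(float)

    @property
    def control_freqs(self) -> np.ndarray:
        return self.table["control_freq"].to_numpy(float)

    @property
    def risk_alleles(self) -> list[str]:
        return self.table["risk_allele"].tolist()

    @property
    def nonrisk_alleles(self) -> list[str]:
        return self.table["nonrisk_allele"].tolist()

    def subset(self, snp_ids: Sequence[str]) -> "SnpPanel":
        keep = self.table[self.table["snp_id"].isin(set(snp_ids))]
        if keep.empty:
            raise ValueError("subset removed every SNP from the panel")
        return SnpPanel(keep.copy())

    def flipped(self) -> "SnpPanel":
        """Panel with risk/non-risk alleles swapped (OR and freqs inverted)."""
        df = self.table.copy()
        df[["risk_allele", "nonrisk_allele"]] = df[["nonrisk_allele", "risk_allele"]].to_numpy()
        df["odds_ratio"] = 1.0 / df["odds_ratio"]
        df["case_freq"] = 1.0 - df["case_freq"]
        df["control_freq"] = 1.0 - df["control_freq"]
        return SnpPanel(df)


@dataclass(frozen=True)
class GenotypeMatrix:
    """Subjects × SNPs risk-allele dosage matrix with explicit missingness."""

    subject_ids: np.ndarray
    snp_ids: np.ndarray
    dosage: np.ndarray  # int8, values in {0, 1, 2, MISSING}

    def __post_init__(self) -> None:
        sid = np.asarray(self.subject_ids, dtype=object)
        snp = np.asarray(self.snp_ids, dtype=object)
        dos = np.asarray(self.dosage, dtype=np.int8)
        if dos.shape != (len(sid), len(snp)):
            raise ValueError(
                f"dosage shape {dos.shape} inconsistent with "
                f"{len(sid)} subjects × {len(snp)} SNPs"
            )
        valid = np.isin(dos, [0, 1, 2, MISSING])
        if not valid.all():
            raise ValueError("dosage entries must be 0, 1, 2 or the missing sentinel")
        if len(set(sid)) != len(sid):
            raise ValueError("subject_ids must be unique")
        object.__setattr__(self, "subject_ids", sid)
        object.__setattr__(self, "snp_ids", snp)
        object.__setattr__(self, "dosage", dos)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        return self.dosage == MISSING

    @property
    def complete_mask(self) -> np.ndarray:
        """Boolean per subject: True when no dosage is missing."""
        return ~self.missing_mask.any(axis=1)

    def take_subjects(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.subject_ids[index], self.snp_ids, self.dosage[index])

    def take_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.subject_ids, self.snp_ids[index], self.dosage[:, index])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.dosage, columns=list(self.snp_ids))
        df.insert(0, "subject_id", list(self.subject_ids))
        return df

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


_SUBJECT_CATEGORICALS = {
    "status": {"case", "control"},
    "sex": {"female", "male"},
    "family_history": {"yes", "no"},
    "psoriasis_type": {"plaque", "guttate"},
    "psa": {"yes", "no"},
    "affected": {"yes", "no"},
}


@dataclass(frozen=True)
class SubjectTable:
    """Per-subject phenotype, covariates, subphenotypes and family structure.

    Covariate columns are those prefixed ``cov_`` (e.g. externally computed
    ancestry principal components); their count must be constant, which a
    DataFrame guarantees.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        for col in ("subject_id", "status"):
            if col not in df.columns:
                raise ValueError(f"subject table is missing required column '{col}'")
        if df["subject_id"].duplicated().any():
            dup = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
            raise ValueError(f"duplicate subject_ids: {sorted(set(dup))}")
        for col, allowed in _SUBJECT_CATEGORICALS.items():
            if col in df.columns:
                vals = set(df[col].dropna().unique()) - allowed
                if vals:
                    raise ValueError(f"invalid values in '{col}': {sorted(map(str, vals))}")
        object.__setattr__(self, "table", df.reset_index(drop=True))

    @property
    def subject_ids(self) -> np.ndarray:
        return self.table["subject_id"].to_numpy(object)

    @property
    def covariate_columns(self) -> list[str]:
        return [c for c in self.table.columns if c.startswith("cov_")]

    @property
    def covariates(self) -> np.ndarray:
        return self.table[self.covariate_columns].to_numpy(float)

    @property
    def is_case(self) -> np.ndarray:
        return (self.table["status"] == "case").to_numpy()

    def aligned_to(self, subject_ids: Sequence) -> "SubjectTable":
        """Rows reordered/restricted to the given subject ids (must all exist)."""
        idx = self.table.set_index("subject_id")
        missing = [s for s in subject_ids if s not in idx.index]
        if missing:
            raise KeyError(f"subjects absent from subject table: {missing[:5]}")
        out = idx.loc[list(subject_ids)].reset_index()
        return SubjectTable(out)


# ---------------------------------------------------------------------------
# readers


def _read_delimited(path: str | Path) -> pd.DataFrame:
    """Read CSV or TSV, sniffing the delimiter from the header line."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        header = fh.readline()
    if not header.strip():
        raise ValueError(f"no records in {path}")
    sep = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    return pd.read_csv(path, sep=sep, dtype={"snp_id": str, "subject_id": str})


def load_snp_panel(path: str | Path) -> SnpPanel:
    """Load and validate a SNP panel from a delimited file with a header."""
    df = _read_delimited(path)
    if len(df) == 0:
        raise ValueError(f"no records in {path}")
    try:
        df["odds_ratio"] = pd.to_numeric(df["odds_ratio"])
        df["case_freq"] = pd.to_numeric(df["case_freq"])
        df["control_freq"] = pd.to_numeric(df["control_freq"])
    except (KeyError, ValueError) as exc:
        raise ValueError(f"malformed panel file {path}: {exc}") from exc
    return SnpPanel(df)


def psoriasis_panel() -> SnpPanel:
    """The packaged ten-SNP psoriasis panel.

    Published per-allele odds ratios and case/control risk-allele frequencies
    for ten replicated psoriasis susceptibility loci (HLA-C, IL12B, IL23R,
    LCE3C/3D, TNIP1/ANXA6, IL13, CDKAL1, TNFAIP3, IL23A/STAT2, ZNF313).
    """
    ref = resources.files("grscore.data").joinpath("psoriasis_panel.csv")
    with resources.as_file(ref) as path:
        return load_snp_panel(path)


def _orient_allele_pair(entry: str, risk: str, nonrisk: str) -> int:
    """Dosage from a two-character allele pair; unknown alleles → MISSING."""
    entry = entry.strip().upper()
    if len(entry) != 2:
        return MISSING
    d = 0
    for allele in entry:
        if allele == risk:
            d += 1
        elif allele != nonrisk:
            return MISSING
    return d


def load_genotypes(path: str | Path, panel: SnpPanel) -> GenotypeMatrix:
    """Read a subjects × SNPs genotype table oriented to risk-allele dosage.

    Each SNP column may hold either two-character allele pairs ("TC") or
    integer dosages; the dialect is auto-detected per column.  Allele pairs
    containing an allele not in the panel become missing (a warning reports
    the count).  SNP columns absent from the panel are an error.
    """
    df = _read_delimited(path)
    if "subject_id" not in df.columns:
        raise ValueError("genotype table must have a 'subject_id' column")
    snp_cols = [c for c in df.columns if c != "subject_id"]
    unknown = sorted(set(snp_cols) - set(panel.snp_ids))
    if unknown:
        raise ValueError(f"SNPs in genotype file absent from panel: {unknown}")
    absent = sorted(set(panel.snp_ids) - set(snp_cols))
    if absent:
        raise ValueError(f"panel SNPs missing from genotype file: {absent}")

    n = len(df)
    dosage = np.full((n, panel.n_snps), MISSING, dtype=np.int8)
    n_mismatch = 0
    for j, (snp, risk, nonrisk) in enumerate(
        zip(panel.snp_ids, panel.risk_alleles, panel.nonrisk_alleles)
    ):
        col = df[snp]
        numeric = pd.to_numeric(col, errors="coerce")
        if numeric.notna().sum() >= col.notna().sum() and col.notna().any():
            # dosage column
            vals = numeric.to_numpy(float)
            ok = np.isin(vals, [0.0, 1.0, 2.0])
            dosage[ok, j] = vals[ok].astype(np.int8)
            # NaN and the -1 sentinel round-trip as missing, not as mismatches
            n_mismatch += int((~ok & ~np.isnan(vals) & (vals != MISSING)).sum())
        else:
            for i, entry in enumerate(col):
                if isinstance(entry, str) and entry.strip():
                    d = _orient_allele_pair(entry, risk, nonrisk)
                    dosage[i, j] = d
                    if d == MISSING:
                        n_mismatch += 1
    if n_mismatch:
        warnings.warn(
            f"{n_mismatch} genotype entries did not match panel alleles; set to missing",
            stacklevel=2,
        )
    return GenotypeMatrix(df["subject_id"].to_numpy(object), np.array(panel.snp_ids, object), dosage)


def load_genotypes_vcf(path: str | Path, panel: SnpPanel) -> GenotypeMatrix:
    """Read genotypes from a VCF, orienting REF/ALT to panel risk alleles.

    Variants are matched to the panel by ID.  REF/ALT must equal the panel's
    allele pair (in either order); a mismatch raises — strand flips are never
    guessed silently.
    """
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    want = {s: j for j, s in enumerate(panel.snp_ids)}
    dosage = np.full((len(samples), panel.n_snps), MISSING, dtype=np.int8)
    seen: set[str] = set()
    for var in vcf:
        if var.ID not in want:
            continue
        j = want[var.ID]
        risk, nonrisk = panel.risk_alleles[j], panel.nonrisk_alleles[j]
        alt = var.ALT[0] if var.ALT else None
        if {var.REF, alt} != {risk, nonrisk}:
            raise ValueError(
                f"{var.ID}: VCF alleles {var.REF}/{alt} do not match panel "
                f"{risk}/{nonrisk} (possible strand flip; not auto-resolved)"
            )
        alt_is_risk = alt == risk
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = var.gt_types
        alt_count = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING)
        dosage[:, j] = np.where(
            alt_count == MISSING, MISSING, alt_count if alt_is_risk else 2 - alt_count
        )
        seen.add(var.ID)
    absent = sorted(set(panel.snp_ids) - seen)
    if absent:
        raise ValueError(f"panel SNPs missing from VCF: {absent}")
    return GenotypeMatrix(
        np.array(samples, object), np.array(panel.snp_ids, object), dosage
    )


def load_subjects(path: str | Path) -> SubjectTable:
    """Read the subject table (CSV/TSV; covariate columns prefixed ``cov_``)."""
    df = _read_delimited(path)
    if "family_id" in df.columns:
        df["family_id"] = df["family_id"].astype("string").astype(object)
        df.loc[df["family_id"].isna(), "family_id"] = np.nan
    return SubjectTable(df)
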
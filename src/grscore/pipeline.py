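"""End-to-end analysis: QC → scores → associations → ROC → liability → family.

One flat YAML config drives the run; every threshold of the analysis is a
config key with the study's value as default.  Outputs are TSV tables plus a
single JSON summary of the headline numbers, and a log that accounts for
every excluded subject and SNP.  Given the same inputs and config the run is
fully deterministic; each stage is the corresponding library call, so stage
outputs can be reproduced individually with the module CLIs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc, family, grs, liability, roc
from .data_io import SnpPanel, load_genotypes, load_snp_panel, load_subjects
from .qc import QcThresholds, qc_filter

__all__ = ["RunConfig", "run_full_analysis"]

logger = logging.getLogger("grscore")


@dataclass(frozen=True)
class RunConfig:
    """Flat run configuration; defaults carry the study's analysis choices."""

    panel_path: str
    genotypes_path: str
    subjects_path: str
    out_dir: str
    prevalence: float = 0.025
    maf_min: float = 0.01
    hwe_p_min: float = 1e-4
    snp_call_min: float = 0.9
    subject_call_min: float = 0.9
    quartiles: bool = True
    subphenotypes: tuple[str, ...] = ("family_history", "age_onset", "psa", "psoriasis_type")
    age_onset_cut: float = 30.0
    interactions: bool = False
    family: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")
        for p in (self.panel_path, self.genotypes_path, self.subjects_path):
            if not Path(p).exists():
                raise FileNotFoundError(p)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "subphenotypes" in raw:
            raw["subphenotypes"] = tuple(raw["subphenotypes"])
        return cls(**raw)


def _dichotomize(st: pd.DataFrame, name: str, age_cut: float) -> pd.Series | None:
    """Binary subphenotype per the standard dichotomizations (cases only)."""
    if name == "age_onset":
        if "age_onset" not in st.columns:
            return None
        age = pd.to_numeric(st["age_onset"], errors="coerce")
        return pd.Series(np.where(age.isna(), None, np.where(age > age_cut, "late", "early")),
                         index=st.index, name="age_onset")
    if name in st.columns:
        return st[name]
    return None


def _assoc_row(res: assoc.AssocResult, label: str) -> dict:
    return {
        "term": label,
        "odds_ratio": res.odds_ratio,
        "ci_low": res.ci_low,
        "ci_high": res.ci_high,
        "p_value": res.p_value,
        "n": res.n,
        "flags": ",".join(res.flags),
    }


def run_full_analysis(cfg: RunConfig) -> dict:
    """Run every stage and write the report bundle under ``cfg.out_dir``.

    Returns the JSON-serializable summary that is also written to
    ``summary.json``.  Any stage failure propagates with the stage name;
    tables written before the failure remain on disk.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": {k: getattr(cfg, k) for k in (
        "prevalence", "maf_min", "hwe_p_min", "snp_call_min", "subject_call_min", "seed")}}

    stage = "load"
    try:
        panel = load_snp_panel(cfg.panel_path)
        gm = load_genotypes(cfg.genotypes_path, panel)
        subjects = load_subjects(cfg.subjects_path)
        n_in = gm.n_subjects
        logger.info("loaded %d subjects × %d SNPs", n_in, gm.n_snps)

        stage = "qc"
        thr = QcThresholds(cfg.maf_min, cfg.hwe_p_min, cfg.snp_call_min, cfg.subject_call_min)
        gm, qc_report = qc_filter(gm, subjects, thr)
        qc_report.write_tsv(out / "qc_snps.tsv", out / "qc_subjects.tsv")
        n_qc_removed = int((~qc_report.subject_report["pass"]).sum())
        for _, row in qc_report.snp_report[~qc_report.snp_report["pass"]].iterrows():
            logger.info("QC removed SNP %s (%s)", row["snp_id"], row["reason"])
        logger.info("QC removed %d subjects by call rate", n_qc_removed)
        panel = panel.subset(list(gm.snp_ids))

        stage = "scores"
        gm_complete, n_incomplete = grs.complete_case_filter(gm)
        st = subjects.aligned_to(list(gm_complete.subject_ids))
        removed_cases = int(
            subjects.table.set_index("subject_id")
            .loc[[s for s in gm.subject_ids if s not in set(gm_complete.subject_ids)], "status"]
            .eq("case").sum()
        ) if n_incomplete else 0
        logger.info(
            "complete-case rule removed %d subjects (%d cases, %d controls)",
            n_incomplete, removed_cases, n_incomplete - removed_cases,
        )
        scores = grs.score_table(gm_complete, panel)
        summary["counts"] = {
            "n_input": n_in,
            "n_qc_removed": n_qc_removed,
            "n_incomplete_removed": n_incomplete,
            "n_analyzed": int(len(scores)),
        }

        stage = "score_distribution"
        is_case = st.is_case
        dist = {
            "case_mean_cgrs": float(scores.loc[is_case, "cgrs"].mean()),
            "case_sd_cgrs": float(scores.loc[is_case, "cgrs"].std()),
            "control_mean_cgrs": float(scores.loc[~is_case, "cgrs"].mean()),
            "control_sd_cgrs": float(scores.loc[~is_case, "cgrs"].std()),
            "case_mean_wgrs": float(scores.loc[is_case, "wgrs"].mean()),
            "control_mean_wgrs": float(scores.loc[~is_case, "wgrs"].mean()),
        }
        _, dist["count_comparison_p"] = assoc.mann_whitney(
            scores.loc[is_case, "cgrs"], scores.loc[~is_case, "cgrs"]
        )
        summary["score_distribution"] = dist
        counts_tab = (
            scores.assign(status=np.where(is_case, "case", "control"))
            .groupby(["status", "cgrs"]).size().rename("n").reset_index()
        )
        counts_tab.to_csv(out / "count_distribution.tsv", sep="\t", index=False)

        stage = "per_snp_association"
        cov, sex = st.covariates, st.table.get("sex")
        snp_rows = []
        for j, snp in enumerate(gm_complete.snp_ids):
            res = assoc.additive_logistic(gm_complete.dosage[:, j], st.table["status"], cov, sex)
            snp_rows.append(_assoc_row(res, snp))
        pd.DataFrame(snp_rows).to_csv(out / "per_snp_association.tsv", sep="\t", index=False)

        if cfg.quartiles:
            stage = "quartiles"
            labels, boundaries = grs.assign_quartiles(scores["wgrs"].to_numpy())
            scores["quartile"] = labels
            qa = assoc.quartile_or(labels, st.table["status"], cov, sex)
            qtab = pd.DataFrame([_assoc_row(r, r.term) for r in qa.quartile_results])
            qtab.to_csv(out / "quartile_or.tsv", sep="\t", index=False)
            summary["quartiles"] = {
                "boundaries": [float(b) for b in boundaries],
                "or_q4_vs_q1": qa.quartile_results[3].odds_ratio,
                "trend_p": qa.trend_p,
            }
        scores.to_csv(out / "scores.tsv", sep="\t", index=False)

        stage = "roc"
        y = np.where(is_case, 1, 0)
        roc_w = roc.empirical_auc(scores["wgrs"], y)
        roc_c = roc.empirical_auc(scores["cgrs"], y)
        cmp_wc = roc.delong_paired_test(scores["wgrs"], scores["cgrs"], y)
        summary["roc"] = {
            "auc_wgrs": roc_w.auc,
            "auc_wgrs_ci": roc_w.auc_ci,
            "auc_cgrs": roc_c.auc,
            "auc_cgrs_ci": roc_c.auc_ci,
            "p_wgrs_vs_cgrs": cmp_wc.p_value,
        }
        # strongest single SNP vs the rest, as in the published contrast
        top = int(np.argmax(panel.odds_ratios))
        top_scores = gm_complete.dosage[:, top].astype(float)
        rest_panel = panel.subset([s for i, s in enumerate(panel.snp_ids) if i != top])
        rest_idx = [i for i in range(panel.n_snps) if i != top]
        rest_w = gm_complete.dosage[:, rest_idx].astype(float) @ rest_panel.weights
        roc_top = roc.empirical_auc(top_scores, y)
        cmp_tc = roc.delong_paired_test(top_scores, scores["cgrs"], y)
        cmp_tr = roc.delong_paired_test(top_scores, rest_w, y)
        summary["roc"].update(
            {
                "top_snp": str(panel.snp_ids[top]),
                "auc_top_snp": roc_top.auc,
                "p_top_vs_cgrs": cmp_tc.p_value,
                "p_top_vs_wgrs_without_top": cmp_tr.p_value,
            }
        )

        stage = "subphenotypes"
        sub_rows = []
        case_mask = is_case
        for name in cfg.subphenotypes:
            col = _dichotomize(st.table, name, cfg.age_onset_cut)
            if col is None:
                continue
            keep = case_mask & col.notna().to_numpy()
            if keep.sum() < 4 or col[keep].nunique() < 2:
                logger.info("subphenotype %s skipped (insufficient data)", name)
                continue
            res = assoc.subphenotype_assoc(
                scores.loc[keep, "wgrs"], col[keep], cov[keep],
                None if sex is None else sex[keep],
                test_level="guttate" if name == "psoriasis_type" else None,
            )
            sub_rows.append(_assoc_row(res, name))
        if sub_rows:
            pd.DataFrame(sub_rows).to_csv(out / "subphenotypes.tsv", sep="\t", index=False)
            summary["subphenotypes"] = {r["term"]: r["p_value"] for r in sub_rows}

        stage = "liability"
        total, var_table = liability.total_variance_explained(panel, cfg.prevalence)
        var_table.to_csv(out / "variance_explained.tsv", sep="\t", index=False)
        summary["liability"] = {
            "total_variance_explained": total,
            "per_snp": dict(zip(var_table["snp_id"], var_table["variance_explained"])),
        }

        if cfg.interactions:
            stage = "interactions"
            itab = assoc.pairwise_interactions(gm_complete, st.table["status"], cov, sex)
            itab.to_csv(out / "interactions.tsv", sep="\t", index=False)
            ok = itab["p_bonferroni"].dropna()
            summary["interactions"] = {
                "n_pairs": int(len(itab)),
                "min_p_bonferroni": float(ok.min()) if len(ok) else None,
            }

        if cfg.family and "family_id" in st.table.columns and st.table["family_id"].notna().any():
            stage = "family"
            fam = family.family_means(scores, st)
            fam.to_csv(out / "families.tsv", sep="\t", index=False)
            both = fam.dropna(subset=["mean_wgrs_affected", "mean_wgrs_unaffected"])
            fam_summary = {"n_families": int(len(fam)), "n_with_both": int(len(both))}
            if len(both) >= 3:
                rho, p = family.within_family_correlation(fam)
                fam_summary.update({"spearman_rho": rho, "spearman_p": p})
            summary["family"] = fam_summary
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
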
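"""Family-level weighted-score summaries and within-family correlation.

To remove the unequal contribution of large sibships, each family is reduced
to the mean wGRS of its affected members and the mean wGRS of its unaffected
members; the correlation between the two means across families (Spearman)
measures how strongly unaffected relatives share the genetic load of their
affected kin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import mann_whitney
from .data_io import SubjectTable

__all__ = ["FamilySummary", "family_means", "within_family_correlation", "group_comparison"]


@dataclass(frozen=True)
class FamilySummary:
    family_id: str
    mean_wgrs_affected: float  # NaN when no scored affected member
    mean_wgrs_unaffected: float
    n_affected: int
    n_unaffected: int


def family_means(scores: pd.DataFrame, subjects: SubjectTable) -> pd.DataFrame:
    """Per-family unweighted member means of the weighted score.

    ``scores`` is a score table (subject_id, wgrs, complete); only scored
    (complete) members contribute.  Subjects with a family id but missing
    affection status are excluded with a warning.  Returns one row per family:
    family_id, mean_wgrs_affected, mean_wgrs_unaffected, n_affected,
    n_unaffected (means are NaN when a member class is absent).
    """
    st = subjects.table
    if "family_id" not in st.columns or "affected" not in st.columns:
        raise ValueError("subject table needs family_id and affected columns")
    fam = st[st["family_id"].notna()].copy()
    no_aff = fam["affected"].isna()
    if no_aff.any():
        warnings.warn(
            f"{int(no_aff.sum())} family subjects lack affection status; excluded",
            stacklevel=2,
        )
        fam = fam[~no_aff]
    merged = fam.merge(scores[["subject_id", "wgrs"]], on="subject_id", how="left")
    merged = merged[merged["wgrs"].notna()]  # complete-case members only

    rows = []
    for fid, grp in merged.groupby("family_id", sort=True):
        aff = grp.loc[grp["affected"] == "yes", "wgrs"]
        una = grp.loc[grp["affected"] == "no", "wgrs"]
        rows.append(
            {
                "family_id": fid,
                "mean_wgrs_affected": aff.mean() if len(aff) else np.nan,
                "mean_wgrs_unaffected": una.mean() if len(una) else np.nan,
                "n_affected": len(aff),
                "n_unaffected": len(una),
            }
        )
    if not rows:
        raise ValueError("no scored family members found")
    return pd.DataFrame(rows)


def within_family_correlation(summaries: pd.DataFrame) -> tuple[float, float]:
    """Spearman correlation of affected vs unaffected family mean scores.

    Uses families where both means exist; requires at least 3 such pairs.
    Returns (rho, two-sided p).
    """
    both = summaries.dropna(subset=["mean_wgrs_affected", "mean_wgrs_unaffected"])
    if len(both) < 3:
        raise ValueError(f"need ≥3 families with both means, got {len(both)}")
    rho, p = stats.spearmanr(
        both["mean_wgrs_affected"], both["mean_wgrs_unaffected"]
    )
    return float(rho), float(p)


def group_comparison(
    group_a: Sequence[float], group_b: Sequence[float]
) -> dict[str, float]:
    """Mean scores of two groups with a two-sided Mann-Whitney p-value."""
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    _, p = mann_whitney(a, b)
    return {"mean_a": float(a.mean()), "mean_b": float(b.mean()), "p_value": p}
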
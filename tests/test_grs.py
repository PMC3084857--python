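"""Score computation, quartiles, and exact score distributions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from grscore.data_io import MISSING, SnpPanel
from grscore.grs import (
    ScoreDistribution,
    assign_quartiles,
    complete_case_filter,
    count_grs,
    exact_score_distribution,
    expected_score,
    score_table,
    snp_weight,
    weighted_grs,
)
from grscore.simulate import SimConfig, simulate_case_control

from .conftest import make_genotypes


def _single_snp_panel(odds_ratio=1.59, case_freq=0.853, control_freq=0.784):
    return SnpPanel(
        pd.DataFrame(
            {
                "snp_id": ["rs0"],
                "chrom": ["1"],
                "gene": ["G"],
                "risk_allele": ["G"],
                "nonrisk_allele": ["A"],
                "odds_ratio": [odds_ratio],
                "case_freq": [case_freq],
                "control_freq": [control_freq],
            }
        )
    )


class TestWeights:
    def test_worked_homozygote_contribution(self):
        """Two risk alleles at per-allele OR 1.59 add 2·ln(1.59) ≈ 0.927."""
        assert 2 * snp_weight(1.59) == pytest.approx(0.9274680, abs=1e-6)

    def test_null_effect(self):
        assert snp_weight(1.0) == 0.0

    def test_large_effect(self):
        assert snp_weight(3.07) == pytest.approx(np.log(3.07), abs=1e-12)

    @pytest.mark.parametrize("bad", [0.0, -1.5])
    def test_domain_error(self, bad):
        with pytest.raises(ValueError):
            snp_weight(bad)


class TestScores:
    def test_count_examples(self):
        assert count_grs([2, 1, 0]) == 3
        assert count_grs([0] * 10) == 0
        assert count_grs([2] * 10) == 20

    def test_count_rejects_missing(self):
        with pytest.raises(ValueError, match="incomplete"):
            count_grs([2, MISSING, 0])

    def test_weighted_single_snp(self):
        assert weighted_grs([2], _single_snp_panel()) == pytest.approx(0.9274680, abs=1e-6)

    def test_weighted_all_zero(self, panel):
        assert weighted_grs([0] * 10, panel) == 0.0

    def test_weighted_all_two(self, panel):
        # 2·Σ ln(OR) over the ten panel SNPs, evaluated directly
        expected = 2 * np.log(panel.odds_ratios).sum()
        assert weighted_grs([2] * 10, panel) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(8.261294, abs=1e-6)

    def test_weighted_length_mismatch(self, panel):
        with pytest.raises(ValueError, match="length"):
            weighted_grs([1, 2], panel)

    @given(
        dosages=st.lists(st.integers(0, 2), min_size=3, max_size=3),
        snp=st.integers(0, 2),
    )
    def test_monotone_in_dosage(self, tiny_panel, dosages, snp):
        """Raising any dosage strictly increases the wGRS when OR > 1."""
        base = weighted_grs(dosages, tiny_panel)
        if dosages[snp] < 2:
            bumped = list(dosages)
            bumped[snp] += 1
            assert weighted_grs(bumped, tiny_panel) > base

    def test_cgrs_equals_wgrs_at_unit_weights(self):
        """With every OR = e the weights are 1 and the two scores coincide."""
        panel = SnpPanel(
            pd.DataFrame(
                {
                    "snp_id": [f"rs{i}" for i in range(4)],
                    "chrom": "1",
                    "gene": "G",
                    "risk_allele": "A",
                    "nonrisk_allele": "G",
                    "odds_ratio": np.e,
                    "case_freq": 0.4,
                    "control_freq": 0.3,
                }
            )
        )
        rng = np.random.default_rng(0)
        for _ in range(20):
            d = rng.integers(0, 3, size=4)
            assert weighted_grs(d, panel) == pytest.approx(count_grs(d), abs=1e-12)


class TestCompleteCase:
    def test_removes_subjects_with_any_missing(self):
        dosage = np.ones((10, 3), np.int8)
        dosage[2, 0] = MISSING
        dosage[7, 2] = MISSING
        gm = make_genotypes(dosage, ["rs1", "rs2", "rs3"])
        out, n_removed = complete_case_filter(gm)
        assert (out.n_subjects, n_removed) == (8, 2)

    def test_identity_without_missing(self):
        gm = make_genotypes(np.ones((5, 2), np.int8), ["rs1", "rs2"])
        out, n_removed = complete_case_filter(gm)
        assert (out.n_subjects, n_removed) == (5, 0)

    def test_all_missing_warns(self):
        dosage = np.full((3, 2), MISSING, np.int8)
        gm = make_genotypes(dosage, ["rs1", "rs2"])
        with pytest.warns(UserWarning, match="every subject"):
            out, n_removed = complete_case_filter(gm)
        assert (out.n_subjects, n_removed) == (0, 3)

    def test_score_table_flags_incomplete(self, tiny_panel):
        dosage = np.array([[1, 1, 1], [2, MISSING, 0]], np.int8)
        gm = make_genotypes(dosage, tiny_panel.snp_ids)
        tab = score_table(gm, tiny_panel)
        assert tab["complete"].tolist() == [True, False]
        assert np.isnan(tab.loc[1, "wgrs"])
        assert tab.loc[0, "cgrs"] == 3


class TestQuartiles:
    def test_symmetric_eight(self):
        labels, _ = assign_quartiles(np.arange(1, 9))
        assert labels.tolist() == [1, 1, 2, 2, 3, 3, 4, 4]

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError, match="distinct"):
            assign_quartiles([3.0] * 10)

    def test_boundary_ties_go_low(self):
        labels, _ = assign_quartiles([1, 1, 1, 2, 3, 4])
        assert labels[:3].tolist() == [1, 1, 1]

    def test_every_subject_labeled(self, rng):
        s = rng.normal(size=501)
        labels, bounds = assign_quartiles(s)
        assert set(labels) == {1, 2, 3, 4}
        assert len(bounds) == 3
        # boundary construction: label consistent with stated tie rule
        recomputed = 1 + (s[:, None] > bounds[None, :]).sum(axis=1)
        assert (labels == recomputed).all()


class TestExactDistribution:
    def test_single_snp_binomial(self):
        panel = _single_snp_panel()
        d = exact_score_distribution([0.5], panel, "cgrs")
        assert d.support.tolist() == [0, 1, 2]
        assert d.mass == pytest.approx([0.25, 0.5, 0.25], abs=1e-12)

    def test_mean_and_variance_closed_form(self, panel):
        """Mean 2Σpᵢwᵢ and variance Σ2pᵢ(1−pᵢ)wᵢ² of the exact law."""
        p = panel.control_freqs
        w = panel.weights
        d = exact_score_distribution(p, panel, "wgrs")
        assert d.mean == pytest.approx(2 * (p @ w), abs=1e-10)
        assert d.var == pytest.approx((2 * p * (1 - p)) @ w**2, abs=1e-10)

    def test_control_count_mean(self, panel):
        d = exact_score_distribution(panel.control_freqs, panel, "cgrs")
        assert d.mean == pytest.approx(12.092, abs=1e-9)

    def test_symmetric_under_snp_exchange(self, tiny_panel):
        a = exact_score_distribution([0.3, 0.3, 0.0], tiny_panel, "cgrs")
        b = exact_score_distribution([0.3, 0.3, 0.0], tiny_panel, "cgrs")
        assert a.support == pytest.approx(b.support)
        assert a.mass == pytest.approx(b.mass)

    def test_too_many_snps_errors(self):
        df = pd.concat(
            [_single_snp_panel().table.assign(snp_id=f"rs{i}") for i in range(13)],
            ignore_index=True,
        )
        panel = SnpPanel(df)
        with pytest.raises(ValueError, match="simulation"):
            exact_score_distribution([0.5] * 13, panel, "cgrs")

    def test_matches_empirical_sampling(self, panel):
        """KS distance between the exact wGRS law and 10⁵ sampled subjects < 0.01."""
        cfg = SimConfig(panel=panel, mode="frequency", n_case=1, n_control=100_000, seed=11)
        gm, _ = simulate_case_control(cfg)
        wgrs = gm.dosage[1:].astype(float) @ panel.weights
        dist = exact_score_distribution(panel.control_freqs, panel, "wgrs")
        exact_cdf = np.cumsum(dist.mass)
        emp_cdf = np.searchsorted(np.sort(wgrs), dist.support + 1e-9) / len(wgrs)
        assert np.abs(emp_cdf - exact_cdf).max() < 0.01

    def test_mass_validation(self):
        with pytest.raises(ValueError, match="sum"):
            ScoreDistribution(np.array([0.0, 1.0]), np.array([0.5, 0.4]), "cgrs")


class TestExpectedScore:
    def test_case_count_mean(self, panel):
        assert expected_score(panel.case_freqs, panel, "cgrs") == pytest.approx(13.152, abs=1e-9)

    def test_control_wgrs_mean(self, panel):
        assert expected_score(panel.control_freqs, panel, "wgrs") == pytest.approx(
            4.19316, abs=1e-5
        )

    def test_zero_freqs(self, panel):
        assert expected_score([0.0] * 10, panel, "wgrs") == 0.0

    def test_consistent_with_exact_distribution(self, panel):
        for kind in ("cgrs", "wgrs"):
            d = exact_score_distribution(panel.case_freqs, panel, kind)
            assert d.mean == pytest.approx(
                expected_score(panel.case_freqs, panel, kind), abs=1e-10
            )
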
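"""Logistic association models, trend test, Mann-Whitney, interaction scan."""

import numpy as np
import pytest
from statsmodels.stats.proportion import proportions_ztest

from grscore.assoc import (
    additive_logistic,
    cochran_armitage_trend,
    mann_whitney,
    pairwise_interactions,
    quartile_or,
    subphenotype_assoc,
)
from grscore.data_io import SnpPanel
from grscore.simulate import SimConfig, simulate_case_control

from .conftest import make_genotypes


def _binom(rng, q, n):
    return rng.binomial(2, q, size=n)


class TestAdditiveLogistic:
    def test_recovers_allelic_odds_ratio(self, rng):
        """Frequency-structured data imply a per-allele OR equal to the
        allelic cross-product ratio; the fit must recover it at large n."""
        p1, p0, n = 0.351, 0.158, 50_000
        d = np.concatenate([_binom(rng, p1, n), _binom(rng, p0, n)])
        y = np.array([1] * n + [0] * n)
        truth = (p1 / (1 - p1)) / (p0 / (1 - p0))
        res = additive_logistic(d, y)
        assert res.odds_ratio == pytest.approx(truth, rel=0.04)
        assert res.ci_low < truth < res.ci_high
        assert res.p_value < 1e-100

    def test_null_is_unbiased(self):
        # independent streams for genotype and status: exchangeable null
        d = _binom(np.random.default_rng(101), 0.3, 100_000)
        y = (np.random.default_rng(202).random(100_000) < 0.3).astype(int)
        res = additive_logistic(d, y)
        assert abs(res.beta) < 0.03

    def test_no_variation_errors(self):
        with pytest.raises(ValueError, match="variation"):
            additive_logistic([1] * 20, [0, 1] * 10)

    def test_wald_ci_identity(self, rng):
        d = _binom(rng, 0.4, 2000)
        y = (rng.random(2000) < 1 / (1 + np.exp(1 - 0.4 * d))).astype(int)
        res = additive_logistic(d, y)
        z = 1.959963984540054
        assert res.ci_low == pytest.approx(np.exp(res.beta - z * res.se), rel=1e-12)
        assert res.ci_high == pytest.approx(np.exp(res.beta + z * res.se), rel=1e-12)

    def test_perfect_separation_flagged(self):
        d = np.array([0] * 10 + [2] * 10)
        y = np.array([0] * 10 + [1] * 10)
        res = additive_logistic(d, y)
        assert "unstable" in res.flags or "separation" in res.flags
        assert res.ci_high == np.inf

    def test_sign_agrees_with_trend_test(self, rng):
        d = np.concatenate([_binom(rng, 0.45, 800), _binom(rng, 0.35, 800)])
        y = np.array([1] * 800 + [0] * 800)
        res = additive_logistic(d, y)
        table = np.vstack(
            [np.bincount(d[y == 1], minlength=3), np.bincount(d[y == 0], minlength=3)]
        )
        z, _ = cochran_armitage_trend(table, scores=[0, 1, 2])
        assert np.sign(res.beta) == np.sign(z)

    def test_covariate_adjustment_accepted(self, rng):
        n = 4000
        d = _binom(rng, 0.3, n)
        cov = rng.standard_normal((n, 4))
        sex = rng.choice(["female", "male"], size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(2 - 0.5 * d))).astype(int)
        res = additive_logistic(d, y, covariates=cov, sex=sex)
        assert res.odds_ratio == pytest.approx(np.exp(0.5), rel=0.25)
        assert "covariates" in res.model and "sex" in res.model


class TestCochranArmitage:
    def test_flat_proportions_give_zero(self):
        z, p = cochran_armitage_trend(np.array([[10, 20, 30], [10, 20, 30]]))
        assert (z, p) == (0.0, 1.0)

    def test_2x2_equals_two_proportion_ztest(self):
        table = np.array([[30, 55], [70, 45]], float)
        z, p = cochran_armitage_trend(table)
        z_ref, p_ref = proportions_ztest(table[0], table.sum(axis=0))
        assert abs(z) == pytest.approx(abs(z_ref), abs=1e-10)
        assert p == pytest.approx(p_ref, abs=1e-10)

    def test_matches_permutation_oracle(self, rng):
        """Asymptotic p agrees with a 2×10⁵-permutation oracle within MC error."""
        table = np.array([[10, 20, 30], [30, 20, 10]], float)
        scores = np.array([1.0, 2.0, 3.0])
        z_obs, p_asym = cochran_armitage_trend(table, scores)
        # permutation oracle: shuffle case labels over subjects, recompute T
        col = np.repeat([0, 1, 2], table.sum(axis=0).astype(int))
        y = np.concatenate([np.ones(10), np.zeros(30), np.ones(20), np.zeros(20),
                            np.ones(30), np.zeros(10)])
        n_perm = 200_000
        s_subj = scores[col]
        t_obs = abs(s_subj @ y - y.sum() * s_subj.mean())
        # permutations in blocks to bound memory
        count = 0
        done = 0
        block = 20_000
        while done < n_perm:
            b = min(block, n_perm - done)
            idx = np.argsort(rng.random((b, len(y))), axis=1)
            y_perm = y[idx]
            t = np.abs(y_perm @ s_subj - y.sum() * s_subj.mean())
            count += int((t >= t_obs - 1e-9).sum())
            done += b
        p_perm = count / n_perm
        mc_se = np.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert p_asym == pytest.approx(p_perm, abs=max(4 * mc_se, 5e-4))

    def test_zero_margin_errors(self):
        with pytest.raises(ValueError, match="margin"):
            cochran_armitage_trend(np.array([[0, 0], [5, 5]]))


class TestMannWhitney:
    def test_identical_samples(self):
        _, p = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_complete_separation_u_maximal(self):
        u, _ = mann_whitney([5.0, 6.0, 7.0], [1.0, 2.0])
        assert u == 6  # n·m

    def test_exact_small_sample(self):
        # 6 equally likely orderings; the observed is one extreme → p = 2/6
        _, p = mann_whitney([1.0, 2.0], [3.0, 4.0])
        assert p == pytest.approx(1 / 3, abs=1e-12)

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestQuartileOr:
    def test_reference_quartile_is_unity(self, rng):
        q = rng.integers(1, 5, size=2000)
        y = (rng.random(2000) < 0.1 * q).astype(int)
        res = quartile_or(q, y)
        q1 = res.quartile_results[0]
        assert (q1.term, q1.odds_ratio) == ("Q1", 1.0)

    def test_null_ors_near_one(self, rng):
        q = rng.integers(1, 5, size=8000)
        y = (rng.random(8000) < 0.3).astype(int)
        res = quartile_or(q, y)
        for r in res.quartile_results[1:]:
            assert 0.8 < r.odds_ratio < 1.25
        assert res.trend_p > 0.001

    def test_signal_increases_monotonically(self, rng):
        q = rng.integers(1, 5, size=8000)
        y = (rng.random(8000) < 1 / (1 + np.exp(2.5 - 0.6 * q))).astype(int)
        res = quartile_or(q, y)
        ors = [r.odds_ratio for r in res.quartile_results]
        assert ors[1] < ors[2] < ors[3]
        assert res.trend_p < 1e-10

    def test_empty_cell_flagged(self, rng):
        q = np.concatenate([np.full(50, 1), np.full(50, 2), np.full(50, 3), np.full(50, 4)])
        y = np.concatenate([np.zeros(50), np.ones(50), np.zeros(100)])  # Q1 has no cases
        res = quartile_or(q, y)
        assert any("empty_cell" in f for f in res.flags)


class TestSubphenotype:
    def test_null_association(self, rng):
        wgrs = rng.normal(4.8, 0.9, size=1000)
        label = rng.choice(["no", "yes"], size=1000)
        res = subphenotype_assoc(wgrs, label)
        assert res.ci_low < 1.0 < res.ci_high

    def test_constant_label_errors(self, rng):
        with pytest.raises(ValueError, match="variation"):
            subphenotype_assoc(rng.normal(size=100), ["yes"] * 100)

    def test_early_onset_enrichment_sign(self, rng):
        """Scores shifted +0.5 in early-onset cases → OR for late onset < 1."""
        n = 500
        early = rng.random(n) < 0.6
        wgrs = rng.normal(4.5, 0.9, size=n) + 0.5 * early
        label = np.where(early, "early", "late")  # sorted levels: early=0, late=1
        res = subphenotype_assoc(wgrs, label)
        assert res.term == "late"
        assert res.odds_ratio < 1.0
        assert res.p_value < 0.05

    def test_low_power_flag(self, rng):
        wgrs = np.concatenate([rng.normal(5, 1, 5), rng.normal(4, 1, 200)])
        label = np.array(["yes"] * 5 + ["no"] * 200)
        res = subphenotype_assoc(wgrs, label)
        assert "low_power" in res.flags

    def test_per_sd_scaling(self, rng):
        wgrs = rng.normal(4.8, 0.9, size=2000)
        label = (rng.random(2000) < 1 / (1 + np.exp(3 - 0.6 * wgrs))).astype(float)
        per_unit = subphenotype_assoc(wgrs, label)
        per_sd = subphenotype_assoc(wgrs, label, per_sd=True)
        sd = np.std(wgrs, ddof=1)
        assert per_sd.beta == pytest.approx(per_unit.beta * sd, rel=1e-6)


class TestInteractions:
    def test_pair_count(self, rng, panel):
        cfg = SimConfig(panel=panel, mode="frequency", n_case=300, n_control=300, seed=5)
        gm, st = simulate_case_control(cfg)
        tab = pairwise_interactions(gm, st.table["status"])
        assert len(tab) == 45
        assert tab.attrs["n_tests"] == 45

    def test_product_term_signal_recovered(self, rng):
        """A strong synergistic pair attains the minimum adjusted p-value."""
        n = 20_000
        d = rng.binomial(2, 0.35, size=(n, 4)).astype(np.int8)
        eta = -2.2 + 0.69 * d[:, 0] * d[:, 1]  # interaction OR 2.0, no main effects
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        gm = make_genotypes(d, [f"rs{j}" for j in range(4)])
        tab = pairwise_interactions(gm, y)
        best = tab.loc[tab["p_int"].idxmin()]
        assert {best["snp_i"], best["snp_j"]} == {"rs0", "rs1"}
        assert best["p_bonferroni"] < 1e-6
        assert best["beta_int"] == pytest.approx(0.69, abs=0.15)

    def test_too_few_snps_errors(self, rng):
        gm = make_genotypes(rng.integers(0, 3, size=(50, 1)), ["rs0"])
        with pytest.raises(ValueError, match="2 SNPs"):
            pairwise_interactions(gm, rng.integers(0, 2, size=50))
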
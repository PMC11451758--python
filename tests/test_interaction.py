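"""SNP x SNP interaction models, joint cis-epistasis disambiguation and
stratified effect estimates."""

import numpy as np
import pytest
from scipy import stats

from vqtlscan.interaction import (
    DegenerateDesignError,
    interaction_scan,
    interaction_test,
    joint_interaction_test,
    pathogenic_allele_count,
    stratified_odds_ratios,
    stratified_trait_means,
)
from vqtlscan.simulate import (
    LogisticSpec,
    TraitSpec,
    simulate_binary,
    simulate_covariates,
    simulate_genotypes,
    simulate_ld_pair,
    simulate_trait,
)


def brute_force_interaction(y, g1, g2, X=None):
    cols = [np.ones(len(y)), g1, g2, g1 * g2]
    if X is not None:
        cols.append(X)
    D = np.column_stack(cols)
    beta = np.linalg.solve(D.T @ D, D.T @ y)
    resid = y - D @ beta
    df = len(y) - D.shape[1]
    sigma2 = resid @ resid / df
    se = np.sqrt(sigma2 * np.linalg.inv(D.T @ D)[3, 3])
    p = 2 * stats.t.sf(abs(beta[3] / se), df)
    return beta[3], se, p


class TestInteractionTest:
    def test_matches_brute_force_least_squares(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = 400
            g1 = rng.binomial(2, 0.3, n).astype(float)
            g2 = rng.binomial(2, 0.4, n).astype(float)
            X = rng.standard_normal((n, 3))
            y = 0.1 * g1 - 0.2 * g2 + 0.05 * g1 * g2 + rng.standard_normal(n)
            r = interaction_test(y, g1, g2, X)
            beta, se, p = brute_force_interaction(y, g1, g2, X)
            assert np.isclose(r.beta_int, beta, rtol=1e-8)
            assert np.isclose(r.se, se, rtol=1e-8)
            assert np.isclose(r.p, p, rtol=1e-6)
            assert np.isclose(r.ci_low, r.beta_int - 1.959963984540054 * r.se, atol=1e-10)

    def test_exchange_symmetry(self):
        rng = np.random.default_rng(1)
        g1 = rng.binomial(2, 0.3, 500).astype(float)
        g2 = rng.binomial(2, 0.4, 500).astype(float)
        y = rng.standard_normal(500)
        a = interaction_test(y, g1, g2)
        b = interaction_test(y, g2, g1)
        assert np.isclose(a.beta_int, b.beta_int, atol=1e-12)
        assert np.isclose(a.p, b.p, atol=1e-12)

    def test_constant_partner_is_degenerate(self):
        rng = np.random.default_rng(2)
        g1 = rng.binomial(2, 0.3, 100).astype(float)
        with pytest.raises(DegenerateDesignError):
            interaction_test(rng.standard_normal(100), g1, np.ones(100))

    def test_logistic_recovers_interaction_log_odds(self):
        from scipy.special import logit

        gm = simulate_genotypes(100_000, [0.3, 0.3], seed=61)
        cov = simulate_covariates(100_000, seed=62, n_pcs=2)
        spec = LogisticSpec(
            intercept=logit(0.10),
            log_odds={"v0": 0.1, "v1": 0.1},
            log_odds_int={("v0", "v1"): 0.31},
        )
        ph = simulate_binary(gm, cov, spec, seed=63)
        r = interaction_test(
            ph["outcome"].to_numpy(), gm.dosage("v0"), gm.dosage("v1"), family="logistic"
        )
        assert abs(r.beta_int - 0.31) < 3 * r.se
        assert not r.flags


class TestInteractionScan:
    def test_planted_partner_ranks_first(self):
        gm = simulate_genotypes(20_000, [0.25] * 30, seed=64)
        cov = simulate_covariates(20_000, seed=65, n_pcs=2)
        ph = simulate_trait(gm, cov, TraitSpec(beta_int={("v0", "v7"): 0.15}), seed=66)
        results, excluded = interaction_scan(gm, "v0", ph["trait"].to_numpy())
        assert excluded["v0"] == "focal"
        assert results[0].partner == "v7"

    def test_null_scan_lambda_near_one(self):
        from vqtlscan.scan import genomic_control_lambda

        gm = simulate_genotypes(5000, [0.3] * 200, seed=67)
        rng = np.random.default_rng(68)
        results, _ = interaction_scan(gm, "v0", rng.standard_normal(5000))
        lam = genomic_control_lambda([r.p for r in results])
        assert 0.85 < lam < 1.15


class TestJointModel:
    def test_disambiguates_ld_proxy_from_true_partner(self):
        """With g_a a D'=0.95 proxy of the true interactor g_b, the joint
        model keeps g_b's product term and nulls g_a's."""
        wins = 0
        for seed in range(25):
            hap, pair = simulate_ld_pair(20_000, 0.3, 0.25, 0.95, seed=700 + seed)
            rng = np.random.default_rng(800 + seed)
            gf = rng.binomial(2, 0.4, 20_000).astype(float)
            ga = pair.dosages[:, 0].astype(float)
            gb = pair.dosages[:, 1].astype(float)
            y = 0.15 * gf * gb + rng.standard_normal(20_000)
            res_a, res_b = joint_interaction_test(y, gf, ga, gb)
            wins += (res_b.p < 1e-4) and (res_a.p > 0.01)
        assert wins >= 20

    def test_independent_loci_converse(self):
        rng = np.random.default_rng(9)
        n = 20_000
        gf = rng.binomial(2, 0.4, n).astype(float)
        ga = rng.binomial(2, 0.3, n).astype(float)
        gb = rng.binomial(2, 0.3, n).astype(float)
        y = 0.15 * gf * ga + rng.standard_normal(n)
        res_a, res_b = joint_interaction_test(y, gf, ga, gb)
        assert res_a.p < 1e-6
        assert res_b.p > 0.01


class TestPathogenicAlleleCount:
    def test_compound_heterozygote_counts_two(self):
        out = pathogenic_allele_count([1, 0, 2], [1, 0, 1])
        assert out["count"].tolist() == [2, 0, 3]
        assert out["group"].tolist() == [2, 0, 2]


class TestStratifiedMeans:
    def test_single_stratum_equals_overall_mean(self):
        y = np.array([1.0, 2.0, 3.0])
        strata = stratified_trait_means(y, np.zeros(3), np.zeros(3))
        assert len(strata) == 1
        assert strata[0].estimate == y.mean()

    def test_pooled_reconstruction_identity(self):
        rng = np.random.default_rng(3)
        y = rng.standard_normal(2000)
        g1 = rng.binomial(2, 0.4, 2000)
        g2 = rng.binomial(2, 0.4, 2000)
        strata = stratified_trait_means(y, g1, g2)
        pooled = sum(s.n * s.estimate for s in strata) / sum(s.n for s in strata)
        assert np.isclose(pooled, y.mean(), atol=1e-10)

    def test_no_interaction_contrast_near_zero(self):
        gm = simulate_genotypes(100_000, [0.4, 0.4], seed=71)
        cov = simulate_covariates(100_000, seed=72, n_pcs=2)
        ph = simulate_trait(
            gm, cov, TraitSpec(beta_mean={"v0": 0.2, "v1": 0.2}), seed=73
        )
        strata = {(s.g1_dosage, s.g2_dosage): s for s in stratified_trait_means(
            ph["trait"].to_numpy(), gm.dosage("v0"), gm.dosage("v1"))}
        # additive model: m(1,1) - m(1,0) - m(0,1) + m(0,0) = 0
        contrast = (
            strata[(1, 1)].estimate - strata[(1, 0)].estimate
            - strata[(0, 1)].estimate + strata[(0, 0)].estimate
        )
        se = np.sqrt(sum(strata[k].se ** 2 for k in [(1, 1), (1, 0), (0, 1), (0, 0)]))
        assert abs(contrast) < 3 * se


class TestStratifiedOddsRatios:
    def test_direct_two_by_two_formula(self):
        # stratum 30 cases / 70 controls vs reference 10 / 90
        y = np.concatenate([np.ones(30), np.zeros(70), np.ones(10), np.zeros(90)])
        g1 = np.concatenate([np.ones(100), np.zeros(100)])
        g2 = np.zeros(200)
        strata = {s.g1_dosage: s for s in stratified_odds_ratios(y, g1, g2)}
        expected_or = (30 * 90) / (70 * 10)
        expected_se = np.sqrt(1 / 30 + 1 / 70 + 1 / 10 + 1 / 90)
        assert np.isclose(strata[1].estimate, expected_or)
        assert np.isclose(strata[1].estimate, 3.857, atol=5e-4)
        assert np.isclose(strata[1].se, expected_se)
        assert strata[0].estimate == 1.0

    def test_independent_outcome_gives_or_near_one(self):
        rng = np.random.default_rng(4)
        n = 50_000
        y = rng.binomial(1, 0.2, n)
        g1 = rng.binomial(2, 0.4, n)
        g2 = rng.binomial(2, 0.4, n)
        for s in stratified_odds_ratios(y, g1, g2):
            if s.n > 500 and s.se > 0:
                assert s.ci_low < 1.0 < s.ci_high

    def test_zero_cell_continuity_correction_flagged(self):
        y = np.array([1, 1, 0, 0, 0, 0])
        g1 = np.array([1, 1, 1, 0, 0, 0])
        g2 = np.zeros(6)
        strata = {s.g1_dosage: s for s in stratified_odds_ratios(y, g1, g2)}
        assert strata[1].continuity_corrected
        assert strata[1].estimate > 0

    def test_main_effects_only_multiplicative(self):
        from scipy.special import logit

        gm = simulate_genotypes(200_000, [0.4, 0.4], seed=74)
        cov = simulate_covariates(200_000, seed=75, n_pcs=2)
        spec = LogisticSpec(intercept=logit(0.15), log_odds={"v0": 0.3, "v1": 0.3})
        ph = simulate_binary(gm, cov, spec, seed=76)
        strata = {(s.g1_dosage, s.g2_dosage): s for s in stratified_odds_ratios(
            ph["outcome"].to_numpy(), gm.dosage("v0"), gm.dosage("v1"))}
        combo = strata[(1, 1)]
        predicted = strata[(1, 0)].estimate * strata[(0, 1)].estimate
        z = abs(np.log(combo.estimate) - np.log(predicted)) / combo.se
        assert z < 3
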
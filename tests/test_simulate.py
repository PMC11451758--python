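"""Generative checks on the synthetic-cohort module: HWE, LD targets,
trait variance structure and determinism."""

import numpy as np
import pytest
from scipy import stats

from vqtlscan.containers import DataError, ParameterError
from vqtlscan.ld import ld_from_haplotypes
from vqtlscan.simulate import (
    LogisticSpec,
    TraitSpec,
    simulate_binary,
    simulate_covariates,
    simulate_genotypes,
    simulate_ld_pair,
    simulate_trait,
)


class TestGenotypes:
    def test_allele_frequency_within_binomial_bound(self):
        n, p = 100_000, 0.10
        gm = simulate_genotypes(n, [p], seed=1)
        bound = 3 * np.sqrt(p * (1 - p) / (2 * n))
        assert abs(gm.allele_freq()[0] - p) < bound

    def test_hwe_class_proportions_at_half(self):
        gm = simulate_genotypes(100_000, [0.5], seed=2)
        counts = np.bincount(gm.dosages[:, 0], minlength=3) / 100_000
        assert np.allclose(counts, [0.25, 0.5, 0.25], atol=0.01)

    def test_degenerate_frequency_all_reference(self):
        gm = simulate_genotypes(1000, [1e-6], seed=3)
        assert (gm.dosages == 0).all()

    def test_determinism_bit_identical(self):
        a = simulate_genotypes(500, [0.2, 0.4], seed=9)
        b = simulate_genotypes(500, [0.2, 0.4], seed=9)
        assert (a.dosages == b.dosages).all()
        assert not (a.dosages == simulate_genotypes(500, [0.2, 0.4], seed=10).dosages).all()

    def test_hwe_chi_squared_rarely_significant(self):
        # HWE goodness of fit at alpha=0.001 across seeds
        failures = 0
        for seed in range(20):
            gm = simulate_genotypes(100_000, [0.3], seed=seed)
            obs = np.bincount(gm.dosages[:, 0], minlength=3)
            p = gm.allele_freq()[0]
            exp = 100_000 * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
            chi2 = ((obs - exp) ** 2 / exp).sum()
            failures += stats.chi2.sf(chi2, df=1) < 0.001
        assert failures <= 1

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.5])
    def test_invalid_maf_raises(self, bad):
        with pytest.raises(ParameterError):
            simulate_genotypes(100, [bad], seed=0)


class TestLDPair:
    def test_composition_haplotypes_sum_to_dosages(self):
        hap, gm = simulate_ld_pair(2000, 0.3, 0.2, 0.6, seed=4)
        assert (hap.hap1 + hap.hap2 == gm.dosages).all()

    def test_equilibrium_gives_near_zero_correlation(self):
        _, gm = simulate_ld_pair(50_000, 0.3, 0.4, 0.0, seed=5)
        r = np.corrcoef(gm.dosages[:, 0], gm.dosages[:, 1])[0, 1]
        assert abs(r) < 0.02

    def test_perfect_ld_identical_dosages(self):
        _, gm = simulate_ld_pair(5000, 0.5, 0.5, 1.0, seed=6)
        assert (gm.dosages[:, 0] == gm.dosages[:, 1]).all()

    def test_d_prime_recovered_from_realized_haplotypes(self):
        hap, _ = simulate_ld_pair(50_000, 0.3, 0.2, 0.6, seed=7)
        alleles = np.vstack([hap.hap1, hap.hap2])
        counts = [
            ((alleles[:, 0] == a) & (alleles[:, 1] == b)).sum()
            for a, b in [(1, 1), (1, 0), (0, 1), (0, 0)]
        ]
        realized = ld_from_haplotypes(*counts)
        assert abs(realized.d_prime - 0.6) < 0.05

    def test_infeasible_d_prime_raises(self):
        with pytest.raises(ParameterError):
            simulate_ld_pair(100, 0.3, 0.2, 1.5, seed=0)


class TestTrait:
    def test_pure_noise_mean_and_variance(self):
        gm = simulate_genotypes(100_000, [0.3], seed=8)
        cov = simulate_covariates(100_000, seed=9, n_pcs=2)
        ph = simulate_trait(gm, cov, TraitSpec(intercept=1.5), seed=10)
        assert abs(ph["trait"].mean() - 1.5) < 0.02
        assert abs(ph["trait"].var() - 1.0) < 0.02

    def test_log_linear_variance_group_ratio(self):
        # gamma_var=0.5: Var(dosage 2) / Var(dosage 0) = e^1
        gm = simulate_genotypes(100_000, [0.5], seed=11)
        cov = simulate_covariates(100_000, seed=12, n_pcs=2)
        ph = simulate_trait(gm, cov, TraitSpec(gamma_var={"v0": 0.5}), seed=13)
        g = gm.dosages[:, 0]
        y = ph["trait"].to_numpy()
        ratio = y[g == 2].var() / y[g == 0].var()
        assert abs(ratio - np.e) < 0.1

    def test_unknown_variant_raises(self):
        gm = simulate_genotypes(100, [0.3], seed=1)
        cov = simulate_covariates(100, seed=2, n_pcs=2)
        with pytest.raises(DataError):
            simulate_trait(gm, cov, TraitSpec(beta_mean={"nope": 1.0}), seed=3)

    def test_interaction_ci_coverage(self):
        # 95% Wald CI for a generated interaction of 0.1 covers it >= 90/100
        from vqtlscan.interaction import interaction_test

        covered = 0
        for seed in range(100):
            gm = simulate_genotypes(2000, [0.3, 0.3], seed=1000 + seed)
            cov = simulate_covariates(2000, seed=2000 + seed, n_pcs=2)
            spec = TraitSpec(beta_int={("v0", "v1"): 0.1})
            ph = simulate_trait(gm, cov, spec, seed=3000 + seed)
            r = interaction_test(ph["trait"].to_numpy(), gm.dosage("v0"), gm.dosage("v1"))
            covered += r.ci_low <= 0.1 <= r.ci_high
        assert covered >= 90


class TestBinary:
    def test_null_prevalence(self):
        gm = simulate_genotypes(100_000, [0.3], seed=14)
        cov = simulate_covariates(100_000, seed=15, n_pcs=2)
        ph = simulate_binary(gm, cov, LogisticSpec(), seed=16)
        assert abs(ph["outcome"].mean() - 0.05) < 0.005

    def test_interaction_makes_odds_super_multiplicative(self):
        from scipy.special import logit

        from vqtlscan.interaction import stratified_odds_ratios

        gm = simulate_genotypes(200_000, [0.4, 0.4], seed=17)
        cov = simulate_covariates(200_000, seed=18, n_pcs=2)
        spec = LogisticSpec(
            intercept=logit(0.10),
            log_odds={"v0": 0.1, "v1": 0.1},
            log_odds_int={("v0", "v1"): 0.31},
        )
        ph = simulate_binary(gm, cov, spec, seed=19)
        strata = stratified_odds_ratios(
            ph["outcome"].to_numpy(), gm.dosage("v0"), gm.dosage("v1")
        )
        by_combo = {(s.g1_dosage, s.g2_dosage): s.estimate for s in strata}
        # OR(2,2) should exceed the product of the marginal ORs OR(2,0)*OR(0,2)
        assert by_combo[(2, 2)] > by_combo[(2, 0)] * by_combo[(0, 2)] * 1.5

    def test_marginal_effect_attenuated_vs_strata(self):
        import statsmodels.api as sm

        gm = simulate_genotypes(100_000, [0.3, 0.3], seed=20)
        cov = simulate_covariates(100_000, seed=21, n_pcs=2)
        from scipy.special import logit

        spec = LogisticSpec(intercept=logit(0.1), log_odds_int={("v0", "v1"): 0.5})
        ph = simulate_binary(gm, cov, spec, seed=22)
        y = ph["outcome"].to_numpy()
        g1, g2 = gm.dosage("v0"), gm.dosage("v1")
        marg = sm.GLM(y, np.column_stack([np.ones_like(g1), g1]),
                      family=sm.families.Binomial()).fit()
        # conditional effect of g1 among g2 hom-alt individuals
        mask = g2 == 2
        cond = sm.GLM(y[mask], np.column_stack([np.ones(mask.sum()), g1[mask]]),
                      family=sm.families.Binomial()).fit()
        assert marg.params[1] < cond.params[1]
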
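"""Synthetic cohort generator.

Simulates genotypes under Hardy-Weinberg equilibrium, optional pairwise LD at
a target D', covariates shaped like a biobank phenotype table (age, age
squared, sex, ancestry PCs), quantitative traits with per-variant mean
effects, log-linear variance effects and pairwise interaction effects, and
logistic binary outcomes. Every function takes an explicit integer ``seed``
and is bit-reproducible given it; there is no global random state.

The variance effect is multiplicative on the residual variance with
log-linear genotype dependence, i.e. ``Var(eps_i) = base_sd**2 *
exp(sum_v gamma_var[v] * g_iv)``, which makes the gamma/log-link dispersion
submodel of :mod:`vqtlscan.dglm` correctly specified, so parameter recovery
is a clean end-to-end check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .containers import (
    DataError,
    GenotypeMatrix,
    HaplotypePair,
    ParameterError,
    covariate_columns,
)

__all__ = [
    "TraitSpec",
    "LogisticSpec",
    "simulate_genotypes",
    "simulate_ld_pair",
    "simulate_covariates",
    "simulate_trait",
    "simulate_binary",
]


@dataclass
class TraitSpec:
    """Generative specification for a quantitative trait.

    ``beta_mean`` maps variant id -> additive effect (trait units per alt
    allele); ``gamma_var`` maps variant id -> log-variance effect per allele;
    ``beta_int`` maps (id, id) pairs -> interaction effect per allele
    product; ``covariate_effects`` maps covariate column -> effect.
    """

    beta_mean: dict[str, float] = field(default_factory=dict)
    gamma_var: dict[str, float] = field(default_factory=dict)
    beta_int: dict[tuple[str, str], float] = field(default_factory=dict)
    covariate_effects: dict[str, float] = field(default_factory=dict)
    base_sd: float = 1.0
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if self.base_sd <= 0:
            raise ParameterError("base_sd must be positive")

    def referenced_variants(self) -> set[str]:
        out = set(self.beta_mean) | set(self.gamma_var)
        for u, v in self.beta_int:
            out.add(u)
            out.add(v)
        return out


@dataclass
class LogisticSpec:
    """Generative specification for a binary outcome on the log-odds scale."""

    intercept: float = logit(0.05)
    log_odds: dict[str, float] = field(default_factory=dict)
    log_odds_int: dict[tuple[str, str], float] = field(default_factory=dict)
    covariate_effects: dict[str, float] = field(default_factory=dict)

    def referenced_variants(self) -> set[str]:
        out = set(self.log_odds)
        for u, v in self.log_odds_int:
            out.add(u)
            out.add(v)
        return out


def _check_mafs(mafs) -> np.ndarray:
    mafs = np.asarray(mafs, dtype=float)
    if np.any((mafs <= 0) | (mafs >= 1)):
        raise ParameterError("allele frequencies must lie strictly in (0, 1)")
    return mafs


def simulate_genotypes(
    n: int,
    mafs,
    seed: int,
    ids: list[str] | None = None,
    chrom: str = "1",
    start_pos: int = 1000,
    pos_step: int = 1000,
) -> GenotypeMatrix:
    """Draw ``n`` individuals at independent HWE variants.

    Each variant's dosage is sampled i.i.d. with genotype probabilities
    ``((1-p)^2, 2p(1-p), p^2)`` at alternate-allele frequency ``p``.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    mafs = _check_mafs(mafs)
    rng = np.random.default_rng(seed)
    m = len(mafs)
    # two independent allele draws per individual = HWE by construction;
    # generated in variant blocks to bound peak memory at wide matrices
    dosages = np.empty((n, m), dtype=np.int8)
    block = 256
    for j0 in range(0, m, block):
        j1 = min(j0 + block, m)
        p = mafs[None, None, j0:j1]
        alleles = rng.random((2, n, j1 - j0)) < p
        dosages[:, j0:j1] = alleles.sum(axis=0, dtype=np.int8)
    if ids is None:
        ids = [f"v{i}" for i in range(m)]
    variants = pd.DataFrame(
        {
            "id": ids,
            "chrom": chrom,
            "pos": start_pos + pos_step * np.arange(m),
            "ref": "A",
            "alt": "G",
        }
    )
    return GenotypeMatrix(dosages, variants)


def _haplotype_freqs(pA: float, pB: float, d_prime: float) -> np.ndarray:
    """Haplotype frequencies (AB, Ab, aB, ab) at a target D'."""
    if not -1.0 <= d_prime <= 1.0:
        raise ParameterError("d_prime must lie in [-1, 1]")
    if d_prime >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    D = d_prime * dmax
    freqs = np.array(
        [
            pA * pB + D,
            pA * (1 - pB) - D,
            (1 - pA) * pB - D,
            (1 - pA) * (1 - pB) + D,
        ]
    )
    if np.any(freqs < -1e-12) or np.any(freqs > 1 + 1e-12):
        bad = ["AB", "Ab", "aB", "ab"][int(np.argmin(freqs))]
        raise ParameterError(
            f"infeasible (pA={pA}, pB={pB}, d_prime={d_prime}): "
            f"haplotype frequency {bad} outside [0, 1]"
        )
    return np.clip(freqs, 0.0, 1.0)


def simulate_ld_pair(
    n: int,
    pA: float,
    pB: float,
    d_prime: float,
    seed: int,
    ids: tuple[str, str] = ("vA", "vB"),
    chrom: str = "1",
    positions: tuple[int, int] = (1000, 2000),
) -> tuple[HaplotypePair, GenotypeMatrix]:
    """Simulate two variants with a target D' from the 4-class haplotype model.

    Each individual receives two independent haplotypes; genotypes are the
    haplotype sums, so ``hap1 + hap2 == dosages`` exactly.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    _check_mafs([pA, pB])
    freqs = _haplotype_freqs(pA, pB, d_prime)
    rng = np.random.default_rng(seed)
    # haplotype classes: 0=AB, 1=Ab, 2=aB, 3=ab
    cls = rng.choice(4, size=(2, n), p=freqs / freqs.sum())
    carries_A = np.isin(cls, (0, 1)).astype(np.int8)
    carries_B = np.isin(cls, (0, 2)).astype(np.int8)
    hap1 = np.stack([carries_A[0], carries_B[0]], axis=1)
    hap2 = np.stack([carries_A[1], carries_B[1]], axis=1)
    pair = HaplotypePair(hap1, hap2)
    variants = pd.DataFrame(
        {
            "id": list(ids),
            "chrom": chrom,
            "pos": list(positions),
            "ref": "A",
            "alt": "G",
        }
    )
    gm = GenotypeMatrix(pair.dosages().astype(np.int8), variants)
    return pair, gm


def simulate_covariates(n: int, seed: int, n_pcs: int = 10) -> pd.DataFrame:
    """Covariate table: age ~ U(40, 70), sex ~ Bernoulli(0.5), PCs ~ N(0,1)."""
    rng = np.random.default_rng(seed)
    age = rng.uniform(40, 70, size=n)
    table = {
        "individual_id": [f"I{i}" for i in range(n)],
        "age": age,
        "age2": age**2,
        "sex": rng.integers(0, 2, size=n).astype(float),
    }
    for i in range(1, n_pcs + 1):
        table[f"PC{i}"] = rng.standard_normal(n)
    return pd.DataFrame(table)


def _genotype_columns(genotypes: GenotypeMatrix, wanted: set[str]) -> dict[str, np.ndarray]:
    known = set(genotypes.variant_ids)
    absent = wanted - known
    if absent:
        raise DataError(f"trait spec references variants absent from genotypes: {sorted(absent)}")
    return {v: genotypes.dosage(v) for v in wanted}


def simulate_trait(
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame,
    spec: TraitSpec,
    seed: int,
    name: str = "trait",
) -> pd.DataFrame:
    """Quantitative trait from the additive + interaction + log-linear variance model.

    trait_i = intercept + sum_v beta_mean[v] g_iv
              + sum_(u,v) beta_int[(u,v)] g_iu g_iv
              + sum_c covariate_effects[c] x_ic + eps_i,
    eps_i ~ Normal(0, base_sd^2 * exp(sum_v gamma_var[v] g_iv)).
    """
    n = genotypes.n_individuals
    if len(covariates) != n:
        raise DataError("covariate table and genotype matrix differ in individuals")
    g = _genotype_columns(genotypes, spec.referenced_variants())
    mu = np.full(n, spec.intercept, dtype=float)
    for v, b in spec.beta_mean.items():
        mu += b * g[v]
    for (u, v), b in spec.beta_int.items():
        mu += b * g[u] * g[v]
    for c, b in spec.covariate_effects.items():
        if c not in covariates.columns:
            raise DataError(f"covariate {c!r} absent from covariate table")
        mu += b * covariates[c].to_numpy(dtype=float)
    log_var = 2.0 * np.log(spec.base_sd) + sum(
        gv * g[v] for v, gv in spec.gamma_var.items()
    )
    rng = np.random.default_rng(seed)
    values = mu + rng.standard_normal(n) * np.exp(0.5 * np.asarray(log_var))
    out = covariates.copy()
    out[name] = values
    return out


def simulate_binary(
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame,
    spec: LogisticSpec,
    seed: int,
    name: str = "outcome",
) -> pd.DataFrame:
    """Binary outcome: outcome_i ~ Bernoulli(expit(linear predictor))."""
    n = genotypes.n_individuals
    if len(covariates) != n:
        raise DataError("covariate table and genotype matrix differ in individuals")
    g = _genotype_columns(genotypes, spec.referenced_variants())
    eta = np.full(n, spec.intercept, dtype=float)
    for v, b in spec.log_odds.items():
        eta += b * g[v]
    for (u, v), b in spec.log_odds_int.items():
        eta += b * g[u] * g[v]
    for c, b in spec.covariate_effects.items():
        if c not in covariates.columns:
            raise DataError(f"covariate {c!r} absent from covariate table")
        eta += b * covariates[c].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    out = covariates.copy()
    out[name] = (rng.random(n) < expit(eta)).astype(int)
    return out
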
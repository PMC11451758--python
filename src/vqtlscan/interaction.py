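"""SNP x SNP interaction models and stratified effect estimates.

The interaction model is ``phenotype ~ g1 + g2 + g1*g2 + covariates`` with
additive dosage coding: OLS for quantitative traits, maximum-likelihood
logistic regression (IRLS) for binary outcomes, and a Wald test on the
product coefficient. Confidence intervals are Wald (beta +/- 1.96 se)
throughout. Stratified estimates report per-genotype-combination means (with
se = sd/sqrt(n)) for traits and 2x2-table odds ratios against a reference
combination for outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .containers import GenotypeMatrix

__all__ = [
    "InteractionModel",
    "InteractionResult",
    "StratumEstimate",
    "interaction_test",
    "interaction_scan",
    "joint_interaction_test",
    "pathogenic_allele_count",
    "stratified_trait_means",
    "stratified_odds_ratios",
    "interactions_to_frame",
    "strata_to_frame",
]

Z95 = 1.959963984540054  # Phi^-1(0.975)
SEPARATION_BOUND = 20.0


class DegenerateDesignError(ValueError):
    """The interaction design is rank deficient (e.g. a constant genotype)."""


@dataclass
class InteractionResult:
    """Wald test of the g1*g2 product coefficient with both main effects."""

    focal: str
    partner: str
    beta_int: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    family: str
    n: int
    beta_focal: float = np.nan
    se_focal: float = np.nan
    beta_partner: float = np.nan
    se_partner: float = np.nan
    flags: list[str] = field(default_factory=list)


@dataclass
class StratumEstimate:
    """Per genotype-combination estimate: a mean (traits) or an odds ratio."""

    label: str
    g1_dosage: int
    g2_dosage: int
    n: int
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p: float = np.nan
    kind: str = "mean"  # "mean" or "odds_ratio"
    continuity_corrected: bool = False


class InteractionModel:
    """Two-variant interaction model with covariates.

    ``family`` is ``"linear"`` (OLS) or ``"logistic"`` (binomial GLM fitted
    by IRLS, max 100 iterations). ``extra_products`` adds further focal x g
    product terms, enabling the joint model used to disambiguate cis
    epistasis (two product terms fitted simultaneously).
    """

    def __init__(
        self,
        endog,
        g1,
        g2,
        covariates=None,
        family: str = "linear",
        extra_products: dict[str, np.ndarray] | None = None,
        names: tuple[str, str] = ("g1", "g2"),
    ):
        y = np.asarray(getattr(endog, "values", endog), dtype=float)
        g1 = np.asarray(g1, dtype=float)
        g2 = np.asarray(g2, dtype=float)
        if not len(y) == len(g1) == len(g2):
            raise ValueError("endog, g1 and g2 must be aligned to the same individuals")
        cols = [np.ones(len(y)), g1, g2]
        self.term_names = ["const", names[0], names[1]]
        extra_products = extra_products or {}
        for nm, g in extra_products.items():
            cols.append(np.asarray(g, dtype=float))
            self.term_names.append(nm)
        cols.append(g1 * g2)
        self.product_name = f"{names[0]}:{names[1]}"
        self.term_names.append(self.product_name)
        self.extra_product_names = []
        for nm, g in extra_products.items():
            cols.append(g1 * np.asarray(g, dtype=float))
            pn = f"{names[0]}:{nm}"
            self.extra_product_names.append(pn)
            self.term_names.append(pn)
        if covariates is not None:
            C = np.asarray(covariates, dtype=float)
            if C.ndim == 1:
                C = C[:, None]
            cnames = [f"x{i}" for i in range(C.shape[1])]
            if hasattr(covariates, "columns"):
                cnames = [str(c) for c in covariates.columns]
            cols.extend(C.T)
            self.term_names.extend(cnames)
        X = np.column_stack(cols)
        keep = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
        self.endog = y[keep]
        self.exog = X[keep]
        self.family = family
        self.names = names
        if np.linalg.matrix_rank(self.exog) < self.exog.shape[1]:
            raise DegenerateDesignError(
                "interaction design is rank deficient "
                "(constant genotype or collinear product term)"
            )

    def fit(self):
        flags: list[str] = []
        if self.family == "linear":
            res = sm.OLS(self.endog, self.exog).fit()
            params, bse = res.params, res.bse
            df = res.df_resid
            pvals = 2.0 * stats.t.sf(np.abs(params / bse), df)
        elif self.family == "logistic":
            glm = sm.GLM(self.endog, self.exog, family=sm.families.Binomial())
            res = glm.fit(maxiter=100, tol=1e-10)
            params, bse = res.params, res.bse
            pvals = 2.0 * stats.norm.sf(np.abs(params / bse))
            if not res.converged:
                flags.append("nonconvergence")
            if np.any(np.abs(params) > SEPARATION_BOUND):
                flags.append("separation")
        else:
            raise ValueError(f"unknown family {self.family!r}")
        table = pd.DataFrame(
            {"coef": params, "se": bse, "p": pvals}, index=self.term_names
        )
        return table, flags

    def result(self, focal_id: str = "g1", partner_id: str = "g2") -> InteractionResult:
        table, flags = self.fit()
        return self._extract(table, flags, self.product_name, focal_id, partner_id)

    def _extract(self, table, flags, product, focal_id, partner_id) -> InteractionResult:
        b = float(table.loc[product, "coef"])
        s = float(table.loc[product, "se"])
        return InteractionResult(
            focal=focal_id,
            partner=partner_id,
            beta_int=b,
            se=s,
            ci_low=b - Z95 * s,
            ci_high=b + Z95 * s,
            p=float(table.loc[product, "p"]),
            family=self.family,
            n=len(self.endog),
            beta_focal=float(table.loc[self.names[0], "coef"]),
            se_focal=float(table.loc[self.names[0], "se"]),
            beta_partner=float(table.loc[self.names[1], "coef"]),
            se_partner=float(table.loc[self.names[1], "se"]),
            flags=list(flags),
        )


def interaction_test(
    phenotype,
    g1,
    g2,
    covariates=None,
    family: str = "linear",
    focal_id: str = "g1",
    partner_id: str = "g2",
) -> InteractionResult:
    """Fit ``phenotype ~ g1 + g2 + g1*g2 + covariates`` and test the product term."""
    model = InteractionModel(phenotype, g1, g2, covariates, family=family)
    return model.result(focal_id, partner_id)


def interaction_scan(
    genotypes: GenotypeMatrix,
    focal: str,
    phenotype,
    covariates=None,
    family: str = "linear",
    maf_min: float = 0.001,
    missing_rate_max: float = 0.1,
) -> tuple[list[InteractionResult], dict[str, str]]:
    """Interaction test of a focal variant against every other passing variant."""
    g_focal = genotypes.dosage(focal)
    maf = genotypes.maf()
    miss = genotypes.missing_rate()
    results: list[InteractionResult] = []
    excluded: dict[str, str] = {}
    for j, vid in enumerate(genotypes.variant_ids):
        if vid == focal:
            excluded[vid] = "focal"
            continue
        if miss[j] > missing_rate_max:
            excluded[vid] = "missing_rate"
            continue
        if not np.isfinite(maf[j]) or maf[j] < maf_min:
            excluded[vid] = "maf"
            continue
        g = genotypes.dosages[:, j].astype(float)
        g[g == -1] = np.nan
        try:
            results.append(
                interaction_test(
                    phenotype, g_focal, g, covariates, family, focal, vid
                )
            )
        except DegenerateDesignError:
            excluded[vid] = "degenerate"
    results.sort(key=lambda r: r.p)
    return results, excluded


def joint_interaction_test(
    phenotype,
    g_focal,
    g_a,
    g_b,
    covariates=None,
    family: str = "linear",
    ids: tuple[str, str, str] = ("focal", "a", "b"),
) -> tuple[InteractionResult, InteractionResult]:
    """Joint model with both focal x a and focal x b product terms.

    Fitting the two interactions simultaneously separates a genuine
    interaction partner from a proxy in linkage disequilibrium with it: only
    the true partner's product term remains significant.
    """
    model = InteractionModel(
        phenotype,
        g_focal,
        g_a,
        covariates,
        family=family,
        extra_products={ids[2]: np.asarray(g_b, dtype=float)},
        names=(ids[0], ids[1]),
    )
    table, flags = model.fit()
    res_a = model._extract(table, flags, f"{ids[0]}:{ids[1]}", ids[0], ids[1])
    res_b = model._extract(table, flags, f"{ids[0]}:{ids[2]}", ids[0], ids[2])
    b = float(table.loc[ids[2], "coef"])
    s = float(table.loc[ids[2], "se"])
    res_b.beta_partner, res_b.se_partner = b, s
    return res_a, res_b


def pathogenic_allele_count(g_v1, g_v2) -> pd.DataFrame:
    """Combined pathogenic allele count across two sites in one gene.

    A compound heterozygote (one alt allele at each site) carries two
    pathogenic alleles. ``group`` pools counts >= 2 into "2"; the raw sum is
    retained in ``count``.
    """
    c = np.asarray(g_v1, dtype=float) + np.asarray(g_v2, dtype=float)
    group = np.where(c >= 2, 2.0, c)
    return pd.DataFrame({"count": c, "group": group})


def _combo_label(d1, d2, alleles1=None, alleles2=None) -> str:
    def geno(d, alleles):
        if alleles is None:
            return str(int(d))
        ref, alt = alleles
        return {0: f"{ref}/{ref}", 1: f"{ref}/{alt}", 2: f"{alt}/{alt}"}[int(d)]

    return f"{geno(d1, alleles1)} x {geno(d2, alleles2)}"


def stratified_trait_means(
    trait, g1, g2, alleles1=None, alleles2=None
) -> list[StratumEstimate]:
    """Per genotype-combination trait mean with se = sd / sqrt(n)."""
    y = np.asarray(getattr(trait, "values", trait), dtype=float)
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    ok = np.isfinite(y) & np.isfinite(g1) & np.isfinite(g2)
    out = []
    for d1 in sorted(np.unique(g1[ok])):
        for d2 in sorted(np.unique(g2[ok])):
            mask = ok & (g1 == d1) & (g2 == d2)
            n = int(mask.sum())
            if n == 0:
                continue
            m = float(y[mask].mean())
            se = float(y[mask].std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
            out.append(
                StratumEstimate(
                    label=_combo_label(d1, d2, alleles1, alleles2),
                    g1_dosage=int(d1),
                    g2_dosage=int(d2),
                    n=n,
                    estimate=m,
                    se=se,
                    ci_low=m - Z95 * se,
                    ci_high=m + Z95 * se,
                    kind="mean",
                )
            )
    return out


def stratified_odds_ratios(
    outcome,
    g1,
    g2,
    reference: tuple[int, int] = (0, 0),
    alleles1=None,
    alleles2=None,
) -> list[StratumEstimate]:
    """Per genotype-combination odds ratio of a binary outcome vs a reference.

    Each combination forms a 2x2 table against the reference combination;
    OR = (a*d)/(b*c) with a Wald CI on the log scale. When any cell is zero,
    0.5 is added to all four cells and the estimate is flagged.
    """
    y = np.asarray(getattr(outcome, "values", outcome), dtype=float)
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    ok = np.isfinite(y) & np.isfinite(g1) & np.isfinite(g2)
    ref_mask = ok & (g1 == reference[0]) & (g2 == reference[1])
    c_ref = float((y[ref_mask] == 1).sum())
    d_ref = float((y[ref_mask] == 0).sum())
    out = []
    for d1 in sorted(np.unique(g1[ok])):
        for d2 in sorted(np.unique(g2[ok])):
            mask = ok & (g1 == d1) & (g2 == d2)
            n = int(mask.sum())
            if n == 0:
                continue
            label = _combo_label(d1, d2, alleles1, alleles2)
            if (int(d1), int(d2)) == (int(reference[0]), int(reference[1])):
                out.append(
                    StratumEstimate(
                        label=label, g1_dosage=int(d1), g2_dosage=int(d2), n=n,
                        estimate=1.0, se=0.0, ci_low=1.0, ci_high=1.0, p=1.0,
                        kind="odds_ratio",
                    )
                )
                continue
            a = float((y[mask] == 1).sum())
            b = float((y[mask] == 0).sum())
            cells = np.array([a, b, c_ref, d_ref])
            corrected = bool(np.any(cells == 0))
            if corrected:
                cells = cells + 0.5
            a_, b_, c_, d_ = cells
            orr = (a_ * d_) / (b_ * c_)
            log_se = float(np.sqrt((1 / cells).sum()))
            log_or = np.log(orr)
            out.append(
                StratumEstimate(
                    label=label,
                    g1_dosage=int(d1),
                    g2_dosage=int(d2),
                    n=n,
                    estimate=float(orr),
                    se=log_se,
                    ci_low=float(np.exp(log_or - Z95 * log_se)),
                    ci_high=float(np.exp(log_or + Z95 * log_se)),
                    p=float(2.0 * stats.norm.sf(abs(log_or) / log_se)),
                    kind="odds_ratio",
                    continuity_corrected=corrected,
                )
            )
    return out


def interactions_to_frame(
    results: list[InteractionResult], genotypes: GenotypeMatrix | None = None
) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {
            "focal": r.focal,
            "partner": r.partner,
            "n": r.n,
            "beta_int": r.beta_int,
            "se": r.se,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "p": r.p,
            "family": r.family,
            "flags": ";".join(r.flags),
        }
        rows.append(row)
    frame = pd.DataFrame(rows)
    if genotypes is not None and not frame.empty:
        af = pd.Series(genotypes.allele_freq(), index=genotypes.variant_ids)
        frame.insert(2, "af_partner", frame["partner"].map(af).to_numpy())
    if not frame.empty:
        frame["p_bonferroni"] = np.minimum(frame["p"] * len(frame), 1.0)
    return frame


def strata_to_frame(strata: list[StratumEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "combination": s.label,
                "g1_dosage": s.g1_dosage,
                "g2_dosage": s.g2_dosage,
                "n": s.n,
                "kind": s.kind,
                "estimate": s.estimate,
                "se": s.se,
                "ci_low": s.ci_low,
                "ci_high": s.ci_high,
                "p": s.p,
                "continuity_corrected": s.continuity_corrected,
            }
            for s in strata
        ]
    )
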
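"""Per-variant association scanning and the vQTL calling rule.

The scale test regresses two prepared phenotypes on each variant in turn:
the rank-inverse-normal transformed trait (mean effects) and the squared
residual of that trait after covariate adjustment (variance effects). A
variant is called a variance QTL when its variance association is
genome-wide significant while its mean association is not.

Association fits are fixed-effects OLS with covariates; for unrelated
synthetic cohorts this carries the same scientific content as the
mixed-model machinery used on biobank data, without the relatedness
correction. Per-variant fits use Frisch-Waugh-Lovell residualization
(vectorized across variants), which is algebraically identical to the full
multi-column OLS; the identity is asserted against a brute-force
normal-equations solve in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix
from .transforms import PreparedPhenotype, rint, squared_residual_phenotype

__all__ = [
    "AssociationResult",
    "VQTLCall",
    "assoc_scan",
    "scale_test",
    "call_vqtls",
    "bonferroni_threshold",
    "genomic_control_lambda",
    "results_to_frame",
]

GENOME_WIDE_P = 5e-8


@dataclass
class AssociationResult:
    """Single-variant Wald test result under a mean or variance phenotype."""

    variant: str
    beta: float
    se: float
    p: float
    n: int
    stage: str  # "mean" or "variance"


@dataclass
class VQTLCall:
    """Paired mean/variance decision for one variant.

    ``is_vqtl`` is True iff the variance association is significant
    (``var_p < var_threshold``) and the mean association is not
    (``mean_p > mean_threshold``).
    """

    variant: str
    mean_p: float
    var_p: float
    var_beta: float
    is_vqtl: bool
    var_threshold: float = GENOME_WIDE_P
    mean_threshold: float = GENOME_WIDE_P


def _p_from_t(t: np.ndarray, df: int) -> np.ndarray:
    return 2.0 * stats.t.sf(np.abs(t), df)


def assoc_scan(
    genotypes: GenotypeMatrix,
    phenotype: PreparedPhenotype | np.ndarray,
    covariates=None,
    maf_min: float = 0.001,
    missing_rate_max: float = 0.1,
    stage: str = "mean",
    include_variants: list[str] | None = None,
) -> tuple[list[AssociationResult], dict[str, str]]:
    """OLS association of a prepared phenotype with every passing variant.

    Variants are excluded when minor allele frequency < ``maf_min``, when the
    missing-call rate exceeds ``missing_rate_max``, or when monomorphic after
    filtering; exclusions are returned as a ``variant -> reason`` map.
    ``include_variants`` restricts the scan (used to keep the mean and
    variance stages of the scale test on an identical variant set).
    """
    y_all = np.asarray(getattr(phenotype, "values", phenotype), dtype=float)
    n_total = genotypes.n_individuals
    if len(y_all) != n_total:
        raise ValueError("phenotype length does not match genotype individuals")
    X, _ = _covariate_matrix(covariates, n_total)

    keep = np.isfinite(y_all) & np.all(np.isfinite(X), axis=1)
    y = y_all[keep]
    Xk = X[keep]
    if y.std() == 0:
        raise ValueError("phenotype is constant; association fits are degenerate")

    # residualize phenotype and covariate projector once (FWL)
    Q, _ = np.linalg.qr(Xk)
    y_r = y - Q @ (Q.T @ y)
    k = Xk.shape[1]

    ids = genotypes.variant_ids
    if include_variants is not None:
        wanted = set(include_variants)
        cols = [i for i, v in enumerate(ids) if v in wanted]
    else:
        cols = list(range(len(ids)))

    maf = genotypes.maf()
    miss = genotypes.missing_rate()
    results: list[AssociationResult] = []
    excluded: dict[str, str] = {}
    dos = genotypes.dosages
    any_missing = dos == -1

    for j in cols:
        vid = ids[j]
        if include_variants is None:
            if miss[j] > missing_rate_max:
                excluded[vid] = "missing_rate"
                continue
            if not np.isfinite(maf[j]) or maf[j] < maf_min:
                excluded[vid] = "maf"
                continue
        g = dos[:, j].astype(float)
        g[any_missing[:, j]] = np.nan
        gk = g[keep]
        ok = np.isfinite(gk)
        if gk[ok].std() == 0:
            excluded[vid] = "monomorphic"
            continue
        if ok.all():
            g_r = gk - Q @ (Q.T @ gk)
            res = _fwl_fit(y_r, g_r, y.size, k)
        else:
            # re-residualize on the per-variant complete subset
            Qs, _ = np.linalg.qr(Xk[ok])
            ys = y[ok]
            ys_r = ys - Qs @ (Qs.T @ ys)
            gs_r = gk[ok] - Qs @ (Qs.T @ gk[ok])
            if gs_r.std() == 0:
                excluded[vid] = "monomorphic"
                continue
            res = _fwl_fit(ys_r, gs_r, int(ok.sum()), k)
        beta, se, p, n_used = res
        results.append(AssociationResult(vid, beta, se, p, n_used, stage))
    return results, excluded


def _covariate_matrix(covariates, n: int) -> tuple[np.ndarray, list[str]]:
    if covariates is None:
        return np.ones((n, 1)), []
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    names = [f"x{i}" for i in range(C.shape[1])]
    if hasattr(covariates, "columns"):
        names = [str(c) for c in covariates.columns]
    return np.column_stack([np.ones(n), C]), names


def _fwl_fit(y_r: np.ndarray, g_r: np.ndarray, n: int, k: int):
    gg = float(g_r @ g_r)
    beta = float(g_r @ y_r) / gg
    df = n - k - 1
    sigma2 = max(float(y_r @ y_r) - beta * beta * gg, 0.0) / df
    se = float(np.sqrt(sigma2 / gg))
    if se == 0:
        return beta, se, 1.0, n
    p = float(_p_from_t(np.array(beta / se), df))
    return beta, se, max(p, np.finfo(float).tiny), n


def scale_test(
    genotypes: GenotypeMatrix,
    trait,
    covariates=None,
    maf_min: float = 0.001,
    missing_rate_max: float = 0.1,
    variance_covariates="same",
) -> tuple[list[AssociationResult], list[AssociationResult], dict[str, str]]:
    """Two-stage scale test: mean scan on RINT(trait), variance scan on the
    squared covariate-adjusted residual.

    Both scans run on the identical variant set (filters applied once).
    ``variance_covariates`` controls whether covariates are re-included in
    the variance-stage regression ("same", default) or omitted (None) since
    the residualization already removed them.
    """
    mean_pheno = rint(trait)
    var_pheno = squared_residual_phenotype(trait, covariates)

    mean_results, excluded = assoc_scan(
        genotypes, mean_pheno, covariates, maf_min, missing_rate_max, stage="mean"
    )
    passing = [r.variant for r in mean_results]
    var_cov = covariates if variance_covariates == "same" else variance_covariates
    var_results, _ = assoc_scan(
        genotypes,
        var_pheno,
        var_cov,
        maf_min,
        missing_rate_max,
        stage="variance",
        include_variants=passing,
    )
    return mean_results, var_results, excluded


def call_vqtls(
    mean_results: list[AssociationResult],
    var_results: list[AssociationResult],
    var_threshold: float = GENOME_WIDE_P,
    mean_threshold: float = GENOME_WIDE_P,
) -> list[VQTLCall]:
    """Apply the vQTL rule to paired mean/variance scan results."""
    mean_p = {r.variant: r.p for r in mean_results}
    calls = []
    for r in var_results:
        if r.variant not in mean_p:
            continue
        mp = mean_p[r.variant]
        calls.append(
            VQTLCall(
                variant=r.variant,
                mean_p=mp,
                var_p=r.p,
                var_beta=r.beta,
                is_vqtl=bool(r.p < var_threshold and mp > mean_threshold),
                var_threshold=var_threshold,
                mean_threshold=mean_threshold,
            )
        )
    return calls


def bonferroni_threshold(m: int) -> float:
    """Candidate-gene significance threshold 0.05 / m."""
    if m < 1:
        raise ValueError("variant count must be >= 1")
    return 0.05 / m


def genomic_control_lambda(pvalues) -> float:
    """Genomic-control lambda: median chi-squared statistic / its null median."""
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))


def results_to_frame(
    results: list[AssociationResult], genotypes: GenotypeMatrix | None = None
) -> pd.DataFrame:
    """Summary-statistics table: variant, chrom, pos, ref, alt, af, n, beta, se, p, stage."""
    rows = [
        {
            "variant": r.variant,
            "n": r.n,
            "beta": r.beta,
            "se": r.se,
            "p": r.p,
            "stage": r.stage,
        }
        for r in results
    ]
    frame = pd.DataFrame(rows)
    if genotypes is not None and not frame.empty:
        meta = genotypes.variants.set_index("id")
        af = pd.Series(genotypes.allele_freq(), index=genotypes.variant_ids)
        frame.insert(1, "chrom", frame["variant"].map(meta["chrom"]).to_numpy())
        frame.insert(2, "pos", frame["variant"].map(meta["pos"]).to_numpy())
        frame.insert(3, "ref", frame["variant"].map(meta["ref"]).to_numpy())
        frame.insert(4, "alt", frame["variant"].map(meta["alt"]).to_numpy())
        frame.insert(5, "af", frame["variant"].map(af).to_numpy())
    return frame
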
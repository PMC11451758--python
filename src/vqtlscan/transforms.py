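"""Phenotype preparation.

Implements the rank-based inverse normal transformation (Blom offset,
mid-ranks for ties), ordinary-least-squares covariate residualization, the
squared-residual variance phenotype used by the scale test, and the
clinical-lab aggregation rule (median after excluding implausible values).

Missing handling is listwise per phenotype: rows with a non-finite trait or
covariate are excluded from the fit and carry NaN in the output, so the
output stays aligned with the input individuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .containers import DataError

__all__ = [
    "PreparedPhenotype",
    "rint",
    "residualize",
    "squared_residual_phenotype",
    "aggregate_labs",
]


@dataclass
class PreparedPhenotype:
    """A phenotype vector tagged with its preparation stage.

    ``stage`` is one of ``raw``, ``rint``, ``residual``, ``squared_residual``.
    ``covariates`` names the covariate columns used for residualization, if
    any; NaN entries mark individuals dropped listwise.
    """

    values: np.ndarray
    stage: str = "raw"
    covariates: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n(self) -> int:
        return int(np.isfinite(self.values).sum())


BLOM_OFFSET = 0.375


def rint(values) -> PreparedPhenotype:
    """Rank-based inverse normal transformation with the Blom offset.

    Maps value with rank ``r`` among ``n`` finite values to
    ``Phi^-1((r - 3/8) / (n + 1/4))``; ties receive mid-ranks. Non-finite
    inputs are excluded from ranking and returned as NaN.
    """
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    n = int(finite.sum())
    if n < 2:
        raise DataError("rank-inverse-normal transform needs at least 2 finite values")
    ranks = stats.rankdata(x[finite], method="average")
    out = np.full(x.shape, np.nan)
    out[finite] = stats.norm.ppf((ranks - BLOM_OFFSET) / (n + 1 - 2 * BLOM_OFFSET))
    return PreparedPhenotype(out, stage="rint")


def _design(covariates, n: int) -> tuple[np.ndarray, list[str]]:
    if covariates is None:
        return np.ones((n, 1)), []
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    names = [f"x{i}" for i in range(X.shape[1])]
    if hasattr(covariates, "columns"):
        names = [str(c) for c in covariates.columns]
    return np.column_stack([np.ones(n), X]), names


def residualize(trait, covariates=None) -> PreparedPhenotype:
    """OLS residuals of the trait on the covariates; intercept always included.

    With no covariates this is plain centering. Individuals with a missing
    trait or covariate are dropped from the fit and returned as NaN.
    """
    y = np.asarray(getattr(trait, "values", trait), dtype=float)
    X, names = _design(covariates, len(y))
    keep = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    if keep.sum() <= X.shape[1]:
        raise DataError("too few complete rows to residualize")
    beta, *_ = np.linalg.lstsq(X[keep], y[keep], rcond=None)
    out = np.full(y.shape, np.nan)
    out[keep] = y[keep] - X[keep] @ beta
    return PreparedPhenotype(out, stage="residual", covariates=names)


def squared_residual_phenotype(trait, covariates=None) -> PreparedPhenotype:
    """Variance phenotype: squared residual of the RINT-transformed trait.

    The trait is rank-inverse-normal transformed, residualized on the
    covariates, and squared element-wise. A variant whose genotype predicts
    this phenotype changes the trait's spread, not (only) its mean.
    """
    res = residualize(rint(trait), covariates)
    return PreparedPhenotype(
        res.values**2, stage="squared_residual", covariates=res.covariates
    )


def aggregate_labs(values, upper_limit_normal: float) -> float:
    """Summarize repeated lab measurements for one individual.

    Values greater than 3x the upper limit of normal are excluded as likely
    acute-illness artifacts; the median of the remainder is returned, or NaN
    if nothing survives.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    x = x[x <= 3.0 * upper_limit_normal]
    if x.size == 0:
        return float("nan")
    return float(np.median(x))
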
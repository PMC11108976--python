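"""Covariate adjustment and group-wise association structure.

Regional volumes are residualized per group on intercept + covariates
(ordinary least squares), and Pearson correlations of the residuals form
the group association matrix — numerically equivalent to partial
correlations of the raw volumes given the covariates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .regions import CohortTable

DEFAULT_COVARIATES = ("age", "sex", "tbv")


@dataclass
class AdjustedMatrix:
    """Per-group residual volumes after removing covariate effects."""

    group: str
    subject_ids: list[str]
    region_ids: list[str]
    residuals: np.ndarray  # subjects x regions
    covariates: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.residuals.shape != (len(self.subject_ids), len(self.region_ids)):
            raise ValidationError("residual matrix shape mismatch")


@dataclass
class AssociationMatrix:
    """Symmetric Pearson correlation matrix over regions for one group."""

    group: str
    region_ids: list[str]
    r: np.ndarray  # p x p, unit diagonal
    n: int

    def __post_init__(self) -> None:
        p = len(self.region_ids)
        if self.r.shape != (p, p):
            raise ValidationError("association matrix shape mismatch")
        if not np.allclose(self.r, self.r.T, atol=1e-12):
            raise ValidationError("association matrix must be symmetric")
        if np.abs(self.r).max() > 1 + 1e-12:
            raise ValidationError("correlations must lie in [-1, 1]")

    def index_of(self, region_id: str) -> int:
        try:
            return self.region_ids.index(region_id)
        except ValueError:
            raise ValidationError(f"region {region_id!r} not in association matrix")

    def value(self, a: str, b: str) -> float:
        return float(self.r[self.index_of(a), self.index_of(b)])

    def submatrix(self, region_ids: Sequence[str]) -> "AssociationMatrix":
        idx = [self.index_of(r) for r in region_ids]
        return AssociationMatrix(
            group=self.group, region_ids=list(region_ids),
            r=self.r[np.ix_(idx, idx)], n=self.n,
        )

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.r, index=self.region_ids, columns=self.region_ids).to_csv(
            path, sep="\t", index_label="region"
        )


def _design_matrix(cov: pd.DataFrame, covariates: Sequence[str]) -> np.ndarray:
    X = np.column_stack(
        [np.ones(len(cov))] + [cov[c].to_numpy(dtype=float) for c in covariates]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # identify an offending column for the error message
        for j, name in enumerate(covariates, start=1):
            reduced = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(reduced) == np.linalg.matrix_rank(X):
                raise ValidationError(
                    f"collinear covariates: {name!r} is linearly dependent "
                    "on the intercept and remaining covariates"
                )
        raise ValidationError("collinear covariates in design matrix")
    return X


def residualize(
    cohort: CohortTable,
    group: str,
    regions: Sequence[str],
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> AdjustedMatrix:
    """OLS-residualize each region's volumes on intercept + covariates.

    Operates within a single group; deterministic for fixed input order.
    """
    regions = list(regions)
    covariates = tuple(covariates)
    idx = cohort.subjects_in(group)
    n = len(idx)
    if n < len(covariates) + 2:
        raise ValidationError(
            f"group {group!r}: n={n} too small for {len(covariates)} covariates"
        )
    missing = [r for r in regions if r not in cohort.volumes.columns]
    if missing:
        raise ValidationError(f"regions not in cohort: {missing}")
    bad = [c for c in covariates if c not in cohort.covariates.columns]
    if bad:
        raise ValidationError(f"unknown covariates: {bad}")

    X = _design_matrix(cohort.covariates.loc[idx], covariates)
    Y = cohort.volumes.loc[idx, regions].to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    residuals = Y - X @ beta
    return AdjustedMatrix(
        group=str(group), subject_ids=[str(s) for s in idx],
        region_ids=regions, residuals=residuals, covariates=covariates,
    )


def correlation_matrix(adj: AdjustedMatrix) -> AssociationMatrix:
    """Pearson correlations of residual columns."""
    sd = adj.residuals.std(axis=0)
    zero = [rid for rid, s in zip(adj.region_ids, sd) if s == 0 or not np.isfinite(s)]
    if zero:
        raise ValidationError(f"zero-variance regions: {zero}")
    r = np.corrcoef(adj.residuals, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return AssociationMatrix(
        group=adj.group, region_ids=list(adj.region_ids), r=r,
        n=len(adj.subject_ids),
    )


def covariance_profile(
    assoc: AssociationMatrix, nucleus: str, targets: Sequence[str]
) -> np.ndarray:
    """Ordered vector of r(nucleus, target) over the profile targets."""
    targets = list(targets)
    if nucleus in targets:
        raise ValidationError(f"nucleus {nucleus!r} listed among its own targets")
    i = assoc.index_of(nucleus)
    idx = [assoc.index_of(t) for t in targets]
    return assoc.r[i, idx].copy()


def group_association_matrices(
    cohort: CohortTable,
    regions: Sequence[str],
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> dict[str, AssociationMatrix]:
    """Residualize and correlate per group; returns {group: AssociationMatrix}."""
    out = {}
    for group in cohort.group_labels:
        out[group] = correlation_matrix(
            residualize(cohort, group, regions, covariates)
        )
    return out
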
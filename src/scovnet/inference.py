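"""Null models and group inference over the density sweep.

Three pieces: Hirschberger-Qi-Steuer (HQS) random covariance matrices
matched to the moments of an observed matrix (a diagnostic reference for
the topology curves), trapezoidal integration of metric curves over the
density grid (the functional-data-analysis summary), and a label
permutation test of the integrated-metric group difference with FDR
across nodes and a Bonferroni factor for the three regional measures.

Permutations re-run the covariate residualization inside each draw so
that exchangeability holds under the null.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .adjust import DEFAULT_COVARIATES, AssociationMatrix, _design_matrix
from .errors import ValidationError
from .graphs import METRIC_NAMES, DensitySweep, density_sweep, nodal_metrics, binarize_at_density
from .regions import CohortTable

N_REGIONAL_MEASURES = 3  # degree, betweenness, clustering
PRINTED_MEASURE_THRESHOLD = 0.02  # alpha/3 reported rounded to .02


# ---------------------------------------------------------------------------
# HQS null covariance matrices
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HQSSpec:
    """Moment targets for a random covariance matrix.

    e and v are the mean and variance of the off-diagonal entries, dbar
    the mean diagonal entry; the latent dimension is
    m = max(2, round((dbar^2 - e^2) / v)).
    """

    e: float
    v: float
    dbar: float
    p: int

    def __post_init__(self) -> None:
        if self.v <= 0:
            raise ValidationError(f"target off-diagonal variance must be > 0, got {self.v}")
        if self.dbar <= 0:
            raise ValidationError(f"target diagonal mean must be > 0, got {self.dbar}")
        if self.dbar**2 <= self.e**2:
            raise ValidationError(
                f"dbar^2 must exceed e^2 (got dbar={self.dbar}, e={self.e})"
            )
        if self.e <= 0:
            raise ValidationError(
                f"off-diagonal mean must be positive for the Gaussian "
                f"construction, got e={self.e}"
            )
        if self.p < 3:
            raise ValidationError("p must be >= 3")

    @property
    def m(self) -> int:
        return max(2, int(round((self.dbar**2 - self.e**2) / self.v)))


def estimate_hqs_spec(matrix: AssociationMatrix | np.ndarray) -> HQSSpec:
    """Moment-match an HQSSpec to an observed covariance/correlation matrix."""
    M = matrix.r if isinstance(matrix, AssociationMatrix) else np.asarray(matrix, float)
    p = M.shape[0]
    if M.shape != (p, p) or p < 3:
        raise ValidationError("need a square matrix with p >= 3")
    off = M[~np.eye(p, dtype=bool)]
    e, v = float(off.mean()), float(off.var())
    if v == 0:
        raise ValidationError("degenerate matrix: all off-diagonal entries equal")
    return HQSSpec(e=e, v=v, dbar=float(np.diag(M).mean()), p=p)


def hqs_null_covariance(
    spec: HQSSpec, seed: int, as_correlation: bool = False
) -> np.ndarray:
    """One HQS random covariance matrix (outer product of a Gaussian p x m).

    Entries of the factor are iid Normal(sqrt(e/m), sqrt((dbar-e)/m)), so
    the product matches e, dbar exactly in expectation and the
    off-diagonal variance approximately; PSD by construction.
    """
    if spec.dbar <= spec.e:
        raise ValidationError(
            f"dbar must exceed e for a real-valued factor SD "
            f"(dbar={spec.dbar}, e={spec.e})"
        )
    m = spec.m
    mu = np.sqrt(spec.e / m)
    sigma = np.sqrt((spec.dbar - spec.e) / m)
    rng = np.random.default_rng(seed)
    X = rng.normal(mu, sigma, size=(spec.p, m))
    C = X @ X.T
    if as_correlation:
        d = np.sqrt(np.diag(C))
        C = C / np.outer(d, d)
        np.fill_diagonal(C, 1.0)
    return C


def null_reference_curves(
    assoc: AssociationMatrix,
    densities: Sequence[float],
    n_null: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Node-averaged metric curves for HQS nulls matched to ``assoc``.

    Diagnostic output: the observed topology should diverge from the
    random-covariance reference.  Returns a long table (null_index,
    density, metric, mean_over_nodes).
    """
    spec = estimate_hqs_spec(assoc)
    rows = []
    for k in range(n_null):
        C = hqs_null_covariance(spec, seed=seed + k, as_correlation=True)
        null_assoc = AssociationMatrix(
            group=f"hqs-null-{k}", region_ids=list(assoc.region_ids),
            r=np.clip(C, -1, 1), n=assoc.n,
        )
        for d in densities:
            metrics = nodal_metrics(binarize_at_density(null_assoc, d))
            for name, vals in metrics.as_dict().items():
                rows.append({"null_index": k, "density": d, "metric": name,
                             "mean_over_nodes": float(np.mean(vals))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# FDA integration and permutation inference
# ---------------------------------------------------------------------------


def fda_auc(metric_curve: Sequence[float], densities: Sequence[float]) -> float:
    """Trapezoidal area under a metric-vs-density curve."""
    y = np.asarray(metric_curve, dtype=float)
    x = np.asarray(densities, dtype=float)
    if y.shape != x.shape:
        raise ValidationError(
            f"curve length {y.shape} does not match grid {x.shape}"
        )
    if x.size < 2:
        raise ValidationError("need at least 2 densities")
    if np.any(np.diff(x) <= 0):
        raise ValidationError("density grid must be strictly increasing")
    return float(np.trapezoid(y, x))


def _integrated_metrics(sweep: DensitySweep) -> dict[str, dict[str, np.ndarray]]:
    """group -> metric -> per-node AUC over the sweep."""
    x = np.asarray(sweep.densities)
    out: dict[str, dict[str, np.ndarray]] = {}
    for group, by_metric in sweep.curves.items():
        out[group] = {
            m: np.trapezoid(curves, x, axis=0) for m, curves in by_metric.items()
        }
    return out


def integrated_metrics(sweep: DensitySweep) -> dict[str, dict[str, np.ndarray]]:
    return _integrated_metrics(sweep)


@dataclass
class PermutationResult:
    """Permutation test of integrated-metric group differences, per node."""

    region_ids: list[str]
    groups: tuple[str, str]
    densities: list[float]
    auc_a: dict[str, np.ndarray]
    auc_b: dict[str, np.ndarray]
    observed_diff: dict[str, np.ndarray]  # metric -> p-vector (a - b)
    null_diffs: dict[str, np.ndarray]  # metric -> (R x p)
    p_two_tailed: dict[str, np.ndarray]
    p_fdr: dict[str, np.ndarray]
    R: int
    seed: int
    alpha: float

    @property
    def measure_threshold(self) -> float:
        """Bonferroni threshold across the three regional measures."""
        return self.alpha / N_REGIONAL_MEASURES

    def significant(self, metric: str) -> np.ndarray:
        return self.p_fdr[metric] <= self.measure_threshold

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for metric in METRIC_NAMES:
            for i, rid in enumerate(self.region_ids):
                rows.append({
                    "region": rid, "metric": metric,
                    "auc_" + self.groups[0]: self.auc_a[metric][i],
                    "auc_" + self.groups[1]: self.auc_b[metric][i],
                    "auc_diff": self.observed_diff[metric][i],
                    "p": self.p_two_tailed[metric][i],
                    "p_fdr": self.p_fdr[metric][i],
                    "significant": bool(self.significant(metric)[i]),
                })
        return pd.DataFrame(rows)


def _group_curves(
    Y: np.ndarray, X: np.ndarray, region_ids: list[str], densities: list[float],
    use_absolute: bool,
) -> dict[str, np.ndarray]:
    """Residualize -> correlate -> sweep for one group's raw data."""
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    res = Y - X @ beta
    sd = res.std(axis=0)
    if np.any(sd == 0):
        raise ValidationError("zero-variance region inside permutation pipeline")
    r = np.corrcoef(res, rowvar=False)
    r = np.clip((r + r.T) / 2, -1, 1)
    np.fill_diagonal(r, 1.0)
    assoc = AssociationMatrix(group="perm", region_ids=region_ids, r=r, n=Y.shape[0])
    p = len(region_ids)
    curves = {m: np.zeros((len(densities), p)) for m in METRIC_NAMES}
    for di, d in enumerate(densities):
        metrics = nodal_metrics(binarize_at_density(assoc, d, use_absolute))
        for m, vals in metrics.as_dict().items():
            curves[m][di] = vals
    return curves


def permutation_group_test(
    cohort: CohortTable,
    regions: Sequence[str],
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    R: int = 1000,
    seed: int = 0,
    step: float = 0.02,
    d_max: float = 0.5,
    d_min: float | None = None,
    alpha: float = 0.05,
    use_absolute: bool = False,
) -> PermutationResult:
    """Two-tailed permutation test of per-node integrated metrics.

    Group labels are permuted preserving group sizes; each draw re-runs
    residualization, correlation, the density sweep (on the observed
    grid) and AUC integration.  p = (#{|null| >= |obs|} + 1) / (R + 1);
    BH-FDR across nodes per metric; the significance threshold divides
    alpha by the three regional measures.
    """
    if R < 100:
        raise ValidationError(f"R must be >= 100, got {R}")
    cohort.require_inferential_sizes()
    regions = list(regions)
    groups = cohort.group_labels
    ga, gb = groups[0], groups[1]

    from .adjust import group_association_matrices

    assoc = group_association_matrices(cohort, regions, covariates)
    sweep = density_sweep(assoc, step=step, d_max=d_max, d_min=d_min,
                          use_absolute=use_absolute)
    densities = sweep.densities
    integrated = _integrated_metrics(sweep)
    observed = {m: integrated[ga][m] - integrated[gb][m] for m in METRIC_NAMES}

    labels = cohort.covariates["group"].to_numpy()
    Y = cohort.volumes[regions].to_numpy(dtype=float)
    Xfull = _design_matrix(cohort.covariates, covariates)
    mask_a = labels == ga
    n_a = int(mask_a.sum())
    n = len(labels)
    p = len(regions)

    rng = np.random.default_rng(seed)
    null = {m: np.zeros((R, p)) for m in METRIC_NAMES}
    x = np.asarray(densities)
    for rep in range(R):
        perm = rng.permutation(n)
        idx_a, idx_b = perm[:n_a], perm[n_a:]
        curves_a = _group_curves(Y[idx_a], Xfull[idx_a], regions, densities,
                                 use_absolute)
        curves_b = _group_curves(Y[idx_b], Xfull[idx_b], regions, densities,
                                 use_absolute)
        for m in METRIC_NAMES:
            null[m][rep] = (np.trapezoid(curves_a[m], x, axis=0)
                            - np.trapezoid(curves_b[m], x, axis=0))

    from .corrstats import bh_fdr

    p_two, p_fdr = {}, {}
    for m in METRIC_NAMES:
        exceed = (np.abs(null[m]) >= np.abs(observed[m])[None, :]).sum(axis=0)
        p_two[m] = (exceed + 1) / (R + 1)
        p_fdr[m] = bh_fdr(p_two[m])

    return PermutationResult(
        region_ids=regions, groups=(str(ga), str(gb)), densities=densities,
        auc_a=integrated[ga], auc_b=integrated[gb],
        observed_diff=observed, null_diffs=null,
        p_two_tailed=p_two, p_fdr=p_fdr, R=R, seed=seed, alpha=alpha,
    )


@dataclass
class FDAResult:
    """Flat per-node functional-data-analysis summary of a permutation run."""

    region_ids: list[str]
    metric: str
    auc_group_a: np.ndarray
    auc_group_b: np.ndarray
    auc_diff: np.ndarray
    p_two_tailed: np.ndarray
    p_fdr: np.ndarray


def fda_results(perm: PermutationResult) -> list[FDAResult]:
    return [
        FDAResult(
            region_ids=perm.region_ids, metric=m,
            auc_group_a=perm.auc_a[m], auc_group_b=perm.auc_b[m],
            auc_diff=perm.observed_diff[m],
            p_two_tailed=perm.p_two_tailed[m], p_fdr=perm.p_fdr[m],
        )
        for m in METRIC_NAMES
    ]
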
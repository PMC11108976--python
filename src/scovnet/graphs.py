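"""Density-thresholded binary graphs and regional topology metrics.

Association matrices are binarized by keeping the top-ranked pairs at a
target edge density (round-half-up edge count, lexicographic tie-break on
region ids for determinism).  Ranking is by signed correlation by
default; absolute-value ranking is available as an option.  Metrics are
nodal degree, unnormalized betweenness centrality (each unordered pair of
endpoints counted once) and local clustering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .adjust import AssociationMatrix
from .errors import ComputeError, ValidationError

logger = logging.getLogger(__name__)

METRIC_NAMES = ("degree", "betweenness", "clustering")


@dataclass
class BinaryGraph:
    region_ids: list[str]
    adjacency: np.ndarray  # p x p, {0,1}, zero diagonal, symmetric
    density: float

    def __post_init__(self) -> None:
        A = self.adjacency
        p = len(self.region_ids)
        if A.shape != (p, p):
            raise ValidationError("adjacency shape mismatch")
        if np.diag(A).any() or not np.array_equal(A, A.T):
            raise ValidationError("adjacency must be symmetric with zero diagonal")

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def is_connected(self) -> bool:
        ncomp, _ = connected_components(
            csr_matrix(self.adjacency), directed=False
        )
        return ncomp == 1

    def to_networkx(self) -> nx.Graph:
        G = nx.from_numpy_array(self.adjacency)
        return nx.relabel_nodes(G, dict(enumerate(self.region_ids)))

    def edge_list(self) -> list[tuple[str, str]]:
        i, j = np.nonzero(np.triu(self.adjacency, 1))
        return [(self.region_ids[a], self.region_ids[b]) for a, b in zip(i, j)]


def _ranked_pairs(assoc: AssociationMatrix, use_absolute: bool) -> list[tuple[int, int]]:
    p = len(assoc.region_ids)
    iu, ju = np.triu_indices(p, 1)
    vals = assoc.r[iu, ju]
    if use_absolute:
        vals = np.abs(vals)
    ids = assoc.region_ids
    order = sorted(
        range(len(vals)),
        key=lambda k: (-vals[k], ids[iu[k]], ids[ju[k]]),
    )
    return [(int(iu[k]), int(ju[k])) for k in order]


def binarize_at_density(
    assoc: AssociationMatrix, density: float, use_absolute: bool = False
) -> BinaryGraph:
    """Keep the top round(density * p(p-1)/2) pairs as edges."""
    if not 0 < density <= 0.5:
        raise ValidationError(f"density must be in (0, 0.5], got {density}")
    p = len(assoc.region_ids)
    n_pairs = p * (p - 1) // 2
    k = int(np.floor(density * n_pairs + 0.5))  # round half up
    if k == 0:
        raise ValidationError(
            f"density {density} yields zero edges for p={p} nodes"
        )
    A = np.zeros((p, p), dtype=np.int8)
    for i, j in _ranked_pairs(assoc, use_absolute)[:k]:
        A[i, j] = A[j, i] = 1
    return BinaryGraph(region_ids=list(assoc.region_ids), adjacency=A,
                       density=float(density))


def density_grid(step: float = 0.02, d_max: float = 0.5) -> list[float]:
    """The density grid {step, 2*step, ..., d_max}."""
    if not 0 < step <= 0.1:
        raise ValidationError(f"step must be in (0, 0.1], got {step}")
    n = int(round(d_max / step))
    return [round(i * step, 10) for i in range(1, n + 1)]


def find_dmin(
    assoc_a: AssociationMatrix,
    assoc_b: AssociationMatrix,
    step: float = 0.02,
    d_max: float = 0.5,
    use_absolute: bool = False,
) -> float:
    """Smallest grid density at which both groups' graphs are connected."""
    if len(assoc_a.region_ids) != len(assoc_b.region_ids):
        raise ValidationError("association matrices must share node count")
    tried = None
    for d in density_grid(step, d_max):
        tried = d
        try:
            ga = binarize_at_density(assoc_a, d, use_absolute)
            gb = binarize_at_density(assoc_b, d, use_absolute)
        except ValidationError:
            continue  # zero-edge density at the bottom of the grid
        if ga.is_connected() and gb.is_connected():
            return d
    raise ComputeError(
        f"no density up to {tried} connects both graphs; increase d_max "
        "or inspect the association matrices"
    )


@dataclass
class NodalMetrics:
    region_ids: list[str]
    density: float
    degree: np.ndarray  # int
    betweenness: np.ndarray  # raw path counts
    clustering: np.ndarray  # in [0, 1]

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"degree": self.degree.astype(float),
                "betweenness": self.betweenness,
                "clustering": self.clustering}


def nodal_metrics(graph: BinaryGraph) -> NodalMetrics:
    """Degree, unnormalized betweenness and local clustering per node."""
    A = graph.adjacency
    degree = A.sum(axis=1).astype(int)
    G = nx.from_numpy_array(A)
    bc = nx.betweenness_centrality(G, normalized=False)
    cl = nx.clustering(G)
    p = len(graph.region_ids)
    return NodalMetrics(
        region_ids=list(graph.region_ids),
        density=graph.density,
        degree=degree,
        betweenness=np.array([bc[i] for i in range(p)], dtype=float),
        clustering=np.array([cl[i] for i in range(p)], dtype=float),
    )


@dataclass
class DensitySweep:
    """Binarized graphs and metric curves over the density grid, per group."""

    densities: list[float]
    region_ids: list[str]
    graphs_by_group: dict[str, list[BinaryGraph]]
    # metric curves: group -> metric -> (n_densities x p) array
    curves: dict[str, dict[str, np.ndarray]]

    @property
    def d_min(self) -> float:
        return self.densities[0]

    def metrics_frame(self) -> pd.DataFrame:
        rows = []
        for group, by_metric in self.curves.items():
            for mi, d in enumerate(self.densities):
                for ni, rid in enumerate(self.region_ids):
                    rows.append({
                        "group": group, "density": d, "region": rid,
                        **{m: by_metric[m][mi, ni] for m in METRIC_NAMES},
                    })
        return pd.DataFrame(rows)


def density_sweep(
    assoc_by_group: Mapping[str, AssociationMatrix],
    step: float = 0.02,
    d_max: float = 0.5,
    d_min: float | None = None,
    use_absolute: bool = False,
) -> DensitySweep:
    """Binarize and measure each group's graph from d_min to d_max.

    When ``d_min`` is not given it is determined by :func:`find_dmin`
    over the two groups.
    """
    matrices = list(assoc_by_group.values())
    if len(matrices) != 2:
        raise ValidationError("density_sweep expects exactly two groups")
    if d_min is None:
        d_min = find_dmin(matrices[0], matrices[1], step=step, d_max=d_max,
                          use_absolute=use_absolute)
    densities = [d for d in density_grid(step, d_max) if d >= d_min - 1e-12]
    region_ids = list(matrices[0].region_ids)
    graphs_by_group: dict[str, list[BinaryGraph]] = {}
    curves: dict[str, dict[str, np.ndarray]] = {}
    p = len(region_ids)
    for group, assoc in assoc_by_group.items():
        graphs = [binarize_at_density(assoc, d, use_absolute) for d in densities]
        stacked = {m: np.zeros((len(densities), p)) for m in METRIC_NAMES}
        for di, g in enumerate(graphs):
            metrics = nodal_metrics(g)
            for m, vals in metrics.as_dict().items():
                stacked[m][di] = vals
        graphs_by_group[str(group)] = graphs
        curves[str(group)] = stacked
    return DensitySweep(
        densities=densities, region_ids=region_ids,
        graphs_by_group=graphs_by_group, curves=curves,
    )


@dataclass(frozen=True)
class HubRecord:
    group: str
    region_id: str
    metric: str
    score: float
    group_mean: float
    group_sd: float


@dataclass
class HubTable:
    hubs: list[HubRecord]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [h.__dict__ for h in self.hubs],
            columns=["group", "region_id", "metric", "score",
                     "group_mean", "group_sd"],
        )


def detect_hubs(
    scores_by_metric: Mapping[str, np.ndarray],
    region_ids: Sequence[str],
    group: str,
) -> HubTable:
    """Flag nodes whose degree or betweenness exceeds mean + 2 SD.

    Scores are density-integrated (AUC over the sweep); the SD is the
    population SD over nodes.  Strict inequality: a node at exactly
    mean + 2 SD is not a hub.
    """
    if len(region_ids) < 3:
        raise ValidationError("hub detection needs at least 3 nodes")
    hubs: list[HubRecord] = []
    for metric in ("degree", "betweenness"):
        if metric not in scores_by_metric:
            continue
        scores = np.asarray(scores_by_metric[metric], dtype=float)
        mean, sd = float(scores.mean()), float(scores.std())
        if sd == 0:
            logger.warning("hub detection: zero SD for %s in group %s", metric, group)
            continue
        cut = mean + 2 * sd
        for rid, s in zip(region_ids, scores):
            if s > cut:
                hubs.append(HubRecord(group=str(group), region_id=rid, metric=metric,
                                      score=float(s), group_mean=mean, group_sd=sd))
    return HubTable(hubs=hubs)
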
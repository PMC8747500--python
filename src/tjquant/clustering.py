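"""Distance-threshold clustering of localization point patterns.

Two localizations belong to the same cluster iff they are connected by a
chain of pairwise distances each *strictly* smaller than the threshold
(single-linkage transitive closure; default threshold 70 nm, admissible
range 50-100 nm).  Every record is assigned to exactly one cluster.

Per-cluster geometry uses the convex hull of member localizations: area in
µm², density = n_points / area in signals/µm².  Clusters whose members do
not span a 2D hull (fewer than 3 points, or collinear) are flagged
degenerate: area 0, density undefined, excluded from density summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import ConvexHull, QhullError, cKDTree

from .errors import ConsistencyError, ParameterError
from .io import LocalizationTable

__all__ = [
    "ClusterPartition",
    "ClusterProperties",
    "ClusterSummary",
    "partition_localizations",
    "compute_cluster_properties",
    "threshold_sweep",
    "cluster_summary",
    "DEFAULT_THRESHOLD_NM",
    "DEFAULT_MIN_POINTS",
    "DEFAULT_AREA_EDGES_UM2",
]

DEFAULT_THRESHOLD_NM = 70.0
DEFAULT_MIN_POINTS = 3
#: area histogram bin edges (µm²); 0.1 and 0.3 are the conventional cuts
DEFAULT_AREA_EDGES_UM2 = (0.0, 0.05, 0.1, 0.2, 0.3, 0.5, 1.0, np.inf)


@dataclass
class ClusterPartition:
    """Exhaustive, exclusive assignment of records to clusters.

    ``assignment[i]`` is the 1-based cluster id of record ``i``; ids are
    contiguous ``1..n_clusters`` in order of first appearance, so the
    partition is invariant under input permutation up to relabeling.
    """

    assignment: np.ndarray
    threshold_nm: float

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=np.int64).ravel()
        if self.assignment.size and (
            self.assignment.min() < 1
            or not np.array_equal(
                np.unique(self.assignment), np.arange(1, self.assignment.max() + 1)
            )
        ):
            raise ConsistencyError("cluster ids must be contiguous 1..n_clusters")

    @property
    def n_clusters(self) -> int:
        return int(self.assignment.max()) if self.assignment.size else 0

    def members(self, cluster_id: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == cluster_id)


@dataclass
class ClusterProperties:
    cluster_id: int
    n_points: int
    area_um2: float
    density_per_um2: float | None
    centroid_nm: tuple[float, float]
    hull_vertices_nm: np.ndarray  # counter-clockwise (m, 2)
    degenerate: bool
    member_points_nm: np.ndarray = field(repr=False, default=None)  # (n, 2)


def _relabel_first_appearance(labels: np.ndarray) -> np.ndarray:
    """Map arbitrary component labels to 1..k in order of first appearance."""
    out = np.empty(labels.size, dtype=np.int64)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(labels):
        key = int(lab)
        if key not in mapping:
            mapping[key] = len(mapping) + 1
        out[i] = mapping[key]
    return out


def partition_localizations(
    table: LocalizationTable, threshold_nm: float = DEFAULT_THRESHOLD_NM
) -> ClusterPartition:
    """Partition a localization table by strict distance-threshold linkage.

    Two records share a cluster iff they are connected by a chain of
    pairwise Euclidean distances each strictly below ``threshold_nm``.
    Pairs at exactly the threshold distance are NOT merged.
    """
    if threshold_nm <= 0:
        raise ParameterError("threshold_nm must be positive")
    n = len(table)
    if n == 0:
        return ClusterPartition(np.zeros(0, dtype=np.int64), threshold_nm)
    coords = table.coords
    tree = cKDTree(coords)
    pairs = tree.query_pairs(threshold_nm, output_type="ndarray")
    if pairs.size:
        d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
        pairs = pairs[d < threshold_nm]  # enforce strict inequality
    if pairs.size:
        graph = coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
        )
        _, labels = connected_components(graph, directed=False)
    else:
        labels = np.arange(n)
    return ClusterPartition(_relabel_first_appearance(labels), threshold_nm)


def _hull(points: np.ndarray) -> tuple[float, np.ndarray, bool]:
    """(area_nm2, ccw hull vertices, degenerate) of a 2D point set."""
    if len(points) < 3:
        return 0.0, points.copy(), True
    try:
        hull = ConvexHull(points)
    except QhullError:  # collinear members
        return 0.0, points.copy(), True
    return float(hull.volume), points[hull.vertices], False


def compute_cluster_properties(
    table: LocalizationTable,
    partition: ClusterPartition,
    min_points: int = DEFAULT_MIN_POINTS,
) -> list[ClusterProperties]:
    """Per-cluster geometry for every cluster with at least ``min_points``.

    Returns one entry per qualifying cluster: convex-hull area (µm²),
    density (signals/µm², None and flagged degenerate when the hull is not
    two-dimensional), centroid and CCW hull vertices.
    """
    if min_points < 1:
        raise ParameterError("min_points must be >= 1")
    if len(partition.assignment) != len(table):
        raise ConsistencyError(
            f"partition covers {len(partition.assignment)} records, table has {len(table)}"
        )
    coords = table.coords
    out: list[ClusterProperties] = []
    order = np.argsort(partition.assignment, kind="stable")
    boundaries = np.searchsorted(
        partition.assignment[order], np.arange(1, partition.n_clusters + 2)
    )
    for cid in range(1, partition.n_clusters + 1):
        idx = order[boundaries[cid - 1] : boundaries[cid]]
        if idx.size < min_points:
            continue
        pts = coords[idx]
        area_nm2, hull_v, degen = _hull(pts)
        area_um2 = area_nm2 / 1e6
        density = None if degen or area_um2 == 0 else idx.size / area_um2
        out.append(
            ClusterProperties(
                cluster_id=cid,
                n_points=int(idx.size),
                area_um2=area_um2,
                density_per_um2=density,
                centroid_nm=(float(pts[:, 0].mean()), float(pts[:, 1].mean())),
                hull_vertices_nm=hull_v,
                degenerate=bool(degen or area_um2 == 0),
                member_points_nm=pts,
            )
        )
    return out


@dataclass
class ClusterSummary:
    """Distribution summary of a set of cluster properties."""

    n_clusters: int
    n_degenerate: int
    area_hist: np.ndarray
    area_edges_um2: np.ndarray
    points_hist: np.ndarray
    points_edges: np.ndarray
    density_mean: float | None
    density_sem: float | None
    n_density: int


def cluster_summary(
    properties: list[ClusterProperties],
    area_edges_um2: tuple[float, ...] = DEFAULT_AREA_EDGES_UM2,
    points_edges: np.ndarray | None = None,
) -> ClusterSummary:
    """Counts, area / points-per-cluster histograms and mean ± s.e.m. density.

    Density statistics are taken over non-degenerate clusters only.
    """
    area_edges = np.asarray(area_edges_um2, dtype=float)
    if properties:
        areas = np.array([p.area_um2 for p in properties])
        npts = np.array([p.n_points for p in properties])
        dens = np.array(
            [p.density_per_um2 for p in properties if not p.degenerate], dtype=float
        )
    else:
        areas = np.zeros(0)
        npts = np.zeros(0)
        dens = np.zeros(0)
    if points_edges is None:
        top = int(npts.max()) + 1 if npts.size else 1
        points_edges = np.concatenate([np.arange(0, top, max(1, top // 20)), [np.inf]])
    area_hist, _ = np.histogram(areas, bins=area_edges)
    points_hist, _ = np.histogram(npts, bins=points_edges)
    mean = float(dens.mean()) if dens.size else None
    sem = float(dens.std(ddof=1) / np.sqrt(dens.size)) if dens.size > 1 else None
    return ClusterSummary(
        n_clusters=len(properties),
        n_degenerate=sum(p.degenerate for p in properties),
        area_hist=area_hist,
        area_edges_um2=area_edges,
        points_hist=points_hist,
        points_edges=np.asarray(points_edges, dtype=float),
        density_mean=mean,
        density_sem=sem,
        n_density=int(dens.size),
    )


def threshold_sweep(
    table: LocalizationTable,
    thresholds_nm: list[float],
    min_points: int = DEFAULT_MIN_POINTS,
) -> dict[float, dict]:
    """Cluster the same table at several thresholds (ascending).

    For single-linkage the partition at a smaller threshold always refines
    the partition at a larger one.  Returns per threshold the partition,
    cluster count and mean density over non-degenerate clusters.
    """
    thresholds = list(thresholds_nm)
    if any(t <= 0 for t in thresholds):
        raise ParameterError("thresholds must be positive")
    if sorted(thresholds) != thresholds:
        raise ParameterError("thresholds must be ascending")
    out: dict[float, dict] = {}
    for t in thresholds:
        part = partition_localizations(table, t)
        props = compute_cluster_properties(table, part, min_points=min_points)
        summ = cluster_summary(props)
        out[t] = {
            "partition": part,
            "n_clusters": summ.n_clusters,
            "density_mean": summ.density_mean,
            "density_sem": summ.density_sem,
        }
    return out
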
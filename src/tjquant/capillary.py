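"""Per-capillary quantifications and two-channel cluster coupling.

A capillary cross-section ROI is treated as one endothelial unit: the total
signal inside it proxies cellular expression of the stained protein, and is
normalized to the capillary diameter (signals/µm) for cross-age comparison.
Cluster coupling classifies clusters of one channel (e.g. claudin-5) as
coupled to or independent of clusters in a partner channel (e.g. ZO1) by
minimum member-to-member distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import Polygon

from .clustering import ClusterProperties
from .errors import ConsistencyError, ParameterError, ValidationError
from .io import CapillaryROI, LocalizationTable

__all__ = [
    "CapillaryMetrics",
    "CouplingLabel",
    "CouplingContrast",
    "total_cellular_signal",
    "estimate_diameter",
    "normalized_cellular_signal",
    "clusters_in_roi",
    "capillary_metrics",
    "pair_clusters",
    "coupling_density_contrast",
    "DEFAULT_PAIRING_NM",
]

DEFAULT_PAIRING_NM = 100.0


@dataclass
class CapillaryMetrics:
    capillary_id: str
    channel: str
    diameter_um: float
    perimeter_um: float
    total_signals: int
    normalized_signal_per_um: float
    normalized_signal_per_um_perimeter: float
    n_clusters: int


@dataclass
class CouplingLabel:
    cluster_id: int
    status: str  # "coupled" | "independent"
    partner_cluster_id: int | None
    gap_nm: float


def _points_covered(poly: Polygon, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Boolean mask: point strictly inside or on the boundary of ``poly``."""
    pts = shapely.points(x, y)
    return shapely.covers(poly, pts)


def total_cellular_signal(table: LocalizationTable, roi: CapillaryROI) -> int:
    """Number of localizations inside (or on the boundary of) the ROI."""
    if len(table) == 0:
        return 0
    return int(np.count_nonzero(_points_covered(roi.polygon, table.x, table.y)))


def _polygon_second_moments(vertices: np.ndarray) -> tuple[float, np.ndarray]:
    """Area and centroid-centered second-moment (covariance) matrix.

    Uses the exact Green's-theorem formulas for a simple polygon; the
    covariance is the area-normalized second central moment, i.e. for an
    ellipse with semi-axes a, b the eigenvalues are a²/4 and b²/4.
    """
    x = vertices[:, 0]
    y = vertices[:, 1]
    xn = np.roll(x, -1)
    yn = np.roll(y, -1)
    cross = x * yn - xn * y
    area = 0.5 * cross.sum()
    if area == 0:
        raise ValidationError("degenerate polygon")
    cx = np.sum((x + xn) * cross) / (6.0 * area)
    cy = np.sum((y + yn) * cross) / (6.0 * area)
    sxx = np.sum((x * x + x * xn + xn * xn) * cross) / (12.0 * area) - cx * cx
    syy = np.sum((y * y + y * yn + yn * yn) * cross) / (12.0 * area) - cy * cy
    sxy = np.sum((2 * x * y + x * yn + xn * y + 2 * xn * yn) * cross) / (24.0 * area) - cx * cy
    return abs(area), np.array([[sxx, sxy], [sxy, syy]])


def estimate_diameter(roi: CapillaryROI, estimator: str = "ellipse") -> float:
    """Capillary diameter (µm) from the ROI polygon.

    Estimators:

    - ``ellipse`` (default): mean of the major and minor axis lengths of
      the ellipse matching the polygon's second central moments.
    - ``equivalent_circle``: 2·sqrt(area/π).
    - ``feret_max``: maximum vertex-to-vertex distance.

    All three coincide on circles up to polygonization error.
    """
    v = roi.vertices
    if estimator == "ellipse":
        _, cov = _polygon_second_moments(v)
        eigvals = np.linalg.eigvalsh(cov)
        if np.any(eigvals <= 0):
            raise ValidationError("degenerate polygon for ellipse estimator")
        axes = 4.0 * np.sqrt(eigvals)  # full axis lengths 2a = 4*sqrt(lambda)
        return float(axes.mean()) / 1e3
    if estimator == "equivalent_circle":
        area, _ = _polygon_second_moments(v)
        return 2.0 * math.sqrt(area / math.pi) / 1e3
    if estimator == "feret_max":
        d2 = np.sum((v[:, None, :] - v[None, :, :]) ** 2, axis=-1)
        return float(np.sqrt(d2.max())) / 1e3
    raise ParameterError(f"unknown diameter estimator {estimator!r}")


def normalized_cellular_signal(total: int, diameter_um: float) -> float:
    """Total signals per µm of capillary diameter."""
    if diameter_um <= 0:
        raise ParameterError("diameter must be positive")
    return total / diameter_um


def clusters_in_roi(
    properties: list[ClusterProperties], roi: CapillaryROI
) -> list[ClusterProperties]:
    """Clusters whose centroid lies inside (or on) the ROI polygon.

    Centroid membership is the deterministic rule for clusters straddling
    the boundary.
    """
    if not properties:
        return []
    cx = np.array([p.centroid_nm[0] for p in properties])
    cy = np.array([p.centroid_nm[1] for p in properties])
    inside = _points_covered(roi.polygon, cx, cy)
    return [p for p, keep in zip(properties, inside) if keep]


def capillary_metrics(
    table: LocalizationTable,
    roi: CapillaryROI,
    properties: list[ClusterProperties] | None = None,
    estimator: str = "ellipse",
) -> CapillaryMetrics:
    """Assemble the per-capillary metrics record for one channel."""
    total = total_cellular_signal(table, roi)
    diameter = estimate_diameter(roi, estimator=estimator)
    inside = clusters_in_roi(properties, roi) if properties is not None else []
    n_clusters = sum(1 for p in inside if not p.degenerate)
    return CapillaryMetrics(
        capillary_id=roi.label,
        channel=table.channel_label,
        diameter_um=diameter,
        perimeter_um=roi.perimeter_um,
        total_signals=total,
        normalized_signal_per_um=normalized_cellular_signal(total, diameter),
        normalized_signal_per_um_perimeter=total / roi.perimeter_um,
        n_clusters=n_clusters,
    )


def pair_clusters(
    primary_props: list[ClusterProperties],
    partner_props: list[ClusterProperties],
    pairing_nm: float = DEFAULT_PAIRING_NM,
) -> list[CouplingLabel]:
    """Classify each primary cluster as coupled to or independent of the
    partner channel.

    ``gap_nm`` is the minimum member-to-member distance from the primary
    cluster to any partner cluster; the cluster is *coupled* iff
    ``gap_nm <= pairing_nm``, with the argmin partner recorded.  With no
    partner clusters every primary cluster is independent with ``gap_nm``
    = +inf.
    """
    if pairing_nm <= 0:
        raise ParameterError("pairing_nm must be positive")
    if not partner_props:
        return [
            CouplingLabel(p.cluster_id, "independent", None, math.inf)
            for p in primary_props
        ]
    partner_pts = np.concatenate([q.member_points_nm for q in partner_props])
    partner_ids = np.concatenate(
        [np.full(len(q.member_points_nm), q.cluster_id) for q in partner_props]
    )
    labels = []
    for p in primary_props:
        d = np.sqrt(
            ((p.member_points_nm[:, None, :] - partner_pts[None, :, :]) ** 2).sum(-1)
        )
        d_min_per_point = d.min(axis=0)
        best = int(np.argmin(d_min_per_point))
        gap = float(d_min_per_point[best])
        coupled = gap <= pairing_nm
        labels.append(
            CouplingLabel(
                p.cluster_id,
                "coupled" if coupled else "independent",
                int(partner_ids[best]) if coupled else None,
                gap,
            )
        )
    return labels


@dataclass
class CouplingContrast:
    coupled_mean: float | None
    coupled_sem: float | None
    n_coupled: int
    independent_mean: float | None
    independent_sem: float | None
    n_independent: int
    ratio: float | None  # coupled / independent mean density
    ratio_defined: bool


def coupling_density_contrast(
    labels: list[CouplingLabel], props: list[ClusterProperties]
) -> CouplingContrast:
    """Mean ± s.e.m. cluster density per coupling group and their ratio.

    Degenerate clusters carry no density and are excluded.  Empty groups
    are reported as absent (ratio undefined, explicitly flagged).
    """
    by_id = {p.cluster_id: p for p in props}
    missing = [l.cluster_id for l in labels if l.cluster_id not in by_id]
    if missing:
        raise ConsistencyError(f"labels reference unknown cluster ids {missing}")
    groups: dict[str, list[float]] = {"coupled": [], "independent": []}
    for lab in labels:
        p = by_id[lab.cluster_id]
        if not p.degenerate:
            groups[lab.status].append(p.density_per_um2)

    def _stats(vals: list[float]) -> tuple[float | None, float | None]:
        if not vals:
            return None, None
        arr = np.asarray(vals)
        sem = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else None
        return float(arr.mean()), sem

    c_mean, c_sem = _stats(groups["coupled"])
    i_mean, i_sem = _stats(groups["independent"])
    defined = c_mean is not None and i_mean is not None and i_mean > 0
    return CouplingContrast(
        coupled_mean=c_mean,
        coupled_sem=c_sem,
        n_coupled=len(groups["coupled"]),
        independent_mean=i_mean,
        independent_sem=i_sem,
        n_independent=len(groups["independent"]),
        ratio=(c_mean / i_mean) if defined else None,
        ratio_defined=defined,
    )
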
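"""Relative tracer-leakage index in a fixed abluminal band.

The claudin-5 ring polygon of a capillary is offset outward (away from the
lumen) by an inner and an outer distance (defaults 100 and 300 nm); the
region between the two offsets is the abluminal band.  Tracer localization
density in the band (signals/µm²), normalized to the mean density of a
reference group, yields the relative leakage index — the reference group's
mean index is 1 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from shapely.geometry import Polygon

from .capillary import _points_covered
from .errors import GeometryError, NormalizationError, ParameterError
from .io import CapillaryROI, LocalizationTable

__all__ = [
    "AbluminalBand",
    "LeakageRecord",
    "build_abluminal_band",
    "leakage_density",
    "relative_leakage_index",
    "ring_from_localizations",
    "DEFAULT_INNER_OFFSET_NM",
    "DEFAULT_OUTER_OFFSET_NM",
]

DEFAULT_INNER_OFFSET_NM = 100.0
DEFAULT_OUTER_OFFSET_NM = 300.0


@dataclass
class AbluminalBand:
    inner_offset_nm: float
    outer_offset_nm: float
    band_polygon: Polygon
    band_area_um2: float


@dataclass
class LeakageRecord:
    capillary_id: str
    group: str
    tracer_channel: str
    band_inner_nm: float
    band_outer_nm: float
    band_area_um2: float
    tracer_count: int
    density_per_um2: float
    relative_index: float | None = None


def ring_from_localizations(table: LocalizationTable, label: str = "ring") -> CapillaryROI:
    """Auto-fit a ring annotation as the convex hull of a channel's
    localizations (alternative to a user-supplied ROI)."""
    from scipy.spatial import ConvexHull

    if len(table) < 3:
        raise GeometryError("need >= 3 localizations to fit a ring")
    hull = ConvexHull(table.coords)
    return CapillaryROI(table.coords[hull.vertices], label=label)


def build_abluminal_band(
    ring: CapillaryROI,
    inner_offset_nm: float = DEFAULT_INNER_OFFSET_NM,
    outer_offset_nm: float = DEFAULT_OUTER_OFFSET_NM,
    quad_segs: int = 32,
) -> AbluminalBand:
    """Region between the outward offsets of the ring polygon.

    ``quad_segs`` controls the circular-arc approximation of the offset
    corners (shapely buffer resolution).
    """
    if inner_offset_nm < 0 or outer_offset_nm <= inner_offset_nm:
        raise ParameterError("offsets must satisfy 0 <= inner < outer")
    poly = ring.polygon
    outer = poly.buffer(outer_offset_nm, quad_segs=quad_segs)
    inner = poly.buffer(inner_offset_nm, quad_segs=quad_segs) if inner_offset_nm > 0 else poly
    band = outer.difference(inner)
    if band.is_empty or not band.is_valid or band.area <= 0:
        raise GeometryError(
            f"offset band construction failed for ROI {ring.label!r} "
            f"(inner={inner_offset_nm}, outer={outer_offset_nm} nm)"
        )
    return AbluminalBand(
        inner_offset_nm=inner_offset_nm,
        outer_offset_nm=outer_offset_nm,
        band_polygon=band,
        band_area_um2=band.area / 1e6,
    )


def leakage_density(
    tracer: LocalizationTable,
    band: AbluminalBand,
    capillary_id: str = "capillary",
    group: str = "",
) -> LeakageRecord:
    """Tracer signal density (signals/µm²) inside the abluminal band."""
    if len(tracer):
        count = int(np.count_nonzero(_points_covered(band.band_polygon, tracer.x, tracer.y)))
    else:
        count = 0
    return LeakageRecord(
        capillary_id=capillary_id,
        group=group,
        tracer_channel=tracer.channel_label,
        band_inner_nm=band.inner_offset_nm,
        band_outer_nm=band.outer_offset_nm,
        band_area_um2=band.band_area_um2,
        tracer_count=count,
        density_per_um2=count / band.band_area_um2,
    )


def relative_leakage_index(
    records: list[LeakageRecord], reference_group: str
) -> list[LeakageRecord]:
    """Fill ``relative_index`` = density / mean density of the reference
    group (whose mean index is therefore exactly 1)."""
    ref = [r.density_per_um2 for r in records if r.group == reference_group]
    if not ref:
        raise ParameterError(f"reference group {reference_group!r} is empty")
    ref_mean = float(np.mean(ref))
    if ref_mean <= 0:
        raise NormalizationError(
            f"reference group {reference_group!r} has zero mean density; index undefined"
        )
    return [replace(r, relative_index=r.density_per_um2 / ref_mean) for r in records]
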
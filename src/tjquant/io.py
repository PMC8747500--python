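"""Reading/writing SMLM molecular lists and ROI annotations, plus QC rendering.

A *molecular list* is the tabular output of single-molecule localization
software: one row per resolved localization with spatial coordinates (and
optionally frame, intensity and localization uncertainty).  The reader is
dialect-driven so that CSV exports from different localization packages can
be adapted by naming their coordinate columns and units.

All coordinates are held internally in nanometres, x rightward, y downward,
origin at the top-left of the camera field.  Areas are reported in µm² and
densities in signals/µm² throughout the package.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr
from shapely.geometry import LinearRing, Polygon

from .errors import FormatError, ParameterError, ParseError, ValidationError

__all__ = [
    "Dialect",
    "THUNDERSTORM",
    "LocalizationTable",
    "CapillaryROI",
    "read_molecular_list",
    "write_molecular_list",
    "read_roi",
    "write_roi",
    "render_localizations",
]

#: nanometres per unit, keyed by the bracketed unit suffix of a column header
_UNIT_TO_NM = {"nm": 1.0, "um": 1000.0, "µm": 1000.0, "μm": 1000.0, "px": None}


def _unit_factor(column: str, override: str | None = None) -> float:
    """Nanometres per unit for a column, inferred from a ``[unit]`` suffix."""
    unit = override
    if unit is None:
        lo, hi = column.rfind("["), column.rfind("]")
        unit = column[lo + 1 : hi].strip() if 0 <= lo < hi else "nm"
    factor = _UNIT_TO_NM.get(unit)
    if factor is None:
        raise FormatError(f"unsupported coordinate unit {unit!r} in column {column!r}")
    return factor


@dataclass(frozen=True)
class Dialect:
    """Column naming/unit convention of a molecular-list CSV.

    The default matches the ThunderSTORM-style export convention:
    comma-separated values with double-quoted headers
    ``"x [nm]","y [nm]","frame","intensity [photon]","uncertainty [nm]"``.
    Units are inferred from the bracketed header suffix unless overridden.
    """

    x: str = "x [nm]"
    y: str = "y [nm]"
    frame: str | None = "frame"
    intensity: str | None = "intensity [photon]"
    uncertainty: str | None = "uncertainty [nm]"
    x_unit: str | None = None  # override; else inferred from header
    y_unit: str | None = None

    def coordinate_factors(self) -> tuple[float, float]:
        return _unit_factor(self.x, self.x_unit), _unit_factor(self.y, self.y_unit)


THUNDERSTORM = Dialect()


@dataclass
class LocalizationTable:
    """Per-molecule 2D localization records of a single imaging channel.

    Coordinates are in nanometres.  ``extra`` preserves unknown columns of
    the source file verbatim (opaque to all computations).
    """

    x: np.ndarray
    y: np.ndarray
    frame: np.ndarray | None = None
    intensity: np.ndarray | None = None
    uncertainty: np.ndarray | None = None
    channel_label: str = "unnamed"
    extra: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float).ravel()
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.x.shape != self.y.shape:
            raise ValidationError("x and y must have equal length")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValidationError("coordinates must be finite")
        if not self.channel_label:
            raise ValidationError("channel_label must be non-empty")
        for name in ("frame", "intensity", "uncertainty"):
            col = getattr(self, name)
            if col is not None:
                col = np.asarray(col)
                if col.shape != self.x.shape:
                    raise ValidationError(f"{name} length mismatch")
                setattr(self, name, col)
        if self.uncertainty is not None and np.any(self.uncertainty < 0):
            raise ValidationError("uncertainty must be >= 0")

    def __len__(self) -> int:
        return self.x.size

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) array of (x, y) in nm."""
        return np.column_stack([self.x, self.y])

    def translated(self, dx: float, dy: float) -> "LocalizationTable":
        return LocalizationTable(
            self.x + dx, self.y + dy, self.frame, self.intensity,
            self.uncertainty, self.channel_label, dict(self.extra),
        )


@dataclass
class CapillaryROI:
    """Simple closed polygon delimiting a capillary cross-section (nm)."""

    vertices: np.ndarray
    label: str = "capillary"

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValidationError("ROI needs >= 3 (x, y) vertices")
        if not np.all(np.isfinite(v)):
            raise ValidationError("ROI vertices must be finite")
        ring = LinearRing(v)
        if not ring.is_simple or not ring.is_valid:
            raise ValidationError("ROI polygon is self-intersecting")
        if Polygon(v).area <= 0:
            raise ValidationError("ROI polygon has zero area")
        self.vertices = v

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def area_um2(self) -> float:
        return self.polygon.area / 1e6

    @property
    def perimeter_um(self) -> float:
        return self.polygon.length / 1e3

    def diameter_um(self, estimator: str = "ellipse") -> float:
        from .capillary import estimate_diameter

        return estimate_diameter(self, estimator=estimator)


def read_molecular_list(
    path: str | Path,
    dialect: Dialect = THUNDERSTORM,
    channel_label: str | None = None,
) -> LocalizationTable:
    """Read a molecular-list CSV into a :class:`LocalizationTable`.

    Coordinates are converted to nm according to the dialect; unknown extra
    columns are preserved untouched; row order is preserved.

    Raises
    ------
    FormatError
        if a coordinate column declared by the dialect is missing.
    ParseError
        if a coordinate cell is non-numeric (carries the 1-based data row).
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in (dialect.x, dialect.y):
        if col not in df.columns:
            raise FormatError(f"missing coordinate column {col!r} in {path}")
    fx, fy = dialect.coordinate_factors()
    coords = {}
    for col, factor in ((dialect.x, fx), (dialect.y, fy)):
        raw = df[col]
        numeric = pd.to_numeric(raw, errors="coerce")
        bad = numeric.isna() & raw.notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise ParseError(
                f"non-numeric value {raw.iloc[row - 1]!r} in column {col!r} at data row {row}",
                row=row,
            )
        if numeric.isna().any():
            row = int(np.flatnonzero(numeric.isna().to_numpy())[0]) + 1
            raise ParseError(f"missing coordinate in column {col!r} at data row {row}", row=row)
        coords[col] = numeric.to_numpy(dtype=float) * factor

    known = {dialect.x, dialect.y}
    kwargs: dict = {}
    for attr, col in (
        ("frame", dialect.frame),
        ("intensity", dialect.intensity),
        ("uncertainty", dialect.uncertainty),
    ):
        if col is not None and col in df.columns:
            kwargs[attr] = pd.to_numeric(df[col], errors="coerce").to_numpy()
            known.add(col)
    extra = {c: df[c].to_numpy() for c in df.columns if c not in known}
    return LocalizationTable(
        coords[dialect.x],
        coords[dialect.y],
        channel_label=channel_label or path.stem,
        extra=extra,
        **kwargs,
    )


def write_molecular_list(
    table: LocalizationTable,
    path: str | Path,
    dialect: Dialect = THUNDERSTORM,
    float_format: str = "%.4f",
) -> None:
    """Write a molecular list as CSV in the given dialect (quoted headers).

    ``read_molecular_list`` inverts it on coordinates up to the float
    formatting (default 1e-4 nm resolution).
    """
    fx, fy = dialect.coordinate_factors()
    columns: list[tuple[str, np.ndarray, bool]] = [
        (dialect.x, table.x / fx, True),
        (dialect.y, table.y / fy, True),
    ]
    for name, col in (
        (dialect.frame, table.frame),
        (dialect.intensity, table.intensity),
        (dialect.uncertainty, table.uncertainty),
    ):
        if name is not None and col is not None:
            columns.append((name, np.asarray(col), False))
    for name, col in table.extra.items():
        columns.append((name, np.asarray(col), False))

    def fmt(value, is_coord: bool) -> str:
        if is_coord:
            return float_format % value
        if isinstance(value, (float, np.floating)):
            return repr(float(value))
        return str(value)

    lines = [",".join(f'"{name}"' for name, _, _ in columns)]
    for i in range(len(table)):
        lines.append(",".join(fmt(col[i], c) for _, col, c in columns))
    Path(path).write_text("\n".join(lines) + "\n")


def read_roi(path: str | Path) -> CapillaryROI:
    """Read an ROI from the package's JSON vertex schema.

    Schema: ``{"label": str, "vertices_nm": [[x, y], ...]}`` with >= 3
    vertices forming a simple (non-self-intersecting) closed polygon in nm.
    """
    payload = json.loads(Path(path).read_text())
    if "vertices_nm" not in payload:
        raise FormatError(f"ROI file {path} lacks 'vertices_nm'")
    return CapillaryROI(
        np.asarray(payload["vertices_nm"], dtype=float),
        label=str(payload.get("label", Path(path).stem)),
    )


def write_roi(roi: CapillaryROI, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps({"label": roi.label, "vertices_nm": roi.vertices.tolist()}, indent=1)
    )


def _render_bounds(
    tables: Sequence[LocalizationTable], pixel_nm: float, pad_nm: float
) -> tuple[float, float, int, int]:
    xs = np.concatenate([t.x for t in tables if len(t)]) if any(len(t) for t in tables) else np.zeros(1)
    ys = np.concatenate([t.y for t in tables if len(t)]) if any(len(t) for t in tables) else np.zeros(1)
    x0 = min(0.0, xs.min()) - pad_nm
    y0 = min(0.0, ys.min()) - pad_nm
    nx = max(1, int(math.ceil((xs.max() + pad_nm - x0) / pixel_nm)) + 1)
    ny = max(1, int(math.ceil((ys.max() + pad_nm - y0) / pixel_nm)) + 1)
    return x0, y0, nx, ny


def render_localizations(
    tables: Sequence[LocalizationTable],
    pixel_nm: float,
    mode: str = "histogram",
    default_uncertainty_nm: float = 20.0,
    bounds: tuple[float, float, int, int] | None = None,
) -> list[np.ndarray]:
    """Render localization channels to 2D rasters (one image per table).

    Both modes conserve mass: the sum of each image equals the record count
    of its table (to 1e-6 relative in gaussian mode, where each record
    contributes a unit-mass Gaussian kernel of width equal to its
    localization uncertainty, truncated at 6 sigma).

    ``bounds`` is ``(x0_nm, y0_nm, nx, ny)``; by default it is derived from
    the data with origin at (0, 0) for non-negative coordinates, padded by
    6 sigma in gaussian mode so that no kernel mass falls off the canvas.
    """
    if pixel_nm <= 0:
        raise ParameterError("pixel_nm must be positive")
    if mode not in ("histogram", "gaussian"):
        raise ParameterError(f"unknown render mode {mode!r}")

    sigmas = []
    for t in tables:
        s = t.uncertainty if t.uncertainty is not None else np.full(len(t), default_uncertainty_nm)
        sigmas.append(np.maximum(np.asarray(s, dtype=float), 1e-6))
    pad = 6.0 * max((s.max() for s in sigmas if s.size), default=0.0) if mode == "gaussian" else 0.0
    if bounds is None:
        x0, y0, nx, ny = _render_bounds(tables, pixel_nm, pad)
    else:
        x0, y0, nx, ny = bounds

    images = []
    x_edges = x0 + pixel_nm * np.arange(nx + 1)
    y_edges = y0 + pixel_nm * np.arange(ny + 1)
    for t, sigma in zip(tables, sigmas):
        if mode == "histogram":
            img, _, _ = np.histogram2d(t.y, t.x, bins=(y_edges, x_edges))
            images.append(img)
            continue
        img = np.zeros((ny, nx))
        for xi, yi, si in zip(t.x, t.y, sigma):
            # separable Gaussian integrated per pixel via the normal CDF
            wx = ndtr((x_edges - xi) / si)
            wy = ndtr((y_edges - yi) / si)
            img += np.outer(np.diff(wy), np.diff(wx))
        images.append(img)
    return images
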
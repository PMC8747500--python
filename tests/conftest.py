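import math

import numpy as np
import pytest

from tjquant.io import CapillaryROI, LocalizationTable


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_table(x, y, **kwargs) -> LocalizationTable:
    return LocalizationTable(np.asarray(x, float), np.asarray(y, float), **kwargs)


def circle_roi(radius_nm: float, center=(0.0, 0.0), n_vertices: int = 256,
               label: str = "circle") -> CapillaryROI:
    theta = np.linspace(0, 2 * math.pi, n_vertices, endpoint=False)
    verts = np.column_stack([
        center[0] + radius_nm * np.cos(theta),
        center[1] + radius_nm * np.sin(theta),
    ])
    return CapillaryROI(verts, label=label)


# ---------------------------------------------------------------------------
# independent oracles (deliberately simple / brute force)
# ---------------------------------------------------------------------------

def union_find_partition(coords: np.ndarray, threshold: float) -> np.ndarray:
    """All-pairs union-find over strict d < threshold; labels 1..k in order
    of first appearance."""
    n = len(coords)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if math.dist(coords[i], coords[j]) < threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    labels = np.array([find(i) for i in range(n)])
    out = np.empty(n, dtype=int)
    seen: dict[int, int] = {}
    for i, lab in enumerate(labels):
        if lab not in seen:
            seen[lab] = len(seen) + 1
        out[i] = seen[lab]
    return out


def canonical_labels(assignment) -> np.ndarray:
    """Relabel a partition to 1..k in order of first appearance."""
    out = np.empty(len(assignment), dtype=int)
    seen: dict[int, int] = {}
    for i, lab in enumerate(assignment):
        key = int(lab)
        if key not in seen:
            seen[key] = len(seen) + 1
        out[i] = seen[key]
    return out


def gift_wrap_hull_area(points: np.ndarray) -> float:
    """Convex hull area by gift wrapping + shoelace (O(n*h) oracle)."""
    pts = np.unique(points, axis=0)
    if len(pts) < 3:
        return 0.0
    start = min(range(len(pts)), key=lambda i: (pts[i][0], pts[i][1]))
    hull = [start]
    while True:
        cur = hull[-1]
        cand = (cur + 1) % len(pts)
        for j in range(len(pts)):
            if j == cur:
                continue
            a = pts[cand] - pts[cur]
            b = pts[j] - pts[cur]
            cross = a[0] * b[1] - a[1] * b[0]
            if cross < 0 or (cross == 0 and
                             np.linalg.norm(pts[j] - pts[cur]) > np.linalg.norm(pts[cand] - pts[cur])):
                cand = j
        if cand == start:
            break
        hull.append(cand)
        if len(hull) > len(pts):  # degenerate safety
            break
    hv = pts[hull]
    x, y = hv[:, 0], hv[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def point_in_polygon(point, vertices) -> bool:
    """Ray-casting point-in-polygon oracle (boundary counts as inside)."""
    x, y = point
    n = len(vertices)
    inside = False
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        # on-segment check
        if (min(x1, x2) - 1e-9 <= x <= max(x1, x2) + 1e-9
                and min(y1, y2) - 1e-9 <= y <= max(y1, y2) + 1e-9):
            cross = (x2 - x1) * (y - y1) - (y2 - y1) * (x - x1)
            if abs(cross) < 1e-6 * max(1.0, abs(x2 - x1) + abs(y2 - y1)):
                return True
        if (y1 > y) != (y2 > y):
            x_int = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < x_int:
                inside = not inside
    return inside
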
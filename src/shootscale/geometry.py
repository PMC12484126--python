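"""Per-leaf geometry from planar lamina outlines.

A scanned lamina is reduced to an ordered ring of boundary coordinates (cm).
From that ring this module computes the three quantities the scaling analysis
consumes: the enclosed area ``A`` (shoelace), the lamina length ``L`` and
width ``W`` (caliper convention, see :func:`length_width`), and the per-leaf
Montgomery ratio ``A / (L * W)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import Polygon

from .exceptions import DegenerateOutlineError, InvalidOutlineError

__all__ = [
    "LeafOutline",
    "polygon_area",
    "length_width",
    "montgomery_ratio",
    "read_outline",
    "read_outline_dir",
]

_AREA_EPS = 1e-12


@dataclass(frozen=True)
class LeafOutline:
    """An ordered, implicitly closed lamina boundary in cm.

    A trailing vertex equal to the first is dropped on construction; winding
    direction is irrelevant (areas are absolute). The ring must be simple
    (non-self-intersecting) and enclose positive area.
    """

    points: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise InvalidOutlineError(
                f"outline must be an (n, 2) coordinate array, got shape {pts.shape}"
            )
        if len(pts) > 1 and np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        if len(pts) < 3:
            raise InvalidOutlineError(f"outline needs >= 3 distinct points, got {len(pts)}")
        if not np.isfinite(pts).all():
            raise InvalidOutlineError("outline contains non-finite coordinates")
        centred = pts - pts.mean(axis=0)
        if np.linalg.matrix_rank(centred, tol=1e-12 * max(1.0, np.abs(pts).max())) < 2:
            raise DegenerateOutlineError("outline is collinear")
        poly = Polygon(pts)
        if not poly.is_valid:
            raise InvalidOutlineError("outline is self-intersecting")
        if poly.area <= _AREA_EPS:
            raise DegenerateOutlineError("outline encloses zero area")
        object.__setattr__(self, "points", pts)

    @property
    def n_points(self) -> int:
        return len(self.points)


def polygon_area(outline: LeafOutline) -> float:
    """Absolute shoelace area (cm^2) of the outline polygon.

    Invariant under vertex-order reversal, starting-vertex rotation, and
    rigid motion of the coordinate frame.
    """
    return Polygon(outline.points).area


def _caliper_axis(pts: np.ndarray) -> np.ndarray:
    """Unit vector of the maximum pairwise point distance (hull diameter)."""
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise DegenerateOutlineError("outline is collinear") from exc
    hp = pts[hull.vertices]
    # hull vertex count is small for digitised laminae; O(h^2) is fine
    diff = hp[:, None, :] - hp[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    axis = hp[i] - hp[j]
    norm = np.linalg.norm(axis)
    if norm <= 0:
        raise DegenerateOutlineError("outline has no positive extent")
    return axis / norm


def _principal_axis(pts: np.ndarray) -> np.ndarray:
    """Unit vector of the leading principal component of the boundary points."""
    centred = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    return vt[0]


def length_width(
    outline: LeafOutline,
    convention: Literal["caliper", "principal"] = "caliper",
) -> tuple[float, float]:
    """Lamina length and width (cm).

    With the default ``caliper`` convention the length axis is the direction
    of the maximum pairwise distance between boundary points (the rotating-
    calipers diameter); ``L`` is the extent of the projections onto that axis
    and ``W`` the extent onto its normal.  The ``principal`` convention uses
    the leading principal component of the boundary instead, which for
    strongly curved laminae tracks the midrib direction more closely.

    ``L >= W`` is not enforced; both values are returned as defined.
    """
    pts = outline.points
    if convention == "caliper":
        u = _caliper_axis(pts)
    elif convention == "principal":
        u = _principal_axis(pts)
    else:
        raise ValueError(f"unknown length convention {convention!r}")
    v = np.array([-u[1], u[0]])
    proj_l = pts @ u
    proj_w = pts @ v
    length = float(proj_l.max() - proj_l.min())
    width = float(proj_w.max() - proj_w.min())
    if length <= 0 or width <= 0:
        raise DegenerateOutlineError("outline is collinear (zero caliper width)")
    return length, width


def montgomery_ratio(
    outline: LeafOutline,
    convention: Literal["caliper", "principal"] = "caliper",
) -> float:
    """Per-leaf Montgomery ratio ``A / (L * W)`` (dimensionless).

    Equals 1 for a rectangle and pi/4 for an ellipse; lies in (0, 1] for any
    convex lamina.
    """
    length, width = length_width(outline, convention=convention)
    return polygon_area(outline) / (length * width)


def read_outline(path: str | Path, delimiter: str | None = None) -> LeafOutline:
    """Read one outline file: two numeric columns (x, y) per row, cm."""
    pts = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    if pts.shape[1] != 2:
        raise InvalidOutlineError(f"{path}: expected 2 columns, got {pts.shape[1]}")
    return LeafOutline(pts)


def read_outline_dir(
    directory: str | Path,
    pattern: str = "*.csv",
    delimiter: str | None = ",",
    convention: Literal["caliper", "principal"] = "caliper",
) -> pd.DataFrame:
    """Batch-read a directory of outline files into a per-leaf trait table.

    The file stem carries the leaf id (e.g. ``shootA_leaf3.csv``). Returns a
    DataFrame with columns ``leaf_id, area, length, width, montgomery_k``.
    """
    rows = []
    paths: Iterable[Path] = sorted(Path(directory).glob(pattern))
    for p in paths:
        outline = read_outline(p, delimiter=delimiter)
        length, width = length_width(outline, convention=convention)
        area = polygon_area(outline)
        rows.append(
            {
                "leaf_id": p.stem,
                "area": area,
                "length": length,
                "width": width,
                "montgomery_k": area / (length * width),
            }
        )
    return pd.DataFrame(rows, columns=["leaf_id", "area", "length", "width", "montgomery_k"])


def ellipse_outline(a: float, b: float, n: int = 512, phase: float = 0.0) -> LeafOutline:
    """Regular n-gon inscribed in an ellipse with semi-axes (a, b).

    Convenience constructor used for calibration and testing; the inscribed
    polygon area is (n/2)*a*b*sin(2*pi/n).
    """
    t = phase + 2 * math.pi * np.arange(n) / n
    return LeafOutline(np.column_stack([a * np.cos(t), b * np.sin(t)]))
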
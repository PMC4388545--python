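"""Modified ovality ratio of the optic disc from margin points.

The classical ovality ratio divides the shortest disc diameter by the
longest, so a tilted (elongated) disc scores below 1 regardless of the
elongation axis. The modified form used here first classifies the disc by
the axis of its longest diameter — measured clockwise from the vertical in
displayed right-eye fundus coordinates (y down, x right) — as *vertical*
(< 45 deg, including the 45 deg tie) or *horizontal* (> 45 deg), then

* vertical disc:   ratio = d_min / d_max  (<= 1, the classical formula)
* horizontal disc: ratio = d_max / d_min  (>= 1)

so that horizontal elongation, the signature of axial-length growth, is
pushed above 1 instead of being conflated with vertical tilt.

``d_max`` is the rotating-calipers diameter of the margin polygon (the
longest point-pair chord); ``d_min`` defaults to the minimum caliper width
(smallest distance between parallel supporting lines), with the chord
through the centroid perpendicular to ``d_max`` available as an
alternative definition.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import LineString, Polygon

__all__ = [
    "DiscOutline",
    "DiameterPair",
    "OvalityResult",
    "principal_diameters",
    "classify_axis",
    "ovality_ratio",
    "load_outline",
    "outline_from_mask",
]


@dataclass(frozen=True)
class DiscOutline:
    """Ordered optic-disc margin points in fundus-photo pixel coordinates."""

    points: np.ndarray
    eye_id: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        if pts.shape[0] < 8:
            raise ValueError(f"outline needs at least 8 margin points, got {pts.shape[0]}")
        if not np.all(np.isfinite(pts)):
            raise ValueError("margin points must be finite")
        poly = Polygon(pts)
        if not poly.is_valid:
            raise ValueError("margin polygon is self-intersecting or degenerate")
        if not poly.contains(poly.centroid):
            raise ValueError("margin polygon does not contain its centroid")

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.points)


@dataclass(frozen=True)
class DiameterPair:
    """Longest diameter, shortest width, and the long-axis angle.

    ``axis_angle`` is the acute angle of the longest diameter measured
    clockwise from the vertical (upward) direction, in degrees, folded
    into [0, 90].
    """

    d_max: float
    d_min: float
    axis_angle: float

    def __post_init__(self) -> None:
        if not (self.d_max >= self.d_min > 0):
            raise ValueError("require d_max >= d_min > 0")
        if not (0.0 <= self.axis_angle <= 90.0):
            raise ValueError("axis_angle must lie in [0, 90] degrees")


@dataclass(frozen=True)
class OvalityResult:
    ratio: float
    axis_class: str  # 'vertical' | 'horizontal'


def _axis_angle_from_chord(dx: float, dy: float) -> float:
    """Acute clockwise-from-vertical angle of a chord in y-down raster coords.

    Up on the displayed photo is (0, -1); clockwise rotates toward (+1, 0),
    so the signed angle is atan2(dx, -dy), folded into [0, 90].
    """
    ang = np.degrees(np.arctan2(dx, -dy)) % 180.0
    return float(180.0 - ang if ang > 90.0 else ang)


def principal_diameters(outline: DiscOutline, min_mode: str = "width") -> DiameterPair:
    """Longest diameter, shortest diameter and long-axis angle of a margin.

    Parameters
    ----------
    outline : DiscOutline
        Margin polygon.
    min_mode : {'width', 'perpendicular'}
        'width' (default): minimum distance between parallel supporting
        lines over all directions — the standard caliper minimum, well
        posed for irregular outlines. 'perpendicular': length of the chord
        through the centroid perpendicular to the longest diameter.

    Raises
    ------
    ValueError
        If the outline is degenerate (collinear points).
    """
    pts = outline.points
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise ValueError("degenerate (collinear) outline") from exc
    hv = pts[hull.vertices]

    # longest point-pair chord over hull vertices
    diff = hv[:, None, :] - hv[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    d_max = float(np.sqrt(d2[i, j]))
    dx, dy = hv[j] - hv[i]
    axis_angle = _axis_angle_from_chord(float(dx), float(dy))

    if min_mode == "width":
        # minimum width: over each hull edge, the farthest vertex distance
        edges = np.roll(hv, -1, axis=0) - hv
        lengths = np.linalg.norm(edges, axis=1)
        keep = lengths > 0
        normals = np.column_stack([-edges[keep, 1], edges[keep, 0]]) / lengths[keep, None]
        # distances of all hull vertices to each edge line
        rel = hv[None, :, :] - hv[keep][:, None, :]
        dists = np.abs(np.einsum("enk,ek->en", rel, normals))
        d_min = float(dists.max(axis=1).min())
    elif min_mode == "perpendicular":
        poly = outline.polygon
        cx, cy = poly.centroid.x, poly.centroid.y
        # unit vector perpendicular to the max chord
        ux, uy = (dx, dy) / np.hypot(dx, dy)
        px, py = -uy, ux
        half = 2.0 * d_max
        line = LineString([(cx - half * px, cy - half * py), (cx + half * px, cy + half * py)])
        d_min = float(poly.intersection(line).length)
    else:
        raise ValueError(f"unknown min_mode {min_mode!r}")
    if d_min <= 0:
        raise ValueError("degenerate outline: zero minimum width")
    d_min = min(d_min, d_max)
    return DiameterPair(d_max=d_max, d_min=d_min, axis_angle=axis_angle)


def classify_axis(pair: DiameterPair) -> str:
    """'vertical' when the long axis is within 45 deg of vertical, else 'horizontal'.

    Exactly 45 deg classifies as vertical, keeping the classical
    (ratio <= 1) formula for the boundary case.
    """
    return "vertical" if pair.axis_angle <= 45.0 else "horizontal"


def ovality_ratio(pair: DiameterPair) -> OvalityResult:
    """Modified ovality ratio with the 45-degree axis rule."""
    if pair.d_min == 0:
        raise ValueError("d_min is zero; ratio undefined")
    axis_class = classify_axis(pair)
    if axis_class == "vertical":
        ratio = pair.d_min / pair.d_max
    else:
        ratio = pair.d_max / pair.d_min
    return OvalityResult(ratio=float(ratio), axis_class=axis_class)


def load_outline(path: str | Path) -> DiscOutline:
    """Read margin points from a two-column CSV (x, y), optional header."""
    path = Path(path)
    raw = pd.read_csv(path, header=None, dtype=str, skip_blank_lines=True)
    if raw.shape[1] != 2:
        raise ValueError(f"{path}: expected 2 columns, found {raw.shape[1]}")
    start = 0
    try:
        raw.iloc[0].astype(float)
    except (ValueError, TypeError):
        start = 1
    pts = raw.iloc[start:].astype(float).to_numpy()
    return DiscOutline(points=pts, eye_id=path.stem)


def outline_from_mask(mask: np.ndarray, eye_id: str = "") -> DiscOutline:
    """Trace the margin of a binary disc mask image.

    Uses the longest 0.5-level contour; contour (row, col) coordinates are
    mapped to (x=col, y=row) photo pixels and subsampled to at most 720
    points.
    """
    from skimage import measure

    contours = measure.find_contours(np.asarray(mask, dtype=float), 0.5)
    if not contours:
        raise ValueError("mask contains no contour")
    contour = max(contours, key=len)
    pts = contour[:, ::-1]  # (row, col) -> (x, y)
    if len(pts) > 720:
        idx = np.linspace(0, len(pts) - 1, 720).astype(int)
        pts = pts[idx]
    # drop the closing duplicate point if present
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    return DiscOutline(points=pts, eye_id=eye_id)
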
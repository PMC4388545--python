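"""RPE trace data model, CSV I/O, coordinate centering, and image extraction.

The course of the retinal pigment epithelium (RPE) along an unrolled
circumpapillary OCT circle scan is represented as an ordered set of
``(x, y)`` pixel coordinates: ``x`` is the column index along the scan
(both scan ends are nasal, the middle temporal), ``y`` is the image row
(larger values are lower in the B-scan, standard raster convention).

Before sine fitting the trace is re-expressed with the center of the wave
as the origin: ``u = x - (min(x) + max(x)) / 2`` and ``v = y - mean(y)``.
Mean-centering of ``y`` stands in for the missing intercept of the
three-parameter sine model; midpoint-centering of ``x`` makes ``u``
symmetric on a full-width uniform grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "RPETrace",
    "CenteredTrace",
    "BScanImage",
    "load_trace",
    "save_trace",
    "center_arrays",
    "center_coordinates",
    "extract_rpe_from_image",
]


@dataclass(frozen=True)
class RPETrace:
    """Ordered RPE coordinates along one unrolled circle scan.

    Parameters
    ----------
    x : ndarray
        Pixel column indices, strictly increasing, within ``[0, scan_width)``.
        Manual plotting is typically sparse, so ``x`` need not cover every
        column.
    y : ndarray
        Pixel rows (image convention: larger = lower), finite, non-negative.
    scan_width : int
        Total number of columns in the source B-scan.
    eye_id : str
        Opaque identifier of the eye/scan.

    Notes
    -----
    A trace with as few as two points is representable (e.g. for I/O round
    trips); the minimum of eight points needed to constrain the
    three-parameter sine model is enforced at fit time.
    """

    x: np.ndarray
    y: np.ndarray
    scan_width: int
    eye_id: str = ""

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.ndim != 1 or y.ndim != 1 or x.size != y.size:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if x.size < 2:
            raise ValueError(f"trace needs at least 2 points, got {x.size}")
        if not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)):
            raise ValueError("trace coordinates must be finite")
        dx = np.diff(x)
        if np.any(dx <= 0):
            bad = x[1:][dx <= 0][0]
            raise ValueError(f"x must be strictly increasing; duplicate or decreasing at x={bad!r}")
        if self.scan_width <= 0:
            raise ValueError("scan_width must be positive")
        if x[0] < 0 or x[-1] >= self.scan_width:
            raise ValueError(
                f"x must lie in [0, scan_width={self.scan_width}); got range [{x[0]}, {x[-1]}]"
            )
        if np.any(y < 0):
            raise ValueError("y must be non-negative (image rows)")

    @property
    def n_points(self) -> int:
        return int(self.x.size)


@dataclass(frozen=True)
class CenteredTrace:
    """Trace re-expressed with the center of the wave as the origin."""

    u: np.ndarray
    v: np.ndarray
    scan_width: int
    eye_id: str = ""

    def __post_init__(self) -> None:
        u = np.asarray(self.u, dtype=float)
        v = np.asarray(self.v, dtype=float)
        object.__setattr__(self, "u", u)
        object.__setattr__(self, "v", v)
        if u.size != v.size:
            raise ValueError("u and v must have equal length")

    @property
    def n_points(self) -> int:
        return int(self.u.size)


@dataclass(frozen=True)
class BScanImage:
    """Grayscale B-scan-like image (rows x columns).

    Stand-in container for rendered synthetic scans or grayscale files; raw
    vendor OCT exports are out of scope.
    """

    pixels: np.ndarray
    provenance: str = "synthetic"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        object.__setattr__(self, "pixels", px)
        if px.ndim != 2:
            raise ValueError("pixels must be a 2-D grayscale array")
        if not np.all(np.isfinite(px)):
            raise ValueError("pixel intensities must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def load_trace(path: str | Path, scan_width: int | None = None) -> RPETrace:
    """Read an RPE trace from a two-column CSV file.

    The file holds ``x,y`` pixel coordinates, one point per row, with an
    optional single header row; comma separator, decimal point, UTF-8.
    Rows are sorted by ``x`` on load. ``scan_width`` defaults to
    ``floor(max(x)) + 1`` when not given.
    """
    path = Path(path)
    raw = pd.read_csv(path, header=None, dtype=str, skip_blank_lines=True)
    if raw.shape[1] != 2:
        raise ValueError(f"{path}: expected 2 columns, found {raw.shape[1]}")
    # optional header: first row allowed to be non-numeric
    start = 0
    try:
        raw.iloc[0].astype(float)
    except (ValueError, TypeError):
        start = 1
    body = raw.iloc[start:]
    if body.empty:
        raise ValueError(f"{path}: no data rows")
    try:
        arr = body.astype(float).to_numpy()
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: non-numeric data row ({exc})") from exc
    order = np.argsort(arr[:, 0], kind="stable")
    x, y = arr[order, 0], arr[order, 1]
    dup = np.flatnonzero(np.diff(x) == 0)
    if dup.size:
        raise ValueError(f"{path}: duplicate x value {x[dup[0]]!r}")
    if scan_width is None:
        scan_width = int(np.floor(x[-1])) + 1
    return RPETrace(x=x, y=y, scan_width=scan_width, eye_id=path.stem)


def save_trace(trace: RPETrace, path: str | Path) -> None:
    """Write a trace as ``x,y`` CSV with a header; round-trips exactly.

    Values are printed with 17 significant digits so that
    ``load_trace(save_trace(t))`` reproduces every float64 bit-identically.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("x,y\n")
        for xi, yi in zip(trace.x, trace.y):
            fh.write(f"{xi:.17g},{yi:.17g}\n")


def center_arrays(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center raw coordinate arrays: ``u = x - (min+max)/2``, ``v = y - mean(y)``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    u = x - (x.min() + x.max()) / 2.0
    v = y - y.mean()
    return u, v


def center_coordinates(trace: RPETrace) -> CenteredTrace:
    """Convert a trace to wave-centered coordinates.

    The x-origin is the midpoint of the plotted span, the y-origin the mean
    height of the trace; ``scan_width`` is carried through unchanged.
    Idempotent and invariant to vertical translation of the input.
    """
    u, v = center_arrays(trace.x, trace.y)
    return CenteredTrace(u=u, v=v, scan_width=trace.scan_width, eye_id=trace.eye_id)


def extract_rpe_from_image(
    image: BScanImage,
    smoothing_halfwidth: int = 3,
    window_halfwidth: int = 8,
    max_missing_fraction: float = 0.10,
) -> RPETrace:
    """Trace the bright RPE band of a B-scan-like image, one point per column.

    Per column the band row is the intensity-weighted centroid within a
    window of ``+/- window_halfwidth`` rows around the column's brightest
    pixel; the resulting row profile is then median-smoothed with kernel
    ``2 * smoothing_halfwidth + 1``. Columns whose intensity is entirely
    zero are omitted; if more than ``max_missing_fraction`` of columns are
    omitted, extraction fails.

    Intended for rendered synthetic scans with a single dominant band (it
    is not a segmentation algorithm for clinical OCT).
    """
    px = image.pixels
    n_rows, n_cols = px.shape
    rows = np.arange(n_rows, dtype=float)
    xs: list[float] = []
    ys: list[float] = []
    for c in range(n_cols):
        col = px[:, c]
        if col.max() <= 0:
            continue
        r0 = int(np.argmax(col))
        lo = max(0, r0 - window_halfwidth)
        hi = min(n_rows, r0 + window_halfwidth + 1)
        w = col[lo:hi]
        total = w.sum()
        if total <= 0:
            continue
        xs.append(float(c))
        ys.append(float((rows[lo:hi] * w).sum() / total))
    n_missing = n_cols - len(xs)
    if n_cols == 0 or n_missing / max(n_cols, 1) > max_missing_fraction:
        raise ValueError(
            f"extraction failed: {n_missing}/{n_cols} columns have no usable intensity"
        )
    y = np.asarray(ys)
    if smoothing_halfwidth > 0:
        y = ndimage.median_filter(y, size=2 * smoothing_halfwidth + 1, mode="nearest")
    return RPETrace(x=np.asarray(xs), y=y, scan_width=n_cols, eye_id="extracted")
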
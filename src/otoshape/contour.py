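"""Closed otolith outlines: extraction, orientation, resampling and the shape signature.

An otolith outline enters as a binary mask or an ordered polygon and leaves as a
:class:`ShapeSignature` — 512 centroid-to-outline distances sampled at equal
arc-length steps, normalized to unit mean and rotated so that index 0 sits at
the farthest point from the centroid.  The signature is invariant to
translation, uniform scaling and the starting vertex of the input polygon,
which is what makes outlines from different photographs comparable.

Orientation convention: all contours are analysed in the left-otolith pose
(sulcus up, rostrum to the right); right otoliths are mirrored first.
Traversal is counterclockwise throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from skimage import measure

__all__ = [
    "Contour",
    "ShapeSignature",
    "extract_contour",
    "canonical_orientation",
    "polygon_centroid",
    "resample_equidistant",
    "signature",
    "otolith_length",
]


@dataclass
class Contour:
    """Ordered closed polygon; closure is implicit (first vertex != last).

    Parameters
    ----------
    vertices : (n, 2) array of x, y pairs, n >= 3.
    side : which otolith the outline came from ('left', 'right' or None).
    units : 'mm' or 'px'.
    px_per_mm : pixel scale, required to convert px extents to mm.
    """

    vertices: np.ndarray
    side: str | None = "left"
    units: str = "mm"
    px_per_mm: float | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array")
        if v.shape[0] >= 4 and np.allclose(v[0], v[-1]):
            v = v[:-1]  # drop explicit closure
        if v.shape[0] < 3:
            raise ValueError("a contour needs at least 3 distinct vertices")
        if not np.all(np.isfinite(v)):
            raise ValueError("contour vertices must be finite")
        self.vertices = v
        if self.side not in ("left", "right", None):
            raise ValueError(f"side must be 'left', 'right' or None, got {self.side!r}")
        if self.units not in ("mm", "px"):
            raise ValueError(f"units must be 'mm' or 'px', got {self.units!r}")

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]


@dataclass
class ShapeSignature:
    """512 mean-normalized centroid distances starting at the farthest point.

    ``distances`` has unit mean by construction; ``distances[0]`` is the global
    maximum of the sequence.  ``centroid`` and ``mean_radius`` record the
    normalization so absolute geometry can be recovered if needed.
    """

    distances: np.ndarray
    centroid: tuple[float, float]
    mean_radius: float
    start_index: int = 0  # index into the resampled contour where rotation began

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        if d.ndim != 1:
            raise ValueError("distances must be one-dimensional")
        if np.any(d <= 0):
            raise ValueError("signature distances must be strictly positive")
        self.distances = d

    def __len__(self) -> int:
        return self.distances.size


def _signed_area(vertices: np.ndarray) -> float:
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _ensure_ccw(vertices: np.ndarray) -> np.ndarray:
    return vertices if _signed_area(vertices) > 0 else vertices[::-1]


def polygon_centroid(contour: Contour) -> tuple[float, float]:
    """Area centroid of a simple closed polygon via the shoelace moments.

    Unlike the vertex average this is robust to uneven vertex density.
    Raises on (numerically) zero-area polygons.
    """
    v = contour.vertices
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area = 0.5 * float(np.sum(cross))
    scale = max(1.0, float(np.abs(v).max()) ** 2)
    if abs(area) < 1e-12 * scale:
        raise ValueError("degenerate polygon: area is (numerically) zero")
    cx = float(np.sum((x + xn) * cross)) / (6.0 * area)
    cy = float(np.sum((y + yn) * cross)) / (6.0 * area)
    return cx, cy


def extract_contour(mask: np.ndarray) -> Contour:
    """Trace the boundary of the largest foreground component of a binary mask.

    Returns a counterclockwise contour in pixel-center coordinates (units
    'px'), with the image row axis flipped so y increases upward.  Interior
    holes are ignored; with several equally large components the first in scan
    order wins, with a warning.
    """
    m = np.asarray(mask)
    if m.ndim != 2:
        raise ValueError("mask must be a 2-D array")
    m = m.astype(bool)
    if not m.any():
        raise ValueError("empty mask: no foreground pixels")
    labels = measure.label(m, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    best = int(np.argmax(counts))
    ties = np.flatnonzero(counts == counts[best])
    if ties.size > 1:
        warnings.warn(
            f"{ties.size} equally large components; keeping the first in scan order",
            stacklevel=2,
        )
    comp = labels == best
    padded = np.pad(comp, 1).astype(float)
    traces = measure.find_contours(padded, 0.5)
    if not traces:  # pragma: no cover - single fg pixel still yields a trace
        raise ValueError("could not trace a boundary")
    # outer boundary = largest absolute enclosed area among traced curves
    outer = max(traces, key=lambda t: abs(_signed_area(t[:-1] if len(t) > 3 else t)))
    if np.allclose(outer[0], outer[-1]):
        outer = outer[:-1]
    rows = outer[:, 0] - 1.0  # undo padding
    cols = outer[:, 1] - 1.0
    h = m.shape[0]
    verts = np.column_stack([cols, (h - 1.0) - rows])  # x right, y up
    verts = _ensure_ccw(verts)
    return Contour(verts, side=None, units="px")


def canonical_orientation(contour: Contour, assume_left: bool = False) -> Contour:
    """Bring a contour into the left-otolith convention.

    Right otoliths are mirrored about the vertical axis (x -> -x) and the
    vertex order reversed so traversal stays counterclockwise.  Left otoliths
    pass through (re-ordered counterclockwise if needed).
    """
    side = contour.side
    if side is None:
        if not assume_left:
            raise ValueError("otolith side unknown; pass assume_left=True to proceed")
        side = "left"
    v = contour.vertices
    if side == "right":
        v = v.copy()
        v[:, 0] = -v[:, 0]
        v = v[::-1]  # mirroring flips orientation
    v = _ensure_ccw(v)
    return replace(contour, vertices=v, side="left")


def resample_equidistant(contour: Contour, n: int = 512) -> Contour:
    """Resample a closed polygon to exactly ``n`` points at equal arc spacing.

    Points sit at arc lengths i * perimeter / n from the first vertex, linearly
    interpolated between source vertices; traversal is counterclockwise.
    """
    if n < 3:
        raise ValueError("need at least 3 resampling points")
    v = _ensure_ccw(contour.vertices)
    closed = np.vstack([v, v[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    perimeter = cum[-1]
    if perimeter <= 0:
        raise ValueError("degenerate polygon: zero perimeter")
    targets = np.arange(n) * (perimeter / n)
    x = np.interp(targets, cum, closed[:, 0])
    y = np.interp(targets, cum, closed[:, 1])
    return replace(contour, vertices=np.column_stack([x, y]))


def signature(contour: Contour) -> ShapeSignature:
    """Mean-normalized centroid-distance signature of a resampled contour.

    Distances from the polygon area centroid are divided by their mean (so the
    signature has unit mean and is scale-free) and circularly rotated so index
    0 is the farthest point from the centroid.  Exact ties for the maximum are
    broken by the smallest polar angle from the positive x-axis, with a
    warning.
    """
    v = _ensure_ccw(contour.vertices)
    cx, cy = polygon_centroid(replace(contour, vertices=v))
    d = np.hypot(v[:, 0] - cx, v[:, 1] - cy)
    if np.any(d <= 0):
        raise ValueError("centroid coincides with a vertex; degenerate outline")
    mean_r = float(d.mean())
    dn = d / mean_r
    dmax = dn.max()
    ties = np.flatnonzero(dn == dmax)
    if ties.size > 1:
        warnings.warn(
            f"{ties.size} vertices tie for farthest point; "
            "breaking by smallest angle from the positive x-axis",
            stacklevel=2,
        )
        ang = np.mod(np.arctan2(v[ties, 1] - cy, v[ties, 0] - cx), 2.0 * np.pi)
        start = int(ties[np.argmin(ang)])
    else:
        start = int(ties[0])
    return ShapeSignature(
        distances=np.roll(dn, -start),
        centroid=(cx, cy),
        mean_radius=mean_r,
        start_index=start,
    )


def otolith_length(contour: Contour) -> float:
    """Anteroposterior extent (max minus min x) in mm, after canonical orientation."""
    if contour.units == "px":
        if not contour.px_per_mm:
            raise ValueError("pixel contour without px_per_mm scale; cannot report mm")
        scale = contour.px_per_mm
    else:
        scale = 1.0
    x = contour.vertices[:, 0]
    return float(x.max() - x.min()) / scale
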
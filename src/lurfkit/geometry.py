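"""Vectorised planar geometry primitives for buffer extraction.

These operate on segment arrays (x1, y1, x2, y2) rather than shapely
objects: buffer feature extraction evaluates tens of thousands of
(point, radius) pairs against the same small set of segments, which is
far cheaper with broadcast arithmetic than with per-pair predicate calls.
Closed forms keep the operations exactly testable against brute-force
densification.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Segments", "segments_from_lines", "point_segment_distance", "length_in_disc"]


class Segments:
    """A flat array-of-segments view of one or more polylines."""

    def __init__(self, x1, y1, x2, y2, attr=None):
        self.x1 = np.asarray(x1, dtype=float)
        self.y1 = np.asarray(y1, dtype=float)
        self.x2 = np.asarray(x2, dtype=float)
        self.y2 = np.asarray(y2, dtype=float)
        # Per-segment scalar attribute (e.g. AADT), broadcast from the parent line.
        self.attr = (
            np.zeros_like(self.x1) if attr is None else np.asarray(attr, dtype=float)
        )

    def __len__(self) -> int:
        return self.x1.size

    @property
    def length(self) -> np.ndarray:
        return np.hypot(self.x2 - self.x1, self.y2 - self.y1)


def segments_from_lines(lines, attrs=None) -> Segments:
    """Explode polylines (sequences of (x, y) vertices) into a Segments array.

    Parameters
    ----------
    lines : iterable of coordinate sequences (or shapely LineStrings)
    attrs : optional per-line scalar carried onto every segment of the line
    """
    x1, y1, x2, y2, attr = [], [], [], [], []
    if attrs is None:
        attrs = np.zeros(len(lines))
    for coords, a in zip(lines, attrs):
        if hasattr(coords, "coords"):  # shapely geometry
            coords = list(coords.coords)
        coords = np.asarray(coords, dtype=float)
        x1.extend(coords[:-1, 0])
        y1.extend(coords[:-1, 1])
        x2.extend(coords[1:, 0])
        y2.extend(coords[1:, 1])
        attr.extend([a] * (len(coords) - 1))
    return Segments(x1, y1, x2, y2, attr)


def point_segment_distance(px, py, seg: Segments) -> np.ndarray:
    """Distances from points to every segment.

    Returns an array of shape (npoints, nsegments).
    """
    px = np.atleast_1d(np.asarray(px, dtype=float))[:, None]
    py = np.atleast_1d(np.asarray(py, dtype=float))[:, None]
    dx = seg.x2 - seg.x1
    dy = seg.y2 - seg.y1
    den = dx * dx + dy * dy
    den = np.where(den == 0.0, 1.0, den)
    t = ((px - seg.x1) * dx + (py - seg.y1) * dy) / den
    t = np.clip(t, 0.0, 1.0)
    cx = seg.x1 + t * dx
    cy = seg.y1 + t * dy
    return np.hypot(px - cx, py - cy)


def length_in_disc(cx, cy, r, seg: Segments) -> np.ndarray:
    """Length of each segment inside the disc of radius ``r`` at (cx, cy).

    Closed form: the segment p1 + t*(p2-p1), t in [0, 1], lies inside the
    disc for the t-interval where |p(t) - c|^2 <= r^2, a quadratic in t.
    Returns shape (npoints, nsegments) of clipped lengths in metres.
    """
    cx = np.atleast_1d(np.asarray(cx, dtype=float))[:, None]
    cy = np.atleast_1d(np.asarray(cy, dtype=float))[:, None]
    dx = seg.x2 - seg.x1
    dy = seg.y2 - seg.y1
    fx = seg.x1 - cx
    fy = seg.y1 - cy
    a = dx * dx + dy * dy  # (nseg,)
    b = 2.0 * (fx * dx + fy * dy)
    c = fx * fx + fy * fy - r * r
    disc = b * b - 4.0 * a[None, :] * c
    safe_a = np.where(a == 0.0, 1.0, a)
    sq = np.sqrt(np.maximum(disc, 0.0))
    t1 = (-b - sq) / (2.0 * safe_a)
    t2 = (-b + sq) / (2.0 * safe_a)
    t1 = np.clip(t1, 0.0, 1.0)
    t2 = np.clip(t2, 0.0, 1.0)
    inside = (disc > 0.0) & (a[None, :] > 0.0)
    seg_len = np.sqrt(a)
    return np.where(inside, (t2 - t1) * seg_len[None, :], 0.0)
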
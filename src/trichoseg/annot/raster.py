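"""Spline geometry: resolution transforms, centripetal Catmull-Rom sampling,
and rasterization to sparse masks.

Splines are the stored representation; masks are drawn on demand at whatever
resolution the pipeline works at.  Rescaling therefore acts on control points
(cheap, shape-preserving) and never on rendered masks, which for thin
structures would break long strokes apart or merge neighbouring ones.
"""

from __future__ import annotations

from typing import Sequence, Tuple

import numpy as np

from .types import SparseMask, SplineAnnotation

__all__ = ["transform_spline", "sample_spline", "rasterize", "DEFAULT_STROKE_WIDTH"]

#: Default brush diameter in pixels at the 768x768 working resolution.
DEFAULT_STROKE_WIDTH = 2.0


def transform_spline(
    spline: SplineAnnotation, target_size: Tuple[int, int]
) -> SplineAnnotation:
    """Rescale a spline's control points to a new reference resolution.

    Each point ``(r, c)`` maps to ``(r * H'/H, c * W'/W)``.  The point count
    is unchanged and the curve shape is preserved at any target resolution.
    """
    th, tw = int(target_size[0]), int(target_size[1])
    if th <= 0 or tw <= 0:
        raise ValueError(f"target_size must be positive, got {target_size}")
    h, w = spline.reference_size
    scale = np.array([th / h, tw / w])
    return SplineAnnotation(
        control_points=spline.control_points * scale,
        reference_size=(th, tw),
        annotation_id=spline.annotation_id,
    )


def _catmull_rom_chain(points: np.ndarray, samples_per_px: float = 2.0) -> np.ndarray:
    """Sample a centripetal Catmull-Rom curve through ``points``.

    The curve passes through every control point (annotators place points on
    the trichome) and the centripetal parameterization avoids cusps and
    overshoot.  End segments use duplicated endpoints as phantom points, so a
    2-point spline degenerates to a straight segment.

    Returns at least ``samples_per_px`` samples per pixel of chord length.
    """
    pts = np.asarray(points, dtype=float)
    n = pts.shape[0]
    if n == 2 and np.allclose(pts[0], pts[1]):
        return pts[:1].copy()
    # phantom endpoints: reflectionless duplication keeps the curve inside
    # the annotated extent
    ext = np.vstack([pts[0], pts, pts[-1]])

    # centripetal knots: t_{i+1} = t_i + |P_{i+1} - P_i|^(1/2)
    d = np.linalg.norm(np.diff(ext, axis=0), axis=1)
    alpha = 0.5
    dt = np.where(d > 0, d**alpha, 1e-9)
    t = np.concatenate([[0.0], np.cumsum(dt)])

    out = []
    for i in range(1, n):
        p0, p1, p2, p3 = ext[i - 1], ext[i], ext[i + 1], ext[i + 2]
        t0, t1, t2, t3 = t[i - 1], t[i], t[i + 1], t[i + 2]
        chord = np.linalg.norm(p2 - p1)
        n_s = max(int(np.ceil(chord * samples_per_px)) + 1, 2)
        ts = np.linspace(t1, t2, n_s, endpoint=(i == n - 1))
        if t2 - t1 <= 0:
            out.append(np.repeat(p1[None, :], len(ts), axis=0))
            continue
        # Barry-Goldman pyramidal evaluation, vectorized over ts
        def lerp(pa, pb, ta, tb):
            denom = tb - ta
            if denom <= 0:
                return np.repeat(np.asarray(pa).reshape(1, -1), len(ts), axis=0)
            wgt = ((ts - ta) / denom)[:, None]
            return (1 - wgt) * pa + wgt * pb

        a1 = lerp(p0, p1, t0, t1)
        a2 = lerp(p1, p2, t1, t2)
        a3 = lerp(p2, p3, t2, t3)
        b1 = lerp(a1, a2, t0, t2)
        b2 = lerp(a2, a3, t1, t3)
        out.append(lerp(b1, b2, t1, t2))
    return np.vstack(out)


def sample_spline(spline: SplineAnnotation, samples_per_px: float = 2.0) -> np.ndarray:
    """Densely sample the interpolated curve in continuous (row, col) coords."""
    return _catmull_rom_chain(spline.control_points, samples_per_px)


def _stamp(samples: np.ndarray, size: Tuple[int, int], stroke_width: float) -> np.ndarray:
    """Mark every pixel whose center lies within ``stroke_width / 2`` of a
    curve sample.  Returns an (n, 2) int array of in-bounds pixel indices."""
    h, w = size
    radius = stroke_width / 2.0
    reach = int(np.floor(radius))  # how far beyond the rounded center a disc extends
    # disc brush offsets relative to floor(sample)
    offs = np.arange(-reach, reach + 2)
    orr, occ = np.meshgrid(offs, offs, indexing="ij")
    offsets = np.stack([orr.ravel(), occ.ravel()], axis=1)  # (k, 2)

    base = np.floor(samples).astype(np.int64)  # (n, 2)
    cand = base[:, None, :] + offsets[None, :, :]  # (n, k, 2)
    # distance from candidate pixel center to the continuous sample
    dist = np.linalg.norm(cand - samples[:, None, :], axis=2)
    keep = dist <= radius
    px = cand[keep]
    inb = (px[:, 0] >= 0) & (px[:, 0] < h) & (px[:, 1] >= 0) & (px[:, 1] < w)
    return px[inb]


def rasterize(
    splines: Sequence[SplineAnnotation],
    size: Tuple[int, int],
    stroke_width: float = DEFAULT_STROKE_WIDTH,
    samples_per_px: float = 2.0,
) -> SparseMask:
    """Draw splines into a sparse binary mask.

    The mask is the union over splines of the interpolated curve (sampled at
    ``samples_per_px`` per pixel of arc length) drawn with a disc brush of
    diameter ``stroke_width`` and clipped to ``size``.  Deterministic.

    An empty spline list yields an empty mask.
    """
    h, w = int(size[0]), int(size[1])
    if stroke_width < 1:
        raise ValueError(f"stroke_width must be >= 1, got {stroke_width}")
    pieces = []
    for s in splines:
        samples = sample_spline(s, samples_per_px)
        px = _stamp(samples, (h, w), stroke_width)
        if px.size:
            pieces.append(px)
    if not pieces:
        return SparseMask.empty((h, w))
    return SparseMask((h, w), np.vstack(pieces))
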
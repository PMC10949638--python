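"""Paired image/annotation augmentation: resize (RS), random crop (RC),
random flip (RF).

The cardinal rule is *geometry before raster*: every step transforms the
spline control points, and the mask is drawn exactly once, at the final
resolution, after all geometry.  Interpolating a rendered mask of thin
structures breaks long strokes apart or merges neighbours; transforming the
splines and re-drawing avoids that entirely.

Recipes use the compact textual names ``RS<size>``, ``RC<size>``, ``RF``
joined with ``+`` (e.g. ``"RS768+RF"``, ``"RC1536+RS1024+RF"``); steps apply
in token order.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from skimage.transform import resize as _sk_resize

from .annot import AnnotatedImage, SparseMask, SplineAnnotation, rasterize
from .annot.raster import DEFAULT_STROKE_WIDTH

__all__ = ["RS", "RC", "RF", "AugmentRecipe", "parse_recipe", "apply"]


@dataclass(frozen=True)
class RS:
    """Resize image (bilinear) and splines to ``size x size``."""

    size: int

    def __str__(self) -> str:
        return f"RS{self.size}"


@dataclass(frozen=True)
class RC:
    """Random crop of ``size x size`` at a uniform valid top-left corner."""

    size: int

    def __str__(self) -> str:
        return f"RC{self.size}"


@dataclass(frozen=True)
class RF:
    """Combined random flip: independent Bernoulli(1/2) vertical and
    horizontal flips, applied identically to image and splines."""

    def __str__(self) -> str:
        return "RF"


Step = Union[RS, RC, RF]

_TOKEN = re.compile(r"^(RS|RC)(\d+)$|^(RF)$")


@dataclass(frozen=True)
class AugmentRecipe:
    """Ordered augmentation steps; serializes back to the compact name."""

    steps: Tuple[Step, ...] = ()

    def __str__(self) -> str:
        return "+".join(str(s) for s in self.steps) if self.steps else ""

    @property
    def output_size(self) -> Optional[int]:
        """Final square size implied by the last RS/RC step, if any."""
        for step in reversed(self.steps):
            if isinstance(step, (RS, RC)):
                return step.size
        return None


def parse_recipe(text: str) -> AugmentRecipe:
    """Parse a compact recipe string such as ``"RC1536+RS1024+RF"``.

    Raises ``ValueError`` naming the first unknown token.
    """
    text = text.strip()
    if not text:
        return AugmentRecipe(())
    steps: List[Step] = []
    for token in text.split("+"):
        m = _TOKEN.match(token.strip())
        if not m:
            raise ValueError(f"unknown augmentation token {token!r} in {text!r}")
        if m.group(3) == "RF":
            steps.append(RF())
        elif m.group(1) == "RS":
            steps.append(RS(int(m.group(2))))
        else:
            steps.append(RC(int(m.group(2))))
    return AugmentRecipe(tuple(steps))


def _resize_image(img: np.ndarray, size: Tuple[int, int]) -> np.ndarray:
    out = _sk_resize(
        img.astype(np.float64), (*size, img.shape[2]), order=1,
        mode="edge", anti_aliasing=False, preserve_range=True,
    )
    return np.clip(out, 0, 255).astype(np.uint8)


def apply(
    recipe: AugmentRecipe,
    record: AnnotatedImage,
    stroke_width: float = DEFAULT_STROKE_WIDTH,
    seed: int = 0,
) -> Tuple[np.ndarray, SparseMask]:
    """Run a recipe on one record and draw the mask at the final geometry.

    Returns ``(image, mask)``.  Deterministic given ``(recipe, record, seed)``.
    Spline control points are carried in continuous coordinates throughout;
    crops translate them (points falling outside are clipped away at raster
    time, keeping partial trichomes), flips mirror them about the pixel-center
    frame, resizes scale them.  The mask is rasterized once at the end.
    """
    rng = np.random.default_rng(seed)
    img = record.pixels
    # raw (n,2) float arrays; validation deferred to raster time since crops
    # may push points far outside the frame
    curves = [s.control_points.copy() for s in record.splines]
    h, w = record.size

    for step in recipe.steps:
        if isinstance(step, RS):
            th = tw = step.size
            scale = np.array([th / h, tw / w])
            curves = [c * scale for c in curves]
            img = _resize_image(img, (th, tw))
            h, w = th, tw
        elif isinstance(step, RC):
            if step.size > h or step.size > w:
                raise ValueError(
                    f"crop size {step.size} exceeds current image size {(h, w)}"
                )
            top = int(rng.integers(0, h - step.size + 1))
            left = int(rng.integers(0, w - step.size + 1))
            img = img[top : top + step.size, left : left + step.size]
            curves = [c - np.array([top, left]) for c in curves]
            h = w = step.size
        elif isinstance(step, RF):
            flip_v = bool(rng.integers(0, 2))
            flip_h = bool(rng.integers(0, 2))
            if flip_v:
                img = img[::-1]
                curves = [np.stack([(h - 1) - c[:, 0], c[:, 1]], axis=1) for c in curves]
            if flip_h:
                img = img[:, ::-1]
                curves = [np.stack([c[:, 0], (w - 1) - c[:, 1]], axis=1) for c in curves]
        else:  # pragma: no cover - recipe construction forbids this
            raise TypeError(f"unknown step {step!r}")

    mask = _rasterize_clipped(curves, (h, w), stroke_width)
    return np.ascontiguousarray(img), mask


def _rasterize_clipped(
    curves: Sequence[np.ndarray], size: Tuple[int, int], stroke_width: float
) -> SparseMask:
    """Rasterize raw control-point arrays, dropping hairs entirely outside.

    Bypasses the 5%-outside invariant of :class:`SplineAnnotation`, which is
    an annotation-time constraint: after a crop, kept splines may legally
    extend well past the window and are clipped pixelwise by the rasterizer.
    """
    h, w = size
    keep = []
    for c in curves:
        if c[:, 0].max() < 0 or c[:, 0].min() >= h or c[:, 1].max() < 0 or c[:, 1].min() >= w:
            continue  # wholly outside the window
        s = SplineAnnotation.__new__(SplineAnnotation)
        object.__setattr__(s, "control_points", np.asarray(c, dtype=float))
        object.__setattr__(s, "reference_size", (h, w))
        object.__setattr__(s, "annotation_id", "")
        keep.append(s)
    return rasterize(keep, (h, w), stroke_width)
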
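"""Procedural leaf-like images with exact ground-truth trichome splines.

Images emulate the statistical structure of the real microscopy data: a
textured green-ish background with a radial vignette, a bright vertical
midvein band, and thin bright curvilinear hairs.  Hairs brighter than
background mirrors white trichomes on a green leaf.  Every image carries the
generating splines as ground truth, so segmentation and scoring are testable
end to end without any external download.

Determinism: each image draws from its own seed stream, derived from the
panel seed and the image's identity by splitmix-style hashing, so a record is
reproducible regardless of generation order.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .annot import AnnotatedImage, GHSLabel, SplineAnnotation, rasterize
from .annot.types import EDGE_TOLERANCE

__all__ = [
    "SyntheticSpec",
    "SyntheticGenotype",
    "generate_image",
    "generate_panel",
    "derive_seed",
    "default_panel",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the generator; all distributions are (mean, spread).

    ``hair_count`` uses ``(mean, dispersion)``: dispersion 0 is deterministic,
    1 is Poisson, >1 a gamma-Poisson mixture with variance ``mean*dispersion``.
    Length/width use truncated normals ``(mean, sd)`` with positive support.
    ``curvature`` caps the perpendicular bow of a hair as a fraction of its
    length.
    """

    image_size: Tuple[int, int] = (256, 256)
    hair_count: Tuple[float, float] = (40.0, 1.0)
    hair_length_px: Tuple[float, float] = (50.0, 15.0)
    hair_width_px: Tuple[float, float] = (2.0, 0.0)
    curvature: float = 0.15
    midvein_half_width: float = 14.0
    midvein_center_col: Optional[float] = None  # None -> image center
    midvein_brightness: float = 70.0
    background_rgb: Tuple[float, float, float] = (70.0, 110.0, 60.0)
    texture_noise_sd: float = 8.0
    vignette_strength: float = 0.25
    hair_brightness: Tuple[float, float, float] = (120.0, 120.0, 120.0)

    def __post_init__(self) -> None:
        h, w = self.image_size
        if h <= 0 or w <= 0:
            raise ValueError("image_size must be positive")
        if self.hair_count[0] < 0:
            raise ValueError("hair_count mean must be >= 0")
        if self.hair_length_px[0] <= 0 or self.hair_width_px[0] <= 0:
            raise ValueError("hair length/width means must be positive")
        if not (0 <= self.curvature < 1):
            raise ValueError("curvature must be in [0, 1)")


@dataclass(frozen=True)
class SyntheticGenotype:
    """A named parameter set standing in for a plant genotype."""

    name: str
    spec: SyntheticSpec
    nominal_class: GHSLabel = field(default_factory=lambda: GHSLabel("3"))


def derive_seed(*parts) -> int:
    """Stable 63-bit seed from arbitrary identity parts (splitmix-style)."""
    digest = hashlib.blake2b(
        "\x1f".join(str(p) for p in parts).encode(), digest_size=8
    ).digest()
    return int.from_bytes(digest, "little") >> 1


def _sample_count(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    if mean <= 0:
        return 0
    if dispersion <= 0:
        return int(round(mean))
    if dispersion <= 1:
        return int(rng.poisson(mean))
    lam = rng.gamma(shape=mean / (dispersion - 1), scale=dispersion - 1)
    return int(rng.poisson(lam))


def _sample_positive(rng: np.random.Generator, mean: float, sd: float, lo: float) -> float:
    if sd <= 0:
        return max(mean, lo)
    return max(float(rng.normal(mean, sd)), lo)


def _background(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.image_size
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = spec.background_rgb
    if spec.texture_noise_sd > 0:
        img += rng.normal(0.0, spec.texture_noise_sd, size=(h, w, 3))
    if spec.vignette_strength > 0:
        rr = (np.arange(h) - (h - 1) / 2) / (h / 2)
        cc = (np.arange(w) - (w - 1) / 2) / (w / 2)
        radius2 = rr[:, None] ** 2 + cc[None, :] ** 2
        img *= (1.0 - spec.vignette_strength * np.clip(radius2, 0, 1))[..., None]
    # midvein: bright vertical band with soft gaussian shoulders
    center = spec.midvein_center_col if spec.midvein_center_col is not None else (w - 1) / 2
    if spec.midvein_half_width > 0 and spec.midvein_brightness != 0:
        dist = np.abs(np.arange(w) - center)
        profile = np.where(
            dist <= spec.midvein_half_width,
            1.0,
            np.exp(-0.5 * ((dist - spec.midvein_half_width) / (spec.midvein_half_width / 2 + 1e-9)) ** 2),
        )
        img += (spec.midvein_brightness * profile)[None, :, None]
    return img


def _midvein_interval(spec: SyntheticSpec) -> Tuple[float, float]:
    w = spec.image_size[1]
    center = spec.midvein_center_col if spec.midvein_center_col is not None else (w - 1) / 2
    return center - spec.midvein_half_width, center + spec.midvein_half_width


def _sample_hair(
    spec: SyntheticSpec, rng: np.random.Generator
) -> Optional[np.ndarray]:
    """Sample control points for one hair, or None if rejected.

    A hair is a smooth bow: endpoints on a chord of sampled length and
    orientation, two interior control points displaced perpendicular to the
    chord by at most ``curvature * length``.  Hairs lying wholly within the
    midvein band are rejected (mirrors the annotation convention of skipping
    trichomes fully on the midvein).
    """
    h, w = spec.image_size
    length = _sample_positive(rng, *spec.hair_length_px, lo=3.0)
    start = rng.uniform((0.0, 0.0), (h, w))
    theta = rng.uniform(0.0, 2 * np.pi)
    direction = np.array([np.sin(theta), np.cos(theta)])
    normal = np.array([-direction[1], direction[0]])
    bow = rng.uniform(-1.0, 1.0) * spec.curvature * length
    fractions = np.array([0.0, 1 / 3, 2 / 3, 1.0])
    # quadratic bow profile, zero at the endpoints
    offsets = bow * 4 * fractions * (1 - fractions)
    pts = start[None, :] + np.outer(fractions * length, direction) + np.outer(offsets, normal)

    # keep control points inside the tolerated frame
    lo = np.array([-EDGE_TOLERANCE * h + 1e-6, -EDGE_TOLERANCE * w + 1e-6])
    hi = np.array([(1 + EDGE_TOLERANCE) * h - 1e-6, (1 + EDGE_TOLERANCE) * w - 1e-6])
    pts = np.clip(pts, lo, hi)

    # reject hairs that never touch the image
    if pts[:, 0].max() < 0 or pts[:, 0].min() >= h or pts[:, 1].max() < 0 or pts[:, 1].min() >= w:
        return None
    band_lo, band_hi = _midvein_interval(spec)
    if pts[:, 1].min() >= band_lo and pts[:, 1].max() <= band_hi:
        return None  # wholly inside the midvein band
    return pts


def generate_image(
    spec: SyntheticSpec, seed: int, image_id: str = "", meta: Optional[dict] = None
) -> AnnotatedImage:
    """Render one synthetic leaf image with its ground-truth splines.

    Bit-identical output for identical ``(spec, seed)``.
    """
    rng = np.random.default_rng(seed)
    h, w = spec.image_size
    img = _background(spec, rng)

    n_hairs = _sample_count(rng, *spec.hair_count)
    splines: List[SplineAnnotation] = []
    for i in range(n_hairs):
        pts = None
        for _ in range(20):  # rejection sampling with a bounded retry budget
            pts = _sample_hair(spec, rng)
            if pts is not None:
                break
        if pts is None:
            continue
        width = _sample_positive(rng, *spec.hair_width_px, lo=1.0)
        splines.append(
            SplineAnnotation(
                control_points=pts,
                reference_size=(h, w),
                annotation_id=f"{image_id or 'hair'}:{i}",
            )
        )
        mask = rasterize([splines[-1]], (h, w), stroke_width=width)
        fg = mask.foreground
        if fg.size:
            img[fg[:, 0], fg[:, 1]] += spec.hair_brightness

    # randomized draw order only matters for overlapping brightness; splines
    # are shuffled so downstream order never encodes generation order
    order = rng.permutation(len(splines))
    splines = [splines[i] for i in order]

    pixels = np.clip(img, 0, 255).astype(np.uint8)
    return AnnotatedImage(
        pixels=pixels, splines=splines, meta=dict(meta or {}), image_id=image_id
    )


def generate_panel(
    genotypes: Sequence[SyntheticGenotype],
    images_per_genotype: int,
    seed: int,
) -> List[AnnotatedImage]:
    """Generate a panel dataset: one record per (genotype, replicate).

    Metadata carries the genotype name and its nominal hairiness class; the
    per-image seed depends only on the panel seed, genotype name and replicate
    index, so two panels with the same seed are identical.
    """
    if images_per_genotype < 1:
        raise ValueError("images_per_genotype must be >= 1")
    names = [g.name for g in genotypes]
    if len(set(names)) != len(names):
        raise ValueError("genotype names within a panel must be distinct")
    records: List[AnnotatedImage] = []
    for j in range(images_per_genotype):  # round-robin over genotypes
        for geno in genotypes:
            img_seed = derive_seed(seed, geno.name, j)
            image_id = f"{geno.name}_{j:03d}.png"
            rec = generate_image(
                geno.spec,
                img_seed,
                image_id=image_id,
                meta={
                    "genotype": geno.name,
                    "ghs": geno.nominal_class,
                    "leaf": "L3",
                    "environment": "GH",
                    "year": "Y1",
                    "position": "First",
                    "replicate": j,
                },
            )
            records.append(rec)
    return records


def default_panel(
    n_genotypes: int = 5,
    base_spec: Optional[SyntheticSpec] = None,
    count_means: Optional[Sequence[float]] = None,
) -> List[SyntheticGenotype]:
    """A convenience panel with strictly increasing hair density.

    Genotype names are stable and density-ordered; nominal classes walk up
    the ordinal scale so ranking checks have a ground truth to compare with.
    """
    base = base_spec or SyntheticSpec()
    if count_means is None:
        count_means = np.linspace(0, 80, n_genotypes)
    classes = ["1", "2", "3", "3/4", "4", "4/4+", "4+", "5", "5+"]
    panel = []
    for i, mean in enumerate(count_means):
        panel.append(
            SyntheticGenotype(
                name=f"geno{i:02d}",
                spec=replace(base, hair_count=(float(mean), base.hair_count[1])),
                nominal_class=GHSLabel(classes[min(i, len(classes) - 1)]),
            )
        )
    return panel
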
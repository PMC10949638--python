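"""Core data types: spline annotations, sparse masks, ordinal hairiness labels,
and annotated image records.

Coordinate convention (used everywhere in this package): 0-based ``(row, col)``
with pixel centers at integer coordinates.  Continuous coordinates are rounded
to the nearest pixel with ``floor(x + 0.5)`` when rasterizing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Tuple

import numpy as np

__all__ = [
    "SplineAnnotation",
    "SparseMask",
    "GHSLabel",
    "GHS_SCALE",
    "AnnotatedImage",
    "EDGE_TOLERANCE",
    "sparse_encode",
    "sparse_decode",
]

#: Fraction of the reference size by which control points may lie outside the
#: image bounds (trichomes crossing the image border are annotated past it).
EDGE_TOLERANCE = 0.05

#: The ordinal hairiness scale, from glabrous to pilose.  The scale is
#: non-linear: no arithmetic on labels, only ordering.
GHS_SCALE: Tuple[str, ...] = ("1", "2", "3", "3/4", "4", "4/4+", "4+", "5", "5+")


@dataclass(frozen=True, order=True)
class GHSLabel:
    """Ordinal hairiness class label on the scale ``1 .. 5+``.

    Instances compare by position on the scale, not lexicographically.
    """

    rank: int = field(init=False, compare=True)
    value: str = field(compare=False)

    def __init__(self, value: str | "GHSLabel") -> None:
        if isinstance(value, GHSLabel):
            value = value.value
        value = str(value)
        if value not in GHS_SCALE:
            raise ValueError(
                f"unknown hairiness label {value!r}; valid labels: {list(GHS_SCALE)}"
            )
        object.__setattr__(self, "value", value)
        object.__setattr__(self, "rank", GHS_SCALE.index(value))

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.value

    def __repr__(self) -> str:
        return f"GHSLabel({self.value!r})"


@dataclass(frozen=True)
class SplineAnnotation:
    """One trichome traced as an ordered sequence of control points.

    Parameters
    ----------
    control_points
        ``(n, 2)`` array of continuous ``(row, col)`` coordinates, ``n >= 2``.
    reference_size
        ``(height, width)`` in pixels the coordinates refer to.
    annotation_id
        Opaque identifier carried through transformations.
    """

    control_points: np.ndarray
    reference_size: Tuple[int, int]
    annotation_id: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.control_points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("control_points must be an (n, 2) array of (row, col)")
        if pts.shape[0] < 2:
            raise ValueError(
                f"spline {self.annotation_id!r} has {pts.shape[0]} control point(s); "
                "at least 2 are required"
            )
        h, w = self.reference_size
        if h <= 0 or w <= 0:
            raise ValueError(f"reference_size must be positive, got {(h, w)}")
        lo = np.array([-EDGE_TOLERANCE * h, -EDGE_TOLERANCE * w])
        hi = np.array([(1 + EDGE_TOLERANCE) * h, (1 + EDGE_TOLERANCE) * w])
        if np.any(pts < lo) or np.any(pts >= hi):
            raise ValueError(
                f"spline {self.annotation_id!r} has control points more than "
                f"{EDGE_TOLERANCE:.0%} outside the {h}x{w} reference frame"
            )
        object.__setattr__(self, "control_points", pts)
        object.__setattr__(self, "reference_size", (int(h), int(w)))

    @property
    def n_points(self) -> int:
        return int(self.control_points.shape[0])


class SparseMask:
    """Binary segmentation mask stored as foreground ``(row, col)`` indices.

    Only the indices of non-zero pixels are kept, so storage is proportional
    to the foreground count rather than the image area.
    """

    __slots__ = ("shape", "_rows", "_cols")

    def __init__(
        self,
        shape: Tuple[int, int],
        foreground: Iterable[Tuple[int, int]] | np.ndarray,
    ) -> None:
        h, w = int(shape[0]), int(shape[1])
        if h <= 0 or w <= 0:
            raise ValueError(f"mask shape must be positive, got {(h, w)}")
        self.shape = (h, w)
        idx = np.asarray(list(foreground) if not isinstance(foreground, np.ndarray) else foreground)
        if idx.size == 0:
            idx = np.empty((0, 2), dtype=np.int64)
        idx = idx.reshape(-1, 2).astype(np.int64)
        if idx.size and (
            idx[:, 0].min() < 0 or idx[:, 1].min() < 0
            or idx[:, 0].max() >= h or idx[:, 1].max() >= w
        ):
            raise ValueError("foreground indices out of bounds")
        # canonical order + dedup makes equality and round trips exact
        flat = np.unique(idx[:, 0] * w + idx[:, 1])
        self._rows = (flat // w).astype(np.int64)
        self._cols = (flat % w).astype(np.int64)

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_dense(cls, dense: np.ndarray) -> "SparseMask":
        dense = np.asarray(dense)
        if dense.ndim != 2:
            raise ValueError("dense mask must be 2-D")
        uniq = np.unique(dense)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("dense mask must be 0/1 valued")
        rows, cols = np.nonzero(dense)
        out = cls.__new__(cls)
        out.shape = dense.shape
        out._rows = rows.astype(np.int64)
        out._cols = cols.astype(np.int64)
        return out

    @classmethod
    def empty(cls, shape: Tuple[int, int]) -> "SparseMask":
        return cls(shape, np.empty((0, 2), dtype=np.int64))

    # -- views ------------------------------------------------------------
    def to_dense(self) -> np.ndarray:
        dense = np.zeros(self.shape, dtype=np.uint8)
        dense[self._rows, self._cols] = 1
        return dense

    @property
    def foreground(self) -> np.ndarray:
        """``(n, 2)`` array of (row, col) foreground indices, row-major order."""
        return np.stack([self._rows, self._cols], axis=1)

    @property
    def n_foreground(self) -> int:
        return int(self._rows.size)

    @property
    def n_total(self) -> int:
        return self.shape[0] * self.shape[1]

    def __len__(self) -> int:
        return self.n_foreground

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SparseMask):
            return NotImplemented
        return (
            self.shape == other.shape
            and np.array_equal(self._rows, other._rows)
            and np.array_equal(self._cols, other._cols)
        )

    def __repr__(self) -> str:
        return f"SparseMask(shape={self.shape}, n_foreground={self.n_foreground})"

    # -- set algebra ------------------------------------------------------
    def _flat(self) -> np.ndarray:
        return self._rows * self.shape[1] + self._cols

    def intersection_size(self, other: "SparseMask") -> int:
        self._check_shape(other)
        return int(np.intersect1d(self._flat(), other._flat(), assume_unique=True).size)

    def union_size(self, other: "SparseMask") -> int:
        self._check_shape(other)
        return int(np.union1d(self._flat(), other._flat()).size)

    def _check_shape(self, other: "SparseMask") -> None:
        if self.shape != other.shape:
            raise ValueError(f"mask shapes differ: {self.shape} vs {other.shape}")


@dataclass
class AnnotatedImage:
    """An image, its trichome splines, and phenotyping metadata.

    ``meta`` keys used by the pipeline: ``genotype``, ``ghs`` (a
    :class:`GHSLabel` or absent), ``leaf`` (L3/L4), ``environment`` (GH/FD),
    ``year``, ``position`` (First/Middle/Last/Blade).  Absent keys are fine.
    """

    pixels: np.ndarray
    splines: list[SplineAnnotation] = field(default_factory=list)
    meta: dict = field(default_factory=dict)
    image_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError("pixels must be an HxWx3 RGB raster")
        if px.dtype != np.uint8:
            raise ValueError("pixels must be 8-bit (uint8)")
        self.pixels = px
        size = self.size
        for s in self.splines:
            if s.reference_size != size:
                raise ValueError(
                    f"spline {s.annotation_id!r} reference_size {s.reference_size} "
                    f"does not match image size {size}"
                )

    @property
    def size(self) -> Tuple[int, int]:
        return (int(self.pixels.shape[0]), int(self.pixels.shape[1]))

    @property
    def ghs(self) -> Optional[GHSLabel]:
        g = self.meta.get("ghs")
        if g is None:
            return None
        return g if isinstance(g, GHSLabel) else GHSLabel(g)


def sparse_encode(dense: np.ndarray) -> SparseMask:
    """Encode a 0/1 raster as foreground indices; exact inverse of decode."""
    return SparseMask.from_dense(dense)


def sparse_decode(mask: SparseMask) -> np.ndarray:
    """Expand a sparse mask back to a dense 0/1 ``uint8`` raster."""
    return mask.to_dense()
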
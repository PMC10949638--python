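"""Reading and writing annotation datasets.

On-disk layout: a directory of images (PNG/TIFF/JPEG) plus one JSON file
describing splines and metadata::

    {"images": [{"file": "img.png", "height": 1920, "width": 2560,
                 "meta": {"genotype": "ebony", "ghs": "3/4", ...},
                 "splines": [{"id": "t0", "points": [[r, c], ...]}, ...]},
                ...]}

Sparse masks travel as CSV with a ``# shape=H,W`` header line and
``row,col`` columns; dense masks as single-channel 0/255 PNG.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Sequence

import imageio.v3 as iio
import numpy as np

from .types import AnnotatedImage, GHSLabel, SparseMask, SplineAnnotation

__all__ = [
    "read_annotations",
    "write_annotations",
    "read_sparse_mask",
    "write_sparse_mask",
    "read_dense_mask",
    "write_dense_mask",
    "ANNOTATION_FILENAME",
]

ANNOTATION_FILENAME = "annotations.json"

_META_KEYS = ("genotype", "ghs", "leaf", "environment", "year", "position")


class AnnotationParseError(ValueError):
    """Raised when the annotation JSON is malformed; names the bad record."""


def _parse_meta(raw: dict) -> dict:
    meta = {}
    for key in _META_KEYS:
        if key in raw and raw[key] is not None:
            meta[key] = raw[key]
    if "ghs" in meta:
        meta["ghs"] = GHSLabel(meta["ghs"])
    # pass through any extra keys untouched
    for key, val in raw.items():
        if key not in meta and val is not None:
            meta[key] = val
    return meta


def read_annotations(path: str | Path) -> List[AnnotatedImage]:
    """Load a directory of images plus their JSON annotation file.

    Every image listed in the JSON becomes one record; entries without
    splines get an empty spline list.  Raises :class:`AnnotationParseError`
    naming the offending record on malformed input, missing image files, or
    a ``height``/``width`` that disagrees with the actual raster.
    """
    path = Path(path)
    ann_file = path / ANNOTATION_FILENAME if path.is_dir() else path
    root = ann_file.parent
    try:
        payload = json.loads(ann_file.read_text())
    except json.JSONDecodeError as exc:
        raise AnnotationParseError(f"malformed JSON in {ann_file}: {exc}") from exc
    if not isinstance(payload, dict) or "images" not in payload:
        raise AnnotationParseError(f"{ann_file}: expected top-level 'images' list")

    records: List[AnnotatedImage] = []
    for i, entry in enumerate(payload["images"]):
        name = entry.get("file", f"<record {i}>")
        img_path = root / name
        if not img_path.exists():
            raise AnnotationParseError(
                f"record {i}: image file {name!r} listed in {ann_file.name} is missing"
            )
        pixels = iio.imread(img_path)
        if pixels.ndim == 2:
            pixels = np.stack([pixels] * 3, axis=-1)
        pixels = np.ascontiguousarray(pixels[..., :3]).astype(np.uint8)
        size = (pixels.shape[0], pixels.shape[1])
        declared = (int(entry.get("height", size[0])), int(entry.get("width", size[1])))
        if declared != size:
            raise AnnotationParseError(
                f"record {i} ({name}): declared size {declared} does not match "
                f"image size {size}"
            )
        splines = []
        for j, sp in enumerate(entry.get("splines", [])):
            pts = sp.get("points", [])
            try:
                splines.append(
                    SplineAnnotation(
                        control_points=np.asarray(pts, dtype=float),
                        reference_size=size,
                        annotation_id=str(sp.get("id", f"{name}:{j}")),
                    )
                )
            except ValueError as exc:
                raise AnnotationParseError(
                    f"record {i} ({name}), spline {j}: {exc}"
                ) from exc
        records.append(
            AnnotatedImage(
                pixels=pixels,
                splines=splines,
                meta=_parse_meta(entry.get("meta", {})),
                image_id=name,
            )
        )
    return records


def write_annotations(
    records: Sequence[AnnotatedImage], path: str | Path, write_images: bool = True
) -> Path:
    """Write records as PNG images plus the JSON annotation file."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, rec in enumerate(records):
        name = rec.image_id or f"image_{i:04d}.png"
        if not name.lower().endswith((".png", ".tif", ".tiff", ".jpg", ".jpeg")):
            name += ".png"
        if write_images:
            iio.imwrite(path / name, rec.pixels)
        meta = dict(rec.meta)
        if isinstance(meta.get("ghs"), GHSLabel):
            meta["ghs"] = meta["ghs"].value
        entries.append(
            {
                "file": name,
                "height": rec.size[0],
                "width": rec.size[1],
                "meta": meta,
                "splines": [
                    {"id": s.annotation_id, "points": s.control_points.tolist()}
                    for s in rec.splines
                ],
            }
        )
    out = path / ANNOTATION_FILENAME
    out.write_text(json.dumps({"images": entries}, indent=1, sort_keys=True))
    return out


# ---------------------------------------------------------------------------
# sparse mask CSV

def write_sparse_mask(mask: SparseMask, path: str | Path) -> None:
    path = Path(path)
    h, w = mask.shape
    fg = mask.foreground
    lines = [f"# shape={h},{w}", "row,col"]
    lines.extend(f"{r},{c}" for r, c in fg)
    path.write_text("\n".join(lines) + "\n")


def read_sparse_mask(path: str | Path) -> SparseMask:
    path = Path(path)
    lines = path.read_text().strip().splitlines()
    if not lines or not lines[0].startswith("# shape="):
        raise ValueError(f"{path}: missing '# shape=H,W' header")
    h, w = (int(v) for v in lines[0].split("=", 1)[1].split(","))
    body = [ln for ln in lines[1:] if ln and not ln.startswith(("row", "#"))]
    if not body:
        return SparseMask.empty((h, w))
    idx = np.array([[int(v) for v in ln.split(",")] for ln in body], dtype=np.int64)
    return SparseMask((h, w), idx)


# ---------------------------------------------------------------------------
# dense mask PNG (0/255)

def write_dense_mask(mask: SparseMask, path: str | Path) -> None:
    iio.imwrite(Path(path), mask.to_dense() * np.uint8(255))


def read_dense_mask(path: str | Path) -> SparseMask:
    raw = iio.imread(Path(path))
    if raw.ndim == 3:
        raw = raw[..., 0]
    return SparseMask.from_dense((raw > 127).astype(np.uint8))
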
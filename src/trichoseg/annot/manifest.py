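"""Dataset bookkeeping: published per-class image counts and design manifests.

The reference annotated trichome dataset ships 1250 images whose distribution
over hairiness classes is fixed; those counts are inputs to sanity checks and
are recorded here so downstream bookkeeping never re-derives them from files.
"""

from __future__ import annotations

from typing import Dict, List, Sequence

from .types import GHS_SCALE

__all__ = [
    "REFERENCE_CLASS_IMAGE_COUNTS",
    "REFERENCE_CLASS_GENOTYPE_COUNTS",
    "REFERENCE_SPLIT_FRACTIONS",
    "total_reference_images",
    "design_manifest",
]

#: Published number of annotated images per hairiness class (sums to 1250).
REFERENCE_CLASS_IMAGE_COUNTS: Dict[str, int] = {
    "1": 152,
    "2": 40,
    "3": 160,
    "3/4": 180,
    "4": 238,
    "4/4+": 200,
    "4+": 240,
    "5": 40,
    "5+": 0,  # too hairy to annotate confidently; excluded by design
}

#: Published number of genotypes per hairiness class (sums to 25).
REFERENCE_CLASS_GENOTYPE_COUNTS: Dict[str, int] = {
    "1": 3,
    "2": 1,
    "3": 3,
    "3/4": 4,
    "4": 5,
    "4/4+": 4,
    "4+": 4,
    "5": 1,
    "5+": 0,
}

#: Published train/validation/test fractions.
REFERENCE_SPLIT_FRACTIONS = (0.65, 0.15, 0.20)


def total_reference_images() -> int:
    """Total annotated images, computed as the sum of per-class counts."""
    assert set(REFERENCE_CLASS_IMAGE_COUNTS) == set(GHS_SCALE)
    return sum(REFERENCE_CLASS_IMAGE_COUNTS.values())


def design_manifest(
    genotypes: Sequence[str],
    plants_per_genotype: int,
    collections: Sequence[str],
    images_per_leaf: int = 1,
) -> List[dict]:
    """Enumerate the image records implied by a sampling design.

    One leaf is harvested per plant and imaged ``images_per_leaf`` times in
    each collection event, so the manifest has
    ``len(genotypes) * plants_per_genotype * len(collections) * images_per_leaf``
    entries.  Used to verify dataset completeness against a stated design
    (e.g. 27 genotypes x 10 plants x 3 collections = 810 images).
    """
    if plants_per_genotype < 1 or images_per_leaf < 1:
        raise ValueError("plants_per_genotype and images_per_leaf must be >= 1")
    manifest = []
    for collection in collections:
        for genotype in genotypes:
            for plant in range(1, plants_per_genotype + 1):
                for img in range(1, images_per_leaf + 1):
                    manifest.append(
                        {
                            "collection": str(collection),
                            "genotype": str(genotype),
                            "plant": plant,
                            "image": img,
                        }
                    )
    return manifest
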
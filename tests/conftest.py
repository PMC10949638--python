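"""Shared fixtures: synthetic datasets and the session-scoped trained model.

Everything is generated programmatically at test time; there are no stored
binary fixtures.  The trained model is expensive (~half a minute on one CPU)
and session-scoped so the segmentation, ranking and acceptance tests share
one training run.
"""

from __future__ import annotations

import pytest

from trichoseg.annot import write_annotations
from trichoseg.segnet import ModelConfig, train
from trichoseg.synthleaf import (
    SyntheticSpec,
    default_panel,
    derive_seed,
    generate_image,
    generate_panel,
)

#: frozen seed for every stochastic fixture in the suite
FIXTURE_SEED = 11


@pytest.fixture(scope="session")
def base_spec() -> SyntheticSpec:
    return SyntheticSpec()  # 256x256, ~40 hairs


@pytest.fixture(scope="session")
def fixture_split(base_spec):
    """The standard 64-train / 16-val synthetic split (frozen seed)."""
    train_set = [
        generate_image(base_spec, derive_seed(FIXTURE_SEED, "tr", i), image_id=f"tr{i}.png")
        for i in range(64)
    ]
    val_set = [
        generate_image(base_spec, derive_seed(FIXTURE_SEED, "va", i), image_id=f"va{i}.png")
        for i in range(16)
    ]
    return train_set, val_set


@pytest.fixture(scope="session")
def fixture_config() -> ModelConfig:
    return ModelConfig(
        encoder="tiny", decoder="unet", loss="dice", recipe="RS256+RF",
        epochs=15, batch_size=4, seed=3,
    )


@pytest.fixture(scope="session")
def trained_report(fixture_split, fixture_config):
    """tiny-UNet trained on the standard fixture until val IoU >= 0.5."""
    train_set, val_set = fixture_split
    return train(fixture_config, train_set, val_set, stop_at_iou=0.5)


@pytest.fixture(scope="session")
def ranking_panel():
    """5 genotypes with strictly increasing hair density, 6 images each."""
    genotypes = default_panel(5, count_means=[0, 15, 35, 60, 90])
    return genotypes, generate_panel(genotypes, images_per_genotype=6, seed=FIXTURE_SEED)


@pytest.fixture()
def disk_dataset(tmp_path):
    """A tiny on-disk dataset: 2 images, 5 splines total, full metadata."""
    spec = SyntheticSpec(image_size=(64, 64), hair_count=(3, 0), hair_length_px=(20, 0))
    recs = []
    for i, n in enumerate((3, 2)):
        s = SyntheticSpec(
            image_size=(64, 64), hair_count=(float(n), 0), hair_length_px=(20, 0)
        )
        rec = generate_image(
            s, derive_seed(FIXTURE_SEED, "disk", i), image_id=f"img{i}.png",
            meta={"genotype": f"g{i}", "ghs": "3", "leaf": "L3",
                  "environment": "GH", "year": "Y1", "position": "First"},
        )
        recs.append(rec)
    assert sum(len(r.splines) for r in recs) == 5
    write_annotations(recs, tmp_path)
    return tmp_path, recs
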
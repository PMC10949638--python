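"""Model assembly: any registered encoder composes with any registered
decoder into a binary segmentation network, plus prediction and checkpoints.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Tuple, Union

import numpy as np

from ..annot import SparseMask
from ..augment import AugmentRecipe, parse_recipe
from ..nn import Module, seed_init
from ..nn import tensor as T
from ..nn.tensor import Tensor
from .decoders import DECODERS, build_decoder
from .encoders import ENCODERS, build_encoder

__all__ = [
    "ModelConfig",
    "SegModel",
    "build_model",
    "predict_proba",
    "predict_mask",
    "save_checkpoint",
    "load_checkpoint",
    "IMAGE_MEAN",
    "IMAGE_STD",
]

# fixed channel statistics (the usual large-corpus constants); applied after
# scaling to [0, 1]
IMAGE_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
IMAGE_STD = np.array([0.229, 0.224, 0.225], dtype=np.float32)


@dataclass(frozen=True)
class ModelConfig:
    """One cell of the architecture study: encoder x decoder x loss x recipe."""

    encoder: str = "tiny"
    decoder: str = "unet"
    pretrained: bool = False
    loss: str = "dice"
    recipe: str = "RS256+RF"
    lr: float = 3e-3
    epochs: int = 15
    batch_size: int = 4
    threshold: float = 0.5
    seed: int = 0
    patience: int = 5
    stroke_width: float = 2.0

    def __post_init__(self) -> None:
        if self.encoder not in ENCODERS:
            raise KeyError(
                f"unknown encoder {self.encoder!r}; registered: {sorted(ENCODERS)}"
            )
        if self.decoder not in DECODERS:
            raise KeyError(
                f"unknown decoder {self.decoder!r}; registered: {sorted(DECODERS)}"
            )
        from .losses import LOSSES

        if self.loss not in LOSSES:
            raise KeyError(f"unknown loss {self.loss!r}; registered: {sorted(LOSSES)}")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError(f"threshold must be in (0, 1), got {self.threshold}")
        parse_recipe(self.recipe)  # validates

    @property
    def parsed_recipe(self) -> AugmentRecipe:
        return parse_recipe(self.recipe)


class SegModel(Module):
    """Encoder + decoder; ``forward`` returns per-pixel foreground
    probability in [0, 1] at input resolution."""

    def __init__(self, cfg: ModelConfig) -> None:
        super().__init__()
        self.cfg = cfg
        self.encoder = build_encoder(cfg.encoder)
        self.decoder = build_decoder(cfg.decoder, self.encoder.out_channels)

    def forward(self, x: Tensor) -> Tensor:
        return T.sigmoid(self.decoder(self.encoder(x)))


def build_model(cfg: ModelConfig) -> SegModel:
    """Construct a model with weights seeded from ``cfg.seed``.

    ``pretrained=True`` is rejected: this implementation runs fully offline
    and has no external weight source; train from scratch instead.
    """
    if cfg.pretrained:
        raise NotImplementedError(
            "pretrained encoder weights are not available offline; "
            "set pretrained=False and train from scratch"
        )
    with seed_init(cfg.seed):
        return SegModel(cfg)


def normalize_image(image: np.ndarray) -> np.ndarray:
    """HxWx3 uint8 -> HxWx3 float32, scaled to [0,1] and standardized."""
    x = image.astype(np.float32) / 255.0
    return np.ascontiguousarray((x - IMAGE_MEAN) / IMAGE_STD)


def _pad_to_multiple(x: np.ndarray, multiple: int = 32) -> Tuple[np.ndarray, Tuple[int, int]]:
    h, w = x.shape[:2]
    ph = (-h) % multiple
    pw = (-w) % multiple
    if ph or pw:
        x = np.pad(x, ((0, ph), (0, pw), (0, 0)), mode="reflect")
    return x, (h, w)


def predict_proba(model: SegModel, image: np.ndarray) -> np.ndarray:
    """Foreground probability map (H, W) for one HxWx3 uint8 image."""
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(
            f"expected an HxWx3 RGB image, got shape {image.shape}"
        )
    x, (h, w) = _pad_to_multiple(normalize_image(image))
    model.eval()
    prob = model(Tensor(x[None])).data[0, :, :, 0]
    return prob[:h, :w]


def predict_mask(
    model: SegModel, image: np.ndarray, threshold: Optional[float] = None
) -> SparseMask:
    """Binarize the probability map at ``threshold`` (default: config value).

    Foreground is strictly greater than the threshold, returned sparse.
    """
    thr = model.cfg.threshold if threshold is None else threshold
    prob = predict_proba(model, image)
    return SparseMask.from_dense((prob > thr).astype(np.uint8))


# ---------------------------------------------------------------------------
# checkpoints: npz weights + embedded JSON config


def save_checkpoint(model: SegModel, path: Union[str, Path]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(asdict(model.cfg)).encode(), dtype=np.uint8
    )
    np.savez(path, **state)


def load_checkpoint(path: Union[str, Path]) -> SegModel:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"checkpoint not found: {path}")
    with np.load(path) as archive:
        state = {k: archive[k] for k in archive.files}
    cfg = ModelConfig(**json.loads(state.pop("__config__").tobytes().decode()))
    model = build_model(cfg)
    model.load_state_dict(state)
    return model
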
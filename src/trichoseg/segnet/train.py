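"""Training loop: augment-on-the-fly, loss optimization, validation
tracking, early stopping on validation overlap.

Determinism contract: with a fixed config (including seed) on a fixed
backend, reruns are bit-identical — numpy has no nondeterministic kernels —
so repeat ranges reported by the grid harness reflect seed variation only.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from ..annot import AnnotatedImage, SparseMask
from ..augment import RS, AugmentRecipe, apply
from ..nn import Adam
from ..nn.tensor import Tensor
from ..quantify import f1 as _f1
from ..quantify import iou as _iou
from ..synthleaf import derive_seed
from .losses import loss_fn
from .model import ModelConfig, SegModel, build_model, normalize_image

__all__ = ["TrainReport", "train", "evaluate_model"]


@dataclass
class TrainReport:
    """Per-epoch history plus the best checkpoint (by validation IoU)."""

    config: ModelConfig
    history: List[Dict[str, float]] = field(default_factory=list)
    best_epoch: int = -1
    best_val_iou: float = -1.0
    best_val_f1: float = -1.0
    stopped_early: bool = False
    best_state: Optional[Dict[str, np.ndarray]] = None
    model: Optional[SegModel] = None

    @property
    def epochs_run(self) -> int:
        return len(self.history)

    def write_csv(self, path: Union[str, Path]) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=["epoch", "loss", "val_iou", "val_f1"])
            writer.writeheader()
            for row in self.history:
                writer.writerow({k: row[k] for k in writer.fieldnames})


def _validation_recipe(recipe: AugmentRecipe) -> AugmentRecipe:
    """Validation sees deterministic resizing only (no crops, no flips)."""
    size = recipe.output_size
    return AugmentRecipe((RS(size),)) if size is not None else AugmentRecipe(())


def _prepare(
    records: Sequence[AnnotatedImage],
    recipe: AugmentRecipe,
    stroke_width: float,
    seeds: Sequence[int],
) -> List[Tuple[np.ndarray, np.ndarray]]:
    out = []
    for rec, seed in zip(records, seeds):
        img, mask = apply(recipe, rec, stroke_width=stroke_width, seed=seed)
        out.append((normalize_image(img), mask.to_dense().astype(np.float32)))
    return out


def _batches(pairs: List[Tuple[np.ndarray, np.ndarray]], batch_size: int):
    """Group consecutive same-shaped samples into batches."""
    i = 0
    while i < len(pairs):
        shape = pairs[i][0].shape
        batch = [pairs[i]]
        i += 1
        while i < len(pairs) and len(batch) < batch_size and pairs[i][0].shape == shape:
            batch.append(pairs[i])
            i += 1
        xs = np.stack([b[0] for b in batch])
        ys = np.stack([b[1] for b in batch])[..., None]  # (N,H,W,1)
        yield xs, ys


def evaluate_model(
    model: SegModel,
    val_pairs: Sequence[Tuple[np.ndarray, np.ndarray]],
    threshold: float,
) -> Tuple[float, float]:
    """Mean IoU and F1 of thresholded predictions over prepared pairs."""
    model.eval()
    ious, f1s = [], []
    for x, y in val_pairs:
        prob = model(Tensor(x[None])).data[0, :, :, 0]
        pred = SparseMask.from_dense((prob > threshold).astype(np.uint8))
        truth = SparseMask.from_dense(y.astype(np.uint8))
        ious.append(_iou(pred, truth))
        f1s.append(_f1(pred, truth)[0])
    return float(np.mean(ious)), float(np.mean(f1s))


def train(
    cfg: ModelConfig,
    train_set: Sequence[AnnotatedImage],
    val_set: Sequence[AnnotatedImage],
    model: Optional[SegModel] = None,
    metrics_path: Optional[Union[str, Path]] = None,
    stop_at_iou: Optional[float] = None,
) -> TrainReport:
    """Optimize ``cfg.loss`` on the train set; checkpoint by validation IoU.

    The training recipe (with its random crops/flips) applies to the train
    set only, re-drawn each epoch; validation uses deterministic resizing.
    Stops early after ``cfg.patience`` epochs without IoU improvement, or as
    soon as validation IoU reaches ``stop_at_iou`` (target early stop).
    """
    if not len(train_set):
        raise ValueError("train set is empty")
    if not len(val_set):
        raise ValueError("validation set is empty")

    recipe = cfg.parsed_recipe
    model = model or build_model(cfg)
    optimizer = Adam(model.parameters(), lr=cfg.lr)
    criterion = loss_fn(cfg.loss)

    val_pairs = _prepare(
        val_set, _validation_recipe(recipe), cfg.stroke_width,
        [derive_seed(cfg.seed, "val", i) for i in range(len(val_set))],
    )

    report = TrainReport(config=cfg)
    order_rng = np.random.default_rng(derive_seed(cfg.seed, "order"))
    since_best = 0
    for epoch in range(cfg.epochs):
        order = order_rng.permutation(len(train_set))
        seeds = [derive_seed(cfg.seed, "aug", epoch, int(i)) for i in order]
        pairs = _prepare([train_set[i] for i in order], recipe, cfg.stroke_width, seeds)

        model.train()
        losses = []
        for x, y in _batches(pairs, cfg.batch_size):
            optimizer.zero_grad()
            pred = model(Tensor(x))
            loss = criterion(pred, y)
            loss.backward()
            optimizer.step()
            losses.append(float(loss.data))

        val_iou, val_f1 = evaluate_model(model, val_pairs, cfg.threshold)
        report.history.append(
            {
                "epoch": epoch,
                "loss": float(np.mean(losses)),
                "val_iou": val_iou,
                "val_f1": val_f1,
            }
        )
        if val_iou > report.best_val_iou:
            report.best_val_iou = val_iou
            report.best_val_f1 = val_f1
            report.best_epoch = epoch
            report.best_state = model.state_dict()
            since_best = 0
            if stop_at_iou is not None and val_iou >= stop_at_iou:
                report.stopped_early = True
                break
        else:
            since_best += 1
            if since_best >= cfg.patience:
                report.stopped_early = True
                break

    if report.best_state is not None:
        model.load_state_dict(report.best_state)
    if metrics_path is not None:
        report.write_csv(metrics_path)
    report.model = model
    return report
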
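"""The model-selection study: a grid over encoder x decoder x augmentation
recipe x loss, with repeat runs reported as mean ± range.

Each grid cell derives its repeat seeds by hashing the cell's identity (never
its position), so results are invariant to axis ordering and the grid is
resumable: completed cells are recognized by content hash and skipped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from itertools import product
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .annot import AnnotatedImage
from .segnet import ModelConfig, train
from .segnet.train import _prepare, _validation_recipe, evaluate_model
from .synthleaf import derive_seed

__all__ = ["GridSpec", "run_grid", "select_best", "markdown_report", "cell_id"]

RESULT_COLUMNS = [
    "encoder", "decoder", "recipe", "loss", "split",
    "mean_iou", "range_iou", "mean_f1", "range_f1", "repeats",
]


@dataclass(frozen=True)
class GridSpec:
    """Axes and base hyperparameters of an architecture study."""

    encoders: Tuple[str, ...] = ("tiny",)
    decoders: Tuple[str, ...] = ("unet",)
    recipes: Tuple[str, ...] = ("RS256",)
    losses: Tuple[str, ...] = ("dice",)
    repeats: int = 1
    base: ModelConfig = field(default_factory=ModelConfig)
    seed: int = 0
    finalists: Tuple[Tuple[str, str, str, str], ...] = ()

    def __post_init__(self) -> None:
        if not (self.encoders and self.decoders and self.recipes and self.losses):
            raise ValueError("all grid axes must be nonempty")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")

    def cells(self) -> List[Tuple[str, str, str, str]]:
        return list(product(self.encoders, self.decoders, self.recipes, self.losses))


def cell_id(encoder: str, decoder: str, recipe: str, loss: str) -> str:
    return f"{encoder}-{decoder}-{recipe}-{loss}"


def _cell_config(spec: GridSpec, cell: Tuple[str, str, str, str], repeat: int) -> ModelConfig:
    encoder, decoder, recipe, loss = cell
    seed = derive_seed(spec.seed, encoder, decoder, recipe, loss, repeat)
    return replace(
        spec.base, encoder=encoder, decoder=decoder, recipe=recipe, loss=loss, seed=seed
    )


def run_grid(
    spec: GridSpec,
    train_set: Sequence[AnnotatedImage],
    val_set: Sequence[AnnotatedImage],
    test_set: Optional[Sequence[AnnotatedImage]] = None,
    out_dir: Optional[Union[str, Path]] = None,
) -> pd.DataFrame:
    """Train every cell ``repeats`` times and tabulate mean ± range metrics.

    Evaluation runs on the validation split for every cell; cells listed in
    ``spec.finalists`` are additionally evaluated on the test split (the
    staged protocol: grids select on validation, finalists confirm on test).
    Cell failures are recorded and the grid continues.  With ``out_dir``,
    completed cells are cached as JSON keyed by a content hash and reruns
    skip them, so a finished grid is idempotent.
    """
    if not len(train_set) or not len(val_set):
        raise ValueError("train and validation sets must be nonempty")
    cache_dir = None
    if out_dir is not None:
        cache_dir = Path(out_dir) / "cells"
        cache_dir.mkdir(parents=True, exist_ok=True)

    rows: List[dict] = []
    failures: List[dict] = []
    for cell in sorted(spec.cells()):  # deterministic cell ordering
        cid = cell_id(*cell)
        cache_key = derive_seed("gridcell", spec.seed, spec.repeats, cid)
        cache_file = cache_dir / f"{cid}.{cache_key:x}.json" if cache_dir else None
        if cache_file is not None and cache_file.exists():
            rows.extend(json.loads(cache_file.read_text()))
            continue
        try:
            cell_rows = _run_cell(spec, cell, train_set, val_set, test_set)
        except Exception as exc:
            failures.append({"cell": cid, "error": str(exc)})
            continue
        rows.extend(cell_rows)
        if cache_file is not None:
            cache_file.write_text(json.dumps(cell_rows, indent=1))

    result = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    result.attrs["failures"] = failures
    if out_dir is not None:
        result.to_csv(Path(out_dir) / "grid_results.csv", index=False)
        if failures:
            (Path(out_dir) / "failures.json").write_text(json.dumps(failures, indent=1))
    return result


def _run_cell(
    spec: GridSpec,
    cell: Tuple[str, str, str, str],
    train_set: Sequence[AnnotatedImage],
    val_set: Sequence[AnnotatedImage],
    test_set: Optional[Sequence[AnnotatedImage]],
) -> List[dict]:
    encoder, decoder, recipe, loss = cell
    val_iou, val_f1, test_iou, test_f1 = [], [], [], []
    is_finalist = cell in set(spec.finalists)
    for repeat in range(spec.repeats):
        cfg = _cell_config(spec, cell, repeat)
        report = train(cfg, train_set, val_set)
        val_iou.append(report.best_val_iou)
        val_f1.append(report.best_val_f1)
        if test_set is not None and is_finalist:
            pairs = _prepare(
                test_set, _validation_recipe(cfg.parsed_recipe), cfg.stroke_width,
                [derive_seed(cfg.seed, "test", i) for i in range(len(test_set))],
            )
            t_iou, t_f1 = evaluate_model(report.model, pairs, cfg.threshold)
            test_iou.append(t_iou)
            test_f1.append(t_f1)

    def row(split: str, ious: List[float], f1s: List[float]) -> dict:
        return {
            "encoder": encoder, "decoder": decoder, "recipe": recipe, "loss": loss,
            "split": split,
            "mean_iou": float(np.mean(ious)),
            "range_iou": float(np.max(ious) - np.min(ious)),
            "mean_f1": float(np.mean(f1s)),
            "range_f1": float(np.max(f1s) - np.min(f1s)),
            "repeats": len(ious),
        }

    out = [row("val", val_iou, val_f1)]
    if test_iou:
        out.append(row("test", test_iou, test_f1))
    return out


def select_best(result: pd.DataFrame, metric: str = "iou") -> Dict[str, str]:
    """Argmax of the validation-split mean metric.

    Ties break by the other metric, then lexicographic cell identity, so the
    selection is total and deterministic.
    """
    if metric not in ("iou", "f1"):
        raise ValueError("metric must be 'iou' or 'f1'")
    val = result[result["split"] == "val"].copy()
    if not len(val):
        raise ValueError("empty grid result")
    other = "f1" if metric == "iou" else "iou"
    val["_cell"] = val.apply(
        lambda r: cell_id(r.encoder, r.decoder, r.recipe, r.loss), axis=1
    )
    val = val.sort_values(
        [f"mean_{metric}", f"mean_{other}", "_cell"],
        ascending=[False, False, True],
        kind="mergesort",
    )
    best = val.iloc[0]
    return {
        "encoder": best["encoder"], "decoder": best["decoder"],
        "recipe": best["recipe"], "loss": best["loss"],
    }


def markdown_report(result: pd.DataFrame, title: str = "Grid results") -> str:
    """Render mean ± range tables per split, one row per cell."""
    lines = [f"# {title}", ""]
    for split, group in result.groupby("split"):
        lines.append(f"## {split} split")
        lines.append("")
        lines.append("| encoder | decoder | recipe | loss | IoU | F1 | repeats |")
        lines.append("|---|---|---|---|---|---|---|")
        for _, r in group.iterrows():
            iou = f"{r.mean_iou:.4f} ± {r.range_iou:.4f}"
            f1s = f"{r.mean_f1:.4f} ± {r.range_f1:.4f}"
            lines.append(
                f"| {r.encoder} | {r.decoder} | {r.recipe} | {r.loss} "
                f"| {iou} | {f1s} | {r.repeats} |"
            )
        lines.append("")
    return "\n".join(lines)
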
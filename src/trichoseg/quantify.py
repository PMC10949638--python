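"""Quantification: overlap metrics, the scaled trichome-density score,
batch scoring, factor-wise aggregation and genotype ranking.

The central quantity is the leaf trichome score of a mask,

    ``lts = 1000 * n_foreground / n_total``

a per-mille trichome pixel density in [0, 1000].  The score is exactly
invariant to integer nearest-neighbour rescaling (both counts scale by the
squared factor), so computing it at the pipeline's working resolution is
benign as long as that resolution is held fixed within a comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .annot import AnnotatedImage, GHSLabel, SparseMask, rasterize

__all__ = [
    "LTSResult",
    "iou",
    "f1",
    "lts",
    "score_batch",
    "score_oracle",
    "evaluate_pairs",
    "aggregate",
    "rank_genotypes",
    "rank_correlation",
    "flag_nonmonotone_classes",
    "SCORE_COLUMNS",
]

SCORE_COLUMNS = [
    "image_id", "genotype", "ghs", "leaf", "environment", "year", "position", "lts",
]


@dataclass(frozen=True)
class LTSResult:
    """Foreground count, total count, and the scaled score."""

    n_fg: int
    n_total: int

    @property
    def lts(self) -> float:
        return 1000.0 * self.n_fg / self.n_total

    @property
    def exact(self) -> Fraction:
        """The score as an exact rational (lts * n_total == 1000 * n_fg)."""
        return Fraction(1000 * self.n_fg, self.n_total)


def iou(pred: SparseMask, truth: SparseMask) -> float:
    """Intersection over union of two foreground pixel sets.

    Both-empty is defined as perfect agreement (1.0).
    """
    union = pred.union_size(truth)  # also validates shapes
    if union == 0:
        return 1.0
    return pred.intersection_size(truth) / union


def f1(pred: SparseMask, truth: SparseMask) -> Tuple[float, float, float]:
    """Returns ``(f1, precision, recall)``.

    ``precision = |P ∩ G| / |P|`` and ``recall = |P ∩ G| / |G|``; an empty
    prediction or truth makes the corresponding ratio 0 (with a warning), and
    F1 is 0 when precision + recall is 0.
    """
    inter = pred.intersection_size(truth)
    if pred.n_foreground == 0:
        warnings.warn("empty prediction: precision defined as 0", stacklevel=2)
        precision = 0.0
    else:
        precision = inter / pred.n_foreground
    if truth.n_foreground == 0:
        warnings.warn("empty ground truth: recall defined as 0", stacklevel=2)
        recall = 0.0
    else:
        recall = inter / truth.n_foreground
    if precision + recall == 0:
        return 0.0, precision, recall
    return 2 * precision * recall / (precision + recall), precision, recall


def lts(mask: SparseMask) -> LTSResult:
    """Leaf trichome score of a mask: ``1000 * foreground / total`` pixels."""
    if mask.n_total <= 0:
        raise ValueError("mask has zero total pixel count")
    return LTSResult(n_fg=mask.n_foreground, n_total=mask.n_total)


# ---------------------------------------------------------------------------
# batch scoring


def _meta_row(rec: AnnotatedImage, score: float) -> dict:
    meta = rec.meta
    ghs = rec.ghs
    return {
        "image_id": rec.image_id,
        "genotype": meta.get("genotype"),
        "ghs": ghs.value if ghs is not None else None,
        "leaf": meta.get("leaf"),
        "environment": meta.get("environment"),
        "year": meta.get("year"),
        "position": meta.get("position"),
        "lts": score,
    }


def score_batch(
    model,
    records: Sequence[AnnotatedImage],
    working_size: int = 256,
    threshold: Optional[float] = None,
) -> pd.DataFrame:
    """Predict a mask for each record at ``working_size`` and score it.

    Metadata is copied through to the returned table (one row per image).
    Unreadable/failed records are collected into an ``error`` column and the
    run continues.
    """
    from .augment import RS, AugmentRecipe, apply
    from .segnet.model import predict_mask

    rows: List[dict] = []
    resize = AugmentRecipe((RS(working_size),))
    for rec in records:
        try:
            img, _ = apply(resize, rec, seed=0)
            mask = predict_mask(model, img, threshold)
            rows.append(_meta_row(rec, lts(mask).lts))
        except Exception as exc:  # row-level failure; keep scoring the rest
            row = _meta_row(rec, np.nan)
            row["error"] = str(exc)
            rows.append(row)
    return pd.DataFrame(rows, columns=SCORE_COLUMNS + (
        ["error"] if any("error" in r for r in rows) else []
    ))


def score_oracle(
    records: Sequence[AnnotatedImage],
    working_size: Optional[int] = None,
    stroke_width: float = 2.0,
) -> pd.DataFrame:
    """Score rasterized ground-truth splines instead of predictions.

    The oracle bypass: identical table layout to :func:`score_batch`, with
    the score computed on the annotation masks themselves.
    """
    from .annot import transform_spline

    rows = []
    for rec in records:
        size = (working_size, working_size) if working_size else rec.size
        splines = (
            [transform_spline(s, size) for s in rec.splines]
            if size != rec.size
            else rec.splines
        )
        mask = rasterize(splines, size, stroke_width)
        rows.append(_meta_row(rec, lts(mask).lts))
    return pd.DataFrame(rows, columns=SCORE_COLUMNS)


def evaluate_pairs(
    pairs: Iterable[Tuple[SparseMask, SparseMask]]
) -> pd.DataFrame:
    """Per-pair IoU/F1/precision/recall plus a trailing mean row."""
    rows = []
    for i, (pred, truth) in enumerate(pairs):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f, p, r = f1(pred, truth)
        rows.append(
            {"index": i, "iou": iou(pred, truth), "f1": f, "precision": p, "recall": r}
        )
    frame = pd.DataFrame(rows)
    if len(frame):
        mean = frame.drop(columns="index").mean()
        mean["index"] = "mean"
        frame = pd.concat([frame, mean.to_frame().T], ignore_index=True)
    return frame


# ---------------------------------------------------------------------------
# aggregation and ranking


def aggregate(
    table: pd.DataFrame,
    by: Sequence[str],
    statistic: str = "mean",
) -> pd.DataFrame:
    """Group scores by metadata keys; mean (or median), sd, n and 95% CI.

    Groups of a single row report ``sd`` and the CI as missing.
    """
    missing = [k for k in by if k not in table.columns]
    if missing:
        raise KeyError(f"unknown metadata key(s): {missing}")
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")

    rows = []
    for key, group in table.groupby(list(by), dropna=False, sort=True):
        vals = group["lts"].to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        n = len(vals)
        center = float(np.mean(vals)) if statistic == "mean" else float(np.median(vals))
        if n >= 2:
            sd = float(np.std(vals, ddof=1))
            half = stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
            lo, hi = float(np.mean(vals) - half), float(np.mean(vals) + half)
        else:
            sd, lo, hi = np.nan, np.nan, np.nan
        row = dict(zip(by, key if isinstance(key, tuple) else (key,)))
        row.update({statistic: center, "sd": sd, "n": n, "ci_lo": lo, "ci_hi": hi})
        rows.append(row)
    return pd.DataFrame(rows)


def rank_genotypes(
    table: pd.DataFrame,
    within: Optional[str] = None,
    statistic: str = "mean",
) -> pd.DataFrame:
    """Order genotypes by their average score, ascending.

    ``within`` restricts to one environment first.  Ties break by genotype
    name, so the ordering is total and stable across runs.  Carries the
    (modal) hairiness class of each genotype for comparison.
    """
    if within is not None:
        table = table[table["environment"] == within]
    if not len(table):
        raise ValueError("no rows selected for ranking")
    agg = aggregate(table, ["genotype"], statistic=statistic)
    ghs = (
        table.groupby("genotype")["ghs"]
        .agg(lambda s: s.mode().iloc[0] if s.notna().any() else None)
        .rename("ghs")
    )
    agg = agg.merge(ghs, on="genotype", how="left")
    agg = agg.sort_values(
        [statistic, "genotype"], ascending=[True, True], kind="mergesort"
    ).reset_index(drop=True)
    agg.insert(0, "rank", np.arange(1, len(agg) + 1))
    return agg[["rank", "genotype", statistic, "ghs", "sd", "n"]].rename(
        columns={statistic: f"{statistic}_lts"}
    )


def rank_correlation(ranking_a, ranking_b) -> float:
    """Spearman rho between two rankings of the same item set.

    Accepts ordered sequences of items (position = rank) or mappings
    item -> score (ties get average ranks).  Tie-free rankings use the exact
    ``1 - 6 * sum(d^2) / (n * (n^2 - 1))`` formula, so identical and reversed
    rankings return exactly +-1.
    """

    def ranks(r) -> dict:
        if isinstance(r, Mapping):
            items = sorted(r)
            return dict(zip(items, stats.rankdata([r[i] for i in items])))
        return {item: float(i + 1) for i, item in enumerate(r)}

    ra, rb = ranks(ranking_a), ranks(ranking_b)
    if set(ra) != set(rb):
        raise ValueError("rankings must cover the same item set")
    n = len(ra)
    if n < 2:
        raise ValueError("need at least 2 items")
    items = sorted(ra)
    va = np.array([ra[i] for i in items])
    vb = np.array([rb[i] for i in items])
    tie_free = len(set(va)) == n and len(set(vb)) == n
    if tie_free:
        d2 = float(np.sum((va - vb) ** 2))
        return 1.0 - 6.0 * d2 / (n * (n * n - 1))
    return float(stats.pearsonr(va, vb).statistic)


def flag_nonmonotone_classes(
    table: pd.DataFrame, statistic: str = "mean"
) -> List[str]:
    """Classes whose mean score drops below the preceding class's mean.

    Orders present classes on the ordinal scale and reports each label whose
    aggregate is strictly lower than its predecessor's — the 'dip' detector
    for class-level summaries.
    """
    agg = aggregate(table.dropna(subset=["ghs"]), ["ghs"], statistic=statistic)
    agg["_rank"] = agg["ghs"].map(lambda v: GHSLabel(v).rank)
    agg = agg.sort_values("_rank")
    vals = agg[statistic].to_numpy()
    labels = agg["ghs"].tolist()
    return [labels[i] for i in range(1, len(labels)) if vals[i] < vals[i - 1]]
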
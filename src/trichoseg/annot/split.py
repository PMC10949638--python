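"""Deterministic train/validation/test splitting.

Rounding rule: ``floor(f_train * N)`` to train, ``floor(f_val * N)`` to
validation, remainder to test — so 1250 records at 65/15/20 give 812/187/251.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from typing import List, Optional, Sequence, Tuple, TypeVar

import numpy as np

__all__ = ["split_dataset"]

T = TypeVar("T")


def _split_sizes(n: int, fractions: Tuple[float, float, float]) -> Tuple[int, int, int]:
    f_train, f_val, f_test = fractions
    n_train = int(np.floor(f_train * n))
    n_val = int(np.floor(f_val * n))
    return n_train, n_val, n - n_train - n_val


def split_dataset(
    records: Sequence[T],
    fractions: Tuple[float, float, float] = (0.65, 0.15, 0.20),
    seed: int = 0,
    stratify_by: Optional[str] = None,
) -> Tuple[List[T], List[T], List[T]]:
    """Shuffle and partition records into disjoint train/val/test lists.

    Parameters
    ----------
    records
        Any sequence; with ``stratify_by`` set, each record must expose a
        ``meta`` mapping (e.g. :class:`~trichoseg.annot.types.AnnotatedImage`)
        and records are partitioned per stratum so group proportions deviate
        from the global fractions by at most one record.  Strata smaller than
        3 records are assigned wholly to train with a warning.
    fractions
        ``(train, val, test)``; must sum to 1 within 1e-9.
    seed
        Shuffle seed; identical seeds give identical splits.
    """
    if len(fractions) != 3 or any(f < 0 for f in fractions):
        raise ValueError("fractions must be three non-negative numbers")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)!r}")

    rng = np.random.default_rng(seed)

    def plain_split(items: Sequence[T]) -> Tuple[List[T], List[T], List[T]]:
        order = rng.permutation(len(items))
        n_train, n_val, _ = _split_sizes(len(items), fractions)
        shuffled = [items[i] for i in order]
        return (
            shuffled[:n_train],
            shuffled[n_train : n_train + n_val],
            shuffled[n_train + n_val :],
        )

    if stratify_by is None:
        return plain_split(records)

    strata: "defaultdict[object, list]" = defaultdict(list)
    for rec in records:
        meta = getattr(rec, "meta", None)
        if meta is None:
            raise ValueError("stratified split requires records with a 'meta' mapping")
        strata[meta.get(stratify_by)].append(rec)

    train: List[T] = []
    val: List[T] = []
    test: List[T] = []
    for key in sorted(strata, key=lambda k: str(k)):
        group = strata[key]
        if len(group) < 3:
            warnings.warn(
                f"stratum {stratify_by}={key!r} has only {len(group)} record(s); "
                "assigning all of them to train",
                stacklevel=2,
            )
            train.extend(group)
            continue
        g_train, g_val, g_test = plain_split(group)
        train.extend(g_train)
        val.extend(g_val)
        test.extend(g_test)
    return train, val, test
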
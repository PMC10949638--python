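"""Segmentation losses on foreground-probability maps.

All four losses operate on probabilities in [0, 1] against 0/1 targets:

* ``bce``      mean pixelwise cross-entropy
* ``dice``     ``1 - (2*sum(p*g) + eps) / (sum(p) + sum(g) + eps)``
* ``jaccard``  ``1 - (sum(p*g) + eps) / (sum(p) + sum(g) - sum(p*g) + eps)``
* ``focal``    mean of ``-(1 - p_t)^gamma * log(p_t)`` with gamma = 2

with smoothing ``eps = 1.0`` in the overlap losses.  For binary inputs, the
dice and jaccard losses are the usual complements of the Sorensen-Dice and
Jaccard overlap coefficients.
"""

from __future__ import annotations

from typing import Union

import numpy as np

from ..nn import tensor as T
from ..nn.tensor import Tensor

__all__ = ["LOSSES", "compute_loss", "loss_fn"]

SMOOTH_EPS = 1.0
FOCAL_GAMMA = 2.0
_CLIP = 1e-7


def _bce(p: Tensor, g: np.ndarray) -> Tensor:
    p = T.clip(p, _CLIP, 1.0 - _CLIP)
    return T.tmean(-(T.mul(T.log(p), g) + T.mul(T.log(1.0 - p), 1.0 - g)))


def _dice(p: Tensor, g: np.ndarray) -> Tensor:
    inter = T.tsum(T.mul(p, g))
    total = T.tsum(p) + float(g.sum())
    return 1.0 - (2.0 * inter + SMOOTH_EPS) / (total + SMOOTH_EPS)


def _jaccard(p: Tensor, g: np.ndarray) -> Tensor:
    inter = T.tsum(T.mul(p, g))
    total = T.tsum(p) + float(g.sum())
    return 1.0 - (inter + SMOOTH_EPS) / (total - inter + SMOOTH_EPS)


def _focal(p: Tensor, g: np.ndarray) -> Tensor:
    p = T.clip(p, _CLIP, 1.0 - _CLIP)
    pos = T.mul(T.mul(T.power(1.0 - p, FOCAL_GAMMA), T.log(p)), g)
    neg = T.mul(T.mul(T.power(p, FOCAL_GAMMA), T.log(1.0 - p)), 1.0 - g)
    return T.tmean(-(pos + neg))


LOSSES = {"bce": _bce, "dice": _dice, "jaccard": _jaccard, "focal": _focal}


def loss_fn(kind: str):
    try:
        return LOSSES[kind]
    except KeyError:
        raise KeyError(
            f"unknown loss {kind!r}; registered losses: {sorted(LOSSES)}"
        ) from None


def compute_loss(
    pred: Union[np.ndarray, Tensor], target: np.ndarray, kind: str
) -> float:
    """Evaluate a named loss between a probability raster and a 0/1 target.

    Raises ``ValueError`` on shape mismatch or probabilities outside [0, 1].
    """
    fn = loss_fn(kind)
    p = pred.data if isinstance(pred, Tensor) else np.asarray(pred)
    p = np.asarray(p, dtype=np.float64)  # scalar API runs in full precision
    g = np.asarray(target, dtype=np.float64)
    if p.shape != g.shape:
        raise ValueError(f"pred shape {p.shape} != target shape {g.shape}")
    if p.min() < 0.0 or p.max() > 1.0:
        raise ValueError("pred must contain probabilities in [0, 1]")
    if not np.all(np.isin(np.unique(g), (0.0, 1.0))):
        raise ValueError("target must be 0/1 valued")
    return float(fn(Tensor(p), g).data)
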
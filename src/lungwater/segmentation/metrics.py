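"""Overlap metrics for segmentation training and evaluation."""

from __future__ import annotations

import numpy as np

__all__ = ["dice_coefficient", "soft_jaccard_loss"]


def dice_coefficient(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap ``2|A∩B| / (|A|+|B|)`` between two binary masks.

    Defined as 1.0 when both masks are empty (perfect agreement on absence).
    """
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def soft_jaccard_loss(prob_map: np.ndarray, truth_mask: np.ndarray,
                      eps: float = 1.0) -> float:
    """Differentiable intersection-over-union loss on a probability map.

    ``1 - (sum(p*g) + eps) / (sum(p) + sum(g) - sum(p*g) + eps)`` with the
    smoothing term ``eps`` keeping the loss finite (and gradients useful) on
    empty masks.
    """
    p = np.asarray(prob_map, dtype=np.float64)
    g = np.asarray(truth_mask, dtype=np.float64)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    if p.min() < 0 or p.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    inter = float((p * g).sum())
    union = float(p.sum() + g.sum()) - inter
    return 1.0 - (inter + eps) / (union + eps)
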
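"""Scalar training objectives.

All reductions follow the convention: sum over classes / non-PAD sequence
steps, mean over the batch.  Probabilities are clamped at ``EPS`` inside
logarithms so a zero probability at a target index yields a large finite
penalty rather than an infinity.
"""

from __future__ import annotations

import numpy as np

EPS = 1e-12


def _as_batch(y: np.ndarray, t: np.ndarray):
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    if y.shape != t.shape:
        raise ValueError(f"shape mismatch {y.shape} vs {t.shape}")
    if y.ndim == 1:
        y, t = y[None], t[None]
    return y, t


def encoder_decoder_loss(y_dec: np.ndarray, l_dec: np.ndarray,
                         mask: np.ndarray | None = None,
                         step_reduction: str = "sum") -> float:
    """Masked reconstruction cross-entropy.

    ``y_dec``: per-step vocabulary distributions (B, T, V) (or (T, V));
    ``l_dec``: one-hot targets of the same shape; ``mask``: (B, T) with 1
    on real tokens.  PAD steps contribute exactly zero.

    The printed objective is defined per output vector; its aggregation
    across the sequence is a design choice.  ``step_reduction='sum'``
    sums the per-step terms, ``'mean'`` averages them over each sample's
    real tokens (keeping the reconstruction term on the same scale as the
    classification term in joint training).
    """
    y = np.asarray(y_dec, dtype=float)
    t = np.asarray(l_dec, dtype=float)
    if y.shape != t.shape:
        raise ValueError(f"shape mismatch {y.shape} vs {t.shape}")
    if y.ndim == 2:
        y, t = y[None], t[None]
        if mask is not None:
            mask = np.asarray(mask)[None]
    B, T, V = y.shape
    if mask is None:
        mask = np.ones((B, T))
    step_ce = -(t * np.log(np.clip(y, EPS, None))).sum(axis=2)
    if step_reduction == "sum":
        return float((step_ce * mask).sum() / B)
    if step_reduction == "mean":
        n_real = np.maximum(mask.sum(axis=1), 1)
        return float(((step_ce * mask).sum(axis=1) / n_real).mean())
    raise ValueError(f"unknown step_reduction {step_reduction!r}")


def classifier_loss(y_cls: np.ndarray, l_cls: np.ndarray) -> float:
    """Classification cross-entropy, batch-averaged."""
    y, t = _as_batch(y_cls, l_cls)
    return float(-(t * np.log(np.clip(y, EPS, None))).sum(axis=1).mean())


def focal_loss(y_cls: np.ndarray, l_cls: np.ndarray, gamma: float = 2.0,
               alpha: np.ndarray | float | None = None) -> float:
    """Focal loss: cross-entropy down-weighted by (1 - p_t)^gamma.

    ``alpha`` may be a scalar, a per-class weight vector, or ``None`` (=1).
    With gamma=0 and alpha=1 this reduces exactly to ``classifier_loss``.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    y, t = _as_batch(y_cls, l_cls)
    p_t = (y * t).sum(axis=1)
    if alpha is None:
        a_t = np.ones_like(p_t)
    else:
        alpha = np.asarray(alpha, dtype=float)
        a_t = (t * alpha).sum(axis=1) if alpha.ndim == 1 and alpha.size == y.shape[1] \
            else np.full_like(p_t, float(alpha))
    return float((-a_t * (1 - p_t) ** gamma
                  * np.log(np.clip(p_t, EPS, None))).mean())


def joint_loss(l_cls: float, l_ed: float, lam: float) -> float:
    """Joint objective: classification loss plus lambda-weighted
    reconstruction loss."""
    if not (np.isfinite(l_cls) and np.isfinite(l_ed)):
        raise ValueError("loss terms must be finite")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    return float(l_cls + lam * l_ed)


def inverse_frequency_alpha(class_counts: np.ndarray) -> np.ndarray:
    """Per-class focal weights: inverse frequency, normalized to mean 1.
    Classes absent from the training set receive the maximum weight."""
    counts = np.asarray(class_counts, dtype=float)
    safe = np.where(counts > 0, counts, np.nan)
    inv = 1.0 / safe
    inv = np.where(np.isnan(inv), np.nanmax(inv), inv)
    return inv / inv.mean()
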
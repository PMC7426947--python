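"""Class-discriminative saliency via gradient-weighted class activation
mapping.

For a target class c with pre-softmax score y^c and the feature maps A^k
of a chosen convolutional layer, the neuron importance weights are the
global-average-pooled gradients

    alpha_k = (1/Z) * sum_ij  d y^c / d A^k_ij ,  Z = u*v,

and the saliency map is the ReLU of their weighted combination

    L^c = ReLU( sum_k alpha_k * A^k ),

a coarse nonnegative heat-map the size of the feature map, upsampled
bilinearly for the image overlay.  Only positively-influencing features
survive the ReLU.  The gradient is taken at the pre-softmax score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _resize

from .models import SharedLatentModel, prepare_images


def neuron_importance(gradients: np.ndarray) -> np.ndarray:
    """Global-average-pool per-map gradients (k, u, v) -> alpha (k,)."""
    g = np.asarray(gradients, dtype=float)
    if g.ndim != 3 or g.shape[1] == 0 or g.shape[2] == 0:
        raise ValueError("gradients must be a non-empty (k, u, v) stack")
    if not np.all(np.isfinite(g)):
        raise ValueError("gradients must be finite")
    return g.mean(axis=(1, 2))


def gradcam_map(feature_maps: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """ReLU of the alpha-weighted feature-map combination; shape (u, v)."""
    A = np.asarray(feature_maps, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if A.ndim != 3 or A.shape[0] != alpha.shape[0]:
        raise ValueError(f"feature maps {A.shape} inconsistent with "
                         f"alpha {alpha.shape}")
    return np.maximum(0.0, np.tensordot(alpha, A, axes=1))


@dataclass
class SaliencyResult:
    map: np.ndarray          # (u, v) nonnegative
    overlay: np.ndarray      # image-sized, scaled to [0, 1]
    target_class: int
    layer: str


def default_target_layer(model: SharedLatentModel) -> str:
    """Last convolutional layer of the encoder."""
    convs = [n for n, l in zip(model.encoder.names, model.encoder.layers)
             if l.spatial and l.params]
    if not convs:
        raise ValueError("encoder has no convolutional layers")
    return convs[-1]


def explain_image(model: SharedLatentModel, image: np.ndarray,
                  target_class: int, layer: str | None = None
                  ) -> SaliencyResult:
    """Saliency map for one image and class from a trained model.

    Runs the image-only forward pass, backpropagates the pre-softmax
    class score to the chosen layer's feature maps, and applies the
    importance-pooling and ReLU-combination steps.
    """
    layer = layer or default_target_layer(model)
    if layer not in model.encoder.names:
        raise ValueError(f"unknown encoder layer {layer!r}")
    x = prepare_images(image, model.enc_cfg)
    z = model.encoder.forward(x, train=False, capture=True)
    acts = model.encoder.activation(layer)
    if acts.ndim != 4:
        raise ValueError(f"layer {layer!r} has no spatial feature maps")
    logits = model.classify(z)
    if not 0 <= target_class < logits.shape[1]:
        raise ValueError(f"target class {target_class} out of range")
    dlogits = np.zeros_like(logits)
    dlogits[0, target_class] = 1.0          # d y^c / d logits
    dz = model.classifier.backward(dlogits)
    model.encoder.backward(dz, capture_at={layer})
    grads = model.encoder.captured_grads[layer][0]     # (k, u, v)
    alpha = neuron_importance(grads)
    smap = gradcam_map(acts[0], alpha)
    H, W = x.shape[2], x.shape[3]
    up = _resize(smap, (H, W), order=1, preserve_range=True,
                 anti_aliasing=False)
    m = up.max()
    overlay = up / m if m > 0 else np.zeros_like(up)
    return SaliencyResult(smap, overlay, target_class, layer)


def lesion_hit_fraction(overlay: np.ndarray, mask: np.ndarray) -> float:
    """Fraction of total saliency mass inside the ground-truth lesion mask.

    Under a uniform map this equals the mask's area fraction, which is the
    natural chance level to compare against.
    """
    if overlay.shape != mask.shape:
        raise ValueError("overlay and mask shapes differ")
    total = overlay.sum()
    if total == 0:
        return 0.0
    return float(overlay[mask.astype(bool)].sum() / total)
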
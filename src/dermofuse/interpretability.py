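"""Gradient-weighted class activation mapping (Grad-CAM, Grad-CAM++).

Saliency is computed per branch of a fusion model (and for the merged
map of the feature-level strategies) against the model's final output
for a chosen class: the gradient of the target score with respect to a
convolutional feature map yields channel weights, and the rectified
weighted channel sum - min-max normalized to [0, 1] - is the heatmap.

Grad-CAM uses the spatial mean of the gradient per channel.  Grad-CAM++
weights each location by coefficients derived from second- and
third-power gradient terms before summing positive gradients, which
sharpens maps when several regions contribute to the class score.

By default the gradient is taken with respect to the pre-softmax score
of the target class; ``use_probability=True`` differentiates the
softmax probability instead.  For the classifier-level fusion model the
per-branch maps are differentiated against the merged output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _resize

from .fusion import FusionModel
from .nn import autodiff as ad

__all__ = ["SaliencyTarget", "SaliencyMap", "grad_cam", "grad_cam_pp",
           "saliency_overlay"]


@dataclass
class SaliencyTarget:
    """Which feature map and class to explain."""

    layer: str          # branch name, or "merged"
    class_index: int


@dataclass
class SaliencyMap:
    heatmap: np.ndarray       # (h, w) in [0, 1], feature-map resolution
    branch: str
    class_index: int
    method: str
    all_zero: bool = False    # no positive class evidence at this layer

    def upsampled(self, out_h: int, out_w: int) -> np.ndarray:
        """Bilinear upsampling to the input image size for overlays."""
        return _resize(self.heatmap, (out_h, out_w), order=1,
                       mode="edge", anti_aliasing=False)


def _forward_with_grads(model: FusionModel, image: np.ndarray,
                        target: SaliencyTarget, use_probability: bool):
    image = np.asarray(image, dtype=np.float32)
    if image.ndim != 3:
        raise ValueError("expected a single H x W x 3 image")
    res = model.forward(image[None])
    if target.layer not in res.branch_maps:
        raise KeyError(
            f"no retained layer {target.layer!r}; available: "
            f"{sorted(res.branch_maps)}")
    k = res.logits.data.shape[1]
    if not 0 <= target.class_index < k:
        raise IndexError(f"class_index {target.class_index} out of range ({k})")
    fmap = res.branch_maps[target.layer]
    if use_probability:
        # d p_c / d z = p_c * (onehot - p); seed the logit gradient directly
        p = ad.softmax(res.logits.data)[0]
        seed = (p[target.class_index]
                * (np.eye(k)[target.class_index] - p)).astype(np.float32)
    else:
        seed = np.zeros(k, dtype=np.float32)
        seed[target.class_index] = 1.0
    res.logits.grad = seed[None]
    # reverse sweep from the logits node
    topo, seen, stack = [], set(), [(res.logits, False)]
    while stack:
        node, done = stack.pop()
        if done:
            topo.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for par in node.parents:
            stack.append((par, False))
    for node in reversed(topo):
        if node.backward_fn is not None and node.grad is not None:
            node.backward_fn(node.grad)
    acts = fmap.data[0].astype(np.float64)
    grads = (fmap.grad[0] if fmap.grad is not None
             else np.zeros_like(fmap.data[0])).astype(np.float64)
    return acts, grads


def _finalize(cam: np.ndarray, branch: str, class_index: int,
              method: str) -> SaliencyMap:
    cam = np.maximum(cam, 0.0)
    peak = cam.max()
    if peak <= 0:
        return SaliencyMap(np.zeros_like(cam), branch, class_index, method,
                           all_zero=True)
    cam = (cam - cam.min()) / (peak - cam.min())
    return SaliencyMap(cam, branch, class_index, method)


def grad_cam(model: FusionModel, image: np.ndarray, target: SaliencyTarget,
             use_probability: bool = False) -> SaliencyMap:
    """Channel weights = spatial mean gradient; map = ReLU(weighted sum)."""
    acts, grads = _forward_with_grads(model, image, target, use_probability)
    weights = grads.mean(axis=(0, 1))
    cam = np.tensordot(acts, weights, axes=([2], [0]))
    return _finalize(cam, target.layer, target.class_index, "grad_cam")


def gradcampp_alpha(acts: np.ndarray, grads: np.ndarray) -> np.ndarray:
    """Per-location Grad-CAM++ coefficients.

    Raw coefficients are ``g^2 / (2 g^2 + sum_spatial(A * g^3))`` with a
    zero-division guard; they are then renormalized per channel over the
    positive-gradient locations so that each channel's coefficients sum
    to 1 (locations with non-positive gradient carry no weight).
    """
    g2 = grads ** 2
    g3 = grads ** 3
    denom = 2.0 * g2 + (acts * g3).sum(axis=(0, 1), keepdims=True)
    alpha = np.where(np.abs(denom) > 1e-12,
                     g2 / np.where(denom == 0, 1.0, denom), 0.0)
    alpha = np.where(grads > 0, alpha, 0.0)
    total = alpha.sum(axis=(0, 1), keepdims=True)
    return np.where(total > 0, alpha / np.where(total == 0, 1.0, total), 0.0)


def grad_cam_pp(model: FusionModel, image: np.ndarray, target: SaliencyTarget,
                use_probability: bool = False) -> SaliencyMap:
    """Grad-CAM++: channel weights = sum_location alpha * ReLU(g), with
    alpha from :func:`gradcampp_alpha`."""
    acts, grads = _forward_with_grads(model, image, target, use_probability)
    alpha = gradcampp_alpha(acts, grads)
    weights = (alpha * np.maximum(grads, 0.0)).sum(axis=(0, 1))
    cam = np.tensordot(acts, weights, axes=([2], [0]))
    return _finalize(cam, target.layer, target.class_index, "grad_cam_pp")


def saliency_overlay(image: np.ndarray, smap: SaliencyMap,
                     alpha: float = 0.4, cmap: str = "jet") -> np.ndarray:
    """Blend a heatmap over the input image; returns an RGB array in [0, 1].

    The colormap is fixed per call for reproducible renders.
    """
    import matplotlib

    image = np.asarray(image, dtype=np.float64)
    if image.max() > 1.0:
        image = image / 255.0
    h, w = image.shape[:2]
    heat = smap.upsampled(h, w)
    colored = matplotlib.colormaps[cmap](heat)[..., :3]
    return np.clip((1 - alpha) * image + alpha * colored, 0.0, 1.0)
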
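"""Gradient-weighted class-activation mapping for the regression networks.

For a chosen output, the gradient of that output with respect to the final
convolutional activations is spatially averaged into per-channel weights;
the ReLU-rectified weighted sum of the activation channels, bilinearly
upsampled to the input size and min-max normalized, localizes the regions
driving the prediction.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .models import _RegressorNet

__all__ = ["gradcam"]


def gradcam(model: _RegressorNet, image: np.ndarray, output_index: int = 0) -> np.ndarray:
    """Grad-CAM heat map in [0, 1] with the same shape as the input image.

    Parameters
    ----------
    model
        A network built by :func:`paiq.nn.build_model`.
    image
        2D array (H, W) already normalized the way the model was trained.
    output_index
        Which output head to explain (0 for single-output models).
    """
    x = np.asarray(image, dtype=np.float32)
    if x.ndim != 2:
        raise ValueError("gradcam expects a single 2D image")
    batch = x[None, :, :, None]

    target = model.final_conv_index
    h = batch
    activations = None
    for i, layer in enumerate(model.layers):
        h = layer.forward(h, training=False)
        if i == target:
            activations = h
    out = h
    n_outputs = out.shape[1]
    if not (0 <= output_index < n_outputs):
        raise IndexError(f"output_index {output_index} out of range ({n_outputs} outputs)")

    grad = np.zeros_like(out)
    grad[0, output_index] = 1.0
    grad_at_target = None
    for i in range(len(model.layers) - 1, -1, -1):
        if i == target:
            grad_at_target = grad
            break
        grad = model.layers[i].backward(grad)

    weights = grad_at_target.mean(axis=(1, 2))[0]  # (C,)
    cam = np.maximum((activations[0] * weights).sum(axis=-1), 0.0)
    if cam.max() <= 0:
        warnings.warn("Grad-CAM map is all zero for this input/output")
        return np.zeros_like(x, dtype=np.float64)
    zoom = (x.shape[0] / cam.shape[0], x.shape[1] / cam.shape[1])
    cam_up = ndimage.zoom(cam.astype(np.float64), zoom, order=1)
    cam_up = cam_up[: x.shape[0], : x.shape[1]]
    cam_up = cam_up - cam_up.min()
    mx = cam_up.max()
    return cam_up / mx if mx > 0 else cam_up
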
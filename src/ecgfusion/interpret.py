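"""Gradient-weighted class activation mapping (Grad-CAM) and overlays.

Grad-CAM backpropagates the target class score to a convolutional feature
map, global-average-pools the gradients into channel importance weights,
forms the rectified weighted sum of the feature maps, upsamples it to the
input spatial size and max-normalizes. Convolutional backbones use their
last convolution by default; for the ViT the patch-embedding grid (8x8 for
128x128 inputs at patch 16) is used, an approximation since attention blocks
after it are not spatially localized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from . import nn
from .ecg_io import ValidationError
from .models import EcgClassifier


@dataclass
class Heatmap:
    """Non-negative class-evidence map at input spatial resolution."""

    values: np.ndarray
    target_class: int
    layer_name: str = ""


def grad_cam(
    model: EcgClassifier,
    image: np.ndarray,
    target_class: int,
    handcrafted: np.ndarray | None = None,
    layer: nn.Conv2d | None = None,
) -> Heatmap:
    """Class-discriminative heatmap for one input image.

    ``layer`` must be a convolutional module of the model; defaults to the
    backbone's designated CAM layer. The model is run in evaluation mode so
    the map is deterministic.
    """
    layer = layer or model.backbone.cam_layer
    if not isinstance(layer, nn.Conv2d):
        raise ValidationError("Grad-CAM requires a convolutional layer")
    model.eval()
    layer.retain_output = True
    try:
        logits = model.forward(image, handcrafted)
        onehot = np.zeros(logits.shape, dtype=np.float32)
        onehot[:, target_class] = 1.0
        logits.backward(onehot)
        act = layer.last_output
        if act is None or act.grad is None:
            raise ValidationError("target layer did not participate in the forward pass")
        fmap = act.data[0]                      # (C, h, w)
        grads = act.grad[0]
        weights = grads.mean(axis=(1, 2))       # GAP of gradients per channel
    finally:
        layer.retain_output = False
        layer.last_output = None
    cam = np.maximum((weights[:, None, None] * fmap).sum(axis=0), 0.0)
    h, w = model.config.image_size[:2]
    cam = resize(cam.astype(np.float64), (h, w), order=1, mode="edge",
                 anti_aliasing=False, preserve_range=True)
    cam = np.maximum(cam, 0.0)
    peak = cam.max()
    if peak > 0:
        cam = cam / peak
    return Heatmap(values=cam, target_class=target_class,
                   layer_name=type(layer).__name__)


def heatmap_to_signal(heatmap: Heatmap, signal_length: int) -> np.ndarray:
    """Back-project the heatmap onto a 1-D trace timeline.

    Column j of the (time-axis-aligned) map covers sample range
    [j*L/W, (j+1)*L/W); each sample gets its column's maximum map value.
    """
    col = heatmap.values.max(axis=0)           # (W,)
    w = col.size
    j = (np.arange(signal_length) * w // signal_length).clip(0, w - 1)
    return col[j]


def overlay(
    base: np.ndarray,
    heatmap: Heatmap,
    path,
    alpha: float = 0.4,
    signal: np.ndarray | None = None,
) -> None:
    """Render the heatmap over a scalogram image (or a 1-D trace) to a file.

    An all-zero heatmap leaves the base image visually unmodified. When
    ``signal`` is given, the map is back-projected onto the trace timeline
    and drawn as red shading under the waveform.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    base = np.asarray(base)
    if signal is None and base.shape[:2] != heatmap.values.shape:
        raise ValidationError(
            f"heatmap {heatmap.values.shape} does not match image {base.shape[:2]}"
        )
    fig, ax = plt.subplots(figsize=(6, 3))
    if signal is not None:
        weight = heatmap_to_signal(heatmap, signal.size)
        ax.plot(signal, color="black", linewidth=0.7)
        ax.fill_between(np.arange(signal.size),
                        signal.min(), signal.max(),
                        where=weight > 0.5, color="red", alpha=alpha)
    else:
        ax.imshow(np.clip(base, 0, 1))
        if heatmap.values.max() > 0:
            ax.imshow(heatmap.values, cmap="jet", alpha=alpha * heatmap.values)
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight", dpi=100)
    plt.close(fig)
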
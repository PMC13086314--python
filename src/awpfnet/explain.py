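"""Grad-CAM visual explanations.

Channel importance for a target class is the spatial mean of that
class-logit's gradient with respect to a feature map (by default the
fused pyramid output; optionally the raw backbone feature, for
comparing how fusion sharpens localisation).  The heatmap is the
ReLU of the importance-weighted channel sum, bilinearly upsampled to
the input size and min-max normalised to [0, 1].
"""

from __future__ import annotations

import numpy as np

from . import nn
from .awpf import AWPFResNet18
from .nn.conv import upsample_bilinear


def grad_cam(model: AWPFResNet18, image: np.ndarray, class_index: int,
             target: str = "fused") -> np.ndarray:
    """Heatmap (H, W) in [0, 1] for one image (3, H, W) and one class."""
    image = np.asarray(image, dtype=np.float32)
    if image.ndim == 3:
        image = image[None]
    if image.shape[0] != 1:
        raise ValueError("grad_cam explains a single image")
    num_classes = model.head.fc.bias.shape[0]
    if not 0 <= class_index < num_classes:
        raise ValueError(f"class_index {class_index} out of range "
                         f"[0, {num_classes})")

    model.eval()
    model.capture_features = True
    try:
        logits = model(nn.Tensor(image))
        fmap = model.captured_features[target].data
        onehot = np.zeros(logits.shape, dtype=np.float32)
        onehot[0, class_index] = 1.0
        logits.backward(onehot)
    finally:
        model.capture_features = False

    grads = fmap.grad                      # (1, C, h, w)
    acts = fmap.numpy()
    weights = grads.mean(axis=(2, 3))      # spatial mean of the gradient
    cam = np.maximum((weights[:, :, None, None] * acts).sum(axis=1), 0.0)
    cam_t = upsample_bilinear(nn.Tensor(cam[:, None]), image.shape[2:])
    cam = cam_t.numpy()[0, 0]
    lo, hi = cam.min(), cam.max()
    if hi > lo:
        cam = (cam - lo) / (hi - lo)
    return cam.astype(np.float32)


def channel_weights(model: AWPFResNet18, image: np.ndarray,
                    class_index: int, target: str = "fused") -> np.ndarray:
    """The Grad-CAM channel-importance vector (gradient spatial means)."""
    image = np.asarray(image, dtype=np.float32)
    if image.ndim == 3:
        image = image[None]
    model.eval()
    model.capture_features = True
    try:
        logits = model(nn.Tensor(image))
        fmap = model.captured_features[target].data
        onehot = np.zeros(logits.shape, dtype=np.float32)
        onehot[0, class_index] = 1.0
        logits.backward(onehot)
    finally:
        model.capture_features = False
    return fmap.grad.mean(axis=(2, 3))[0]


def save_heatmap_png(cam: np.ndarray, image: np.ndarray, path,
                     alpha: float = 0.45) -> None:
    """Overlay a [0,1] heatmap on the (3, H, W) image and write a PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    img = np.asarray(image)
    if img.ndim == 4:
        img = img[0]
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(img.transpose(1, 2, 0))
    ax.imshow(cam, cmap="jet", alpha=alpha)
    ax.axis("off")
    fig.tight_layout(pad=0)
    fig.savefig(path, dpi=120)
    plt.close(fig)
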
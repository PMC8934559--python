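"""Class activation maps, vertical-bias analysis, noise robustness and
the inversion test."""

from __future__ import annotations

import numpy as np
import pandas as pd
from skimage.transform import resize

from . import nn
from .classifiers import CNNModel, accuracy, labels_to_binary
from .features.colorhist import intensity_plane
from .hyperopt import human_correlation_objective
from .synthetic import IMAGE_SIZE

CLASS_INDEX = {"glass": 0, "mirror": 1}


def _gap_featuremaps_and_weights(model: CNNModel, images: np.ndarray):
    """Forward up to the global-average-pooling stage; return the final
    convolutional feature maps (n, h, w, c) and the class read-out
    weight matrix (c, 2)."""
    if model.spec.head != "gap":
        raise ValueError(
            "class activation mapping requires the global-average-pooled "
            "('gap') head; rebuild the model with CNNSpec(head='gap')"
        )
    x = model._to_input(images)
    gap_idx = next(
        i for i, layer in enumerate(model.net.layers) if isinstance(layer, nn.GlobalAvgPool)
    )
    for layer in model.net.layers[:gap_idx]:
        x = layer.forward(x, train=False)
    dense = next(
        layer for layer in model.net.layers[gap_idx:] if isinstance(layer, nn.Dense)
    )
    return x, dense.W


def compute_cam(model: CNNModel, image: np.ndarray, cls: str = "mirror") -> np.ndarray:
    """64x64 class activation map: the class-weighted sum of the final
    convolutional feature maps, bilinearly upsampled."""
    if cls not in CLASS_INDEX:
        raise ValueError(f"class must be 'mirror' or 'glass', got {cls!r}")
    maps, W = _gap_featuremaps_and_weights(model, image[None])
    cam = maps[0] @ W[:, CLASS_INDEX[cls]]
    return resize(cam, (IMAGE_SIZE, IMAGE_SIZE), order=1, mode="edge",
                  anti_aliasing=False, preserve_range=True)


def compute_cams(model: CNNModel, images: np.ndarray, cls: str = "mirror",
                 batch: int = 128) -> np.ndarray:
    """Vectorized :func:`compute_cam` over a stack of images."""
    if cls not in CLASS_INDEX:
        raise ValueError(f"class must be 'mirror' or 'glass', got {cls!r}")
    out = []
    for i in range(0, images.shape[0], batch):
        maps, W = _gap_featuremaps_and_weights(model, images[i : i + batch])
        cams = maps @ W[:, CLASS_INDEX[cls]]
        for cam in cams:
            out.append(
                resize(cam, (IMAGE_SIZE, IMAGE_SIZE), order=1, mode="edge",
                       anti_aliasing=False, preserve_range=True)
            )
    return np.stack(out)


def class_mean_cam_difference(
    model: CNNModel, images: np.ndarray, labels
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean mirror-class CAM, mean glass-class CAM (grouped by true
    label) and their difference (mirror - glass)."""
    y = labels_to_binary(labels)
    if (y == 1).sum() < 1 or (y == 0).sum() < 1:
        raise ValueError("need at least one image per class")
    mirror_maps = compute_cams(model, images[y == 1], cls="mirror")
    glass_maps = compute_cams(model, images[y == 0], cls="glass")
    mean_mirror = mirror_maps.mean(axis=0)
    mean_glass = glass_maps.mean(axis=0)
    return mean_mirror, mean_glass, mean_mirror - mean_glass


def vertical_profile(map2d: np.ndarray) -> np.ndarray:
    """Row means, top row first."""
    m = np.asarray(map2d, dtype=float)
    if m.ndim != 2:
        raise ValueError(f"expected a 2-D map, got shape {m.shape}")
    return m.mean(axis=1)


def pixel_intensity_difference_profile(images: np.ndarray, labels) -> np.ndarray:
    """Vertical profile of mean mirror-image intensity minus mean
    glass-image intensity."""
    y = labels_to_binary(labels)
    inten = np.stack([intensity_plane(im) for im in images])
    diff = inten[y == 1].mean(axis=0) - inten[y == 0].mean(axis=0)
    return vertical_profile(diff)


def profile_correlation(profile_a: np.ndarray, profile_b: np.ndarray) -> float:
    """Pearson correlation between two vertical profiles."""
    a = np.asarray(profile_a, dtype=float).ravel()
    b = np.asarray(profile_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("profiles have different lengths")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance profile")
    return float(np.corrcoef(a, b)[0, 1])


def noise_robustness_curve(
    model,
    images: np.ndarray,
    reference_ratings: np.ndarray,
    sigmas=(1e-3, 1e-2, 1e-1, 1e0),
    n_reps: int = 3,
    seed=0,
) -> pd.DataFrame:
    """Correlation with reference ratings under additive Gaussian pixel
    noise (per channel, clipped to [0, 1]), averaged over noise draws.

    Returns a table with columns sigma, r, mc_sd.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for sigma in sigmas:
        rs = []
        for _ in range(n_reps):
            if sigma > 0:
                noisy = np.clip(images + rng.normal(0.0, sigma, images.shape), 0.0, 1.0)
            else:
                noisy = images
            rs.append(human_correlation_objective(model.predict_score(noisy),
                                                  reference_ratings))
        rs = np.asarray(rs)
        rows.append({"sigma": float(sigma), "r": float(rs.mean()),
                     "mc_sd": float(rs.std(ddof=1)) if n_reps > 1 else 0.0})
    return pd.DataFrame(rows)


def flip_vertical(images: np.ndarray) -> np.ndarray:
    """Reverse the row order of (n, H, W, C) or (H, W, C) images."""
    axis = 0 if images.ndim == 3 else 1
    return np.flip(images, axis=axis).copy()


def inversion_test(model, images: np.ndarray, labels) -> tuple[float, float, float]:
    """(accuracy upright, accuracy vertically flipped, delta)."""
    acc_up = accuracy(model.predict_score(images), labels)
    acc_flip = accuracy(model.predict_score(flip_vertical(images)), labels)
    return acc_up, acc_flip, acc_up - acc_flip


def log_sigma_grid(lo: float = 1e-3, hi: float = 1.0, n_between: int = 5) -> np.ndarray:
    """Log-spaced sigma grid covering the four canonical decades plus
    intermediate points."""
    return np.logspace(np.log10(lo), np.log10(hi), 4 + n_between)


__all__ = [
    "class_mean_cam_difference",
    "compute_cam",
    "compute_cams",
    "flip_vertical",
    "inversion_test",
    "log_sigma_grid",
    "noise_robustness_curve",
    "pixel_intensity_difference_profile",
    "profile_correlation",
    "vertical_profile",
]
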
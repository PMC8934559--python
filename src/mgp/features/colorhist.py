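"""Eight-moment color-histogram features.

Mean, variance, skewness and excess kurtosis of the intensity plane
followed by the same four moments of the saturation plane.  Intensity is
the channel mean (R+G+B)/3; saturation is HSV-style (max-min)/max with 0
where max=0.  Zero-variance planes yield skewness 0 and kurtosis 0 by
convention.
"""

from __future__ import annotations

import numpy as np

COLORHIST_NAMES = (
    "intensity_mean",
    "intensity_var",
    "intensity_skew",
    "intensity_kurt",
    "saturation_mean",
    "saturation_var",
    "saturation_skew",
    "saturation_kurt",
)


def intensity_plane(pixels: np.ndarray) -> np.ndarray:
    return pixels.mean(axis=-1)


def saturation_plane(pixels: np.ndarray) -> np.ndarray:
    mx = pixels.max(axis=-1)
    mn = pixels.min(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        sat = np.where(mx > 0, (mx - mn) / mx, 0.0)
    return sat


def _moments(plane: np.ndarray) -> list[float]:
    x = plane.ravel().astype(np.float64)
    mean = x.mean()
    var = x.var()  # population variance
    if var <= 0:
        return [float(mean), 0.0, 0.0, 0.0]
    z = (x - mean) / np.sqrt(var)
    skew = float((z**3).mean())
    kurt = float((z**4).mean() - 3.0)  # excess kurtosis, normal -> 0
    return [float(mean), float(var), skew, kurt]


def colorhist_features(pixels: np.ndarray) -> np.ndarray:
    """8-vector of intensity then saturation moments for a 64x64x3 image."""
    if pixels.ndim != 3 or pixels.shape[-1] != 3:
        raise ValueError(f"expected (H, W, 3) image, got shape {pixels.shape}")
    values = _moments(intensity_plane(pixels)) + _moments(saturation_plane(pixels))
    return np.asarray(values, dtype=np.float64)
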
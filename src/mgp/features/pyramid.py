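"""Complex steerable pyramid, implemented in the frequency domain.

Full-resolution variant: every band is kept at the input resolution and
scale selectivity comes entirely from the radial frequency masks, so all
statistics downstream are exactly invariant to circular shifts of the
input.  Radial masks are raised-cosine in log2 frequency with
H(r)^2 + L(r)^2 = 1; angular masks follow the standard cos^(O-1)
steerable construction with a single lobe (analytic bands).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial

import numpy as np


def _log_rad_angle(size: int) -> tuple[np.ndarray, np.ndarray]:
    f = np.fft.fftshift(np.fft.fftfreq(size)) * 2.0  # in [-1, 1)
    fx, fy = np.meshgrid(f, f)
    rad = np.sqrt(fx**2 + fy**2)
    rad[size // 2, size // 2] = rad[size // 2, size // 2 - 1]  # avoid log(0)
    log_rad = np.log2(rad)
    angle = np.arctan2(fy, fx)
    return log_rad, angle


def _hi_mask(log_rad: np.ndarray) -> np.ndarray:
    """1 above log_rad 0, 0 below -1, raised-cosine between."""
    t = np.clip(log_rad, -1.0, 0.0)
    return np.sin((np.pi / 2.0) * (t + 1.0))


def _lo_mask(log_rad: np.ndarray) -> np.ndarray:
    t = np.clip(log_rad, -1.0, 0.0)
    return np.cos((np.pi / 2.0) * (t + 1.0))


def _angle_masks(angle: np.ndarray, n_orientations: int) -> list[np.ndarray]:
    o = n_orientations
    const = (2.0 ** (o - 1)) * factorial(o - 1) / np.sqrt(o * factorial(2 * (o - 1)))
    masks = []
    for b in range(o):
        theta = np.mod(angle - np.pi * b / o + np.pi, 2 * np.pi) - np.pi
        m = 2.0 * const * (np.cos(theta) ** (o - 1)) * (np.abs(theta) < np.pi / 2)
        masks.append(m)
    return masks


@dataclass(frozen=True)
class SteerablePyramid:
    """Decomposition of one grayscale image.

    highpass:  real residual above the top radial band
    bands:     bands[s][o], complex analytic band at scale s (fine->coarse)
    lowpass:   progressively blurred real images, lowpass[s] for
               s = 0..n_scales (lowpass[0] only removes the highpass)
    """

    highpass: np.ndarray
    bands: list[list[np.ndarray]]
    lowpass: list[np.ndarray]


def build_pyramid(image: np.ndarray, n_scales: int, n_orientations: int) -> SteerablePyramid:
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError(f"expected square 2-D image, got shape {image.shape}")
    size = image.shape[0]
    if size < 2 ** (n_scales + 2):
        raise ValueError(
            f"image of size {size} too small for {n_scales} scales "
            f"(needs >= {2 ** (n_scales + 2)})"
        )
    log_rad, angle = _log_rad_angle(size)
    fft = np.fft.fftshift(np.fft.fft2(image.astype(np.float64)))

    hi0 = _hi_mask(log_rad)
    lo0 = _lo_mask(log_rad)
    highpass = np.real(np.fft.ifft2(np.fft.ifftshift(fft * hi0)))

    amasks = _angle_masks(angle, n_orientations)
    bands: list[list[np.ndarray]] = []
    lowpass: list[np.ndarray] = []
    lo_accum = lo0.copy()
    lodft = fft * lo0
    for s in range(n_scales):
        lowpass.append(np.real(np.fft.ifft2(np.fft.ifftshift(fft * lo_accum))))
        hmask = _hi_mask(log_rad + s)
        scale_bands = []
        for am in amasks:
            banddft = lodft * hmask * am * ((-1j) ** (n_orientations - 1))
            scale_bands.append(np.fft.ifft2(np.fft.ifftshift(banddft)))
        bands.append(scale_bands)
        lmask = _lo_mask(log_rad + s)
        lo_accum = lo_accum * lmask
        lodft = lodft * lmask
    lowpass.append(np.real(np.fft.ifft2(np.fft.ifftshift(fft * lo_accum))))
    return SteerablePyramid(highpass=highpass, bands=bands, lowpass=lowpass)
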
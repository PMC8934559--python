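"""Texture-statistic feature vector from a steerable-pyramid decomposition.

Statistic families, concatenated in this fixed order (S = n_scales,
O = n_orientations, N = neighborhood):

1. pixel marginals of the intensity plane: mean, var, skew, kurt, min,
   max                                                     -> 6
2. skewness and kurtosis of each progressive lowpass image -> 2*(S+1)
3. central N x N circular autocorrelation of each lowpass  -> N^2*(S+1)
4. central N x N circular autocorrelation of each band
   magnitude (centered)                                    -> N^2*S*O
5. band magnitude means                                    -> S*O
6. highpass residual variance                              -> 1
7. within-scale magnitude covariance, upper triangle with
   diagonal                                                -> S*O*(O+1)/2
8. cross-scale magnitude covariance, adjacent scale pairs  -> (S-1)*O^2
9. phase statistics: correlation of the fine band's real part with the
   real and imaginary parts of the phase-doubled coarser band, same
   orientation                                             -> (S-1)*2*O

The vector length is a closed-form function of the config only
(:func:`texture_feature_length`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .colorhist import intensity_plane
from .pyramid import build_pyramid


@dataclass(frozen=True)
class PyramidConfig:
    n_scales: int = 3
    n_orientations: int = 4
    neighborhood: int = 5

    def __post_init__(self) -> None:
        if self.n_scales < 1 or self.n_orientations < 1:
            raise ValueError("n_scales and n_orientations must be >= 1")
        if self.neighborhood < 1 or self.neighborhood % 2 == 0:
            raise ValueError("neighborhood must be a positive odd integer")


def texture_feature_length(config: PyramidConfig) -> int:
    """Closed-form length of the texture feature vector."""
    s, o, n = config.n_scales, config.n_orientations, config.neighborhood
    return (
        6
        + 2 * (s + 1)
        + n * n * (s + 1)
        + n * n * s * o
        + s * o
        + 1
        + s * o * (o + 1) // 2
        + (s - 1) * o * o
        + (s - 1) * 2 * o
    )


def _autocorr_window(x: np.ndarray, n: int) -> np.ndarray:
    """Central n x n window of the variance-normalized circular
    autocorrelation of ``x`` (flattened, row-major over offsets)."""
    xc = x - x.mean()
    var = (xc**2).mean()
    f = np.fft.fft2(xc)
    ac = np.real(np.fft.ifft2(f * np.conj(f))) / x.size
    if var > 0:
        ac = ac / var
    h = n // 2
    ac = np.roll(ac, (h, h), axis=(0, 1))
    return ac[: 2 * h + 1, : 2 * h + 1].ravel()


def _skew_kurt(x: np.ndarray) -> tuple[float, float]:
    xc = x - x.mean()
    var = (xc**2).mean()
    if var <= 0:
        return 0.0, 0.0
    z = xc / np.sqrt(var)
    return float((z**3).mean()), float((z**4).mean() - 3.0)


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    ac = a - a.mean()
    bc = b - b.mean()
    denom = np.sqrt((ac**2).mean() * (bc**2).mean())
    if denom <= 0:
        return 0.0
    return float((ac * bc).mean() / denom)


def texture_features(
    pixels: np.ndarray, config: PyramidConfig | None = None
) -> tuple[np.ndarray, list[str]]:
    """Texture statistics of the intensity plane of an RGB image.

    Returns ``(values, names)`` with ``len(values)`` equal to
    :func:`texture_feature_length`.
    """
    config = config or PyramidConfig()
    if pixels.ndim == 3:
        gray = intensity_plane(pixels)
    elif pixels.ndim == 2:
        gray = pixels
    else:
        raise ValueError(f"expected 2-D or (H, W, 3) image, got shape {pixels.shape}")

    s, o, n = config.n_scales, config.n_orientations, config.neighborhood
    pyr = build_pyramid(gray, s, o)

    values: list[float] = []
    names: list[str] = []

    def emit(name: str, val: float) -> None:
        names.append(name)
        values.append(float(val))

    # 1. pixel marginals
    g = gray.ravel()
    skew, kurt = _skew_kurt(g)
    for name, v in zip(
        ("mean", "var", "skew", "kurt", "min", "max"),
        (g.mean(), g.var(), skew, kurt, g.min(), g.max()),
    ):
        emit(f"pix_{name}", v)

    # 2. lowpass skew/kurt
    for i, lp in enumerate(pyr.lowpass):
        sk, ku = _skew_kurt(lp.ravel())
        emit(f"lp{i}_skew", sk)
        emit(f"lp{i}_kurt", ku)

    # 3. lowpass autocorrelations
    for i, lp in enumerate(pyr.lowpass):
        for j, v in enumerate(_autocorr_window(lp, n)):
            emit(f"lp{i}_ac{j}", v)

    mags = [[np.abs(b) for b in scale] for scale in pyr.bands]

    # 4. magnitude autocorrelations
    for si, scale in enumerate(mags):
        for oi, m in enumerate(scale):
            for j, v in enumerate(_autocorr_window(m, n)):
                emit(f"mag_s{si}o{oi}_ac{j}", v)

    # 5. magnitude means
    for si, scale in enumerate(mags):
        for oi, m in enumerate(scale):
            emit(f"mag_s{si}o{oi}_mean", m.mean())

    # 6. highpass variance
    emit("highpass_var", pyr.highpass.var())

    # 7. within-scale magnitude covariance (upper triangle incl. diagonal)
    for si, scale in enumerate(mags):
        centered = [m - m.mean() for m in scale]
        for i in range(o):
            for j in range(i, o):
                emit(f"xori_s{si}_o{i}o{j}", (centered[i] * centered[j]).mean())

    # 8. cross-scale magnitude covariance (fine scale si vs si+1)
    for si in range(s - 1):
        fine = [m - m.mean() for m in mags[si]]
        coarse = [m - m.mean() for m in mags[si + 1]]
        for i in range(o):
            for j in range(o):
                emit(f"xscl_s{si}_o{i}o{j}", (fine[i] * coarse[j]).mean())

    # 9. phase statistics: real(fine) vs phase-doubled coarse band
    for si in range(s - 1):
        for oi in range(o):
            fine = np.real(pyr.bands[si][oi])
            c = pyr.bands[si + 1][oi]
            mag = np.abs(c)
            with np.errstate(divide="ignore", invalid="ignore"):
                unit = np.where(mag > 0, c / np.where(mag > 0, mag, 1.0), 0.0)
            doubled = mag * unit**2
            emit(f"phase_s{si}o{oi}_re", _corr(fine, np.real(doubled)))
            emit(f"phase_s{si}o{oi}_im", _corr(fine, np.imag(doubled)))

    out = np.asarray(values, dtype=np.float64)
    assert out.size == texture_feature_length(config)
    return out, names
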
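"""Synthetic stimuli and simulated observers.

Stimuli are 64x64 RGB noise textures whose class-conditional statistics
are controlled by a latent appearance parameter ``a`` in [0, 1]
(0 = fully glass-like, 1 = fully mirror-like).  Appearance drives a
small set of planted cues: a vertical luminance gradient (top brighter
for mirror-like images), a global contrast multiplier, a saturation
offset, and optionally a second-order vertical contrast-energy gradient.

Observers are simulated as latent-evidence raters: the rating is the
fifth-of-[0,1] bin containing ``a`` plus Gaussian noise, with a lapse
probability of responding uniformly at random.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

IMAGE_SIZE = 64

CLASS_LABELS = ("mirror", "glass", "amb_mirror", "amb_glass")
RENDER_CLASSES = ("mirror", "glass")
AMBIGUOUS_CLASSES = ("amb_mirror", "amb_glass")

RATING_LEVELS = (1, 2, 3, 4, 5)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CueGains:
    """Gains of the planted appearance cues.

    gradient:          signed vertical luminance gradient magnitude
    contrast:          global contrast multiplier gain
    saturation:        saturation offset gain
    luminance:         uniform mean-luminance offset gain (mirror-like
                       images slightly brighter overall)
    energy_gradient:   second-order cue; vertical gradient of texture
                       contrast (amplitude), requiring rectification +
                       pooling to read out
    top_luminance:     one-sided cue: brightening of the upper half of
                       mirror-like images only (sky reflection)
    bottom_saturation: one-sided cue: saturation boost in the lower half
                       of glass-like images only (refracted ground)
    """

    gradient: float = 0.25
    contrast: float = 0.2
    saturation: float = 0.2
    luminance: float = 0.05
    energy_gradient: float = 0.0
    top_luminance: float = 0.0
    bottom_saturation: float = 0.0


@dataclass(frozen=True)
class StimulusSpec:
    """Latent description of one stimulus."""

    image_id: str
    class_label: str
    a: float
    texture_seed: int
    conflict: bool = False
    recog_p: float = 1.0

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.class_label!r}")
        if not 0.0 <= self.a <= 1.0:
            raise ValueError(f"appearance a={self.a} outside [0, 1]")
        if not 0.0 <= self.recog_p <= 1.0:
            raise ValueError("recog_p outside [0, 1]")
        if self.conflict and self.class_label in RENDER_CLASSES:
            looks_mirror = self.a >= 0.5
            if (self.class_label == "mirror") == looks_mirror:
                raise ValueError(
                    "conflict=True but label and appearance agree "
                    f"({self.class_label}, a={self.a})"
                )

    @property
    def true_class(self) -> str:
        """Binary ground-truth class (ambiguous images inherit their
        generator's class, e.g. amb_mirror -> mirror)."""
        return "mirror" if self.class_label in ("mirror", "amb_mirror") else "glass"


@dataclass(frozen=True)
class StimulusImage:
    spec: StimulusSpec
    pixels: np.ndarray  # (64, 64, 3) float64 in [0, 1]


@dataclass(frozen=True)
class ObserverProfile:
    observer_id: str
    rating_noise_sd: float = 0.05
    lapse_rate: float = 0.0
    p_hard: float = 0.0
    p_recog_slope: float = 1.0

    def __post_init__(self) -> None:
        if self.rating_noise_sd < 0:
            raise ValueError("rating_noise_sd must be >= 0")
        for name in ("lapse_rate", "p_hard"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} outside [0, 1]")


# ---------------------------------------------------------------------------
# Stimulus generation
# ---------------------------------------------------------------------------

def _base_texture(texture_seed: int, size: int = IMAGE_SIZE) -> tuple[np.ndarray, np.ndarray]:
    """Band-pass filtered noise (luminance) and a zero-intensity chroma field."""
    rng = np.random.default_rng(texture_seed)
    noise = rng.standard_normal((size, size))
    band = gaussian_filter(noise, 1.0, mode="wrap") - gaussian_filter(noise, 4.0, mode="wrap")
    band = band / max(band.std(), 1e-12)

    chroma_noise = rng.standard_normal((size, size, 3))
    chroma = np.stack(
        [gaussian_filter(chroma_noise[..., k], 3.0, mode="wrap") for k in range(3)], axis=-1
    )
    # remove the intensity component so chroma only perturbs hue/saturation
    chroma = chroma - chroma.mean(axis=-1, keepdims=True)
    cstd = max(chroma.std(), 1e-12)
    chroma = chroma / cstd
    return band, chroma


def generate_stimulus(
    spec: StimulusSpec,
    gains: CueGains | None = None,
    base_amplitude: float = 0.12,
    chroma_amplitude: float = 0.06,
) -> StimulusImage:
    """Render the stimulus for ``spec``.

    The appearance parameter drives every cue through m = 2a - 1;
    conflicting labels do not alter the image (cues follow ``a``).
    Deterministic: identical specs give bit-identical pixel grids.
    """
    gains = gains or CueGains()
    band, chroma = _base_texture(spec.texture_seed)
    m = 2.0 * spec.a - 1.0
    size = band.shape[0]

    # +0.5 at the top row, -0.5 at the bottom row
    ramp = np.linspace(0.5, -0.5, size)[:, None]

    amp = base_amplitude * (1.0 + gains.energy_gradient * m * 2.0 * ramp)
    img = 0.5 + (amp * band)[..., None] + chroma_amplitude * chroma

    img = 0.5 + (img - 0.5) * (1.0 + gains.contrast * m)

    sat_factor = 1.0 + gains.saturation * m
    if gains.bottom_saturation:
        sat_factor = sat_factor + (
            gains.bottom_saturation * max(-m, 0.0) * 2.0 * np.maximum(-ramp, 0.0)
        )
    lum = img.mean(axis=-1, keepdims=True)
    img = lum + (img - lum) * sat_factor

    img = img + (gains.gradient * m * ramp)[..., None] + gains.luminance * m
    if gains.top_luminance:
        img = img + (gains.top_luminance * max(m, 0.0) * 2.0 * np.maximum(ramp, 0.0))[..., None]

    return StimulusImage(spec=spec, pixels=np.clip(img, 0.0, 1.0))


# default appearance distributions per class; ambiguous classes draw from
# a mid-range band standing in for the GAN images' intermediate appearance
DEFAULT_CLASS_MIX: dict[str, tuple] = {
    "mirror": ("uniform", 0.55, 1.0),
    "glass": ("uniform", 0.0, 0.45),
    "amb_mirror": ("uniform", 0.3, 0.7),
    "amb_glass": ("uniform", 0.3, 0.7),
}


def _draw_appearance(dist: tuple, rng: np.random.Generator) -> float:
    kind = dist[0]
    if kind == "uniform":
        return float(rng.uniform(dist[1], dist[2]))
    if kind == "beta":
        return float(rng.beta(dist[1], dist[2]))
    if kind == "fixed":
        return float(dist[1])
    raise ValueError(f"invalid class_mix distribution {dist!r}")


def generate_specs(
    n_per_class: int,
    class_mix: dict[str, tuple] | None = None,
    master_seed: int = 0,
) -> list[StimulusSpec]:
    """Draw balanced stimulus specs; pure function of (config, seed)."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    mix = class_mix if class_mix is not None else DEFAULT_CLASS_MIX
    for label in mix:
        if label not in CLASS_LABELS:
            raise ValueError(f"invalid class_mix label {label!r}")
    rng = np.random.default_rng(master_seed)
    specs: list[StimulusSpec] = []
    for label in sorted(mix):
        for i in range(n_per_class):
            a = _draw_appearance(mix[label], rng)
            seed = int(rng.integers(0, 2**31 - 1))
            conflict = label in RENDER_CLASSES and (
                (label == "mirror") != (a >= 0.5)
            )
            specs.append(
                StimulusSpec(
                    image_id=f"{label}_{i:06d}",
                    class_label=label,
                    a=a,
                    texture_seed=seed,
                    conflict=conflict,
                )
            )
    return specs


def specs_to_manifest(specs: list[StimulusSpec], master_seed: int | None = None) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "image_id": [s.image_id for s in specs],
            "class_label": [s.class_label for s in specs],
            "true_class": [s.true_class for s in specs],
            "a": [s.a for s in specs],
            "conflict": [s.conflict for s in specs],
            "texture_seed": [s.texture_seed for s in specs],
            "recog_p": [s.recog_p for s in specs],
        }
    )
    if master_seed is not None:
        df["master_seed"] = master_seed
    return df


def generate_dataset(
    n_per_class: int,
    class_mix: dict[str, tuple] | None = None,
    master_seed: int = 0,
    gains: CueGains | None = None,
) -> tuple[list[StimulusImage], pd.DataFrame]:
    """Balanced rendered dataset plus its manifest."""
    specs = generate_specs(n_per_class, class_mix, master_seed)
    images = [generate_stimulus(s, gains) for s in specs]
    return images, specs_to_manifest(specs, master_seed)


def render_specs(specs: list[StimulusSpec], gains: CueGains | None = None) -> np.ndarray:
    """Stack rendered pixels as an (n, 64, 64, 3) array."""
    return np.stack([generate_stimulus(s, gains).pixels for s in specs])


# ---------------------------------------------------------------------------
# Observer simulation
# ---------------------------------------------------------------------------

def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def rating_bin(x: float) -> int:
    """Fifth-of-[0,1] bin: k with x in [(k-1)/5, k/5), 1.0 -> 5."""
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"value {x} outside [0, 1]")
    return min(int(x * 5) + 1, 5)


def simulate_rating(a: float, obs: ObserverProfile, seed) -> int:
    """One 5-point rating: binned a + Gaussian noise, with lapses."""
    if not 0.0 <= a <= 1.0:
        raise ValueError("a outside [0, 1]")
    rng = _as_rng(seed)
    if obs.lapse_rate > 0 and rng.random() < obs.lapse_rate:
        return int(rng.integers(1, 6))
    x = a + (rng.normal(0.0, obs.rating_noise_sd) if obs.rating_noise_sd > 0 else 0.0)
    return rating_bin(min(max(x, 0.0), 1.0))


def simulate_threeway(a: float, obs: ObserverProfile, seed) -> str:
    """Three-way judgment: 'hard' with prob p_hard, else threshold at 0.5
    (boundary assigned to mirror)."""
    if not 0.0 <= a <= 1.0:
        raise ValueError("a outside [0, 1]")
    rng = _as_rng(seed)
    if obs.p_hard > 0 and rng.random() < obs.p_hard:
        return "hard"
    x = a + (rng.normal(0.0, obs.rating_noise_sd) if obs.rating_noise_sd > 0 else 0.0)
    return "mirror" if x >= 0.5 else "glass"


def simulate_recognizability(spec: StimulusSpec, obs: ObserverProfile, seed) -> bool:
    """Binary recognizability vote from the spec's planted probability."""
    rng = _as_rng(seed)
    p = 0.5 + obs.p_recog_slope * (spec.recog_p - 0.5)
    p = min(max(p, 0.0), 1.0)
    return bool(rng.random() < p)


def simulate_rating_table(
    specs: list[StimulusSpec],
    observers: list[ObserverProfile],
    n_trials: int = 1,
    seed=0,
) -> pd.DataFrame:
    """Full crossing of specs x observers x trials, as ResponseRecords."""
    rng = _as_rng(seed)
    rows = []
    trial = 0
    for t in range(n_trials):
        for obs in observers:
            for s in specs:
                rows.append(
                    (s.image_id, obs.observer_id, "rating5",
                     simulate_rating(s.a, obs, rng), trial)
                )
                trial += 1
    return pd.DataFrame(
        rows, columns=["image_id", "observer_id", "task", "value", "trial_index"]
    )


def simulate_threeway_table(
    specs: list[StimulusSpec],
    observers: list[ObserverProfile],
    seed=0,
) -> pd.DataFrame:
    rng = _as_rng(seed)
    rows = []
    trial = 0
    for obs in observers:
        for s in specs:
            rows.append(
                (s.image_id, s.true_class, obs.observer_id, "threeway",
                 simulate_threeway(s.a, obs, rng), trial)
            )
            trial += 1
    return pd.DataFrame(
        rows,
        columns=["image_id", "true_class", "observer_id", "task", "value", "trial_index"],
    )


def simulate_recognizability_table(
    specs: list[StimulusSpec],
    observers: list[ObserverProfile],
    seed=0,
) -> pd.DataFrame:
    rng = _as_rng(seed)
    rows = []
    trial = 0
    for obs in observers:
        for s in specs:
            rows.append(
                (s.image_id, obs.observer_id, "recog",
                 int(simulate_recognizability(s, obs, rng)), trial)
            )
            trial += 1
    return pd.DataFrame(
        rows, columns=["image_id", "observer_id", "task", "value", "trial_index"]
    )


def _catch_specs(n_catch: int) -> list[StimulusSpec]:
    """Extreme-appearance catch stimuli, alternating mirror/glass."""
    specs = []
    for i in range(n_catch):
        mirror = i % 2 == 0
        specs.append(
            StimulusSpec(
                image_id=f"catch_{i:03d}",
                class_label="mirror" if mirror else "glass",
                a=1.0 if mirror else 0.0,
                texture_seed=10_000_000 + i,
            )
        )
    return specs


def simulate_crowd_session(
    images: list[StimulusSpec],
    workers: list[ObserverProfile],
    n_per_worker: int = 100,
    n_catch: int = 2,
    seed=0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Crowdsourced rating session with catch-trial based rejection.

    Each worker rates ``n_per_worker - n_catch`` test images drawn
    uniformly without replacement, plus ``n_catch`` extreme catch
    stimuli.  A catch passes iff the binary class of the rating
    (ratings 1-2 = glass, 3-5 = mirror) matches the catch ground truth;
    a worker failing any catch is flagged rejected and their test
    ratings carry accepted=False.

    Returns (response table, worker status table).
    """
    n_test = n_per_worker - n_catch
    if len(images) < n_test:
        raise ValueError(
            f"need at least {n_test} images for {n_per_worker} trials "
            f"with {n_catch} catches; got {len(images)}"
        )
    rng = _as_rng(seed)
    catches = _catch_specs(n_catch)
    records, status = [], []
    for w in workers:
        accepted = True
        for c in catches:
            k = simulate_rating(c.a, w, rng)
            rated_mirror = (k - 1) / 4 >= 0.5
            if rated_mirror != (c.class_label == "mirror"):
                accepted = False
        chosen = rng.choice(len(images), size=n_test, replace=False)
        for t, idx in enumerate(chosen):
            s = images[int(idx)]
            records.append(
                (s.image_id, s.true_class, w.observer_id, "rating5",
                 simulate_rating(s.a, w, rng), t, accepted)
            )
        status.append((w.observer_id, accepted))
    responses = pd.DataFrame(
        records,
        columns=["image_id", "true_class", "observer_id", "task", "value",
                 "trial_index", "accepted"],
    )
    worker_status = pd.DataFrame(status, columns=["observer_id", "accepted"])
    return responses, worker_status


def make_observers(
    n: int,
    rating_noise_sd: float = 0.05,
    lapse_rate: float = 0.0,
    p_hard: float = 0.0,
    prefix: str = "obs",
) -> list[ObserverProfile]:
    return [
        ObserverProfile(
            observer_id=f"{prefix}{i:03d}",
            rating_noise_sd=rating_noise_sd,
            lapse_rate=lapse_rate,
            p_hard=p_hard,
        )
        for i in range(n)
    ]


__all__ = [
    "AMBIGUOUS_CLASSES",
    "CLASS_LABELS",
    "CueGains",
    "DEFAULT_CLASS_MIX",
    "IMAGE_SIZE",
    "ObserverProfile",
    "RENDER_CLASSES",
    "StimulusImage",
    "StimulusSpec",
    "generate_dataset",
    "generate_specs",
    "generate_stimulus",
    "make_observers",
    "rating_bin",
    "render_specs",
    "simulate_crowd_session",
    "simulate_rating",
    "simulate_rating_table",
    "simulate_recognizability",
    "simulate_recognizability_table",
    "simulate_threeway",
    "simulate_threeway_table",
    "specs_to_manifest",
]
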
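"""Reference simulation scenarios.

Builders that populate simulated response tables at the published
per-round quotas (so the selection rules reproduce the printed counts),
plus a desk-scale end-to-end run of the whole diagnostic pipeline on
simulated observers.  Both the acceptance report and the test suite
drive the pipeline exclusively through these entry points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import diagnostic as dg
from . import synthetic as syn

# published per-round quotas
A1_QUOTA = 2744            # per cell -> 10,976 total
A2_CONFLICTS = 261         # per class -> 522 total
A3_CONFLICTS = 51          # per class -> 102 total
B1_KEPT = 500              # of 1,400 ambiguous images
B2_QUOTA = 19              # per bin -> 95 total
VERIDICAL_N = 68
RENDER_PER_BIN = 34        # -> 170 renderings
FINAL_N = 265


def _specs(label: str, a_values, start: int, rng: np.random.Generator,
           prefix: str = "", recog_p: float = 1.0) -> list[syn.StimulusSpec]:
    out = []
    for i, a in enumerate(a_values):
        a = float(np.clip(a, 0.0, 1.0))
        conflict = label in syn.RENDER_CLASSES and ((label == "mirror") != (a >= 0.5))
        out.append(
            syn.StimulusSpec(
                image_id=f"{prefix}{label}_{start + i:06d}",
                class_label=label,
                a=a,
                texture_seed=int(rng.integers(0, 2**31 - 1)),
                conflict=conflict,
                recog_p=recog_p,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Round-count scenarios (targets t1-t7)
# ---------------------------------------------------------------------------

def scenario_round_a1(seed: int = 0, n_images: int = 30_000,
                      quota: int = A1_QUOTA) -> int:
    """Three-way judgments for ``n_images`` renderings whose appearance
    distributions populate all four true-by-judged cells; returns the
    Round A1 selection count."""
    rng = np.random.default_rng(seed)
    half = n_images // 2
    specs = _specs("mirror", rng.uniform(0.2, 1.0, half), 0, rng, prefix="a1_")
    specs += _specs("glass", rng.uniform(0.0, 0.8, half), 0, rng, prefix="a1_")
    observers = syn.make_observers(3, rating_noise_sd=0.05, p_hard=0.029, prefix="a1obs")
    table = syn.simulate_threeway_table(specs, observers, seed=rng)
    selected = dg.round_a1_select(table, quota_per_bin=quota, seed=rng)
    return len(selected)


def scenario_round_a2(seed: int = 0, n_conflicts: int = A2_CONFLICTS,
                      n_filler: int = 78, n_workers: int = 120) -> int:
    """Crowd session over a pool planted with ``n_conflicts`` mirror and
    glass conflict images each; returns the Round A2 selection count."""
    rng = np.random.default_rng(seed)
    specs = _specs("mirror", rng.uniform(0.05, 0.15, n_conflicts), 0, rng, prefix="a2_")
    specs += _specs("glass", rng.uniform(0.85, 0.95, n_conflicts), 0, rng, prefix="a2_")
    specs += _specs("mirror", rng.uniform(0.88, 0.97, n_filler // 2), n_conflicts, rng,
                    prefix="a2_")
    specs += _specs("glass", rng.uniform(0.03, 0.12, n_filler // 2), n_conflicts, rng,
                    prefix="a2_")
    workers = [
        syn.ObserverProfile(f"wrk{i:03d}", rating_noise_sd=0.03, lapse_rate=0.0)
        for i in range(n_workers)
    ]
    responses, _ = syn.simulate_crowd_session(specs, workers, seed=rng)
    mirror_ids, glass_ids = dg.round_a2_select(responses, min_ratings=3)
    return len(mirror_ids) + len(glass_ids)


def scenario_round_a3(seed: int = 0, n_conflicts: int = A3_CONFLICTS,
                      n_candidates: int = 522) -> int:
    """Lab re-rating of a Round-A2-sized candidate list planted with
    ``n_conflicts`` per class in the selection ranges; returns the Round
    A3 selection count."""
    rng = np.random.default_rng(seed)
    n_verid = (n_candidates - 2 * n_conflicts) // 2
    specs = _specs("mirror", rng.uniform(0.1, 0.3, n_conflicts), 0, rng, prefix="a3_")
    specs += _specs("glass", rng.uniform(0.7, 0.9, n_conflicts), 0, rng, prefix="a3_")
    specs += _specs("mirror", rng.uniform(0.88, 0.97, n_verid), n_conflicts, rng, prefix="a3_")
    specs += _specs("glass", rng.uniform(0.03, 0.12, n_verid), n_conflicts, rng, prefix="a3_")
    observers = syn.make_observers(10, rating_noise_sd=0.05, prefix="a3obs")
    table = syn.simulate_rating_table(specs, observers, n_trials=3, seed=rng)
    table = table.merge(
        pd.DataFrame({"image_id": [s.image_id for s in specs],
                      "true_class": [s.true_class for s in specs]}),
        on="image_id",
    )
    return len(dg.round_a3_select(table))


def scenario_round_b1(seed: int = 0, n_images: int = 1400,
                      n_recognizable: int = B1_KEPT) -> int:
    """Recognizability votes for ``n_images`` ambiguous images with
    planted vote probabilities; returns the Round B1 keep count."""
    rng = np.random.default_rng(seed)
    a = rng.uniform(0.3, 0.7, n_images)
    specs = []
    for i in range(n_images):
        label = "amb_mirror" if i % 2 == 0 else "amb_glass"
        specs.append(
            syn.StimulusSpec(
                image_id=f"b1_gan_{i:06d}",
                class_label=label,
                a=float(a[i]),
                texture_seed=int(rng.integers(0, 2**31 - 1)),
                recog_p=1.0 if i < n_recognizable else 0.0,
            )
        )
    observers = syn.make_observers(10, prefix="b1obs")
    table = syn.simulate_recognizability_table(specs, observers, seed=rng)
    return len(dg.round_b1_select(table, min_votes=6, n_observers=10))


def scenario_round_b2(seed: int = 0, n_images: int = 500,
                      quota: int = B2_QUOTA) -> int:
    """Consistent 10-observer ratings spread over all five bins;
    returns the Round B2 selection count."""
    rng = np.random.default_rng(seed)
    centers = [0.1, 0.3, 0.5, 0.7, 0.9]
    specs = []
    for i in range(n_images):
        label = "amb_mirror" if i % 2 == 0 else "amb_glass"
        specs.append(
            syn.StimulusSpec(
                image_id=f"b2_gan_{i:06d}",
                class_label=label,
                a=centers[i % 5],
                texture_seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    observers = syn.make_observers(10, rating_noise_sd=0.0, prefix="b2obs")
    table = syn.simulate_rating_table(specs, observers, seed=rng)
    return len(dg.round_b2_select(table, per_bin_quota=quota, seed=rng))


def scenario_assembly(seed: int = 0, render_per_bin_per_class: int = 17,
                      amb_per_bin: int = B2_QUOTA) -> dg.DiagnosticSet:
    """Assemble a diagnostic set from component lists at the published
    sizes (68 veridical / 102 illusory / 95 ambiguous by default)."""
    rng = np.random.default_rng(seed)
    centers = [0.1, 0.3, 0.5, 0.7, 0.9]
    specs: list[syn.StimulusSpec] = []
    counter = 0
    for label in ("mirror", "glass"):
        for b, c in enumerate(centers):
            specs += _specs(label, [c] * render_per_bin_per_class, counter, rng, prefix="fin_")
            counter += render_per_bin_per_class
    for b, c in enumerate(centers):
        for label in ("amb_mirror", "amb_glass"):
            n = amb_per_bin // 2 + (amb_per_bin % 2 if label == "amb_mirror" else 0)
            specs += _specs(label, [c] * n, counter, rng, prefix="fin_")
            counter += n
    observers = syn.make_observers(10, rating_noise_sd=0.0, prefix="finobs")
    table = syn.simulate_rating_table(specs, observers, seed=rng)
    table = table.merge(
        pd.DataFrame({"image_id": [s.image_id for s in specs],
                      "true_class": [s.true_class for s in specs],
                      "class_label": [s.class_label for s in specs]}),
        on="image_id",
    )
    summaries = dg.summarize_ratings(table)

    spec_by_id = {s.image_id: s for s in specs}
    veridical, illusory, ambiguous = [], [], []
    for _, row in summaries.iterrows():
        s = spec_by_id[row["image_id"]]
        if s.class_label in syn.AMBIGUOUS_CLASSES:
            ambiguous.append(s.image_id)
        elif (s.class_label == "mirror" and row["bin"] >= 4) or (
            s.class_label == "glass" and row["bin"] <= 2
        ):
            veridical.append(s.image_id)
        else:
            illusory.append(s.image_id)
    return dg.assemble_diagnostic(veridical, illusory, ambiguous, summaries)


# ---------------------------------------------------------------------------
# Desk-scale end-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EndToEndConfig:
    """Scaled-down quotas for a full pipeline run on simulated observers."""

    n_exp1_per_class: int = 1000
    n_a1_per_class: int = 2000
    a1_quota: int = 250
    crowd_coverage: float = 4.5  # mean accepted ratings per image in A2
    n_amb_images: int = 600
    final_per_bin_render: int = 8   # per class per bin
    final_per_bin_amb: int = 8
    rating_noise_sd: float = 0.05
    crowd_noise_sd: float = 0.08
    p_hard: float = 0.029
    # appearance mixtures: (weight, low, high) components
    mirror_mix: tuple = ((0.42, 0.6, 1.0), (0.28, 0.0, 0.4), (0.3, 0.34, 0.52))
    amb_range: tuple = (0.0, 1.0)


def _mixture(rng: np.random.Generator, n: int, components) -> np.ndarray:
    weights = np.array([c[0] for c in components])
    weights = weights / weights.sum()
    which = rng.choice(len(components), size=n, p=weights)
    lo = np.array([components[k][1] for k in which])
    hi = np.array([components[k][2] for k in which])
    return rng.uniform(lo, hi)


def run_end_to_end(seed: int = 0, config: EndToEndConfig | None = None) -> dict:
    """Run Experiment-1 simulation, rounds A1-A3 and B1-B2, and assemble
    a flat, decorrelated diagnostic set.  Returns all intermediate
    artifacts keyed by stage."""
    cfg = config or EndToEndConfig()
    rng = np.random.default_rng(seed)
    out: dict = {"config": cfg, "seed": seed}

    # --- Experiment 1: random renderings, 10 observers, 5-point ratings
    exp1_specs = _specs("mirror", _mixture(rng, cfg.n_exp1_per_class,
                                           ((0.8, 0.55, 1.0), (0.2, 0.0, 0.45))), 0, rng,
                        prefix="e1_")
    exp1_specs += _specs("glass", 1.0 - _mixture(rng, cfg.n_exp1_per_class,
                                                 ((0.8, 0.55, 1.0), (0.2, 0.0, 0.45))), 0, rng,
                         prefix="e1_")
    lab = syn.make_observers(10, rating_noise_sd=cfg.rating_noise_sd, prefix="lab")
    exp1_table = syn.simulate_rating_table(exp1_specs, lab, seed=rng)
    exp1_table = exp1_table.merge(
        syn.specs_to_manifest(exp1_specs)[["image_id", "true_class"]], on="image_id"
    )
    exp1_summary = dg.summarize_ratings(exp1_table)
    out["exp1_specs"] = exp1_specs
    out["exp1_summary"] = exp1_summary

    # veridical pool: consistent images whose bin matches ground truth
    verid = exp1_summary[exp1_summary["consistent"]]
    verid_pool = verid[
        ((verid["true_class"] == "mirror") & (verid["bin"] >= 4))
        | ((verid["true_class"] == "glass") & (verid["bin"] <= 2))
    ]
    out["veridical_pool"] = verid_pool

    # --- Round A1: fresh renderings, three-way judgment
    a1_specs = _specs("mirror", _mixture(rng, cfg.n_a1_per_class, cfg.mirror_mix), 0, rng,
                      prefix="p_")
    a1_specs += _specs("glass", 1.0 - _mixture(rng, cfg.n_a1_per_class, cfg.mirror_mix), 0,
                       rng, prefix="p_")
    a1_observers = syn.make_observers(3, rating_noise_sd=cfg.rating_noise_sd,
                                      p_hard=cfg.p_hard, prefix="a1")
    a1_table = syn.simulate_threeway_table(a1_specs, a1_observers, seed=rng)
    a1_ids = dg.round_a1_select(a1_table, quota_per_bin=cfg.a1_quota, seed=rng)
    out["a1_ids"] = a1_ids

    # --- Round A2: crowdsourced ratings with catch trials
    spec_by_id = {s.image_id: s for s in a1_specs}
    a1_selected = [spec_by_id[i] for i in a1_ids]
    n_workers = max(5, int(np.ceil(cfg.crowd_coverage * len(a1_selected) / 98)))
    workers = [
        syn.ObserverProfile(f"cw{i:03d}", rating_noise_sd=cfg.crowd_noise_sd,
                            lapse_rate=0.02)
        for i in range(n_workers)
    ]
    crowd, worker_status = syn.simulate_crowd_session(a1_selected, workers, seed=rng)
    mirror_conf, glass_conf = dg.round_a2_select(crowd, min_ratings=3)
    out["a2_ids"] = mirror_conf + glass_conf
    out["worker_status"] = worker_status

    # --- Round A3: lab confirmation, 3 trials x 10 observers
    a3_specs = [spec_by_id[i] for i in out["a2_ids"]]
    a3_lab = syn.make_observers(10, rating_noise_sd=cfg.rating_noise_sd, prefix="a3")
    a3_table = syn.simulate_rating_table(a3_specs, a3_lab, n_trials=3, seed=rng)
    a3_table = a3_table.merge(
        syn.specs_to_manifest(a3_specs)[["image_id", "true_class"]], on="image_id"
    )
    illusory_ids = dg.round_a3_select(a3_table)
    a3_summary = dg.summarize_ratings(a3_table)
    out["a3_summary"] = a3_summary
    out["illusory_ids"] = illusory_ids

    # --- Rounds B1-B2: ambiguous images
    amb_a = rng.uniform(*cfg.amb_range, cfg.n_amb_images)
    amb_specs = []
    for i in range(cfg.n_amb_images):
        label = "amb_mirror" if i % 2 == 0 else "amb_glass"
        amb_specs.append(
            syn.StimulusSpec(
                image_id=f"gan_{i:06d}", class_label=label, a=float(amb_a[i]),
                texture_seed=int(rng.integers(0, 2**31 - 1)),
                recog_p=float(rng.uniform(0.55, 1.0)) if rng.random() < 0.8 else
                float(rng.uniform(0.0, 0.4)),
            )
        )
    b1_lab = syn.make_observers(10, prefix="b1")
    b1_table = syn.simulate_recognizability_table(amb_specs, b1_lab, seed=rng)
    b1_ids = dg.round_b1_select(b1_table)
    out["b1_ids"] = b1_ids

    amb_by_id = {s.image_id: s for s in amb_specs}
    b2_specs = [amb_by_id[i] for i in b1_ids]
    b2_lab = syn.make_observers(10, rating_noise_sd=cfg.rating_noise_sd, prefix="b2")
    b2_table = syn.simulate_rating_table(b2_specs, b2_lab, n_trials=3, seed=rng)
    b2_table = b2_table.merge(
        syn.specs_to_manifest(b2_specs)[["image_id", "true_class"]], on="image_id"
    )
    b2_summary = dg.summarize_ratings(b2_table)
    amb_sel = dg.round_b2_select(b2_table, per_bin_quota=cfg.final_per_bin_amb, seed=rng)
    out["b2_summary"] = b2_summary
    out["ambiguous_ids"] = amb_sel

    # --- Flat assembly
    per_bin = cfg.final_per_bin_render
    verid_sum = verid_pool.copy()
    ill_sum = a3_summary[a3_summary["image_id"].isin(illusory_ids)]
    veridical_sel, illusory_sel = [], []
    for cls, vbins, ibins in (("mirror", (4, 5), (1, 2, 3)), ("glass", (1, 2), (3, 4, 5))):
        for b in vbins:
            pool = np.sort(verid_sum[(verid_sum["true_class"] == cls)
                                     & (verid_sum["bin"] == b)]["image_id"].to_numpy())
            if len(pool) < per_bin:
                raise ValueError(f"veridical cell ({cls}, bin {b}) underfull: {len(pool)}")
            veridical_sel.extend(rng.choice(pool, size=per_bin, replace=False))
        for b in ibins:
            pool = np.sort(ill_sum[(ill_sum["true_class"] == cls)
                                   & (ill_sum["bin"] == b)]["image_id"].to_numpy())
            if len(pool) < per_bin:
                raise ValueError(f"illusory cell ({cls}, bin {b}) underfull: {len(pool)}")
            illusory_sel.extend(rng.choice(pool, size=per_bin, replace=False))

    summaries = pd.concat([verid_sum, ill_sum, b2_summary], ignore_index=True)
    diag = dg.assemble_diagnostic(
        [str(v) for v in veridical_sel],
        [str(v) for v in illusory_sel],
        amb_sel,
        summaries,
    )
    out["diagnostic"] = diag
    out["all_specs"] = {**spec_by_id, **amb_by_id,
                        **{s.image_id: s for s in exp1_specs}}
    return out


def make_midlevel_evaluator(seed: int = 0, n_train_per_class: int = 100,
                            n_diag_per_class: int = 30, max_epochs: int = 6):
    """Evaluator for depth-wise searches on data whose only class cue is
    the second-order vertical contrast-energy gradient (a mid-level cue
    that shallow single-layer read-outs struggle with)."""
    from .hyperopt import Evaluator

    gains = syn.CueGains(gradient=0.0, contrast=0.0, saturation=0.0, luminance=0.0,
                         energy_gradient=0.5)
    train_mix = {"mirror": ("uniform", 0.55, 1.0), "glass": ("uniform", 0.0, 0.45)}
    diag_mix = {"mirror": ("uniform", 0.3, 1.0), "glass": ("uniform", 0.0, 0.7)}
    train_specs = syn.generate_specs(n_train_per_class, train_mix, seed)
    diag_specs = [
        syn.StimulusSpec("d_" + s.image_id, s.class_label, s.a, s.texture_seed, s.conflict)
        for s in syn.generate_specs(n_diag_per_class, diag_mix, seed + 1000)
    ]
    observers = syn.make_observers(10, rating_noise_sd=0.05)
    ratings = syn.simulate_rating_table(diag_specs, observers, seed=seed + 2000)
    summary = dg.summarize_ratings(ratings).set_index("image_id")
    diag_ids = [s.image_id for s in diag_specs]
    return Evaluator(
        train_images=syn.render_specs(train_specs, gains),
        train_labels=np.array([s.true_class for s in train_specs]),
        train_ids=[s.image_id for s in train_specs],
        diag_images=syn.render_specs(diag_specs, gains),
        diag_ratings=summary.loc[diag_ids, "mean_norm_rating"].to_numpy(),
        diag_ids=diag_ids,
        max_epochs=max_epochs,
    )


__all__ = [
    "A1_QUOTA",
    "A2_CONFLICTS",
    "A3_CONFLICTS",
    "B1_KEPT",
    "B2_QUOTA",
    "EndToEndConfig",
    "FINAL_N",
    "RENDER_PER_BIN",
    "make_midlevel_evaluator",
    "VERIDICAL_N",
    "run_end_to_end",
    "scenario_assembly",
    "scenario_round_a1",
    "scenario_round_a2",
    "scenario_round_a3",
    "scenario_round_b1",
    "scenario_round_b2",
]
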
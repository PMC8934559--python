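"""Multi-round diagnostic image-set construction.

Ratings on the 5-point scale are normalized to [0, 1] as (k - 1) / 4 and
averaged per image; bin membership uses fifths of [0, 1], half-open
[(k-1)/5, k/5) with the last bin closed at 1.0.  The rounds progressively
filter simulated responses: A1 (three-way judgment, per-cell quota
sampling), A2 (crowdsourced conflict selection), A3 (lab conflict
confirmation), B1 (recognizability screen), B2 (per-bin quota among
consistent images); the assembled set must have exactly flat per-class
bin counts, decorrelating perceived from true class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import rating_bin

N_BINS = 5


def normalize_rating(k) -> np.ndarray:
    """5-point rating -> [0, 1] as (k - 1) / 4."""
    k = np.asarray(k, dtype=float)
    if np.any((k < 1) | (k > 5)):
        raise ValueError("ratings must lie in 1..5")
    return (k - 1.0) / 4.0


def bin_of(value: float) -> int:
    """Fifths of [0, 1]: k with value in [(k-1)/5, k/5), 1.0 -> 5."""
    return rating_bin(float(value))


def summarize_ratings(ratings: pd.DataFrame) -> pd.DataFrame:
    """Per-image RatingSummary table.

    ``ratings`` needs columns image_id, observer_id, value (1..5);
    optional true_class is carried through.  ``consistent`` is True iff
    the image has >= 2 ratings and every observer's mean rating (over
    their trials) falls in the same bin.
    """
    norm = normalize_rating(ratings["value"].to_numpy())
    df = ratings.assign(_norm=norm)
    per_obs = (
        df.groupby(["image_id", "observer_id"], sort=True)["_norm"].mean().reset_index()
    )
    per_obs["_bin"] = [bin_of(v) for v in per_obs["_norm"]]
    bins_used = per_obs.groupby("image_id")["_bin"].nunique()
    grouped = df.groupby("image_id", sort=True)
    out = grouped.agg(
        n_ratings=("_norm", "size"),
        mean_norm_rating=("_norm", "mean"),
    ).reset_index()
    out["n_bins_used"] = bins_used.reindex(out["image_id"]).to_numpy()
    out["bin"] = [bin_of(v) for v in out["mean_norm_rating"]]
    out["consistent"] = (out["n_ratings"] >= 2) & (out["n_bins_used"] == 1)
    out = out.drop(columns="n_bins_used")
    if "true_class" in ratings.columns:
        cls = grouped["true_class"].first().reset_index(drop=True)
        out["true_class"] = cls
    return out


def consistency_filter(per_observer_bins: np.ndarray, n_required: int = 10) -> np.ndarray:
    """True per image iff all ``n_required`` observers used one bin.

    ``per_observer_bins``: (n_images, n_observers) integer bins.
    """
    bins = np.asarray(per_observer_bins)
    if bins.ndim != 2 or bins.shape[1] != n_required:
        raise ValueError(f"expected exactly {n_required} observers per image")
    return (bins == bins[:, :1]).all(axis=1)


# ---------------------------------------------------------------------------
# Round A1: three-way judgment, per-cell quota
# ---------------------------------------------------------------------------

def round_a1_select(
    threeway_table: pd.DataFrame, quota_per_bin: int, seed=0
) -> list[str]:
    """Quota-sample the four true-class x majority-judged-class cells.

    Images whose majority judgment is "hard" are excluded first.  Each
    cell must hold at least ``quota_per_bin`` images.
    """
    if quota_per_bin < 0:
        raise ValueError("quota_per_bin must be >= 0")
    if quota_per_bin == 0:
        return []
    rng = np.random.default_rng(seed)

    def majority(values: pd.Series) -> str:
        counts = values.value_counts()
        top = counts[counts == counts.max()].index.tolist()
        for pref in ("hard", "mirror", "glass"):  # deterministic tie-break
            if pref in top:
                return pref
        return top[0]

    per_image = (
        threeway_table.groupby("image_id")
        .agg(true_class=("true_class", "first"), judged=("value", majority))
        .reset_index()
    )
    per_image = per_image[per_image["judged"] != "hard"]
    selected: list[str] = []
    for true_cls in ("mirror", "glass"):
        for judged in ("mirror", "glass"):
            cell = per_image[
                (per_image["true_class"] == true_cls) & (per_image["judged"] == judged)
            ]["image_id"].to_numpy()
            if len(cell) < quota_per_bin:
                raise ValueError(
                    f"cell (true={true_cls}, judged={judged}) holds {len(cell)} "
                    f"images, fewer than the quota of {quota_per_bin}"
                )
            cell = np.sort(cell)
            selected.extend(rng.choice(cell, size=quota_per_bin, replace=False))
    return [str(s) for s in selected]


# ---------------------------------------------------------------------------
# Round A2: crowdsourced conflict selection
# ---------------------------------------------------------------------------

def round_a2_select(
    crowd_responses: pd.DataFrame, min_ratings: int = 3
) -> tuple[list[str], list[str]]:
    """Conflict images from accepted crowd ratings.

    Images rated by fewer than ``min_ratings`` accepted workers are
    dropped; mirror images with mean normalized rating in [0, 0.4) and
    glass images with mean in [0.6, 1.0] are returned as
    (mirror_conflicts, glass_conflicts).
    """
    df = crowd_responses
    if "accepted" in df.columns:
        df = df[df["accepted"]]
    summary = summarize_ratings(df)
    summary = summary[summary["n_ratings"] >= min_ratings]
    m = summary["mean_norm_rating"].to_numpy()
    mirror = summary[(summary["true_class"] == "mirror") & (m >= 0.0) & (m < 0.4)]
    glass = summary[(summary["true_class"] == "glass") & (m >= 0.6) & (m <= 1.0)]
    return sorted(mirror["image_id"]), sorted(glass["image_id"])


# ---------------------------------------------------------------------------
# Round A3: lab conflict confirmation
# ---------------------------------------------------------------------------

def round_a3_select(
    lab_ratings: pd.DataFrame, n_trials: int = 3, n_observers: int = 10
) -> list[str]:
    """Illusory images: mirror with mean rating in [0, 0.6), glass with
    mean in [0.4, 1.0].  Every candidate must carry exactly
    n_trials x n_observers ratings."""
    counts = lab_ratings.groupby("image_id").size()
    expected = n_trials * n_observers
    bad = counts[counts != expected]
    if len(bad):
        raise ValueError(
            f"{len(bad)} image(s) lack the required {expected} ratings "
            f"(e.g. {bad.index[0]!r} has {bad.iloc[0]})"
        )
    summary = summarize_ratings(lab_ratings)
    m = summary["mean_norm_rating"].to_numpy()
    mirror = summary[(summary["true_class"] == "mirror") & (m < 0.6)]
    glass = summary[(summary["true_class"] == "glass") & (m >= 0.4) & (m <= 1.0)]
    return sorted(pd.concat([mirror, glass])["image_id"])


# ---------------------------------------------------------------------------
# Round B1: recognizability screen
# ---------------------------------------------------------------------------

def round_b1_select(
    recog_table: pd.DataFrame, min_votes: int = 6, n_observers: int = 10
) -> list[str]:
    """Keep images judged recognizable by at least ``min_votes`` of
    exactly ``n_observers`` voters."""
    counts = recog_table.groupby("image_id")["value"].agg(["size", "sum"])
    bad = counts[counts["size"] != n_observers]
    if len(bad):
        raise ValueError(
            f"{len(bad)} image(s) do not have exactly {n_observers} votes"
        )
    keep = counts[counts["sum"] >= min_votes]
    return sorted(keep.index)


# ---------------------------------------------------------------------------
# Round B2: per-bin quota among consistent images
# ---------------------------------------------------------------------------

def round_b2_select(
    ratings: pd.DataFrame, per_bin_quota: int = 19, seed=0
) -> list[str]:
    """Uniformly sample ``per_bin_quota`` images per bin among those
    passing the consistency criterion."""
    if per_bin_quota == 0:
        return []
    summary = summarize_ratings(ratings)
    summary = summary[summary["consistent"]]
    rng = np.random.default_rng(seed)
    selected: list[str] = []
    for b in range(1, N_BINS + 1):
        pool = np.sort(summary[summary["bin"] == b]["image_id"].to_numpy())
        if len(pool) < per_bin_quota:
            raise ValueError(
                f"bin {b} holds {len(pool)} consistent images, fewer than "
                f"the quota of {per_bin_quota}"
            )
        selected.extend(rng.choice(pool, size=per_bin_quota, replace=False))
    return [str(s) for s in selected]


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiagnosticSet:
    members: pd.DataFrame  # image_id, component, true_class, bin, mean_norm_rating
    bin_counts: pd.DataFrame  # class x bin count table
    decorrelation_r: float

    def __len__(self) -> int:
        return len(self.members)


def select_flat(
    summaries: pd.DataFrame, per_bin: int, classes: list[str], seed=0
) -> list[str]:
    """Helper: sample ``per_bin`` images per (class, bin) cell so the
    resulting pool is exactly flat across bins for every class."""
    rng = np.random.default_rng(seed)
    out: list[str] = []
    for cls in classes:
        for b in range(1, N_BINS + 1):
            pool = np.sort(
                summaries[
                    (summaries["true_class"] == cls) & (summaries["bin"] == b)
                ]["image_id"].to_numpy()
            )
            if len(pool) < per_bin:
                raise ValueError(
                    f"cell (class={cls}, bin={b}) holds {len(pool)} images, "
                    f"fewer than {per_bin}"
                )
            out.extend(rng.choice(pool, size=per_bin, replace=False))
    return [str(s) for s in out]


def assemble_diagnostic(
    veridical_ids: list[str],
    illusory_ids: list[str],
    ambiguous_ids: list[str],
    summaries: pd.DataFrame,
    decorrelation_tolerance: float = 0.1,
) -> DiagnosticSet:
    """Assemble the diagnostic set and certify flatness/decorrelation.

    ``summaries`` must cover every member id with columns image_id,
    true_class, bin, mean_norm_rating.  Flatness (equal bin counts) is
    asserted separately for mirror renderings, glass renderings and the
    ambiguous component; decorrelation_r is the Pearson correlation
    between binary true class and mean rating over renderings only.
    """
    sets = [set(veridical_ids), set(illusory_ids), set(ambiguous_ids)]
    if sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2]:
        raise ValueError("component lists must be disjoint")
    component = (
        [(i, "veridical") for i in veridical_ids]
        + [(i, "illusory") for i in illusory_ids]
        + [(i, "ambiguous") for i in ambiguous_ids]
    )
    comp_df = pd.DataFrame(component, columns=["image_id", "component"])
    members = comp_df.merge(
        summaries[["image_id", "true_class", "bin", "mean_norm_rating"]],
        on="image_id",
        how="left",
        validate="one_to_one",
    )
    if members["true_class"].isna().any():
        missing = members[members["true_class"].isna()]["image_id"].iloc[0]
        raise ValueError(f"no rating summary for member {missing!r}")

    rendering = members["component"] != "ambiguous"
    members["group"] = np.where(rendering, members["true_class"], "ambiguous")
    counts = (
        members.groupby(["group", "bin"]).size().unstack(fill_value=0)
        .reindex(columns=range(1, N_BINS + 1), fill_value=0)
    )
    for group, row in counts.iterrows():
        if row.nunique() != 1:
            raise ValueError(
                f"flat-distribution violation for {group!r}; counts per bin:\n{counts}"
            )

    rend = members[rendering]
    truth = (rend["true_class"] == "mirror").astype(float).to_numpy()
    ratings = rend["mean_norm_rating"].to_numpy()
    if truth.std() == 0 or ratings.std() == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(truth, ratings)[0, 1])
    if abs(r) > decorrelation_tolerance:
        raise ValueError(
            f"|decorrelation_r| = {abs(r):.3f} exceeds tolerance {decorrelation_tolerance}"
        )
    return DiagnosticSet(
        members=members.drop(columns="group"),
        bin_counts=counts,
        decorrelation_r=r,
    )


__all__ = [
    "DiagnosticSet",
    "N_BINS",
    "assemble_diagnostic",
    "bin_of",
    "consistency_filter",
    "normalize_rating",
    "round_a1_select",
    "round_a2_select",
    "round_a3_select",
    "round_b1_select",
    "round_b2_select",
    "select_flat",
    "summarize_ratings",
]
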
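import numpy as np
import pandas as pd
import pytest

from mgp import diagnostic as dg
from mgp import synthetic as syn


def rating_table(entries):
    """entries: list of (image_id, true_class, [ratings])."""
    rows = []
    for image_id, true_class, ratings in entries:
        for i, k in enumerate(ratings):
            rows.append((image_id, true_class, f"obs{i}", k))
    return pd.DataFrame(rows, columns=["image_id", "true_class", "observer_id", "value"])


class TestBinOf:
    @pytest.mark.parametrize(
        "value,expected", [(0.0, 1), (0.19, 1), (0.2, 2), (0.5, 3), (0.99, 5), (1.0, 5)]
    )
    def test_fifths(self, value, expected):
        assert dg.bin_of(value) == expected

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            dg.bin_of(1.1)


class TestSummaries:
    def test_mean_and_bin(self):
        table = rating_table([("a", "mirror", [5, 5, 4])])
        s = dg.summarize_ratings(table)
        assert s.loc[0, "mean_norm_rating"] == pytest.approx((1 + 1 + 0.75) / 3)
        assert s.loc[0, "bin"] == 5

    def test_consistency_by_observer_bins(self):
        table = rating_table([("a", "mirror", [4, 4, 4]), ("b", "mirror", [4, 4, 5])])
        s = dg.summarize_ratings(table).set_index("image_id")
        assert bool(s.loc["a", "consistent"])
        assert not bool(s.loc["b", "consistent"])

    def test_single_rating_never_consistent(self):
        s = dg.summarize_ratings(rating_table([("a", "mirror", [3])]))
        assert not bool(s.loc[0, "consistent"])


class TestConsistencyFilter:
    def test_all_same(self):
        bins = np.full((3, 10), 4)
        assert dg.consistency_filter(bins).all()

    def test_one_deviant(self):
        bins = np.full((1, 10), 4)
        bins[0, 3] = 5
        assert not dg.consistency_filter(bins).any()

    def test_wrong_observer_count(self):
        with pytest.raises(ValueError):
            dg.consistency_filter(np.full((2, 7), 1))


def threeway_table(cells, n_hard=0):
    """cells: dict (true, judged) -> count; single judgment per image."""
    rows = []
    i = 0
    for (true_cls, judged), count in cells.items():
        for _ in range(count):
            rows.append((f"img{i:05d}", true_cls, "obs0", judged))
            i += 1
    for _ in range(n_hard):
        rows.append((f"img{i:05d}", "mirror", "obs0", "hard"))
        i += 1
    return pd.DataFrame(rows, columns=["image_id", "true_class", "observer_id", "value"])


class TestRoundA1:
    CELLS = {
        ("mirror", "mirror"): 30,
        ("mirror", "glass"): 25,
        ("glass", "mirror"): 22,
        ("glass", "glass"): 40,
    }

    def test_quota_sampling(self):
        table = threeway_table(self.CELLS, n_hard=5)
        selected = dg.round_a1_select(table, quota_per_bin=20, seed=0)
        assert len(selected) == 80
        assert len(set(selected)) == 80

    def test_hard_images_excluded(self):
        table = threeway_table(self.CELLS, n_hard=10)
        hard_ids = set(table[table["value"] == "hard"]["image_id"])
        selected = dg.round_a1_select(table, quota_per_bin=20, seed=0)
        assert not hard_ids & set(selected)

    def test_zero_quota(self):
        assert dg.round_a1_select(threeway_table(self.CELLS), 0) == []

    def test_underfull_cell_error_names_cell(self):
        with pytest.raises(ValueError, match="judged=glass"):
            dg.round_a1_select(threeway_table(self.CELLS), quota_per_bin=26)

    def test_deterministic(self):
        table = threeway_table(self.CELLS)
        assert dg.round_a1_select(table, 20, seed=3) == dg.round_a1_select(table, 20, seed=3)

    def test_majority_vote_excludes_hard(self):
        rows = []
        for obs, judged in enumerate(["hard", "hard", "mirror"]):
            rows.append(("imgX", "mirror", f"obs{obs}", judged))
        table = pd.concat(
            [threeway_table(self.CELLS),
             pd.DataFrame(rows, columns=["image_id", "true_class", "observer_id", "value"])]
        )
        selected = dg.round_a1_select(table, 20, seed=0)
        assert "imgX" not in selected


class TestRoundA2:
    def test_planted_conflicts_selected(self):
        entries = []
        for i in range(4):  # mirror rated low -> conflict
            entries.append((f"m{i}", "mirror", [1, 1, 2]))
        for i in range(3):  # glass rated high -> conflict
            entries.append((f"g{i}", "glass", [5, 4, 5]))
        for i in range(5):  # veridical
            entries.append((f"vm{i}", "mirror", [5, 5, 4]))
        table = rating_table(entries)
        mirror_ids, glass_ids = dg.round_a2_select(table)
        assert len(mirror_ids) == 4 and len(glass_ids) == 3

    def test_agreeing_ratings_empty(self):
        table = rating_table([("m0", "mirror", [5, 5, 5]), ("g0", "glass", [1, 1, 1])])
        mirror_ids, glass_ids = dg.round_a2_select(table)
        assert mirror_ids == [] and glass_ids == []

    def test_min_ratings_rule(self):
        table = rating_table([("m0", "mirror", [1, 1])])  # only 2 ratings
        mirror_ids, _ = dg.round_a2_select(table, min_ratings=3)
        assert mirror_ids == []

    def test_rejected_workers_excluded(self):
        table = rating_table([("m0", "mirror", [1, 1, 1])])
        table["accepted"] = [True, True, False]
        mirror_ids, _ = dg.round_a2_select(table, min_ratings=3)
        assert mirror_ids == []  # only 2 accepted ratings remain

    def test_boundary_04_excluded_for_mirror(self):
        # mean exactly 0.4 is outside [0, 0.4)
        table = rating_table([("m0", "mirror", [3, 3, 2, 2, 2])])  # mean 0.35
        assert dg.round_a2_select(table)[0] == ["m0"]
        table = rating_table([("m1", "mirror", [3, 3, 3, 2, 2])])  # mean 0.4
        assert dg.round_a2_select(table)[0] == []


class TestRoundA3:
    @staticmethod
    def full_table(entries):
        return rating_table(
            [(i, c, r * 10) for i, c, r in entries]  # 3 ratings x 10 observers
        )

    def test_planted_conflicts(self):
        entries = [(f"m{i}", "mirror", [1, 2, 2]) for i in range(3)]
        entries += [(f"g{i}", "glass", [4, 5, 4]) for i in range(2)]
        entries += [("vm0", "mirror", [5, 5, 5]), ("vg0", "glass", [1, 1, 1])]
        assert len(dg.round_a3_select(self.full_table(entries))) == 5

    def test_boundary_mean_half_selects_both_classes(self):
        # mean exactly 0.5: mirror (0.5 < 0.6) and glass (0.5 >= 0.4) both selected
        entries = [("m0", "mirror", [3, 3, 3]), ("g0", "glass", [3, 3, 3])]
        assert dg.round_a3_select(self.full_table(entries)) == ["g0", "m0"]

    def test_no_candidates(self):
        entries = [("m0", "mirror", [5, 5, 5]), ("g0", "glass", [1, 1, 1])]
        assert dg.round_a3_select(self.full_table(entries)) == []

    def test_wrong_rating_count_rejected(self):
        table = rating_table([("m0", "mirror", [1] * 29)])
        with pytest.raises(ValueError, match="30"):
            dg.round_a3_select(table)


def recog_table(vote_counts, n_observers=10):
    rows = []
    for i, yes in enumerate(vote_counts):
        for o in range(n_observers):
            rows.append((f"img{i:04d}", f"obs{o}", int(o < yes)))
    return pd.DataFrame(rows, columns=["image_id", "observer_id", "value"])


class TestRoundB1:
    def test_planted_counts(self):
        votes = [10] * 3 + [7] * 2 + [6] * 2 + [5] * 4 + [0] * 3
        assert len(dg.round_b1_select(recog_table(votes))) == 7

    def test_boundary_six_kept(self):
        assert dg.round_b1_select(recog_table([6])) == ["img0000"]

    def test_all_zero_votes(self):
        assert dg.round_b1_select(recog_table([0, 0])) == []

    def test_wrong_vote_count(self):
        with pytest.raises(ValueError):
            dg.round_b1_select(recog_table([5], n_observers=9))


class TestRoundB2:
    @staticmethod
    def consistent_table(per_bin):
        entries = []
        ratings_for_bin = {1: [1], 2: [2], 3: [3], 4: [4], 5: [5]}
        i = 0
        for b, count in per_bin.items():
            for _ in range(count):
                entries.append((f"img{i:04d}", "mirror", ratings_for_bin[b] * 10))
                i += 1
        return rating_table(entries)

    def test_quota_per_bin(self):
        table = self.consistent_table({b: 5 for b in range(1, 6)})
        assert len(dg.round_b2_select(table, per_bin_quota=3, seed=0)) == 15

    def test_zero_quota(self):
        table = self.consistent_table({b: 2 for b in range(1, 6)})
        assert dg.round_b2_select(table, per_bin_quota=0) == []

    def test_underfull_bin_named(self):
        table = self.consistent_table({1: 5, 2: 5, 3: 1, 4: 5, 5: 5})
        with pytest.raises(ValueError, match="bin 3"):
            dg.round_b2_select(table, per_bin_quota=3)

    def test_inconsistent_images_ineligible(self):
        entries = [(f"img{i}", "mirror", [1] * 10) for i in range(3)]
        entries.append(("mixed", "mirror", [1] * 9 + [2]))
        table = rating_table(entries)
        with pytest.raises(ValueError):  # bin 2..5 empty
            dg.round_b2_select(table, per_bin_quota=1)


class TestAssembly:
    @staticmethod
    def summaries(render_per_bin=2, amb_per_bin=2):
        rows = []
        i = 0
        centers = [0.1, 0.3, 0.5, 0.7, 0.9]
        for cls in ("mirror", "glass"):
            for b, c in enumerate(centers, start=1):
                for _ in range(render_per_bin):
                    rows.append((f"r{i:04d}", cls, b, c, "render"))
                    i += 1
        for b, c in enumerate(centers, start=1):
            for _ in range(amb_per_bin):
                rows.append((f"a{i:04d}", "mirror" if i % 2 else "glass", b, c, "amb"))
                i += 1
        return pd.DataFrame(
            rows, columns=["image_id", "true_class", "bin", "mean_norm_rating", "kind"]
        )

    def components(self, s):
        rend = s[s["kind"] == "render"]
        verid = rend[
            ((rend["true_class"] == "mirror") & (rend["bin"] >= 4))
            | ((rend["true_class"] == "glass") & (rend["bin"] <= 2))
        ]["image_id"].tolist()
        ill = [i for i in rend["image_id"] if i not in set(verid)]
        amb = s[s["kind"] == "amb"]["image_id"].tolist()
        return verid, ill, amb

    def test_balanced_set_assembles(self):
        s = self.summaries()
        verid, ill, amb = self.components(s)
        d = dg.assemble_diagnostic(verid, ill, amb, s)
        assert len(d) == len(verid) + len(ill) + len(amb)
        assert abs(d.decorrelation_r) < 0.05

    def test_flatness_violation_reports_counts(self):
        s = self.summaries()
        verid, ill, amb = self.components(s)
        with pytest.raises(ValueError, match="counts per bin"):
            dg.assemble_diagnostic(verid[:-1], ill, amb, s)

    def test_overlapping_components_rejected(self):
        s = self.summaries()
        verid, ill, amb = self.components(s)
        with pytest.raises(ValueError, match="disjoint"):
            dg.assemble_diagnostic(verid, ill + [verid[0]], amb, s)

    def test_missing_summary_rejected(self):
        s = self.summaries()
        verid, ill, amb = self.components(s)
        with pytest.raises(ValueError, match="ghost"):
            dg.assemble_diagnostic(verid + ["ghost"], ill, amb, s)

    def test_select_flat(self):
        s = self.summaries(render_per_bin=4)
        ids = dg.select_flat(s, per_bin=2, classes=["mirror", "glass"], seed=1)
        assert len(ids) == 2 * 5 * 2
        sel = s[s["image_id"].isin(ids)]
        counts = sel.groupby(["true_class", "bin"]).size()
        assert (counts == 2).all()
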
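"""Replicate merging, tissue classification, overlap, CV, ranks and diff calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from m6abasemap.atlas import (
    TissueSiteSet,
    build_atlas,
    classify_shared_unique,
    compare_conditions,
    cv_profile,
    merge_replicates,
    overlap_with_window,
    phase_unique_sites,
    rank_normalize,
    rank_normalize_atlas,
)
from m6abasemap.annotation import TranscriptModel

from conftest import make_calls


def site_set(tissue, keys, fractions=None):
    fractions = fractions or [0.5] * len(keys)
    table = pd.DataFrame(
        {
            "chrom": [k[0] for k in keys],
            "pos": [k[1] for k in keys],
            "strand": [k[2] for k in keys],
            "fraction": fractions,
            "depth_rep1": 100,
            "depth_rep2": 100,
        }
    )
    return TissueSiteSet(tissue, table)


class TestMergeReplicates:
    def test_intersection_with_mean_fraction(self):
        r1 = make_calls([("chr1", 100, "+", 0.4), ("chr1", 200, "+", 0.5)])
        r2 = make_calls([("chr1", 200, "+", 0.5), ("chr1", 300, "+", 0.6)])
        r2.loc[r2["pos"] == 200, "fraction"] = 0.6
        ts = merge_replicates(r1, r2, "flower")
        assert ts.keys == {("chr1", 200, "+")}
        assert ts.fractions()[("chr1", 200, "+")] == pytest.approx(0.55)

    def test_failed_sites_excluded(self):
        r1 = make_calls([("chr1", 100, "+", 0.4, False), ("chr1", 200, "+", 0.5)])
        r2 = make_calls([("chr1", 100, "+", 0.4), ("chr1", 200, "+", 0.5)])
        assert merge_replicates(r1, r2).keys == {("chr1", 200, "+")}

    def test_empty_replicate_warns(self):
        r1 = make_calls([("chr1", 100, "+", 0.4)])
        with pytest.warns(UserWarning, match="empty"):
            ts = merge_replicates(r1, make_calls([]), "seed")
        assert ts.keys == set()


class TestSharedUnique:
    def setup_method(self):
        self.sets = [
            site_set("flower", [("chr1", 10, "+"), ("chr1", 20, "+"), ("chr1", 30, "+")]),
            site_set("root", [("chr1", 10, "+"), ("chr1", 30, "+")]),
            site_set("seed", [("chr1", 10, "+"), ("chr1", 40, "+"), ("chr1", 30, "+")]),
        ]

    def test_labels(self):
        out = classify_shared_unique(self.sets).set_index("pos")["label"]
        assert out[10] == "common"
        assert out[20] == "unique:flower"
        assert out[40] == "unique:seed"
        assert out[30] == "common"

    def test_labels_partition_universe(self):
        out = classify_shared_unique(self.sets)
        universe = set().union(*(s.keys for s in self.sets))
        assert len(out) == len(universe)

    def test_partial_label(self):
        sets = self.sets
        sets[2] = site_set("seed", [("chr1", 40, "+"), ("chr1", 30, "+")])
        out = classify_shared_unique(sets).set_index("pos")["label"]
        assert out[10] == "partial"  # flower+root only

    def test_phase_grouping(self):
        grouping = {"flower": "reproductive", "seed": "reproductive", "root": "vegetative"}
        phased = phase_unique_sites(self.sets, grouping)
        assert ("chr1", 20, "+") in phased["reproductive_unique"]  # flower only
        assert ("chr1", 40, "+") in phased["reproductive_unique"]  # seed only
        assert ("chr1", 10, "+") in phased["common"]
        assert phased["vegetative_unique"] == set()
        with pytest.raises(ValueError, match="missing"):
            phase_unique_sites(self.sets, {"flower": "reproductive"})


class TestOverlapWindow:
    @pytest.mark.parametrize(
        "pa,pb,w,expected",
        [(100, 100, 0, (1, 1)), (100, 105, 5, (1, 1)), (100, 106, 5, (0, 0))],
    )
    def test_window_boundary(self, pa, pb, w, expected):
        a = {("chr1", pa, "+")}
        b = {("chr1", pb, "+")}
        na, nb, _ = overlap_with_window(a, b, w)
        assert (na, nb) == expected

    def test_strand_and_chrom_respected(self):
        a = {("chr1", 100, "+")}
        na, _, _ = overlap_with_window(a, {("chr1", 100, "-")}, 5)
        assert na == 0
        na, _, _ = overlap_with_window(a, {("chr2", 100, "+")}, 5)
        assert na == 0

    def test_matches_all_pairs_brute_force(self):
        rng = np.random.default_rng(21)
        chroms = [f"chr{i}" for i in range(1, 6)]

        def random_sites(n):
            return {
                (chroms[rng.integers(5)], int(rng.integers(0, 3000)), "+-"[rng.integers(2)])
                for _ in range(n)
            }

        A, B = random_sites(500), random_sites(500)
        na, nb, pairs = overlap_with_window(A, B, 5)
        brute_a = sum(
            1 for (c, p, s) in A if any(cb == c and sb == s and abs(pb - p) <= 5 for (cb, pb, sb) in B)
        )
        brute_b = sum(
            1 for (c, p, s) in B if any(ca == c and sa == s and abs(pa - p) <= 5 for (ca, pa, sa) in A)
        )
        assert (na, nb) == (brute_a, brute_b)
        assert len(pairs) == na
        with pytest.raises(ValueError):
            overlap_with_window(A, B, -1)


class TestCvProfile:
    def make_inputs(self, fractions_by_tissue):
        t = TranscriptModel("t1", "g1", "chr1", "+", [(0, 300)], 50, 250)
        sets = []
        for tissue, fracs in fractions_by_tissue.items():
            keys = [("chr1", 260 + 3 * i, "+") for i in range(len(fracs))]
            sets.append(site_set(tissue, keys, fracs))
        atlas = build_atlas(sets)
        site_tx = {k: "t1" for s in sets for k in s.keys}
        return atlas, {"t1": t}, site_tx

    def test_identical_tissues_cv_zero(self):
        atlas, models, site_tx = self.make_inputs({"a": [0.5, 0.5], "b": [0.5, 0.5]})
        prof = cv_profile(atlas, models, site_tx, bins_per_region=2)
        measured = prof.dropna(subset=["cv"])
        assert (measured["cv"] == 0).all()

    def test_known_cv(self):
        # one 3'UTR bin with totals {1, 2, 3} across tissues -> CV = 0.5
        atlas, models, site_tx = self.make_inputs({"a": [1.0], "b": [2.0], "c": [3.0]})
        prof = cv_profile(atlas, models, site_tx, bins_per_region=1)
        utr3 = prof.loc[(prof["region"] == "3UTR")].iloc[0]
        assert utr3["cv"] == pytest.approx(0.5)

    def test_scale_invariance_and_missing_bins(self):
        atlas, models, site_tx = self.make_inputs({"a": [0.2, 0.7], "b": [0.4, 0.1]})
        p1 = cv_profile(atlas, models, site_tx, bins_per_region=2)
        p2 = cv_profile(atlas * 3.0, models, site_tx, bins_per_region=2)
        pd.testing.assert_series_equal(p1["cv"], p2["cv"])
        assert p1.loc[p1["region"] == "5UTR", "cv"].isna().all()  # no 5'UTR sites
        with pytest.raises(ValueError):
            cv_profile(atlas[["a"]], models, site_tx)


class TestRankNormalize:
    def test_examples(self):
        np.testing.assert_allclose(rank_normalize([0.1, 0.5, 0.9]), [0.0, 0.5, 1.0])
        np.testing.assert_allclose(rank_normalize([0.3, 0.3, 0.3]), [0.5, 0.5, 0.5])

    def test_missing_preserved_and_short_rows_skipped(self):
        out = rank_normalize([0.2, np.nan, 0.8])
        assert np.isnan(out[1]) and out[0] == 0.0 and out[2] == 1.0
        with pytest.raises(ValueError):
            rank_normalize([0.2, np.nan, np.nan])
        atlas = pd.DataFrame({"a": [0.1, 0.2], "b": [0.9, np.nan], "c": [0.5, np.nan]})
        normed = rank_normalize_atlas(atlas)
        assert len(normed) == 1

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(0, 1, width=32), min_size=2, max_size=8, unique=True))
    def test_monotone_transform_invariance(self, vals):
        arr = np.asarray(vals)
        np.testing.assert_allclose(rank_normalize(arr), rank_normalize(np.exp(3 * arr)))
        out = rank_normalize(arr)
        assert out.min() >= 0 and out.max() <= 1


def fisher_oracle(m1, d1, m2, d2):
    return stats.fisher_exact([[m1, d1 - m1], [m2, d2 - m2]])[1]


class TestCompareConditions:
    cal = staticmethod(lambda motif: (0.005, 0.85))

    def pileup(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "motif", "depth", "mut_count"])

    def test_identical_counts_unchanged(self):
        p = self.pileup([("chr1", 100, "+", "GGACT", 100, 40)])
        out = compare_conditions([p], [p.copy()], self.cal)
        assert out.iloc[0]["verdict"] == "unchanged"
        assert out.iloc[0]["p_value"] == pytest.approx(1.0)

    def test_strong_loss_called_hypo(self):
        a = self.pileup([("chr1", 100, "+", "GGACT", 100, 80)])
        b = self.pileup([("chr1", 100, "+", "GGACT", 100, 20)])
        out = compare_conditions([a], [b], self.cal)
        assert out.iloc[0]["verdict"] == "hypo"
        assert out.iloc[0]["p_value"] == pytest.approx(fisher_oracle(80, 100, 20, 100))
        assert out.iloc[0]["p_value"] < 1e-10

    def test_low_depth_undertested(self):
        a = self.pileup([("chr1", 100, "+", "GGACT", 5, 3)])
        b = self.pileup([("chr1", 100, "+", "GGACT", 100, 50)])
        assert compare_conditions([a], [b], self.cal).iloc[0]["verdict"] == "undertested"

    def test_replicates_pooled(self):
        a1 = self.pileup([("chr1", 100, "+", "GGACT", 50, 40)])
        a2 = self.pileup([("chr1", 100, "+", "GGACT", 50, 40)])
        b = self.pileup([("chr1", 100, "+", "GGACT", 100, 20)])
        out = compare_conditions([a1, a2], [b], self.cal)
        assert out.iloc[0]["p_value"] == pytest.approx(fisher_oracle(80, 100, 20, 100))

    def test_no_shared_sites_errors(self):
        a = self.pileup([("chr1", 100, "+", "GGACT", 100, 50)])
        b = self.pileup([("chr1", 999, "+", "GGACT", 100, 50)])
        with pytest.raises(ValueError, match="shared"):
            compare_conditions([a], [b], self.cal)

    def test_type_one_error_and_power(self):
        """Fisher verdicts: conservative under the null, powerful at delta-f 0.3."""
        rng = np.random.default_rng(17)
        n, depth = 400, 100
        f0 = rng.uniform(0.2, 0.6, n)
        rate0 = 0.005 + f0 * 0.845

        def pile(rates):
            return self.pileup(
                [("chr1", i + 1, "+", "GGACT", depth, int(m))
                 for i, m in enumerate(rng.binomial(depth, rates))]
            )

        null = compare_conditions([pile(rate0)], [pile(rate0)], self.cal)
        assert (null["p_value"] < 0.05).mean() <= 0.06
        alt = compare_conditions([pile(rate0)], [pile(rate0 + 0.3 * 0.845)], self.cal)
        assert (alt["verdict"] == "hyper").mean() >= 0.9
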
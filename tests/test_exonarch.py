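"""Exon-level statistics, length bins and junction-aligned profiles."""

import numpy as np
import pandas as pd
import pytest

from m6abasemap.annotation import ExonRecord, TranscriptModel
from m6abasemap.exonarch import (
    bin_exons_by_length,
    detect_profile_peak,
    exon_levels_table,
    exon_m6a_level,
    junction_profile,
    m6a_density,
    ProfileTrack,
)

from conftest import make_calls


def exon(tid="t1", index=2, klass="internal", lo=1000, hi=1100, chrom="chr1", strand="+", t_lo=0):
    return ExonRecord(tid, index, klass, hi - lo, chrom, strand, (lo, hi), (t_lo, t_lo + hi - lo))


class TestExonLevelAndDensity:
    def test_empty_exon_level_zero(self):
        assert exon_m6a_level(exon(), make_calls([])) == 0.0

    def test_sum_of_fractions(self):
        calls = make_calls([("chr1", 1010, "+", 0.2), ("chr1", 1050, "+", 0.3)])
        assert exon_m6a_level(exon(), calls) == pytest.approx(0.5)

    def test_half_open_end_excluded(self):
        # pos column is 1-based: genomic 0-based 1100 == exon end -> excluded
        calls = make_calls([("chr1", 1101, "+", 0.9), ("chr1", 1100, "+", 0.1)])
        assert exon_m6a_level(exon(), calls) == pytest.approx(0.1)

    def test_failed_sites_ignored(self):
        calls = make_calls([("chr1", 1010, "+", 0.2, False), ("chr1", 1050, "+", 0.3, True)])
        assert exon_m6a_level(exon(), calls) == pytest.approx(0.3)

    @pytest.mark.parametrize(
        "length,fracs,expected",
        [(500, [0.5], 1.0), (300, [], 0.0), (1000, [0.2, 0.3], 0.5)],
    )
    def test_density_formula(self, length, fracs, expected):
        ex = exon(lo=0, hi=length)
        calls = make_calls([("chr1", 10 + i, "+", f) for i, f in enumerate(fracs)])
        assert m6a_density(ex, calls) == pytest.approx(expected)

    def test_density_identity_fuzz(self):
        """density == 1000 * level / length exactly, and the vectorized table
        agrees with the per-exon function."""
        rng = np.random.default_rng(3)
        exons, call_rows = [], []
        cursor = 0
        for i in range(300):
            L = int(rng.integers(40, 800))
            ex = exon(tid=f"t{i}", lo=cursor, hi=cursor + L)
            exons.append(ex)
            for _ in range(rng.integers(0, 4)):
                call_rows.append(("chr1", int(rng.integers(cursor, cursor + L)) + 1, "+", float(rng.uniform(0, 1))))
            cursor += L + 50
        calls = make_calls(call_rows)
        table = exon_levels_table(exons, calls)
        for row, ex in zip(table.itertuples(index=False), exons):
            level = exon_m6a_level(ex, calls)
            assert row.level == pytest.approx(level, abs=1e-12)
            assert row.density == 1000.0 * row.level / row.length

    def test_level_split_concatenation(self):
        """Splitting an exon at an interior point conserves the summed level."""
        rng = np.random.default_rng(4)
        calls = make_calls(
            [("chr1", int(p) + 1, "+", float(f)) for p, f in zip(rng.integers(0, 400, 25), rng.uniform(0, 1, 25))]
        )
        parent = exon(lo=0, hi=400)
        for cut in (1, 100, 399):
            left, right = exon(lo=0, hi=cut), exon(lo=cut, hi=400)
            assert exon_m6a_level(left, calls) + exon_m6a_level(right, calls) == pytest.approx(
                exon_m6a_level(parent, calls)
            )


class TestLengthBins:
    def frame(self, n):
        rng = np.random.default_rng(0)
        return pd.DataFrame(
            {
                "transcript_id": [f"t{i}" for i in range(n)],
                "index": 1,
                "klass": "internal",
                "length": rng.integers(50, 500, n),
                "level": rng.uniform(0, 2, n),
                "density": rng.uniform(0, 5, n),
            }
        )

    def test_even_split(self):
        out = bin_exons_by_length(self.frame(300), n_bins=100)
        assert (out["n_exons"] == 3).all()

    def test_remainder_rule_larger_bins_first(self):
        out = bin_exons_by_length(self.frame(205), n_bins=100)
        assert list(out["n_exons"][:5]) == [3] * 5
        assert (out["n_exons"][5:] == 2).all()

    def test_partition_and_tie_break_determinism(self):
        df = self.frame(120)
        df["length"] = 100  # all equal -> deterministic via tie-break keys
        a = bin_exons_by_length(df, n_bins=10)
        b = bin_exons_by_length(df.sample(frac=1, random_state=1), n_bins=10)
        assign_a = a.attrs["assignment"].sort_values(["transcript_id", "index"]).reset_index(drop=True)
        assign_b = b.attrs["assignment"].sort_values(["transcript_id", "index"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(assign_a, assign_b)
        assert assign_a.groupby("bin_index").size().sum() == 120

    def test_too_few_exons(self):
        with pytest.raises(ValueError, match="n_bins"):
            bin_exons_by_length(self.frame(50), n_bins=100)


def brute_force_profile(exons, sites, anchor, window, step, span, transcripts=None):
    """O(exons x windows x sites) oracle mirroring the anchoring rules."""
    offsets = np.arange(-span, span + 1, step)
    raw = np.zeros(len(offsets))
    cov = np.zeros(len(offsets), dtype=int)
    copies = []
    for ex in exons:
        L = ex.length
        if anchor == "internal_junction":
            copies += [(0, L, ex), (-L, 0, ex)]
        elif anchor == "last_junction":
            copies += [(0, L, ex)]
        else:
            t = transcripts[ex.transcript_id]
            if not t.is_coding:
                continue
            ts, te = ex.transcript_interval
            copies += [(ts - t.cds_end, ts - t.cds_end + L, ex)]
    passed = sites.loc[sites["passed"]]
    for i, d in enumerate(offsets):
        for s0, s1, ex in copies:
            if d + window > s0 and d < s1:
                cov[i] += 1
            lo, hi = ex.genomic_interval
            for rec in passed.itertuples(index=False):
                if rec.chrom != ex.chrom or rec.strand != ex.strand:
                    continue
                p = rec.pos - 1
                if not lo <= p < hi:
                    continue
                within = p - lo if ex.strand == "+" else hi - 1 - p
                off = s0 + within
                if d <= off < d + window:
                    raw[i] += rec.fraction
    return offsets, raw, cov


class TestJunctionProfile:
    def test_single_site_placement(self):
        ex = exon(lo=0, hi=100)
        calls = make_calls([("chr1", 13, "+", 0.4)])  # +12 nt from 5' junction
        track = junction_profile([ex], calls, "last_junction", window=10, step=10, span=50)
        i = list(track.offsets).index(10)
        assert track.raw_level[i] == pytest.approx(0.4)
        assert track.coverage[i] == 1
        assert track.likelihood[i] == pytest.approx(0.4)
        others = np.delete(track.raw_level, i)
        assert np.all(others == 0)

    def test_beyond_exon_coverage_zero(self):
        ex = exon(lo=0, hi=100)
        track = junction_profile([ex], make_calls([]), "last_junction", window=10, step=10, span=300)
        i = list(track.offsets).index(200)
        assert track.coverage[i] == 0
        assert np.isnan(track.likelihood[i])

    def test_minus_strand_offsets_run_5prime_to_3prime(self):
        ex = exon(strand="-", lo=1000, hi=1100)
        # genomic 0-based 1087 is 12 nt from the 5' (right) end on minus strand
        calls = make_calls([("chr1", 1088, "-", 0.5)])
        track = junction_profile([ex], calls, "last_junction", window=5, step=1, span=20)
        hit = track.offsets[track.raw_level > 0]
        assert set(hit) == {8, 9, 10, 11, 12}

    @pytest.mark.parametrize("anchor", ["internal_junction", "last_junction", "stop_codon"])
    def test_matches_brute_force_oracle(self, anchor):
        rng = np.random.default_rng(9)
        exons, transcripts, call_rows = [], {}, []
        cursor = 0
        for i in range(40):
            L1, L2 = int(rng.integers(30, 200)), int(rng.integers(100, 400))
            strand = "+" if i % 2 else "-"
            e1 = (cursor, cursor + L1)
            e2 = (cursor + L1 + 80, cursor + L1 + 80 + L2)
            exon_list = [e1, e2] if strand == "+" else [e2, e1]
            t = TranscriptModel(f"t{i}", f"g{i}", "chr1", strand, exon_list, 10, 10 + ((L1 + L2 - 60) // 3) * 3)
            transcripts[f"t{i}"] = t
            lo2, hi2 = (e2 if strand == "+" else e1)
            exons.append(ExonRecord(f"t{i}", 2, "last", hi2 - lo2, "chr1", strand,
                                    (lo2, hi2), (L1, L1 + (hi2 - lo2))))
            for _ in range(rng.integers(0, 5)):
                p = int(rng.integers(cursor, cursor + L1 + 80 + L2))
                call_rows.append(("chr1", p + 1, strand, float(rng.uniform(0, 1))))
            cursor += L1 + L2 + 300
        calls = make_calls(call_rows)
        track = junction_profile(exons, calls, anchor, window=25, step=10, span=400, transcripts=transcripts)
        offsets, raw, cov = brute_force_profile(exons, calls, anchor, 25, 10, 400, transcripts)
        np.testing.assert_array_equal(track.offsets, offsets)
        np.testing.assert_allclose(track.raw_level, raw, atol=1e-12)
        np.testing.assert_array_equal(track.coverage, cov)

    def test_invalid_geometry(self):
        with pytest.raises(ValueError):
            junction_profile([exon()], make_calls([]), "last_junction", window=0)
        with pytest.raises(ValueError, match="anchor"):
            junction_profile([exon()], make_calls([]), "nope")


def flat_track(values, step=5):
    n = len(values)
    offsets = np.arange(0, n * step, step)
    return ProfileTrack(
        anchor="last_junction", window=25, step=step, offsets=offsets,
        raw_level=np.asarray(values, dtype=float),
        coverage=np.ones(n, dtype=int), covered_bases=np.full(n, 25),
    )


class TestPeakDetection:
    def test_flat_track_no_peak(self):
        call = detect_profile_peak(flat_track([0.5] * 40), min_prominence=0.05)
        assert call.peak_offset is None

    def test_gaussian_peak_recovered(self):
        offsets = np.arange(0, 600, 5)
        vals = 0.1 + 0.5 * np.exp(-((offsets - 300.0) ** 2) / (2 * 75.0**2))
        track = flat_track(vals)
        call = detect_profile_peak(track, min_prominence=0.1)
        assert call.peak_offset is not None
        assert abs(track.offsets[np.argmax(vals)] - call.peak_offset) <= 5

    def test_step_discontinuity_reported_at_step(self):
        vals = [0.2] * 20 + [0.8] * 20  # jump where the new value starts
        track = flat_track(vals)
        call = detect_profile_peak(track, min_prominence=10.0)
        assert call.breakpoint_offset == track.offsets[20]
        assert call.breakpoint_magnitude == pytest.approx(0.6)

    def test_all_undefined_errors(self):
        t = flat_track([0.5] * 20)
        t.coverage[:] = 0
        with pytest.raises(ValueError):
            detect_profile_peak(t)
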
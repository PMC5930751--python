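"""Signal tracks, staggered windows, meta-profiles and side sums."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bidiprom.intervals import GenomicInterval
from bidiprom.profiles import (
    FrameOutOfBounds,
    WindowFrame,
    build_meta_profile,
    chop_stagger,
    intergenic_midpoint,
    make_frame,
    side_cumulative_enrichment,
    subinterval_offsets,
)
from bidiprom.tracks import PeakSet, SignalTrack, map_mean, read_bedgraph, read_peaks

from oracles import brute_mean, brute_side_sums, track_base_values


def random_track_records(rng, chrom="chr1", lo=0, hi=6000, max_records=25):
    """Random sorted non-overlapping scored records on one chromosome."""
    n = int(rng.integers(0, max_records))
    cuts = np.sort(rng.choice(np.arange(lo, hi), size=2 * n, replace=False)) if n else []
    records = []
    for i in range(0, len(cuts), 2):
        if cuts[i] < cuts[i + 1] and rng.random() < 0.8:  # leave some gaps
            records.append((chrom, int(cuts[i]), int(cuts[i + 1]), float(rng.uniform(0, 10))))
    return records


class TestMidpoint:
    @pytest.mark.parametrize("tm,tp,mid", [(100, 200, 150), (100, 201, 151), (100, 101, 101)])
    def test_plus_one_then_halve(self, tm, tp, mid):
        assert intergenic_midpoint(tm, tp) == mid

    def test_order_violation(self):
        with pytest.raises(ValueError):
            intergenic_midpoint(200, 100)

    @given(st.integers(0, 10**6), st.integers(1, 1000), st.integers(0, 10**5))
    def test_translation_invariance(self, tss, d, shift):
        assert intergenic_midpoint(tss + shift, tss + d + shift) == (
            intergenic_midpoint(tss, tss + d) + shift
        )


class TestFrames:
    def test_frame_is_centered_and_4kb(self):
        f = make_frame(5000)
        assert (f.start, f.end) == (3000, 7000)
        assert len(f) == 4000

    def test_frame_beyond_chromosome_start_or_end(self):
        with pytest.raises(FrameOutOfBounds):
            make_frame(1000)
        with pytest.raises(FrameOutOfBounds):
            make_frame(9000, chrom_size=10_000)

    def test_chop_4kb_gives_52_subintervals_on_75bp_lattice(self):
        subs = chop_stagger(make_frame(5000))
        assert len(subs) == 52
        starts = np.array([s.start for s in subs])
        assert np.all(np.diff(starts) == 75)
        assert all(len(s) == 170 for s in subs)
        assert starts[-1] - starts[0] == 3825

    def test_chop_degenerate_cases(self):
        one = chop_stagger(GenomicInterval("c", 0, 170))
        assert len(one) == 1
        tiling = chop_stagger(GenomicInterval("c", 0, 680), length=170, stagger=170)
        assert [s.start for s in tiling] == [0, 170, 340, 510]

    def test_chop_length_exceeding_frame_rejected(self):
        with pytest.raises(ValueError):
            chop_stagger(GenomicInterval("c", 0, 100), length=170)

    @given(
        st.integers(500, 8000), st.integers(50, 500), st.integers(1, 400)
    )
    def test_chop_count_formula(self, size, length, stagger):
        if length > size:
            return
        subs = chop_stagger(GenomicInterval("c", 10_000, 10_000 + size), length, stagger)
        assert len(subs) == 1 + (size - length) // stagger

    def test_offsets_shared_by_all_frames(self):
        f1 = WindowFrame("a", "chr1", 5000)
        f2 = WindowFrame("b", "chr2", 987_654)
        assert np.array_equal(f1.offsets, f2.offsets)
        assert np.array_equal(f1.offsets, subinterval_offsets())


class TestBedgraphIO:
    def test_roundtrip_and_uncovered_zero(self, tmp_path):
        p = tmp_path / "a.bedgraph"
        p.write_text("chr1\t0\t100\t2.5\nchr1\t200\t300\t1.0\n")
        track = read_bedgraph(p)
        assert track.value_sum("chr1", 0, 100) == pytest.approx(250.0)
        assert track.value_sum("chr1", 100, 200) == 0.0  # gap
        assert track.value_sum("chr2", 0, 50) == 0.0  # absent chromosome

    def test_unsorted_sorted_in_memory_unless_strict(self, tmp_path):
        p = tmp_path / "a.bedgraph"
        p.write_text("chr1\t200\t300\t1.0\nchr1\t0\t100\t2.5\n")
        assert read_bedgraph(p).value_sum("chr1", 0, 100) == pytest.approx(250.0)
        with pytest.raises(ValueError, match="sorted"):
            read_bedgraph(p, strict_sorted=True)

    def test_overlapping_records_rejected(self, tmp_path):
        p = tmp_path / "a.bedgraph"
        p.write_text("chr1\t0\t100\t2.5\nchr1\t50\t150\t1.0\n")
        with pytest.raises(ValueError, match="overlap"):
            read_bedgraph(p)

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "a.bedgraph"
        p.write_text("chr1\t0\t100\t2.5\nchr1\t100\tfoo\t1.0\n")
        with pytest.raises(ValueError, match="line 2"):
            read_bedgraph(p)

    def test_narrowpeak_qvalue_recovered_from_neglog10(self, tmp_path):
        p = tmp_path / "a.narrowPeak"
        p.write_text("chr1\t100\t400\tpeak_0\t800\t.\t5.2\t4.0\t2.0\t150\n")
        peaks = read_peaks(p)
        assert peaks.df["qvalue"].iloc[0] == pytest.approx(0.01)

    def test_qvalue_bedgraph_dialect(self, tmp_path):
        p = tmp_path / "q.bedgraph"
        p.write_text("chr1\t100\t400\t3.0\n")
        assert read_peaks(p).df["qvalue"].iloc[0] == pytest.approx(1e-3)


class TestMapMean:
    def test_constant_track_identity(self):
        track = SignalTrack({"chr1": ([0], [1000], [4.0])})
        assert map_mean(track, GenomicInterval("chr1", 100, 270)) == pytest.approx(4.0)

    def test_half_covered_interval(self):
        track = SignalTrack({"chr1": ([0], [100], [4.0])})
        assert map_mean(track, GenomicInterval("chr1", 0, 200)) == pytest.approx(2.0)

    def test_empty_track(self):
        assert map_mean(SignalTrack({}), GenomicInterval("chr1", 0, 100)) == 0.0

    def test_invariant_to_record_splitting(self):
        whole = SignalTrack({"chr1": ([0], [1000], [3.0])})
        split = SignalTrack({"chr1": ([0, 400, 700], [400, 700, 1000], [3.0, 3.0, 3.0])})
        iv = GenomicInterval("chr1", 123, 911)
        assert map_mean(whole, iv) == pytest.approx(map_mean(split, iv))

    @pytest.mark.parametrize("seed", range(30))
    def test_agrees_with_per_base_oracle(self, seed):
        rng = np.random.default_rng(seed)
        records = random_track_records(rng)
        track = (
            SignalTrack.from_dataframe(
                pd.DataFrame(records, columns=["chrom", "start", "end", "value"])
            )
            if records
            else SignalTrack({})
        )
        base = track_base_values(records)
        for _ in range(5):
            s = int(rng.integers(0, 5000))
            e = s + int(rng.integers(1, 900))
            got = map_mean(track, GenomicInterval("chr1", s, e))
            assert got == pytest.approx(brute_mean(base, s, e), abs=1e-9)


class TestSideEnrichment:
    def _frame(self, midpoint=5000):
        return WindowFrame("pair", "chr1", midpoint)

    def _peaks(self, rows):
        return PeakSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "qvalue"]))

    def test_no_significant_peaks_gives_zero(self):
        track = SignalTrack({"chr1": ([0], [10_000], [2.0])})
        peaks = self._peaks([("chr1", 5200, 5400, 0.2)])  # q >= 0.05
        se = side_cumulative_enrichment(self._frame(), track, peaks)
        assert (se.left_sum, se.right_sum) == (0.0, 0.0)

    def test_peak_right_of_midpoint_counts_right(self):
        track = SignalTrack({"chr1": ([0], [10_000], [3.0])})
        peaks = self._peaks([("chr1", 5200, 5400, 0.01)])
        se = side_cumulative_enrichment(self._frame(), track, peaks)
        assert se.left_sum == 0.0
        assert se.right_sum == pytest.approx(3.0 * 200)

    def test_midpoint_straddling_peak_discarded_from_both_sides(self):
        track = SignalTrack({"chr1": ([0], [10_000], [3.0])})
        peaks = self._peaks([("chr1", 4900, 5100, 0.01)])
        se = side_cumulative_enrichment(self._frame(), track, peaks)
        assert (se.left_sum, se.right_sum) == (0.0, 0.0)

    def test_peak_clipped_to_frame(self):
        track = SignalTrack({"chr1": ([0], [10_000], [1.0])})
        peaks = self._peaks([("chr1", 100, 3500, 0.01)])  # frame starts at 3000
        se = side_cumulative_enrichment(self._frame(), track, peaks)
        assert se.left_sum == pytest.approx(500.0)

    @pytest.mark.parametrize("seed", range(30))
    def test_agrees_with_per_base_oracle(self, seed):
        rng = np.random.default_rng(1000 + seed)
        records = random_track_records(rng, lo=2500, hi=7500)
        track = (
            SignalTrack.from_dataframe(
                pd.DataFrame(records, columns=["chrom", "start", "end", "value"])
            )
            if records
            else SignalTrack({})
        )
        base = track_base_values(records)
        peak_rows = []
        for _ in range(int(rng.integers(0, 6))):
            s = int(rng.integers(2000, 7800))
            peak_rows.append(("chr1", s, s + int(rng.integers(10, 600)), float(rng.uniform(0.001, 0.2))))
        peaks = self._peaks(peak_rows)
        fr = self._frame()
        se = side_cumulative_enrichment(fr, track, peaks)
        left, right = brute_side_sums(
            base, [(s, e, q) for _, s, e, q in peak_rows], fr.frame.start, fr.frame.end, fr.midpoint
        )
        assert se.left_sum == pytest.approx(left, abs=1e-9)
        assert se.right_sum == pytest.approx(right, abs=1e-9)

    def test_translation_invariance(self, rng):
        records = random_track_records(rng, lo=2500, hi=7500)
        if not records:
            records = [("chr1", 3000, 4000, 2.0)]
        shift = 13_117
        shifted = [(c, s + shift, e + shift, v) for c, s, e, v in records]
        t0 = SignalTrack.from_dataframe(pd.DataFrame(records, columns=["chrom", "start", "end", "value"]))
        t1 = SignalTrack.from_dataframe(pd.DataFrame(shifted, columns=["chrom", "start", "end", "value"]))
        p0 = self._peaks([("chr1", 4800, 4990, 0.01), ("chr1", 5100, 5600, 0.01)])
        p1 = self._peaks([("chr1", 4800 + shift, 4990 + shift, 0.01),
                          ("chr1", 5100 + shift, 5600 + shift, 0.01)])
        s0 = side_cumulative_enrichment(self._frame(5000), t0, p0)
        s1 = side_cumulative_enrichment(self._frame(5000 + shift), t1, p1)
        assert s0.left_sum == pytest.approx(s1.left_sum)
        assert s0.right_sum == pytest.approx(s1.right_sum)


class TestMetaProfile:
    def _track_with_bump(self, center, chrom="chr1"):
        xs = np.arange(0, 10_000, 10)
        vals = 1.0 + 5.0 * np.exp(-((xs + 5 - center) ** 2) / (2 * 150.0**2))
        return SignalTrack({chrom: (xs, xs + 10, vals)})

    def test_single_pair_profile_is_normalized_signal(self):
        track = self._track_with_bump(5600)
        frames = {"plus_high": [WindowFrame("a", "chr1", 5000)]}
        prof = build_meta_profile(frames, track)["plus_high"]
        assert prof.values.max() == pytest.approx(1.0)
        assert prof.n_pairs == 1
        assert prof.offsets[np.argmax(prof.values)] > 0

    def test_two_identical_pairs_same_shape_as_one(self):
        track = self._track_with_bump(5600)
        one = build_meta_profile({"c": [WindowFrame("a", "chr1", 5000)]}, track)["c"]
        two = build_meta_profile(
            {"c": [WindowFrame("a", "chr1", 5000), WindowFrame("b", "chr1", 5000)]}, track
        )["c"]
        assert np.allclose(one.values, two.values)

    def test_empty_category_gives_zero_profile(self):
        prof = build_meta_profile({"silent": []}, SignalTrack({}))["silent"]
        assert prof.n_pairs == 0
        assert np.all(prof.values == 0)

    def test_values_in_unit_interval_with_unique_max(self, rng):
        records = random_track_records(rng, lo=0, hi=9000)
        if not records:
            records = [("chr1", 4000, 6000, 2.0)]
        track = SignalTrack.from_dataframe(
            pd.DataFrame(records, columns=["chrom", "start", "end", "value"])
        )
        prof = build_meta_profile(
            {"c": [WindowFrame("a", "chr1", 4500), WindowFrame("b", "chr1", 5500)]}, track
        )["c"]
        assert np.all((prof.values >= 0) & (prof.values <= 1))
        if prof.values.max() > 0:
            assert np.sum(prof.values == 1.0) >= 1

    def test_mismatched_layouts_rejected(self):
        frames = {"c": [WindowFrame("a", "chr1", 5000, stagger=50)]}
        with pytest.raises(ValueError, match="layout"):
            build_meta_profile(frames, SignalTrack({}), stagger=75)
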
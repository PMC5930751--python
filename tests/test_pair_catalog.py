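"""Pair discovery, coordinate conventions and nucleosome binning."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from bidiprom.pair_catalog import (
    AnnotationParseError,
    BidirectionalPair,
    TranscriptModel,
    assign_nucleosome_bin,
    find_bidirectional_pairs,
    interval_length,
    read_annotation,
)

from conftest import make_tx, random_transcripts
from oracles import brute_force_pairs


class TestReadAnnotation:
    def test_gtf_coordinates_become_zero_based_half_open(self, tmp_path):
        gtf = tmp_path / "a.gtf"
        gtf.write_text(
            'chr1\tsrc\ttranscript\t101\t200\t.\t+\t.\ttranscript_id "t1"; gene_id "g1";\n'
            'chr1\tsrc\ttranscript\t101\t200\t.\t-\t.\ttranscript_id "t2"; gene_id "g2";\n'
        )
        t1, t2 = read_annotation(gtf)
        assert (t1.start, t1.end, t1.tss) == (100, 200, 100)
        assert t2.tss == 199  # minus strand: TSS at the right end

    def test_non_transcript_features_and_comments_skipped(self, tmp_path):
        gtf = tmp_path / "a.gtf"
        gtf.write_text(
            "# header\n"
            'chr1\tsrc\texon\t101\t150\t.\t+\t.\ttranscript_id "t1"; gene_id "g1";\n'
            'chr1\tsrc\ttranscript\t101\t200\t.\t+\t.\ttranscript_id "t1"; gene_id "g1";\n'
        )
        assert len(read_annotation(gtf)) == 1

    def test_empty_file_gives_empty_list(self, tmp_path):
        gtf = tmp_path / "a.gtf"
        gtf.write_text("")
        assert read_annotation(gtf) == []

    def test_malformed_line_error_names_line_number(self, tmp_path):
        gtf = tmp_path / "a.gtf"
        gtf.write_text(
            'chr1\tsrc\ttranscript\t101\t200\t.\t+\t.\ttranscript_id "t1"; gene_id "g1";\n'
            "chr1\tbroken line\n"
        )
        with pytest.raises(AnnotationParseError, match="line 2"):
            read_annotation(gtf)

    def test_missing_transcript_id_skipped_with_warning(self, tmp_path, caplog):
        gtf = tmp_path / "a.gtf"
        gtf.write_text('chr1\tsrc\ttranscript\t101\t200\t.\t+\t.\tgene_id "g1";\n')
        with caplog.at_level("WARNING"):
            assert read_annotation(gtf) == []
        assert "transcript_id" in caplog.text

    def test_bed6_reads_native_coordinates(self, tmp_path):
        bed = tmp_path / "a.bed"
        bed.write_text("chr1\t100\t200\tt1\t0\t+\nchr1\t300\t400\tt2\t0\t-\n")
        t1, t2 = read_annotation(bed)
        assert (t1.start, t1.end, t1.tss) == (100, 200, 100)
        assert t2.tss == 399

    def test_missing_file(self):
        with pytest.raises(FileNotFoundError):
            read_annotation("/nonexistent/file.gtf")


class TestFindPairs:
    def test_minimal_divergent_pair(self):
        txs = [make_tx("m", "-", 1000), make_tx("p", "+", 1500)]
        cat = find_bidirectional_pairs(txs)
        assert len(cat) == 1
        assert cat.pairs[0].distance == 500

    def test_convergent_orientation_is_not_a_pair(self):
        txs = [make_tx("p", "+", 1000), make_tx("m", "-", 1500)]
        assert len(find_bidirectional_pairs(txs)) == 0

    def test_distance_bound_is_inclusive_at_1000(self):
        at_bound = [make_tx("m", "-", 5000), make_tx("p", "+", 6000)]
        beyond = [make_tx("m", "-", 5000), make_tx("p", "+", 6001)]
        assert len(find_bidirectional_pairs(at_bound)) == 1
        assert len(find_bidirectional_pairs(beyond)) == 0

    def test_isoforms_give_independent_pairs(self):
        txs = [
            make_tx("m1", "-", 5000, gene="gm"),
            make_tx("p1", "+", 5400, gene="gp"),
            make_tx("p2", "+", 5800, gene="gp"),
        ]
        cat = find_bidirectional_pairs(txs)
        assert len(cat) == 2
        assert sorted(p.distance for p in cat) == [400, 800]

    def test_gene_pair_removed_if_any_isoform_overlaps(self):
        # p2's TSS sits left of the minus TSS: the whole gene pair goes
        txs = [
            make_tx("m1", "-", 5000, gene="gm"),
            make_tx("p1", "+", 5400, gene="gp"),
            make_tx("p2", "+", 4900, gene="gp", length=500),
        ]
        assert len(find_bidirectional_pairs(txs)) == 0

    def test_coincident_tss_is_not_a_pair(self):
        txs = [make_tx("m", "-", 5000), make_tx("p", "+", 5000)]
        assert len(find_bidirectional_pairs(txs)) == 0

    def test_duplicate_tss_triples_collapse(self):
        txs = [
            make_tx("m1", "-", 5000, gene="gm1"),
            make_tx("m2", "-", 5000, gene="gm2", length=900),
            make_tx("p1", "+", 5500, gene="gp"),
        ]
        assert len(find_bidirectional_pairs(txs)) == 1

    def test_chromosomes_do_not_mix(self):
        txs = [make_tx("m", "-", 1000, chrom="chr1"), make_tx("p", "+", 1500, chrom="chr2")]
        assert len(find_bidirectional_pairs(txs)) == 0

    def test_max_distance_parameter(self):
        txs = [make_tx("m", "-", 1000), make_tx("p", "+", 1500)]
        assert len(find_bidirectional_pairs(txs, max_distance=499)) == 0
        assert len(find_bidirectional_pairs(txs, max_distance=500)) == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_brute_force_oracle(self, seed):
        import numpy as np

        rng = np.random.default_rng(seed)
        txs = random_transcripts(rng, int(rng.integers(20, 120)))
        got = {(p.chrom, p.tss_minus, p.tss_plus) for p in find_bidirectional_pairs(txs)}
        assert got == brute_force_pairs(txs)

    def test_invariant_under_input_order(self, rng):
        txs = random_transcripts(rng, 80)
        forward = find_bidirectional_pairs(txs).to_dataframe()
        backward = find_bidirectional_pairs(list(reversed(txs))).to_dataframe()
        assert forward.equals(backward)

    def test_emitted_pairs_satisfy_invariants(self, rng):
        txs = random_transcripts(rng, 150)
        for p in find_bidirectional_pairs(txs):
            assert p.tss_minus < p.tss_plus
            assert 0 < p.distance <= 1000
            assert p.tss_minus < p.midpoint <= p.tss_plus


class TestNucleosomeBin:
    @pytest.mark.parametrize("d,expected", [(1, 1), (170, 1), (171, 2), (431, 3), (1000, 6)])
    def test_boundaries(self, d, expected):
        assert assign_nucleosome_bin(d) == expected

    def test_partitions_1_to_1000_into_six_bins(self):
        sizes = {}
        for d in range(1, 1001):
            sizes.setdefault(assign_nucleosome_bin(d), 0)
            sizes[assign_nucleosome_bin(d)] += 1
        assert sizes == {1: 170, 2: 170, 3: 170, 4: 170, 5: 170, 6: 150}

    @pytest.mark.parametrize("d", [0, -5, 1001])
    def test_out_of_range(self, d):
        with pytest.raises(ValueError):
            assign_nucleosome_bin(d)

    @given(st.integers(1, 1000))
    def test_matches_ceiling_rule(self, d):
        assert assign_nucleosome_bin(d) == math.ceil(d / 170)


class TestIntervalLength:
    @pytest.mark.parametrize(
        "region,length",
        [
            ("chr15:90777156-90777587", 431),
            ("chr1:32687713-32,688,023", 310),
            ("chr12:54653296–54654074", 778),  # en-dash, as printed
        ],
    )
    def test_end_minus_start(self, region, length):
        assert interval_length(region) == length

    def test_negative_span_rejected(self):
        with pytest.raises(ValueError, match="negative span"):
            interval_length("chr1:200-100")

    def test_garbage_rejected(self):
        with pytest.raises(ValueError):
            interval_length("not a region")


class TestPairModel:
    def test_wrong_strand_order_rejected(self):
        with pytest.raises(ValueError):
            BidirectionalPair(make_tx("p", "+", 1000), make_tx("m", "-", 2000))

    def test_midpoint_rounds_toward_plus_tss_for_odd_distance(self):
        pair = BidirectionalPair(make_tx("m", "-", 100), make_tx("p", "+", 201))
        assert pair.midpoint == 151

    def test_transcript_validation(self):
        with pytest.raises(ValueError):
            TranscriptModel("t", "g", "chr1", "*", 0, 100)
        with pytest.raises(ValueError):
            TranscriptModel("t", "g", "chr1", "+", 100, 100)
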
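"""Independent brute-force oracles for cross-checking the fast paths.

Everything here is deliberately naive — O(n^2) scans and per-base python
dictionaries — and shares no code with the implementations it checks.
"""

from __future__ import annotations


def brute_force_pairs(transcripts, max_distance=1000):
    """All-pairs scan for divergent pairs, with gene-level overlap removal.

    Returns a set of (chrom, tss_minus, tss_plus) triples.
    """

    def tss(t):
        return t.start if t.strand == "+" else t.end - 1

    minus = [t for t in transcripts if t.strand == "-"]
    plus = [t for t in transcripts if t.strand == "+"]

    # gene pairs with at least one qualifying isoform combination
    candidate_genes = set()
    for m in minus:
        for p in plus:
            if m.chrom == p.chrom and 0 < tss(p) - tss(m) <= max_distance:
                candidate_genes.add((m.gene_id, p.gene_id))

    # remove gene pairs where any isoform combination overlaps
    bad_genes = set()
    for mg, pg in candidate_genes:
        for m in minus:
            if m.gene_id != mg:
                continue
            for p in plus:
                if p.gene_id != pg:
                    continue
                if m.chrom == p.chrom and tss(p) - tss(m) <= 0:
                    bad_genes.add((mg, pg))

    found = set()
    for m in minus:
        for p in plus:
            if (m.gene_id, p.gene_id) in bad_genes:
                continue
            if m.chrom == p.chrom and 0 < tss(p) - tss(m) <= max_distance:
                found.add((m.chrom, tss(m), tss(p)))
    return found


def track_base_values(records):
    """Per-base {position: value} mapping from (chrom, start, end, value) rows.

    All records are assumed to be on one chromosome.
    """
    values = {}
    for _chrom, start, end, value in records:
        for pos in range(start, end):
            assert pos not in values, "overlapping oracle records"
            values[pos] = value
    return values


def brute_mean(base_values, start, end):
    """Base-weighted mean over [start, end); uncovered bases count as 0."""
    return sum(base_values.get(pos, 0.0) for pos in range(start, end)) / (end - start)


def brute_sum(base_values, start, end):
    return sum(base_values.get(pos, 0.0) for pos in range(start, end))


def brute_side_sums(base_values, peaks, frame_start, frame_end, midpoint, q_max=0.05):
    """Per-base left/right peak-restricted sums, discarding straddlers.

    ``peaks`` is an iterable of (start, end, qvalue) on the frame's chromosome.
    """
    left = right = 0.0
    for start, end, q in peaks:
        if q >= q_max:
            continue
        if end <= frame_start or start >= frame_end:
            continue
        if start < midpoint < end:
            continue  # straddles the reference point: attributed to neither side
        for pos in range(max(start, frame_start), min(end, frame_end)):
            if pos < midpoint:
                left += base_values.get(pos, 0.0)
            else:
                right += base_values.get(pos, 0.0)
    return left, right
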
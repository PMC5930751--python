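"""Discovery and binning of divergent (bidirectional) gene pairs.

A bidirectional gene pair is two transcripts on opposite strands in
head-to-head orientation whose TSSs are at most ``max_distance`` (default
1000 bp, inclusive) apart. The intergenic region between the two TSSs is
the putative bidirectional promoter. Pairs are binned by how many
nucleosome units (170 bp = ~150 bp octamer-wrapped DNA + 20 bp linker)
fit between the TSSs.

Rules applied by :func:`find_bidirectional_pairs`:

* only divergent orientation counts: the minus-strand TSS must lie
  strictly left of the plus-strand TSS on the same chromosome;
* every isoform combination of two genes that independently satisfies the
  definition is emitted as its own pair;
* if *any* isoform combination of a candidate gene pair has overlapping or
  convergently ordered TSSs (distance <= 0), the whole gene pair is
  removed — such genes may be driven by two independent promoters inside
  the partner's gene body;
* pairs that duplicate an already-seen ``(chrom, tss_minus, tss_plus)``
  triple collapse to a single entry.
"""

from __future__ import annotations

import itertools
import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval

log = logging.getLogger(__name__)

NUCLEOSOME_UNIT = 170
MAX_PAIR_DISTANCE = 1000

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')
_REGION_RE = re.compile(r"^(\S+?):([\d,]+)\s*[-–—]\s*([\d,]+)$")


class AnnotationParseError(ValueError):
    """Raised for a malformed annotation line; message names the line number."""


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript's span and strand, with derived TSS/TES.

    ``start``/``end`` are 0-based half-open; ``tss`` is the first
    transcribed base (``start`` on +, ``end - 1`` on -).
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"transcript {self.transcript_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not self.start < self.end:
            raise ValueError(
                f"transcript {self.transcript_id}: start ({self.start}) must be < end ({self.end})"
            )

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


@dataclass(frozen=True)
class BidirectionalPair:
    """A divergent transcript pair: minus-strand TSS left of plus-strand TSS."""

    minus_tx: TranscriptModel
    plus_tx: TranscriptModel

    def __post_init__(self) -> None:
        if self.minus_tx.strand != "-" or self.plus_tx.strand != "+":
            raise ValueError("pair must be (minus-strand tx, plus-strand tx)")
        if self.minus_tx.chrom != self.plus_tx.chrom:
            raise ValueError("pair members must share a chromosome")
        if self.distance <= 0:
            raise ValueError(
                f"pair {self.minus_tx.transcript_id}/{self.plus_tx.transcript_id}: "
                f"TSSs overlap or are convergently ordered (distance {self.distance})"
            )

    @property
    def chrom(self) -> str:
        return self.minus_tx.chrom

    @property
    def tss_minus(self) -> int:
        return self.minus_tx.tss

    @property
    def tss_plus(self) -> int:
        return self.plus_tx.tss

    @property
    def distance(self) -> int:
        return self.plus_tx.tss - self.minus_tx.tss

    @property
    def midpoint(self) -> int:
        # "+1 then halve" for odd distances; exact half for even.
        return self.tss_minus + (self.distance + 1) // 2

    @property
    def nucleosome_bin(self) -> int:
        return math.ceil(self.distance / NUCLEOSOME_UNIT)

    @property
    def pair_id(self) -> str:
        return f"{self.chrom}:{self.tss_minus}-{self.tss_plus}"

    @property
    def intergenic(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.tss_minus, self.tss_plus)


@dataclass
class PairCatalog:
    """All discovered pairs plus the provenance of the discovery run."""

    pairs: list[BidirectionalPair]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "pair_id": p.pair_id,
                "chrom": p.chrom,
                "tss_minus": p.tss_minus,
                "tss_plus": p.tss_plus,
                "distance": p.distance,
                "nucleosome_bin": p.nucleosome_bin,
                "minus_tx": p.minus_tx.transcript_id,
                "plus_tx": p.plus_tx.transcript_id,
                "minus_gene": p.minus_tx.gene_id,
                "plus_gene": p.plus_tx.gene_id,
            }
            for p in self.pairs
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "pair_id",
                "chrom",
                "tss_minus",
                "tss_plus",
                "distance",
                "nucleosome_bin",
                "minus_tx",
                "plus_tx",
                "minus_gene",
                "plus_gene",
            ],
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    def write_intergenic_bed(self, path: str | Path) -> None:
        """BED4 of the intergenic (putative promoter) regions."""
        with open(path, "w") as fh:
            for p in self.pairs:
                fh.write(f"{p.chrom}\t{p.tss_minus}\t{p.tss_plus}\t{p.pair_id}\n")


def _parse_gtf(path: Path) -> list[TranscriptModel]:
    out: list[TranscriptModel] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise AnnotationParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            chrom, _source, feature, start1, end1, _score, strand, _frame, attrs = fields[:9]
            if feature != "transcript":
                continue
            try:
                start1i, end1i = int(start1), int(end1)
            except ValueError as exc:
                raise AnnotationParseError(
                    f"{path}: line {lineno}: non-integer coordinates ({start1!r}, {end1!r})"
                ) from exc
            attr = dict(_ATTR_RE.findall(attrs))
            if "transcript_id" not in attr:
                log.warning("%s: line %d: transcript record lacks transcript_id; skipped", path, lineno)
                continue
            if "gene_id" not in attr:
                log.warning(
                    "%s: line %d: transcript %s lacks gene_id; using transcript_id",
                    path, lineno, attr["transcript_id"],
                )
            strand = strand.replace("−", "-")
            try:
                out.append(
                    TranscriptModel(
                        transcript_id=attr["transcript_id"],
                        gene_id=attr.get("gene_id", attr["transcript_id"]),
                        chrom=chrom,
                        strand=strand,
                        # GTF is 1-based inclusive -> 0-based half-open
                        start=start1i - 1,
                        end=end1i,
                    )
                )
            except ValueError as exc:
                raise AnnotationParseError(f"{path}: line {lineno}: {exc}") from exc
    return out


def _parse_bed6(path: Path) -> list[TranscriptModel]:
    out: list[TranscriptModel] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise AnnotationParseError(
                    f"{path}: line {lineno}: BED6 needs 6 fields, got {len(fields)}"
                )
            chrom, start, end, name, _score, strand = fields[:6]
            try:
                out.append(
                    TranscriptModel(
                        transcript_id=name,
                        gene_id=name,  # BED6 carries no separate gene id
                        chrom=chrom,
                        strand=strand.replace("−", "-"),
                        start=int(start),
                        end=int(end),
                    )
                )
            except ValueError as exc:
                raise AnnotationParseError(f"{path}: line {lineno}: {exc}") from exc
    return out


def read_annotation(path: str | Path) -> list[TranscriptModel]:
    """Read transcript models from a GTF (.gtf/.gff) or BED6 (.bed) file.

    GTF coordinates (1-based inclusive) are converted to the internal
    0-based half-open convention. Only ``transcript`` feature rows are used.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".bed",):
        return _parse_bed6(path)
    return _parse_gtf(path)


def assign_nucleosome_bin(distance: int) -> int:
    """Nucleosome-unit bin of an intergenic distance: ``ceil(d / 170)``.

    Bin 1 covers 1-170 bp, bin 2 covers 171-340 bp, ..., bin 6 covers
    851-1000 bp (the printed bin edges overlap; the ceiling rule resolves
    a boundary distance into the lower bin).
    """
    if not 1 <= distance <= MAX_PAIR_DISTANCE:
        raise ValueError(f"distance {distance} outside the valid range 1..{MAX_PAIR_DISTANCE}")
    return math.ceil(distance / NUCLEOSOME_UNIT)


def interval_length(chrom_region: str) -> int:
    """Length of a printed ``chr:start-end`` region as ``end - start``.

    Accepts thousands separators and hyphen/en-dash/em-dash range marks.
    """
    m = _REGION_RE.match(chrom_region.strip())
    if m is None:
        raise ValueError(f"cannot parse genomic region {chrom_region!r}")
    start = int(m.group(2).replace(",", ""))
    end = int(m.group(3).replace(",", ""))
    if end < start:
        raise ValueError(f"negative span in region {chrom_region!r}")
    return end - start


def find_bidirectional_pairs(
    transcripts: Sequence[TranscriptModel],
    max_distance: int = MAX_PAIR_DISTANCE,
) -> PairCatalog:
    """Discover divergent transcript pairs with ``0 < distance <= max_distance``.

    See the module docstring for the isoform-expansion, gene-level
    TSS-overlap removal and duplicate-suppression rules.
    """
    if max_distance <= 0:
        raise ValueError("max_distance must be positive")
    for t in transcripts:
        if t.strand not in ("+", "-"):  # defensive; TranscriptModel enforces it
            raise ValueError(f"unknown strand {t.strand!r} for {t.transcript_id}")

    by_chrom_minus: dict[str, list[TranscriptModel]] = {}
    by_chrom_plus: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        (by_chrom_minus if t.strand == "-" else by_chrom_plus).setdefault(t.chrom, []).append(t)

    # isoforms per gene, for the gene-level overlap check
    gene_isoforms: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        gene_isoforms.setdefault(t.gene_id, []).append(t)

    candidates: list[BidirectionalPair] = []
    candidate_gene_pairs: set[tuple[str, str]] = set()
    for chrom, minus_list in by_chrom_minus.items():
        plus_list = by_chrom_plus.get(chrom)
        if not plus_list:
            continue
        plus_sorted = sorted(plus_list, key=lambda t: (t.tss, t.transcript_id))
        plus_tss = np.array([t.tss for t in plus_sorted])
        for m in minus_list:
            lo = int(np.searchsorted(plus_tss, m.tss, side="right"))
            hi = int(np.searchsorted(plus_tss, m.tss + max_distance, side="right"))
            for p in plus_sorted[lo:hi]:
                candidates.append(BidirectionalPair(minus_tx=m, plus_tx=p))
                candidate_gene_pairs.add((m.gene_id, p.gene_id))

    # drop whole gene pairs for which any isoform combination overlaps
    dropped_gene_pairs: set[tuple[str, str]] = set()
    for mg, pg in candidate_gene_pairs:
        for mt, pt in itertools.product(gene_isoforms[mg], gene_isoforms[pg]):
            if mt.strand != "-" or pt.strand != "+" or mt.chrom != pt.chrom:
                continue
            if pt.tss - mt.tss <= 0:
                dropped_gene_pairs.add((mg, pg))
                break
    if dropped_gene_pairs:
        log.info("removed %d gene pair(s) with overlapping TSS isoform combinations",
                 len(dropped_gene_pairs))

    kept: dict[tuple[str, int, int], BidirectionalPair] = {}
    for pair in sorted(
        candidates,
        key=lambda p: (p.chrom, p.tss_minus, p.tss_plus,
                       p.minus_tx.transcript_id, p.plus_tx.transcript_id),
    ):
        if (pair.minus_tx.gene_id, pair.plus_tx.gene_id) in dropped_gene_pairs:
            continue
        key = (pair.chrom, pair.tss_minus, pair.tss_plus)
        kept.setdefault(key, pair)  # identical TSS triples collapse

    catalog = PairCatalog(
        pairs=list(kept.values()),
        provenance={"n_transcripts": len(transcripts), "max_distance": max_distance},
    )
    log.info("pair discovery: %d transcripts -> %d candidate combinations -> %d pairs",
             len(transcripts), len(candidates), len(catalog))
    return catalog
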
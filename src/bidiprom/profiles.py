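"""Midpoint-anchored 4 kb frames, staggered sub-windows and meta-profiles.

Every pair contributes one frame of exactly ``size`` bp (default 4000)
centered on the midpoint of its intergenic region, chopped into
overlapping sub-intervals of ``length`` bp (default 170, one nucleosome
unit) whose starts advance by ``stagger`` bp (default 75). Because every
frame has the identical layout, frames can be overlaid by offset
(sub-interval start minus midpoint) and aggregated across pairs.

Frames are never strand-flipped: the plotting categories already encode
direction (a plus-high pair keeps its high gene on the right).
Frames that would extend past a chromosome end are dropped, not clipped,
so that all aggregated frames are strictly comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval
from .tracks import PeakSet, SignalTrack

log = logging.getLogger(__name__)

FRAME_SIZE = 4000
CHOP_LENGTH = 170
CHOP_STAGGER = 75


class FrameOutOfBounds(ValueError):
    """Frame would extend past a chromosome end."""


def intergenic_midpoint(tss_minus: int, tss_plus: int) -> int:
    """Midpoint between two TSSs; odd distances add 1 before halving."""
    if not tss_minus < tss_plus:
        raise ValueError(f"tss_minus ({tss_minus}) must be < tss_plus ({tss_plus})")
    d = tss_plus - tss_minus
    return tss_minus + (d + 1) // 2


def make_frame(
    midpoint: int,
    size: int = FRAME_SIZE,
    chrom: str = "",
    chrom_size: int | None = None,
) -> GenomicInterval:
    """The ``[midpoint - size/2, midpoint + size/2)`` window around a midpoint."""
    half = size // 2
    if midpoint < half:
        raise FrameOutOfBounds(f"frame around {midpoint} extends past the chromosome start")
    if chrom_size is not None and midpoint + half > chrom_size:
        raise FrameOutOfBounds(
            f"frame around {midpoint} extends past the chromosome end ({chrom_size})"
        )
    return GenomicInterval(chrom or "frame", midpoint - half, midpoint + half)


def chop_stagger(
    frame: GenomicInterval,
    length: int = CHOP_LENGTH,
    stagger: int = CHOP_STAGGER,
) -> list[GenomicInterval]:
    """Overlapping sub-intervals of ``length`` bp whose starts advance by ``stagger``."""
    if stagger < 1:
        raise ValueError("stagger must be >= 1")
    if length > len(frame):
        raise ValueError(f"sub-interval length {length} exceeds frame width {len(frame)}")
    starts = np.arange(frame.start, frame.end - length + 1, stagger)
    return [GenomicInterval(frame.chrom, int(s), int(s) + length) for s in starts]


def subinterval_offsets(
    size: int = FRAME_SIZE,
    length: int = CHOP_LENGTH,
    stagger: int = CHOP_STAGGER,
) -> np.ndarray:
    """Signed sub-interval start offsets relative to the midpoint."""
    half = size // 2
    return np.arange(-half, half - length + 1, stagger, dtype=np.int64)


@dataclass(frozen=True)
class WindowFrame:
    """One pair's frame with its sub-interval layout."""

    pair_id: str
    chrom: str
    midpoint: int
    size: int = FRAME_SIZE
    length: int = CHOP_LENGTH
    stagger: int = CHOP_STAGGER

    @property
    def frame(self) -> GenomicInterval:
        half = self.size // 2
        return GenomicInterval(self.chrom, self.midpoint - half, self.midpoint + half)

    @property
    def offsets(self) -> np.ndarray:
        return subinterval_offsets(self.size, self.length, self.stagger)

    @property
    def sub_starts(self) -> np.ndarray:
        return self.midpoint + self.offsets

    @property
    def subintervals(self) -> list[GenomicInterval]:
        return [GenomicInterval(self.chrom, int(s), int(s) + self.length) for s in self.sub_starts]


def build_frames(
    pairs: Iterable,
    chrom_sizes: Mapping[str, int] | None = None,
    size: int = FRAME_SIZE,
    length: int = CHOP_LENGTH,
    stagger: int = CHOP_STAGGER,
) -> list[WindowFrame]:
    """Frames for an iterable of objects with ``pair_id``/``chrom``/``midpoint``.

    Pairs whose frame would leave the chromosome are dropped with a warning.
    """
    out: list[WindowFrame] = []
    for p in pairs:
        chrom_size = None if chrom_sizes is None else chrom_sizes.get(p.chrom)
        try:
            make_frame(p.midpoint, size=size, chrom=p.chrom, chrom_size=chrom_size)
        except FrameOutOfBounds as exc:
            log.warning("pair %s dropped: %s", p.pair_id, exc)
            continue
        out.append(WindowFrame(p.pair_id, p.chrom, p.midpoint, size, length, stagger))
    return out


@dataclass
class MetaProfile:
    """Per-category cumulative enrichment over the common frame layout.

    ``values`` are the across-pair sums of per-sub-interval mean signal,
    divided by the category's own maximum, hence in [0, 1] with the
    maximum exactly 1 whenever any signal is present.
    """

    category: str
    offsets: np.ndarray
    values: np.ndarray
    n_pairs: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "category": self.category,
                "offset": self.offsets,
                "value": self.values,
                "n_pairs": self.n_pairs,
            }
        )


def build_meta_profile(
    frames_by_category: Mapping[str, Sequence[WindowFrame]],
    track: SignalTrack,
    size: int = FRAME_SIZE,
    length: int = CHOP_LENGTH,
    stagger: int = CHOP_STAGGER,
) -> dict[str, MetaProfile]:
    """Max-normalized cumulative meta-profile for each category.

    For each offset the raw value is the sum, over the category's pairs,
    of the mean track signal in the 170 bp sub-interval at that offset;
    the category vector is then scaled by its own maximum. An empty
    category yields a zero profile with ``n_pairs = 0``.
    """
    offsets = subinterval_offsets(size, length, stagger)
    out: dict[str, MetaProfile] = {}
    for category, frames in frames_by_category.items():
        total = np.zeros(len(offsets), dtype=float)
        for fr in frames:
            if (fr.size, fr.length, fr.stagger) != (size, length, stagger):
                raise ValueError("all frames must share the sub-interval layout")
            starts = fr.sub_starts
            total += track.value_sums(fr.chrom, starts, starts + length) / length
        peak = total.max() if len(frames) else 0.0
        values = total / peak if peak > 0 else total
        out[category] = MetaProfile(category, offsets.copy(), values, n_pairs=len(frames))
    return out


@dataclass(frozen=True)
class SideEnrichment:
    """Peak-restricted cumulative signal on each side of a pair's midpoint."""

    pair_id: str
    mark: str
    left_sum: float
    right_sum: float

    def __post_init__(self) -> None:
        if self.left_sum < 0 or self.right_sum < 0:
            raise ValueError("side sums must be non-negative")


def side_cumulative_enrichment(
    frame: WindowFrame,
    track: SignalTrack,
    peaks: PeakSet,
    q_max: float = 0.05,
    mark: str = "",
) -> SideEnrichment:
    """Cumulative signal inside significant peaks on each side of the midpoint.

    Only peaks with ``q < q_max`` contribute, clipped to the frame. A peak
    interval straddling the midpoint is discarded from *both* sides — the
    reference point cannot attribute it to one gene without double counting.
    """
    fi = frame.frame
    mid = frame.midpoint
    left = right = 0.0
    for _, pk in peaks.overlapping(fi, q_max=q_max).iterrows():
        s, e = int(pk["start"]), int(pk["end"])
        if s < mid < e:
            log.debug("pair %s: peak [%d,%d) straddles the midpoint; discarded", frame.pair_id, s, e)
            continue
        cs, ce = max(s, fi.start), min(e, fi.end)
        if cs >= ce:
            continue
        if ce <= mid:
            left += track.value_sum(fi.chrom, cs, ce)
        else:
            right += track.value_sum(fi.chrom, cs, ce)
    return SideEnrichment(frame.pair_id, mark, left, right)


def side_enrichment_table(
    frames: Sequence[WindowFrame],
    track: SignalTrack,
    peaks: PeakSet,
    mark: str,
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Per-pair left/right peak-restricted sums for one mark."""
    rows = [
        side_cumulative_enrichment(fr, track, peaks, q_max=q_max, mark=mark)
        for fr in frames
    ]
    return pd.DataFrame(
        [(r.pair_id, r.mark, r.left_sum, r.right_sum) for r in rows],
        columns=["pair_id", "mark", "left_sum", "right_sum"],
    )
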
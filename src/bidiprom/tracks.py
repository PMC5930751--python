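"""Piecewise-constant signal tracks and significance-scored peak sets.

``SignalTrack`` holds a fold-enrichment track with bedgraph semantics:
sorted, non-overlapping scored intervals per chromosome; any base not
covered by a record has value 0. Interval aggregation uses prefix sums,
so querying is O(log n) per interval regardless of how finely the track
is fragmented.

``map_mean`` is the base-weighted mean over *all* bases of the query
interval (uncovered bases contribute 0). This deliberately differs from
element-wise averaging of overlapping records: the base-weighted mean is
invariant to how a constant region is split into bedgraph records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import GenomicInterval

log = logging.getLogger(__name__)

BEDGRAPH_COLS = ["chrom", "start", "end", "value"]
NARROWPEAK_COLS = [
    "chrom", "start", "end", "name", "score",
    "strand", "signalValue", "pValue", "qValue", "peak",
]


class SignalTrack:
    """Sorted non-overlapping scored intervals over a genome."""

    def __init__(self, data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self._prefix: dict[str, np.ndarray] = {}
        for chrom, (starts, ends, vals) in data.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            vals = np.asarray(vals, dtype=float)
            if not (len(starts) == len(ends) == len(vals)):
                raise ValueError(f"{chrom}: ragged track arrays")
            if np.any(starts >= ends):
                raise ValueError(f"{chrom}: track has an empty or inverted interval")
            if np.any(ends[:-1] > starts[1:]):
                i = int(np.argmax(ends[:-1] > starts[1:]))
                raise ValueError(
                    f"{chrom}: overlapping bedgraph records at "
                    f"[{starts[i]},{ends[i]}) and [{starts[i + 1]},{ends[i + 1]})"
                )
            if not np.all(np.isfinite(vals)):
                raise ValueError(f"{chrom}: non-finite track value")
            self._data[chrom] = (starts, ends, vals)
            self._prefix[chrom] = np.concatenate([[0.0], np.cumsum(vals * (ends - starts))])

    @property
    def chroms(self) -> list[str]:
        return sorted(self._data)

    def n_records(self) -> int:
        return sum(len(s) for s, _, _ in self._data.values())

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, sort: bool = True) -> "SignalTrack":
        if sort:
            df = df.sort_values(["chrom", "start"], kind="mergesort")
        data = {
            str(chrom): (
                g["start"].to_numpy(np.int64),
                g["end"].to_numpy(np.int64),
                g["value"].to_numpy(float),
            )
            for chrom, g in df.groupby("chrom", sort=True)
        }
        return cls(data)

    def to_dataframe(self) -> pd.DataFrame:
        frames = [
            pd.DataFrame({"chrom": chrom, "start": s, "end": e, "value": v})
            for chrom, (s, e, v) in sorted(self._data.items())
        ]
        if not frames:
            return pd.DataFrame(columns=BEDGRAPH_COLS)
        return pd.concat(frames, ignore_index=True)

    def value_sums(self, chrom: str, starts, ends) -> np.ndarray:
        """Vectorized sum of value x covered-length over each [start, end)."""
        qs = np.asarray(starts, dtype=np.int64)
        qe = np.asarray(ends, dtype=np.int64)
        if np.any(qs >= qe):
            raise ValueError("query intervals must satisfy start < end")
        if chrom not in self._data:
            return np.zeros(len(qs), dtype=float)
        ts, te, tv = self._data[chrom]
        pref = self._prefix[chrom]
        lo = np.searchsorted(te, qs, side="right")   # first record ending after qs
        hi = np.searchsorted(ts, qe, side="left")    # first record starting at/after qe
        total = pref[np.maximum(hi, lo)] - pref[lo]
        has = hi > lo
        if np.any(has):
            lo_h = lo[has]
            hi_h = hi[has] - 1
            # trim the partially overlapped first/last records
            left_trim = np.clip(qs[has] - ts[lo_h], 0, None) * tv[lo_h]
            right_trim = np.clip(te[hi_h] - qe[has], 0, None) * tv[hi_h]
            total[has] = total[has] - left_trim - right_trim
        return total

    def value_sum(self, chrom: str, start: int, end: int) -> float:
        return float(self.value_sums(chrom, [start], [end])[0])

    def write_bedgraph(self, path: str | Path, float_format: str = "%.6g") -> None:
        self.to_dataframe().to_csv(
            path, sep="\t", header=False, index=False, float_format=float_format
        )


def map_mean(track: SignalTrack, interval: GenomicInterval) -> float:
    """Base-weighted mean of the track over the interval (uncovered = 0)."""
    return track.value_sum(interval.chrom, interval.start, interval.end) / len(interval)


def _locate_bad_line(path: Path, ncols: int) -> str:
    """Best-effort line-number diagnostics for a malformed numeric file."""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < ncols:
                return f"{path}: line {lineno}: expected {ncols} fields, got {len(fields)}"
            try:
                int(fields[1]); int(fields[2]); float(fields[3])
            except ValueError:
                return f"{path}: line {lineno}: malformed numeric field"
    return f"{path}: malformed file"


def read_bedgraph(path: str | Path, strict_sorted: bool = False) -> SignalTrack:
    """Read a 4-column bedgraph into a :class:`SignalTrack`.

    Unsorted input is sorted unless ``strict_sorted`` is set, in which
    case it is an error. Overlapping records are always an error.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep=r"\s+", names=BEDGRAPH_COLS, comment="#",
            dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": float},
        )
    except (ValueError, TypeError) as exc:
        raise ValueError(_locate_bad_line(path, 4)) from exc
    if df.empty:
        return SignalTrack({})
    is_sorted = (
        df.groupby("chrom", sort=False)["start"].apply(lambda s: s.is_monotonic_increasing).all()
    )
    if not is_sorted:
        if strict_sorted:
            raise ValueError(f"{path}: bedgraph is not coordinate-sorted")
        log.warning("%s: bedgraph not sorted; sorting in memory", path)
    return SignalTrack.from_dataframe(df)


@dataclass
class PeakSet:
    """Significant intervals with per-interval q-values (FDR)."""

    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["chrom", "start", "end", "qvalue"]))

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "qvalue"}
        if not required.issubset(self.df.columns):
            raise ValueError(f"PeakSet frame needs columns {sorted(required)}")
        if len(self.df):
            if (self.df["start"] >= self.df["end"]).any():
                raise ValueError("peak with start >= end")
            q = self.df["qvalue"]
            if ((q <= 0) | (q > 1)).any():
                raise ValueError("peak q-values must lie in (0, 1]")

    def __len__(self) -> int:
        return len(self.df)

    def significant(self, q_max: float = 0.05) -> pd.DataFrame:
        return self.df[self.df["qvalue"] < q_max]

    def overlapping(self, interval: GenomicInterval, q_max: float = 0.05) -> pd.DataFrame:
        sig = self.significant(q_max)
        m = (
            (sig["chrom"] == interval.chrom)
            & (sig["start"] < interval.end)
            & (sig["end"] > interval.start)
        )
        return sig[m]

    def write_narrowpeak(self, path: str | Path) -> None:
        df = self.df
        out = pd.DataFrame(
            {
                "chrom": df["chrom"],
                "start": df["start"],
                "end": df["end"],
                "name": df.get("name", pd.Series([f"peak_{i}" for i in range(len(df))])),
                "score": df.get("score", pd.Series([0] * len(df))),
                "strand": ".",
                "signalValue": df.get("signalValue", pd.Series([0.0] * len(df))),
                "pValue": df.get("pValue", pd.Series([-1.0] * len(df))),
                "qValue": -np.log10(df["qvalue"]),
                "peak": df.get("peak", pd.Series([-1] * len(df))),
            }
        )
        out.to_csv(path, sep="\t", header=False, index=False, float_format="%.5f")


def read_peaks(path: str | Path) -> PeakSet:
    """Read peak calls from narrowPeak (10 cols) or a q-value bedgraph (4 cols).

    In both dialects the significance column holds ``-log10(q)`` (MACS2
    convention); the stored q-value is recovered as ``10**(-col)``.
    """
    path = Path(path)
    with open(path) as fh:
        first = ""
        for line in fh:
            if line.strip() and not line.startswith(("#", "track", "browser")):
                first = line
                break
    ncols = len(first.split("\t")) if first else 0
    if ncols >= 10:
        df = pd.read_csv(path, sep="\t", names=NARROWPEAK_COLS, comment="#")
        q = np.power(10.0, -df["qValue"].astype(float))
        out = df[["chrom", "start", "end", "name", "signalValue"]].copy()
        out["qvalue"] = q
    elif ncols == 4:
        df = pd.read_csv(path, sep=r"\s+", names=BEDGRAPH_COLS, comment="#")
        out = df[["chrom", "start", "end"]].copy()
        out["qvalue"] = np.power(10.0, -df["value"].astype(float))
    else:
        raise ValueError(f"{path}: expected narrowPeak (10 columns) or q-value bedgraph (4)")
    return PeakSet(out)
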
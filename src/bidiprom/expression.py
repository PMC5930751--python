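"""Expression-symmetry classification of bidirectional pairs.

Each pair falls in exactly one of three classes, judged from the TPM of
its two member transcripts:

* ``symmetric_silent`` — both TPM below the silent threshold (default 1);
* ``asymmetric`` — expression ratio strictly greater than the fold
  threshold (default 2); the more highly expressed strand is recorded;
* ``symmetric_expressed`` — everything else.

The ratio is ``max(tpm) / max(min(tpm), floor)`` with a small floor
(default 0.1 TPM) so a pair like (50, 0) is asymmetric rather than
undefined. Classification is per transcript (isoform), matching the
isoform-level pair expansion of the catalog.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .pair_catalog import PairCatalog, TranscriptModel

log = logging.getLogger(__name__)

LABELS = ("asymmetric", "symmetric_expressed", "symmetric_silent")
PLOT_CATEGORIES = ("plus_high", "minus_high", "both_expressed", "silent")


@dataclass(frozen=True)
class PairClassification:
    """Symmetry label of one pair plus the derived plotting category."""

    label: str
    high_side: str  # {plus, minus, none}
    ratio: float
    pair_id: str = ""

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if (self.label == "asymmetric") != (self.high_side != "none"):
            raise ValueError("high_side must be set exactly for asymmetric pairs")
        if self.ratio < 1:
            raise ValueError("ratio is defined as larger/smaller and must be >= 1")

    @property
    def plot_category(self) -> str:
        return assign_plot_category(self)


def assign_plot_category(classification: PairClassification) -> str:
    """Map a classification to its meta-profile plotting category."""
    if classification.label == "asymmetric":
        return "plus_high" if classification.high_side == "plus" else "minus_high"
    if classification.label == "symmetric_expressed":
        return "both_expressed"
    return "silent"


def read_tpm_table(path: str | Path) -> pd.Series:
    """Read a per-transcript TPM table (RSEM ``isoforms.results`` dialect).

    The header must contain a ``transcript_id`` column and a ``TPM``
    column (matched case-insensitively); any extra columns are ignored.
    Returns a float Series indexed by transcript id.
    """
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if "transcript_id" not in cols or "tpm" not in cols:
        raise ValueError(
            f"{path}: expected header with 'transcript_id' and 'TPM' columns, got {list(df.columns)}"
        )
    tpm = pd.to_numeric(df[cols["tpm"]], errors="raise").astype(float)
    ids = df[cols["transcript_id"]].astype(str)
    dup = ids[ids.duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicated transcript_id(s): {sorted(set(dup))[:5]}")
    if (tpm < 0).any():
        bad = ids[tpm < 0].iloc[0]
        raise ValueError(f"{path}: negative TPM for transcript {bad}")
    out = pd.Series(tpm.to_numpy(), index=pd.Index(ids, name="transcript_id"), name="tpm")
    return out


def classify_pair(
    tpm_minus: float,
    tpm_plus: float,
    fold_threshold: float = 2.0,
    silent_threshold: float = 1.0,
    floor: float = 0.1,
    pair_id: str = "",
) -> PairClassification:
    """Classify one pair from the TPM of its minus- and plus-strand members."""
    for name, v in (("tpm_minus", tpm_minus), ("tpm_plus", tpm_plus)):
        if not math.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v}")
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")
    if tpm_minus < silent_threshold and tpm_plus < silent_threshold:
        return PairClassification("symmetric_silent", "none", 1.0, pair_id)
    hi, lo = max(tpm_minus, tpm_plus), min(tpm_minus, tpm_plus)
    ratio = hi / max(lo, floor)
    ratio = max(ratio, 1.0)  # floored denominator can otherwise push ratio below 1
    if ratio > fold_threshold:  # strictly more than fold_threshold-fold
        side = "minus" if tpm_minus > tpm_plus else "plus"
        return PairClassification("asymmetric", side, ratio, pair_id)
    return PairClassification("symmetric_expressed", "none", ratio, pair_id)


def classify_catalog(
    catalog: PairCatalog,
    tpm: pd.Series,
    fold_threshold: float = 2.0,
    silent_threshold: float = 1.0,
    floor: float = 0.1,
) -> pd.DataFrame:
    """Classify every pair of a catalog against a TPM table.

    Raises ``KeyError`` naming the first transcript absent from the table.
    """
    rows = []
    for p in catalog:
        for tx in (p.minus_tx.transcript_id, p.plus_tx.transcript_id):
            if tx not in tpm.index:
                raise KeyError(f"transcript {tx} of pair {p.pair_id} missing from the TPM table")
        c = classify_pair(
            float(tpm[p.minus_tx.transcript_id]),
            float(tpm[p.plus_tx.transcript_id]),
            fold_threshold=fold_threshold,
            silent_threshold=silent_threshold,
            floor=floor,
            pair_id=p.pair_id,
        )
        rows.append(
            {
                "pair_id": p.pair_id,
                "label": c.label,
                "high_side": c.high_side,
                "ratio": c.ratio,
                "plot_category": c.plot_category,
                "tpm_minus": float(tpm[p.minus_tx.transcript_id]),
                "tpm_plus": float(tpm[p.plus_tx.transcript_id]),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["pair_id", "label", "high_side", "ratio", "plot_category",
                 "tpm_minus", "tpm_plus"],
    )
    if not df.empty:
        log.info("classification: %s", df["label"].value_counts().to_dict())
    return df


def sample_matched_unidirectional(
    all_transcripts: list[TranscriptModel],
    expression: pd.Series,
    bidir_catalog: PairCatalog,
    n: int,
    seed: int,
) -> list[str]:
    """Sample ``n`` unidirectional control transcripts, expression-matched.

    Eligible transcripts are not members of any bidirectional pair and have
    a TPM inside the [min, max] envelope of the TPMs of pair members.
    Sampling is uniform without replacement under ``seed``.
    """
    members: set[str] = set()
    member_tpms: list[float] = []
    for p in bidir_catalog:
        for tx in (p.minus_tx.transcript_id, p.plus_tx.transcript_id):
            members.add(tx)
            if tx in expression.index:
                member_tpms.append(float(expression[tx]))
    if not member_tpms:
        raise ValueError("no bidirectional pair member has an expression value")
    lo, hi = min(member_tpms), max(member_tpms)

    eligible = sorted(
        t.transcript_id
        for t in all_transcripts
        if t.transcript_id not in members
        and t.transcript_id in expression.index
        and lo <= float(expression[t.transcript_id]) <= hi
    )
    if n < 0:
        raise ValueError("n must be non-negative")
    if len(eligible) < n:
        raise ValueError(
            f"only {len(eligible)} eligible unidirectional transcripts for a request of {n} "
            f"(shortfall {n - len(eligible)})"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(eligible), size=n, replace=False)
    return [eligible[i] for i in sorted(idx)]
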
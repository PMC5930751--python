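"""Synthetic annotation, expression, signal and peak generator.

The generator lays out divergent gene pairs (and unidirectional control
genes) along one synthetic chromosome, draws intergenic distances from a
six-bin nucleosome-unit mixture, designs each pair's expression class
with construction margins wide enough that the classifier must recover
the designed label, and paints per-mark fold-enrichment tracks:

* initiation marks: a Gaussian bump centered a fixed offset downstream of
  each expressed TSS in the direction of transcription;
* elongation marks: a plateau over the expressed gene body starting a
  fixed offset downstream of the TSS;

in both cases scaled by ``amplitude_per_log_tpm * log2(1 + TPM)`` on top
of a flat background. Peaks are derived from the *noiseless* signal
(regions exceeding ``background * peak_fold``) so that recovery tests are
not flaky; seeded Gaussian noise perturbs only the emitted track values.

Everything is deterministic under the config seed: two runs with an
identical config produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .pair_catalog import TranscriptModel, assign_nucleosome_bin
from .tracks import PeakSet, SignalTrack

log = logging.getLogger(__name__)

# Table-derived default mixture of intergenic distances over the six
# nucleosome-unit bins (1-170, 171-340, ..., 851-1000 bp).
DEFAULT_DISTANCE_WEIGHTS = (453, 245, 120, 78, 44, 34)
_BIN_LO = np.array([1, 171, 341, 511, 681, 851])
_BIN_HI = np.array([170, 340, 510, 680, 850, 1000])

LABELS = ("asymmetric", "symmetric_expressed", "symmetric_silent")


@dataclass(frozen=True)
class MarkModel:
    """Shape model of one histone mark's enrichment around active genes."""

    kind: str  # "initiation" | "elongation"
    amplitude_per_log_tpm: float
    bump_offset: int = 100     # bump center, bp downstream of the TSS
    bump_sd: float = 130.0     # bump width (Gaussian sd, bp)
    body_offset: int = 500     # plateau start, bp downstream of the TSS
    background_level: float = 1.0
    noise_sd: float = 0.25

    def __post_init__(self) -> None:
        if self.kind not in ("initiation", "elongation"):
            raise ValueError(f"unknown mark kind {self.kind!r}")
        if self.bump_sd <= 0 or self.amplitude_per_log_tpm < 0:
            raise ValueError("bump_sd must be > 0 and amplitude >= 0")


def default_marks() -> dict[str, MarkModel]:
    return {
        "H3K4me3": MarkModel("initiation", amplitude_per_log_tpm=2.0),
        "H3K27ac": MarkModel("initiation", amplitude_per_log_tpm=1.5),
        "H3K36me3": MarkModel("elongation", amplitude_per_log_tpm=1.0),
        "H3K79me1": MarkModel("elongation", amplitude_per_log_tpm=0.8),
    }


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults emulate the study's inputs."""

    seed: int = 0
    n_pairs: int = 300
    n_unidirectional: int = 500
    chrom: str = "chrS"
    chrom_size: int | None = None  # None -> sized automatically
    spacing: int = 45_000          # bp between successive gene loci
    margin: int = 25_000           # bp clear of each chromosome end
    distance_weights: tuple = DEFAULT_DISTANCE_WEIGHTS
    # fix every intergenic distance to one value (used for null calibration,
    # where constant pair geometry makes left/right sums iid)
    fixed_distance: int | None = None
    # asymmetric : symmetric expressed : symmetric silent
    class_mix: tuple = (319 / 974, 65 / 974, 590 / 974)
    asym_fold: float = 3.0         # designed fold gap of asymmetric pairs
    tpm_meanlog: float = math.log(10.0)
    tpm_sdlog: float = 1.0
    gene_length_range: tuple = (2000, 20_000)
    uni_silent_fraction: float = 0.4
    resolution: int = 10           # bp per simulated signal bin
    peak_fold: float = 2.0         # noiseless > background*fold -> peak
    peak_q: float = 0.01
    silent_threshold: float = 1.0  # TPM below which a gene paints no signal
    marks: dict = field(default_factory=default_marks)

    def __post_init__(self) -> None:
        w = np.asarray(self.distance_weights, dtype=float)
        if len(w) != 6 or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("distance_weights must be 6 non-negative values")
        mix = np.asarray(self.class_mix, dtype=float)
        if len(mix) != 3 or np.any(mix < 0) or not np.isclose(mix.sum(), 1.0, atol=1e-6):
            raise ValueError("class_mix must be 3 proportions summing to 1")
        if self.n_pairs < 0 or self.n_unidirectional < 0:
            raise ValueError("gene counts must be non-negative")
        lo, hi = self.gene_length_range
        if not (0 < lo <= hi):
            raise ValueError("invalid gene_length_range")
        if self.resolution < 1:
            raise ValueError("resolution must be >= 1")
        marks = {
            name: (m if isinstance(m, MarkModel) else MarkModel(**m))
            for name, m in self.marks.items()
        }
        object.__setattr__(self, "marks", marks)
        needed = self.required_chrom_size()
        if self.chrom_size is not None and self.chrom_size < needed:
            raise ValueError(
                f"chromosome of {self.chrom_size} bp too small for "
                f"{self.n_pairs} pairs + {self.n_unidirectional} unidirectional genes "
                f"(needs >= {needed} bp)"
            )
        if self.margin < self.gene_length_range[1] + 2500:
            raise ValueError("margin must exceed the maximum gene length + 2500 bp")

    def required_chrom_size(self) -> int:
        return 2 * self.margin + self.spacing * (self.n_pairs + self.n_unidirectional)

    @property
    def effective_chrom_size(self) -> int:
        return self.chrom_size if self.chrom_size is not None else self.required_chrom_size()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["marks"] = {k: asdict(v) for k, v in self.marks.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("distance_weights", "class_mix", "gene_length_range"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


def _stage_rng(config: SimulationConfig, stage: int, sub: int = 0) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % (2**31), stage, sub])


def simulate_pairs(config: SimulationConfig):
    """Lay out divergent pairs and unidirectional genes along the chromosome.

    Returns ``(transcripts, truth, uni)``: the transcript models of every
    simulated gene (one isoform each), the designed pair truth table
    (distances, bins, class labels, high sides; TPMs are filled in by
    :func:`simulate_expression`) and the unidirectional gene table.
    """
    rng = _stage_rng(config, 1)
    n, nu = config.n_pairs, config.n_unidirectional
    w = np.asarray(config.distance_weights, float)
    w = w / w.sum()
    glo, ghi = config.gene_length_range

    bins = rng.choice(6, size=n, p=w)
    dist = rng.integers(_BIN_LO[bins], _BIN_HI[bins] + 1)
    if config.fixed_distance is not None:
        if not 1 <= config.fixed_distance <= 1000:
            raise ValueError("fixed_distance must lie in 1..1000")
        dist = np.full(n, config.fixed_distance, dtype=np.int64)
    lengths = rng.integers(glo, ghi + 1, size=(n, 2))
    labels = np.array(LABELS)[rng.choice(3, size=n, p=np.asarray(config.class_mix, float))]
    high_side = np.where(
        labels == "asymmetric", np.where(rng.random(n) < 0.5, "minus", "plus"), "none"
    )
    uni_strand = np.where(rng.random(nu) < 0.5, "+", "-")
    uni_lengths = rng.integers(glo, ghi + 1, size=nu)

    anchors = config.margin + np.arange(n, dtype=np.int64) * config.spacing
    tss_minus = anchors
    tss_plus = anchors + dist

    transcripts: list[TranscriptModel] = []
    rows = []
    for i in range(n):
        tm, tp = int(tss_minus[i]), int(tss_plus[i])
        lm, lp = int(lengths[i, 0]), int(lengths[i, 1])
        minus = TranscriptModel(
            f"TXM{i:05d}", f"GM{i:05d}", config.chrom, "-", tm - lm + 1, tm + 1
        )
        plus = TranscriptModel(
            f"TXP{i:05d}", f"GP{i:05d}", config.chrom, "+", tp, tp + lp
        )
        transcripts += [minus, plus]
        rows.append(
            {
                "pair_id": f"{config.chrom}:{tm}-{tp}",
                "chrom": config.chrom,
                "tss_minus": tm,
                "tss_plus": tp,
                "distance": int(dist[i]),
                "nucleosome_bin": assign_nucleosome_bin(int(dist[i])),
                "label": labels[i],
                "high_side": high_side[i],
                "minus_tx": minus.transcript_id,
                "plus_tx": plus.transcript_id,
            }
        )
    truth = pd.DataFrame(rows)

    uni_rows = []
    uni_anchor0 = config.margin + n * config.spacing
    for j in range(nu):
        anchor = int(uni_anchor0 + j * config.spacing)
        lg = int(uni_lengths[j])
        if uni_strand[j] == "+":
            tx = TranscriptModel(f"TXU{j:05d}", f"GU{j:05d}", config.chrom, "+", anchor, anchor + lg)
        else:
            tx = TranscriptModel(
                f"TXU{j:05d}", f"GU{j:05d}", config.chrom, "-", anchor - lg + 1, anchor + 1
            )
        transcripts.append(tx)
        uni_rows.append(
            {
                "transcript_id": tx.transcript_id,
                "gene_id": tx.gene_id,
                "chrom": tx.chrom,
                "strand": tx.strand,
                "tss": tx.tss,
                "start": tx.start,
                "end": tx.end,
            }
        )
    uni = pd.DataFrame(
        uni_rows,
        columns=["transcript_id", "gene_id", "chrom", "strand", "tss", "start", "end"],
    )
    return transcripts, truth, uni


def simulate_expression(config: SimulationConfig, truth: pd.DataFrame, uni: pd.DataFrame):
    """Draw TPMs realizing the designed class labels with safety margins.

    Margins: designed asymmetric ratios are at least ``1.5 * asym_fold``
    (well above the 2-fold classification threshold), silent TPMs stay
    below 0.5, and symmetric expressed TPMs stay above 2 with within-pair
    ratio at most 1.3 — so the classifier recovers every designed label.
    Returns ``(expression, truth)`` with TPM columns added to the truth.
    """
    if config.asym_fold <= 2:
        raise ValueError(
            f"asym_fold must exceed the 2-fold classification threshold, got {config.asym_fold}"
        )
    rng = _stage_rng(config, 2)
    n = len(truth)
    tpm_minus = np.empty(n)
    tpm_plus = np.empty(n)
    u_cap = math.sqrt(1.3)  # two independent factors keep ratios <= 1.3

    for i, row in enumerate(truth.itertuples(index=False)):
        if row.label == "asymmetric":
            low = math.exp(rng.uniform(math.log(1.5), math.log(20.0)))
            ratio = rng.uniform(config.asym_fold * 1.5, config.asym_fold * 3.0)
            hi_v, lo_v = low * ratio, low
            if row.high_side == "minus":
                tpm_minus[i], tpm_plus[i] = hi_v, lo_v
            else:
                tpm_minus[i], tpm_plus[i] = lo_v, hi_v
        elif row.label == "symmetric_expressed":
            base = float(np.clip(rng.lognormal(config.tpm_meanlog, config.tpm_sdlog), 2.0, 500.0))
            tpm_minus[i] = base * rng.uniform(1.0, u_cap)
            tpm_plus[i] = base * rng.uniform(1.0, u_cap)
        else:  # symmetric_silent
            tpm_minus[i] = rng.uniform(0.0, 0.5)
            tpm_plus[i] = rng.uniform(0.0, 0.5)

    nu = len(uni)
    uni_tpm = np.where(
        rng.random(nu) < config.uni_silent_fraction,
        rng.uniform(0.0, 0.5, size=nu),
        np.clip(rng.lognormal(config.tpm_meanlog, config.tpm_sdlog, size=nu), 1.5, 500.0),
    )

    truth = truth.copy()
    truth["tpm_minus"] = np.round(tpm_minus, 4)
    truth["tpm_plus"] = np.round(tpm_plus, 4)
    expression = pd.Series(
        np.concatenate(
            [np.round(tpm_minus, 4), np.round(tpm_plus, 4), np.round(uni_tpm, 4)]
        ),
        index=pd.Index(
            list(truth["minus_tx"]) + list(truth["plus_tx"]) + list(uni["transcript_id"]),
            name="transcript_id",
        ),
        name="tpm",
    )
    return expression, truth


def _mark_signal(
    config: SimulationConfig,
    mark: MarkModel,
    transcripts: list[TranscriptModel],
    expression: pd.Series,
    nb: int,
) -> np.ndarray:
    """Noiseless per-bin signal for one mark over the whole chromosome."""
    res = config.resolution
    signal = np.full(nb, mark.background_level, dtype=float)
    centers = np.arange(nb, dtype=float) * res + res / 2.0
    for tx in transcripts:
        tpm = float(expression.get(tx.transcript_id, 0.0))
        if tpm < config.silent_threshold:
            continue
        amp = mark.amplitude_per_log_tpm * math.log2(1.0 + tpm)
        if mark.kind == "initiation":
            c = tx.tss + mark.bump_offset if tx.strand == "+" else tx.tss - mark.bump_offset
            lo = max(0, int((c - 4 * mark.bump_sd) // res))
            hi = min(nb, int((c + 4 * mark.bump_sd) // res) + 1)
            xs = centers[lo:hi]
            signal[lo:hi] += amp * np.exp(-((xs - c) ** 2) / (2.0 * mark.bump_sd**2))
        else:  # elongation plateau over the gene body, body_offset past the TSS
            if tx.strand == "+":
                b0, b1 = tx.start + mark.body_offset, tx.end
            else:
                b0, b1 = tx.start, tx.end - mark.body_offset
            if b1 <= b0:
                continue
            # bins whose center falls in [b0, b1): keeps the painted plateau
            # mirror-symmetric between the strands regardless of bin phase
            mlo = max(0, math.ceil((b0 - res / 2) / res))
            mhi = min(nb, math.ceil((b1 - res / 2) / res))
            signal[mlo:mhi] += amp
    return signal


def _noise_regions(
    config: SimulationConfig,
    truth: pd.DataFrame,
    uni: pd.DataFrame,
    transcripts: list[TranscriptModel],
    nb: int,
) -> list[tuple[int, int]]:
    """Bin-index spans around each locus inside which noise is added."""
    res = config.resolution
    span_by_tx = {t.transcript_id: (t.start, t.end) for t in transcripts}
    regions = []
    for row in truth.itertuples(index=False):
        s = span_by_tx[row.minus_tx][0] - 500
        e = span_by_tx[row.plus_tx][1] + 500
        regions.append((max(0, s // res), min(nb, -(-e // res))))
    for row in uni.itertuples(index=False):
        regions.append(
            (max(0, (row.start - 2500) // res), min(nb, -(-(row.end + 2500) // res)))
        )
    regions.sort()
    merged: list[tuple[int, int]] = []
    for s, e in regions:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _rle_track(chrom: str, values: np.ndarray, res: int) -> SignalTrack:
    change = np.flatnonzero(np.diff(values)) + 1
    starts = np.concatenate([[0], change]) * res
    ends = np.concatenate([change, [len(values)]]) * res
    return SignalTrack({chrom: (starts, ends, values[starts // res])})


def _peaks_from_mask(
    chrom: str, mask: np.ndarray, signal: np.ndarray, bg: float, res: int, q: float
) -> PeakSet:
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[0::2], edges[1::2]
    rows = []
    for k, (s, e) in enumerate(zip(starts, ends)):
        seg = signal[s:e]
        rows.append(
            {
                "chrom": chrom,
                "start": int(s) * res,
                "end": int(e) * res,
                "name": f"peak_{k}",
                "signalValue": float(seg.max() - bg),
                "qvalue": q,
                "peak": int(np.argmax(seg)) * res,
            }
        )
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "signalValue", "qvalue", "peak"])
    if df.empty:
        df = pd.DataFrame(columns=["chrom", "start", "end", "qvalue"])
    return PeakSet(df)


def simulate_tracks(
    config: SimulationConfig,
    truth: pd.DataFrame,
    uni: pd.DataFrame,
    transcripts: list[TranscriptModel],
    expression: pd.Series,
):
    """Per-mark fold-enrichment tracks and q-valued peak calls.

    Returns ``(tracks, peaks)``: dicts keyed by mark name. Peaks are the
    contiguous regions where the *noiseless* signal exceeds
    ``background * peak_fold``; the emitted track adds seeded Gaussian
    noise (clipped at 0) inside each simulated locus.
    """
    res = config.resolution
    nb = config.effective_chrom_size // res
    regions = _noise_regions(config, truth, uni, transcripts, nb)
    tracks: dict[str, SignalTrack] = {}
    peak_sets: dict[str, PeakSet] = {}
    for mark_idx, (name, mark) in enumerate(sorted(config.marks.items())):
        rng = _stage_rng(config, 3, mark_idx)
        noiseless = _mark_signal(config, mark, transcripts, expression, nb)
        mask = noiseless > mark.background_level * config.peak_fold
        peak_sets[name] = _peaks_from_mask(
            config.chrom, mask, noiseless, mark.background_level, res, config.peak_q
        )
        noisy = noiseless.copy()
        for s, e in regions:
            noisy[s:e] += rng.normal(0.0, mark.noise_sd, size=e - s)
        np.clip(noisy, 0.0, None, out=noisy)
        np.round(noisy, 6, out=noisy)
        tracks[name] = _rle_track(config.chrom, noisy, res)
    return tracks, peak_sets


@dataclass
class SimulatedDataset:
    """An in-memory simulated study: annotation, truth, expression, tracks."""

    config: SimulationConfig
    transcripts: list[TranscriptModel]
    truth: pd.DataFrame
    uni: pd.DataFrame
    expression: pd.Series
    tracks: dict[str, SignalTrack]
    peaks: dict[str, PeakSet]

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {self.config.chrom: self.config.effective_chrom_size}

    def write(self, outdir: str | Path) -> dict:
        """Write GTF/TSV/bedgraph/narrowPeak files plus a manifest; byte-stable."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}

        gtf = outdir / "annotation.gtf"
        with open(gtf, "w") as fh:
            for t in self.transcripts:
                fh.write(
                    f"{t.chrom}\tbidiprom_sim\ttranscript\t{t.start + 1}\t{t.end}\t.\t"
                    f"{t.strand}\t.\ttranscript_id \"{t.transcript_id}\"; "
                    f"gene_id \"{t.gene_id}\";\n"
                )
        paths["annotation"] = gtf

        expr = outdir / "expression.tsv"
        lengths = {t.transcript_id: t.end - t.start for t in self.transcripts}
        genes = {t.transcript_id: t.gene_id for t in self.transcripts}
        edf = pd.DataFrame(
            {
                "transcript_id": self.expression.index,
                "gene_id": [genes[i] for i in self.expression.index],
                "length": [lengths[i] for i in self.expression.index],
                "TPM": self.expression.to_numpy(),
            }
        )
        edf.to_csv(expr, sep="\t", index=False, float_format="%.4f")
        paths["expression"] = expr

        truth_p = outdir / "truth_pairs.tsv"
        self.truth.to_csv(truth_p, sep="\t", index=False, float_format="%.4f")
        paths["truth_pairs"] = truth_p
        uni_p = outdir / "truth_unidirectional.tsv"
        self.uni.to_csv(uni_p, sep="\t", index=False)
        paths["truth_unidirectional"] = uni_p

        sizes = outdir / "chrom.sizes"
        with open(sizes, "w") as fh:
            for chrom, size in self.chrom_sizes.items():
                fh.write(f"{chrom}\t{size}\n")
        paths["chrom_sizes"] = sizes

        for name in sorted(self.tracks):
            bg = outdir / f"{name}.fe.bedgraph"
            self.tracks[name].write_bedgraph(bg)
            paths[f"track_{name}"] = bg
            npk = outdir / f"{name}.peaks.narrowPeak"
            self.peaks[name].write_narrowpeak(npk)
            paths[f"peaks_{name}"] = npk

        manifest = {
            "generator": "bidiprom.simulate",
            "config": self.config.to_dict(),
            "files": {
                key: {"path": p.name, "sha256": _sha256(p)} for key, p in sorted(paths.items())
            },
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return manifest


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run all generator stages under the config seed."""
    transcripts, truth, uni = simulate_pairs(config)
    expression, truth = simulate_expression(config, truth, uni)
    tracks, peaks = simulate_tracks(config, truth, uni, transcripts, expression)
    return SimulatedDataset(config, transcripts, truth, uni, expression, tracks, peaks)
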
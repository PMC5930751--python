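"""File-level pipeline stages tying the analysis modules together.

Each ``run_*`` function reads the standard files of the upstream stage,
performs one analysis step and writes that stage's canonical TSV outputs
plus a JSON manifest (parameters, input checksums, package version) into
the output directory. The click CLI and the numbered analysis scripts are
thin wrappers over these functions.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .expression import classify_catalog, read_tpm_table
from .pair_catalog import PairCatalog, find_bidirectional_pairs, read_annotation
from .profiles import (
    CHOP_LENGTH,
    CHOP_STAGGER,
    FRAME_SIZE,
    build_frames,
    build_meta_profile,
    side_enrichment_table,
)
from .simulate import SimulationConfig, simulate_dataset
from .stats import compare_asymmetric, compare_symmetric
from .tracks import read_bedgraph, read_peaks

log = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(outdir: Path, stage: str, params: dict, inputs: Mapping[str, Path],
                    outputs: Mapping[str, Path]) -> None:
    manifest = {
        "stage": stage,
        "version": __version__,
        "parameters": params,
        "inputs": {k: {"path": str(p), "sha256": _sha256(Path(p))} for k, p in inputs.items()},
        "outputs": {k: str(Path(p).name) for k, p in outputs.items()},
    }
    with open(outdir / f"manifest_{stage}.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                chrom, size = line.split()[:2]
                sizes[chrom] = int(size)
    return sizes


@dataclass(frozen=True)
class _PairRow:
    """Midpoint-bearing shim so frames can be built from a catalog TSV."""

    pair_id: str
    chrom: str
    midpoint: int


def pairs_from_tsv(path: str | Path) -> list[_PairRow]:
    df = pd.read_csv(path, sep="\t")
    return [
        _PairRow(
            r.pair_id, r.chrom, int(r.tss_minus) + (int(r.tss_plus) - int(r.tss_minus) + 1) // 2
        )
        for r in df.itertuples(index=False)
    ]


def run_simulate(config: SimulationConfig, outdir: str | Path) -> dict:
    """Generate a full synthetic dataset into ``outdir``."""
    outdir = Path(outdir)
    ds = simulate_dataset(config)
    manifest = ds.write(outdir)
    log.info("simulated %d pairs, %d unidirectional genes, %d marks into %s",
             config.n_pairs, config.n_unidirectional, len(config.marks), outdir)
    return manifest


def run_pairs(annotation: str | Path, outdir: str | Path, max_distance: int = 1000) -> PairCatalog:
    """Discover bidirectional pairs from an annotation file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    transcripts = read_annotation(annotation)
    catalog = find_bidirectional_pairs(transcripts, max_distance=max_distance)
    catalog.write_tsv(outdir / "pairs.tsv")
    catalog.write_intergenic_bed(outdir / "intergenic.bed")
    if len(catalog):
        bins = catalog.to_dataframe()["nucleosome_bin"].value_counts().sort_index()
        log.info("pairs per nucleosome bin: %s", bins.to_dict())
    _write_manifest(
        outdir, "pairs", {"max_distance": max_distance},
        {"annotation": Path(annotation)},
        {"pairs": outdir / "pairs.tsv", "intergenic": outdir / "intergenic.bed"},
    )
    return catalog


def run_classify(
    annotation: str | Path,
    tpm_table: str | Path,
    outdir: str | Path,
    max_distance: int = 1000,
    fold_threshold: float = 2.0,
    silent_threshold: float = 1.0,
    floor: float = 0.1,
) -> pd.DataFrame:
    """Classify every discovered pair by expression symmetry."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    transcripts = read_annotation(annotation)
    catalog = find_bidirectional_pairs(transcripts, max_distance=max_distance)
    tpm = read_tpm_table(tpm_table)
    classes = classify_catalog(
        catalog, tpm,
        fold_threshold=fold_threshold, silent_threshold=silent_threshold, floor=floor,
    )
    classes.to_csv(outdir / "classes.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
    _write_manifest(
        outdir, "classify",
        {"max_distance": max_distance, "fold_threshold": fold_threshold,
         "silent_threshold": silent_threshold, "floor": floor},
        {"annotation": Path(annotation), "tpm": Path(tpm_table)},
        {"classes": outdir / "classes.tsv"},
    )
    return classes


def run_profile(
    pairs_tsv: str | Path,
    classes_tsv: str | Path,
    track_paths: Mapping[str, str | Path],
    peak_paths: Mapping[str, str | Path],
    chrom_sizes_path: str | Path,
    outdir: str | Path,
    frame_size: int = FRAME_SIZE,
    chop_length: int = CHOP_LENGTH,
    stagger: int = CHOP_STAGGER,
    q_max: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Meta-profiles per category and peak-restricted side sums, per mark."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pairs = pairs_from_tsv(pairs_tsv)
    classes = pd.read_csv(classes_tsv, sep="\t")
    chrom_sizes = read_chrom_sizes(chrom_sizes_path)
    category = dict(zip(classes["pair_id"], classes["plot_category"]))

    frames = build_frames(pairs, chrom_sizes, size=frame_size, length=chop_length, stagger=stagger)
    by_cat: dict[str, list] = {c: [] for c in ("plus_high", "minus_high", "both_expressed", "silent")}
    for fr in frames:
        cat = category.get(fr.pair_id)
        if cat is not None:
            by_cat[cat].append(fr)
    log.info("frames per category: %s", {c: len(v) for c, v in by_cat.items()})

    outputs: dict[str, Path] = {}
    profile_frames = []
    side_tables = []
    for mark in sorted(track_paths):
        track = read_bedgraph(track_paths[mark])
        profiles = build_meta_profile(by_cat, track, size=frame_size,
                                      length=chop_length, stagger=stagger)
        pdf = pd.concat([p.to_dataframe() for p in profiles.values()], ignore_index=True)
        pdf.insert(0, "mark", mark)
        profile_frames.append(pdf)
        if mark in peak_paths:
            peaks = read_peaks(peak_paths[mark])
            side_tables.append(side_enrichment_table(frames, track, peaks, mark, q_max=q_max))

    prof_path = outdir / "meta_profiles.tsv"
    pd.concat(profile_frames, ignore_index=True).to_csv(
        prof_path, sep="\t", index=False, float_format=FLOAT_FMT
    )
    outputs["meta_profiles"] = prof_path
    result = {"meta_profiles": pd.concat(profile_frames, ignore_index=True)}
    if side_tables:
        side_path = outdir / "side_enrichment.tsv"
        side_df = pd.concat(side_tables, ignore_index=True)
        side_df.to_csv(side_path, sep="\t", index=False, float_format=FLOAT_FMT)
        outputs["side_enrichment"] = side_path
        result["side_enrichment"] = side_df

    inputs = {"pairs": Path(pairs_tsv), "classes": Path(classes_tsv),
              "chrom_sizes": Path(chrom_sizes_path)}
    inputs.update({f"track_{m}": Path(p) for m, p in track_paths.items()})
    inputs.update({f"peaks_{m}": Path(p) for m, p in peak_paths.items()})
    _write_manifest(
        outdir, "profile",
        {"frame_size": frame_size, "chop_length": chop_length, "stagger": stagger, "q_max": q_max},
        inputs, outputs,
    )
    return result


def run_compare(
    side_tsv: str | Path,
    classes_tsv: str | Path,
    outdir: str | Path,
    variant: str = "welch",
) -> pd.DataFrame:
    """Unpaired t-tests of side enrichment for asymmetric and symmetric pairs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    side = pd.read_csv(side_tsv, sep="\t")
    classes = pd.read_csv(classes_tsv, sep="\t")
    rows = []
    violins = []
    for mark, sub in side.groupby("mark", sort=True):
        for which, fn in (("asymmetric", compare_asymmetric), ("symmetric", compare_symmetric)):
            try:
                cmp = fn(sub, classes, variant=variant)
            except ValueError as exc:
                log.warning("%s/%s comparison skipped: %s", mark, which, exc)
                continue
            row = {"mark": mark, "comparison": which}
            row.update(cmp.summary_row())
            rows.append(row)
            v = cmp.to_long_dataframe()
            v.insert(0, "comparison", which)
            v.insert(0, "mark", mark)
            violins.append(v)
    comparisons = pd.DataFrame(rows)
    comparisons.to_csv(outdir / "comparisons.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
    if violins:
        pd.concat(violins, ignore_index=True).to_csv(
            outdir / "violin_values.tsv", sep="\t", index=False, float_format=FLOAT_FMT
        )
    _write_manifest(
        outdir, "compare", {"variant": variant},
        {"side_enrichment": Path(side_tsv), "classes": Path(classes_tsv)},
        {"comparisons": outdir / "comparisons.tsv"},
    )
    return comparisons


def run_all(config: SimulationConfig, outdir: str | Path) -> dict:
    """simulate -> pairs -> classify -> profile -> compare, chained on files."""
    outdir = Path(outdir)
    sim_dir = outdir / "sim"
    run_simulate(config, sim_dir)
    run_pairs(sim_dir / "annotation.gtf", outdir)
    run_classify(sim_dir / "annotation.gtf", sim_dir / "expression.tsv", outdir)
    marks = sorted(config.marks)
    tracks = {m: sim_dir / f"{m}.fe.bedgraph" for m in marks}
    peaks = {m: sim_dir / f"{m}.peaks.narrowPeak" for m in marks}
    run_profile(
        outdir / "pairs.tsv", outdir / "classes.tsv",
        tracks, peaks, sim_dir / "chrom.sizes", outdir,
    )
    run_compare(outdir / "side_enrichment.tsv", outdir / "classes.tsv", outdir)
    return {"outdir": str(outdir)}
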
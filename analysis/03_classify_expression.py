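#!/usr/bin/env python
"""Classify pairs by expression symmetry; sample the matched control set.

A pair is asymmetric when one member's TPM exceeds its partner's by more
than 2-fold, symmetric silent when both are below 1 TPM, and symmetric
expressed otherwise. Also samples unidirectional control genes whose TPM
lies inside the expression range of the pair members.
"""

from pathlib import Path

from bidiprom.expression import read_tpm_table, sample_matched_unidirectional
from bidiprom.pair_catalog import find_bidirectional_pairs, read_annotation
from bidiprom.pipeline import run_classify

ROOT = Path(__file__).resolve().parents[1]

if __name__ == "__main__":
    sim = ROOT / "results" / "sim"
    outdir = ROOT / "results" / "classes"
    classes = run_classify(sim / "annotation.gtf", sim / "expression.tsv", outdir)
    print(f"{len(classes)} pairs classified:")
    print(classes["label"].value_counts().to_string())
    print(classes["plot_category"].value_counts().to_string())

    transcripts = read_annotation(sim / "annotation.gtf")
    catalog = find_bidirectional_pairs(transcripts)
    tpm = read_tpm_table(sim / "expression.tsv")
    n_control = min(len(classes), 300)
    control = sample_matched_unidirectional(transcripts, tpm, catalog, n=n_control, seed=1)
    control_path = outdir / "control_set.txt"
    control_path.write_text("\n".join(control) + "\n")
    print(f"{len(control)} expression-matched unidirectional controls -> {control_path}")
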
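#!/usr/bin/env python
"""Calibration of the side-sum statistics and the qPCR arithmetic.

Short versions of the calibration runs (the full-size runs live in the
acceptance script): type-I error of the symmetric left/right comparison
under the generator's exchangeable null, power of the high/low
comparison at the default asymmetric effect size, and the closed-form
percent-input / occupancy / ddCt identities.
"""

import json
from pathlib import Path

from bidiprom.benchmarks import asymmetric_power, symmetric_null_rejection
from bidiprom.qpcr import QpcrMeasurement, fold_change_ddct, occupancy, percent_input

ROOT = Path(__file__).resolve().parents[1]

if __name__ == "__main__":
    outdir = ROOT / "results" / "stats"
    outdir.mkdir(parents=True, exist_ok=True)

    null = symmetric_null_rejection(base_seed=1, n_reps=300)
    print(f"symmetric-null rejection rate at alpha=0.05: "
          f"{null['rejections']}/{null['n_reps']} = {null['rejections'] / null['n_reps']:.3f}")

    power = asymmetric_power(base_seed=1, n_reps=50, n_pairs=100)
    print(f"asymmetric power at default effect size (n=100 pairs): {power['power']:.2f}")

    pct_specific = percent_input(QpcrMeasurement(ct_chip=26.0, ct_input=30.0, x_percent=10.0))
    pct_background = percent_input(QpcrMeasurement(ct_chip=29.0, ct_input=30.0, x_percent=10.0))
    print(f"percent input, specific locus:   {pct_specific:.3f}%")
    print(f"percent input, background locus: {pct_background:.3f}%")
    print(f"relative occupancy: {occupancy(pct_specific, pct_background):.1f}")
    fc = fold_change_ddct(20.0, 18.0, 24.0, 18.0)
    print(f"expression fold change, 2^-(ddCt) with ddCt = -4: {fc:.1f}")

    summary = {
        "null_rejection_rate": null["rejections"] / null["n_reps"],
        "asymmetric_power": power["power"],
        "occupancy_example": occupancy(pct_specific, pct_background),
        "fold_change_example": fc,
    }
    (outdir / "calibration.json").write_text(json.dumps(summary, indent=2) + "\n")
    print(f"summary -> {outdir}/calibration.json")
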
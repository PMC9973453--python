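#!/usr/bin/env python
"""Syllable-level mixed models: does stress shape SOI and intensity, and do
tacks break the pattern?

Fits the four sum-coded models (regular/tack x SOI/intensity) with the
two-pass residual-outlier procedure and reports the coefficient tables.
Because the coding is +-1, the predicted strong-weak difference is twice
the stress coefficient.
"""

import sys
import warnings
from pathlib import Path

import pandas as pd

from verserhythm.inference import (
    regular_syllable_spec,
    report_table,
    tack_spec,
    two_pass_outlier_fit,
)

IN = Path(__file__).resolve().parent.parent / "results" / "synthetic_study"
OUT = IN / "fits"


def main() -> int:
    src = IN / "syllable_features.tsv"
    if not src.exists():
        print("run analysis/01_simulate_reading.py first", file=sys.stderr)
        return 1
    warnings.filterwarnings("ignore", message="REML estimate is singular")
    features = pd.read_csv(src, sep="\t")
    OUT.mkdir(parents=True, exist_ok=True)
    specs = {
        "regular-soi": regular_syllable_spec("soi_ms"),
        "regular-intensity": regular_syllable_spec("i_mean_db"),
        "tack-soi": tack_spec("soi_ms"),
        "tack-intensity": tack_spec("i_mean_db"),
    }
    for name, spec in specs.items():
        _first, _retained, fit = two_pass_outlier_fit(features, spec)
        fit.coefficients.to_csv(OUT / f"{name}.tsv", sep="\t")
        (OUT / f"{name}.txt").write_text(report_table(fit) + "\n")
        print(report_table(fit))
        print()

    reg = pd.read_csv(OUT / "regular-soi.tsv", sep="\t", index_col=0)
    tck = pd.read_csv(OUT / "tack-soi.tsv", sep="\t", index_col=0)
    print("findings:")
    print(f"  regular syllables: strong syllables are spoken "
          f"{2 * reg.loc['stress', 'beta']:.1f} ms longer than weak ones "
          f"(2 x beta, p = {reg.loc['stress', 'p']:.2g}).")
    print(f"  tacks: the stress effect collapses "
          f"(beta = {tck.loc['stress', 'beta']:.2f} ms, "
          f"p = {tck.loc['stress', 'p']:.2f}); instead each later tack in a "
          f"line adds {2 * tck.loc['tack_index', 'beta']:.1f} ms "
          f"(tack index, p = {tck.loc['tack_index', 'p']:.2g}).")
    return 0


if __name__ == "__main__":
    sys.exit(main())
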
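#!/usr/bin/env python
"""Line-level rhythmicity: does the presence (and count) of tacks flatten
the alternating long-short rhythm of a verse line?

Fits the nPVI line models in both variants -- the binary tack-line contrast
and the continuous tacks-per-line slope -- for SOI-based and intensity-based
nPVI, with the two-pass outlier procedure.
"""

import sys
import warnings
from pathlib import Path

import pandas as pd

from verserhythm.inference import line_spec, report_table, two_pass_outlier_fit

IN = Path(__file__).resolve().parent.parent / "results" / "synthetic_study"
OUT = IN / "fits"


def main() -> int:
    src = IN / "line_records.tsv"
    if not src.exists():
        print("run analysis/01_simulate_reading.py first", file=sys.stderr)
        return 1
    warnings.filterwarnings("ignore", message="REML estimate is singular")
    lines = pd.read_csv(src, sep="\t")
    OUT.mkdir(parents=True, exist_ok=True)
    fits = {}
    for response in ("npvi_soi", "npvi_i_mean"):
        for predictor in ("tack_line", "tacks_per_line"):
            spec = line_spec(response, predictor)
            _f, _r, fit = two_pass_outlier_fit(lines, spec)
            fits[spec.name] = fit
            fit.coefficients.to_csv(OUT / f"{spec.name}.tsv", sep="\t")
            (OUT / f"{spec.name}.txt").write_text(report_table(fit) + "\n")
            print(report_table(fit))
            print()

    soi = fits["line-npvi_soi-tacks-per-line"].coefficients
    inten = fits["line-npvi_i_mean-tacks-per-line"].coefficients
    print("findings:")
    print(f"  each additional tack in a line lowers the SOI-based nPVI by "
          f"{-2 * soi.loc['tacks_per_line', 'beta']:.2f} "
          f"(2 x beta, p = {soi.loc['tacks_per_line', 'p']:.2g}): lines with "
          f"tacks are read with less long-short alternation.")
    print(f"  the intensity-based nPVI shows no reliable tack-count effect "
          f"(beta = {inten.loc['tacks_per_line', 'beta']:.2f}, "
          f"p = {inten.loc['tacks_per_line', 'p']:.2f}).")
    return 0


if __name__ == "__main__":
    sys.exit(main())
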
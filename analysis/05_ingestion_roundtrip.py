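#!/usr/bin/env python
"""Ingestion fidelity: emit the synthetic reading as Praat TextGrids, read
them back, and verify that the annotation path reproduces the simulate-path
features and model estimates.

TextGrids serialise times at microsecond precision, so the check compares
against the simulate path with times rounded the same way.
"""

import sys
import tempfile
import warnings
from pathlib import Path

import numpy as np

from verserhythm.inference import regular_syllable_spec, two_pass_outlier_fit
from verserhythm.pipeline import RunConfig, _ingest_inputs
from verserhythm.rhythm_features import compute_soi, filter_max_soi
from verserhythm.stimulus_model import poems_to_table, study_poems
from verserhythm.synthetic_reader import (
    default_participants,
    participants_to_table,
    simulate_intensity_table,
    simulate_syllables,
    tokens_to_textgrids,
)


def main() -> int:
    warnings.filterwarnings("ignore", message="REML estimate is singular")
    rng = np.random.default_rng(1)
    poems = study_poems(seed=rng)
    participants = default_participants()
    tokens = simulate_syllables(poems, participants, seed=rng)

    with tempfile.TemporaryDirectory() as td:
        tmp = Path(td)
        paths = tokens_to_textgrids(tokens, tmp / "grids")
        poems_to_table(poems).to_csv(tmp / "poems.tsv", sep="\t", index=False)
        participants_to_table(participants).to_csv(
            tmp / "participants.tsv", sep="\t", index=False)
        simulate_intensity_table(tokens, participants, seed=rng).to_csv(
            tmp / "intensity.tsv", sep="\t", index=False)
        print(f"emitted {len(paths)} TextGrids "
              f"({len(tokens)} syllable intervals plus pauses)")
        config = RunConfig(
            mode="ingest", textgrid_dir=str(tmp / "grids"),
            poem_table=str(tmp / "poems.tsv"),
            participant_table=str(tmp / "participants.tsv"),
            intensity_table=str(tmp / "intensity.tsv"))
        ingested, _, _ = _ingest_inputs(config)

    sim = tokens.drop(columns=["soi_ms"]).copy()
    sim[["onset_s", "offset_s"]] = sim[["onset_s", "offset_s"]].round(6)
    key = ["participant_id", "poem_id", "syll_idx_in_poem"]
    a = compute_soi(sim).sort_values(key).reset_index(drop=True)
    b = compute_soi(ingested).sort_values(key).reset_index(drop=True)
    feat_diff = float(np.abs(a["soi_ms"].to_numpy() - b["soi_ms"].to_numpy()).max())
    print(f"max |SOI difference| between paths: {feat_diff:.2e} ms")

    spec = regular_syllable_spec("soi_ms").with_df_method("residual")
    fit_a = two_pass_outlier_fit(filter_max_soi(a), spec)[2]
    fit_b = two_pass_outlier_fit(filter_max_soi(b), spec)[2]
    coef_diff = float(np.abs(fit_a.coefficients["beta"].to_numpy()
                             - fit_b.coefficients["beta"].to_numpy()).max())
    print(f"max |coefficient difference| between paths: {coef_diff:.2e}")
    ok = feat_diff < 1e-9 and coef_diff < 1e-9
    print("ingestion path reproduces the simulate path"
          if ok else "PATHS DIVERGE")
    return 0 if ok else 1


if __name__ == "__main__":
    sys.exit(main())
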
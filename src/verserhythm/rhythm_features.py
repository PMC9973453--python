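"""Per-syllable rhythm features: SOI, duration, intensity, exclusion rules.

The syllable onset interval (SOI) runs from a syllable's onset to the onset
of the next syllable in the same line, so it integrates any within-line
speaking pause.  The pause after the last syllable of a line is excluded:
line-final syllables get their own duration as SOI.  Rows whose SOI exceeds
a maximum (default 2000 ms) are flagged for exclusion, not dropped.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["compute_soi", "filter_max_soi", "attach_intensity", "MAX_SOI_MS"]

MAX_SOI_MS = 2000.0

_LINE_KEY = ["participant_id", "poem_id", "line_no"]


def compute_soi(tokens: pd.DataFrame) -> pd.DataFrame:
    """Compute soi_ms and duration_ms for a syllable-token table.

    ``tokens`` must carry the syllable-table schema (onset_s/offset_s plus
    participant/poem/line keys) with tokens sorted by onset within each
    line.  Returns a copy with ``duration_ms``, ``soi_ms``, ``excluded``
    and ``exclusion_reason`` columns added.
    """
    df = tokens.copy()
    if (df["offset_s"] <= df["onset_s"]).any():
        raise ValueError("tokens with non-positive duration")
    for _key, grp in df.groupby(_LINE_KEY, sort=False):
        onsets = grp["onset_s"].to_numpy()
        if np.any(np.diff(onsets) <= 0):
            raise ValueError(f"tokens not strictly sorted by onset in line {_key}")
        offs = grp["offset_s"].to_numpy()
        if np.any(onsets[1:] < offs[:-1] - 1e-9):
            raise ValueError(f"overlapping tokens in line {_key}")
    df["duration_ms"] = (df["offset_s"] - df["onset_s"]) * 1000.0
    next_onset = df.groupby(_LINE_KEY, sort=False)["onset_s"].shift(-1)
    soi = (next_onset - df["onset_s"]) * 1000.0
    df["soi_ms"] = soi.fillna(df["duration_ms"])  # line-final: pause excluded
    df["excluded"] = False
    df["exclusion_reason"] = "none"
    return df


def filter_max_soi(rows: pd.DataFrame, max_ms: float = MAX_SOI_MS) -> pd.DataFrame:
    """Flag rows whose SOI strictly exceeds ``max_ms``.  Idempotent."""
    df = rows.copy()
    over = df["soi_ms"] > max_ms
    df.loc[over, "excluded"] = True
    df.loc[over, "exclusion_reason"] = "soi_over_max"
    return df


def attach_intensity(rows: pd.DataFrame, intensity: pd.DataFrame) -> pd.DataFrame:
    """Join per-interval mean intensity (dB) onto the feature table.

    ``intensity`` must have exactly one row per syllable interval, keyed by
    participant_id, poem_id and syll_idx_in_poem, with column ``i_mean_db``.
    Missing or duplicated keys raise with the offending keys named.
    """
    key = ["participant_id", "poem_id", "syll_idx_in_poem"]
    dup = intensity.duplicated(subset=key)
    if dup.any():
        bad = intensity.loc[dup, key].head(5).to_records(index=False).tolist()
        raise ValueError(f"duplicate intensity keys, e.g. {bad}")
    merged = rows.merge(intensity[key + ["i_mean_db"]], on=key, how="left", validate="m:1")
    missing = merged["i_mean_db"].isna()
    if missing.any():
        bad = merged.loc[missing, key].head(5).to_records(index=False).tolist()
        raise ValueError(
            f"{int(missing.sum())} syllable intervals without intensity, e.g. {bad}"
        )
    return merged
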
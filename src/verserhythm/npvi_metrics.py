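"""The normalized pairwise variability index and line-level aggregation.

For an ordered sequence d_1..d_m of positive values the nPVI is

    nPVI = 100/(m-1) * sum_{k=1}^{m-1} |d_k - d_{k+1}| / ((d_k + d_{k+1})/2)

i.e. 100 times the mean relative contrast of adjacent pairs.  It is 0 for a
constant sequence, bounded above by 200, scale-invariant, and invariant to
sequence reversal.  High values mean strongly alternating (long-short /
loud-quiet) rhythm; leveling adjacent values lowers it.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = ["npvi", "aggregate_lines", "center_covariates"]

log = logging.getLogger(__name__)

_LINE_KEY = ["participant_id", "poem_id", "line_no"]


def npvi(values) -> float:
    """nPVI of an ordered sequence of positive values (length >= 2)."""
    d = np.asarray(values, dtype=float)
    if d.ndim != 1 or d.size < 2:
        raise ValueError(f"nPVI needs an ordered sequence of length >= 2, got {d.size}")
    if np.any(d <= 0) or not np.all(np.isfinite(d)):
        raise ValueError("nPVI is defined for positive finite values only")
    contrasts = np.abs(d[:-1] - d[1:]) / ((d[:-1] + d[1:]) / 2.0)
    return float(100.0 * contrasts.mean())


def aggregate_lines(features: pd.DataFrame, use_excluded: bool = False) -> pd.DataFrame:
    """Aggregate syllable features to one record per verse line.

    Computes npvi_soi and (when ``i_mean_db`` is present) npvi_i_mean over
    the line's retained syllables, plus tack_line, tacks_per_line, n_sylls
    and line_no.  Lines left with fewer than 2 usable syllables get missing
    nPVI values and a logged warning; they are kept in the table.
    """
    has_intensity = "i_mean_db" in features.columns
    records = []
    for (pid, poem, line_no), grp in features.groupby(_LINE_KEY, sort=False):
        usable = grp if use_excluded else grp[~grp["excluded"]]
        rec = {
            "participant_id": pid,
            "poem_id": poem,
            "meter": grp["meter"].iloc[0],
            "line_no": line_no,
            "tack_line": bool(grp["is_tack"].any()),
            "tacks_per_line": int(grp["is_tack"].sum()),
            "n_sylls": int(len(grp)),
        }
        if len(usable) < 2:
            log.warning(
                "line %s/%s/%s has %d usable syllables; nPVI undefined",
                pid, poem, line_no, len(usable),
            )
            rec["npvi_soi"] = np.nan
            if has_intensity:
                rec["npvi_i_mean"] = np.nan
        else:
            rec["npvi_soi"] = npvi(usable["soi_ms"].to_numpy())
            if has_intensity:
                rec["npvi_i_mean"] = npvi(usable["i_mean_db"].to_numpy())
        records.append(rec)
    out = pd.DataFrame.from_records(records)
    if "musical" in features.columns:
        keymap = features.drop_duplicates("participant_id").set_index("participant_id")
        out["musical"] = out["participant_id"].map(keymap["musical"])
        if "instruction" in keymap.columns:
            out["instruction"] = out["participant_id"].map(keymap["instruction"])
    return out


def center_covariates(
    table: pd.DataFrame,
    variables: list[str],
    standardize: bool = True,
    suffix: str = "_C",
) -> pd.DataFrame:
    """Center (and by default standardize) numeric covariates.

    Adds ``<name>_C`` columns with mean 0 (and SD 1 when ``standardize``);
    originals are preserved.  A zero-variance column with ``standardize``
    raises.
    """
    df = table.copy()
    for var in variables:
        x = df[var].astype(float)
        centered = x - x.mean()
        if standardize:
            sd = x.std(ddof=1)
            if not np.isfinite(sd) or sd == 0:
                raise ValueError(f"cannot standardize zero-variance column {var!r}")
            centered = centered / sd
        df[var + suffix] = centered
    return df
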
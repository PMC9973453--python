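"""Sum-contrast coding and factorial design-matrix construction.

All factors in the study design are binary and sum-coded to +1/-1, so the
intercept estimates the grand mean and the predicted difference between a
factor's two levels is twice its coefficient.  The positive level of each
factor is fixed here and logged with every fit: strong stress, musically
active, iambic meter, and tack-free lines (``tack_line`` codes the absence
of a tack as +1) are +1.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

__all__ = ["SUM_CODES", "code_factor", "build_design"]

#: level -> code maps for the study's binary factors (codes sum to zero)
SUM_CODES: dict[str, dict[object, float]] = {
    "stress": {"s": +1.0, "w": -1.0},
    "musical": {"active": +1.0, "not_active": -1.0},
    "meter": {"iambic": +1.0, "trochaic": -1.0},
    "tack_line": {False: +1.0, True: -1.0},
}


def code_factor(values: pd.Series, factor: str) -> pd.Series:
    """Sum-code a binary factor column to +1/-1.

    Factors outside :data:`SUM_CODES` are coded from their sorted unique
    values (first level -1, second +1); more than two levels raise, since
    the study design is fully binary.
    """
    mapping = SUM_CODES.get(factor)
    if mapping is None:
        levels = sorted(pd.unique(values.dropna()))
        if len(levels) != 2:
            raise ValueError(
                f"sum coding supports exactly 2 levels; factor {factor!r} "
                f"has {len(levels)}: {levels}"
            )
        mapping = {levels[0]: -1.0, levels[1]: +1.0}
    coded = values.map(mapping)
    if coded.isna().any():
        bad = sorted(set(values[coded.isna()].astype(str)))
        raise ValueError(f"factor {factor!r}: unknown levels {bad}")
    return coded.astype(float)


def _sum_columns(values: pd.Series, factor: str) -> dict[str, np.ndarray]:
    """Sum-contrast columns for a factor of two or more levels.

    Two levels give one +-1 column named after the factor; k > 2 levels
    give k-1 columns ``factor[level]`` coded 1 on that level, -1 on the
    last (alphabetically) level, 0 elsewhere -- the usual contr.sum layout.
    """
    if factor in SUM_CODES or values.nunique(dropna=True) <= 2:
        return {factor: code_factor(values, factor).to_numpy()}
    levels = sorted(pd.unique(values.dropna()))
    ref = levels[-1]
    out = {}
    for lev in levels[:-1]:
        col = np.where(values == lev, 1.0, np.where(values == ref, -1.0, 0.0))
        out[f"{factor}[{lev}]"] = col
    return out


def build_design(
    data: pd.DataFrame,
    factors: list[str],
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Full-factorial sum-coded design matrix with intercept.

    ``factors`` are sum-coded (binary factors to a single +-1 column,
    multi-level factors to contr.sum columns); ``covariates`` enter as
    numeric columns.  All main effects and all interaction products of the
    combined predictor set are included, with ``:``-joined names, matching
    the coefficient layout of a full factorial model.
    """
    covariates = covariates or []
    groups: list[dict[str, np.ndarray]] = []
    for f in factors:
        groups.append(_sum_columns(data[f], f))
    for c in covariates:
        groups.append({c: np.asarray(data[c], dtype=float)})
    cols: dict[str, np.ndarray] = {"(Intercept)": np.ones(len(data))}
    for r in range(1, len(groups) + 1):
        for combo in itertools.combinations(range(len(groups)), r):
            for parts in itertools.product(*(groups[i].items() for i in combo)):
                names = [nm for nm, _ in parts]
                col = np.ones(len(data))
                for _, v in parts:
                    col = col * v
                cols[":".join(names)] = col
    return pd.DataFrame(cols, index=data.index)
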
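"""Sum-coded mixed-model inference for the rhythm analyses.

Four canonical model families are provided, all Gaussian LMMs estimated by
REML with Satterthwaite denominator df:

* regular syllables: response ~ stress * musical * meter, random
  participant (intercept + stress slope, correlated) and syllable-type
  intercept;
* tack syllables: the same plus the centred tack index in the full
  factorial, random participant (intercept + stress slope) only;
* lines, tack-line variant: nPVI ~ tack_line * musical * meter, random
  participant (intercept + tack_line slope) and poem intercept;
* lines, tacks-per-line variant: the binary tack_line replaced by the
  centred tack count.

Every family supports the two-pass procedure: fit, drop rows whose
residual falls outside the Tukey fences (1.5 x IQR beyond the residual
quartiles), refit, and report the second fit.  Effect sizes are Cohen's
d = 2 t / sqrt(df); |d| <= 0.1 is conventionally not reported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .coding import SUM_CODES, build_design, code_factor
from .lmm import LMMResult, RandomTermSpec, fit_lmm

__all__ = [
    "MixedModelSpec",
    "ModelFit",
    "code_musical",
    "sum_code",
    "cohens_d",
    "fit_mixed",
    "two_pass_outlier_fit",
    "tukey_fences",
    "icc_from_components",
    "report_table",
    "regular_syllable_spec",
    "tack_spec",
    "line_spec",
    "CANONICAL_SPECS",
]

NOT_AT_ALL = "Not at all"


def code_musical(profile) -> str:
    """Binary musical-activity coding from the MusA questionnaire answers.

    A reader who was never musically active (Q4 = no) is ``not_active``.
    Otherwise the reader is ``active`` iff at least one of the last-12-months
    frequency answers (instrument, singing) differs from "Not at all".
    """
    q4 = getattr(profile, "musa_q4", None)
    instrument = getattr(profile, "musa_instrument", None)
    singing = getattr(profile, "musa_singing", None)
    if q4 is None or (q4 != "no" and (instrument is None or singing is None)):
        raise ValueError(f"incomplete musical-activity answers for {profile!r}")
    if q4 == "no":
        return "not_active"
    if instrument != NOT_AT_ALL or singing != NOT_AT_ALL:
        return "active"
    return "not_active"


def sum_code(table: pd.DataFrame, factors: list[str]) -> pd.DataFrame:
    """Full-factorial sum-coded design matrix for binary factors.

    Each factor must have exactly two levels; codes are +-1 (positive
    levels per :data:`verserhythm.coding.SUM_CODES`), interactions are
    products of main-effect columns, and the intercept estimates the grand
    mean.
    """
    for f in factors:
        nlev = table[f].nunique(dropna=True)
        if nlev != 2:
            raise ValueError(
                f"sum coding supports two-level factors only; {f!r} has {nlev} levels"
            )
    return build_design(table, factors)


def cohens_d(t: float, df: float) -> float:
    """Effect size d = 2 t / sqrt(df) from a mixed-model t statistic."""
    if df <= 0:
        raise ValueError(f"df must be > 0, got {df}")
    return 2.0 * t / np.sqrt(df)


def icc_from_components(tau00: list[float] | float, sigma2: float) -> float:
    """Intraclass correlation: summed intercept variances over total."""
    tau = float(np.sum(tau00))
    return tau / (tau + sigma2)


# ---------------------------------------------------------------------------
# Model specifications


@dataclass(frozen=True)
class MixedModelSpec:
    """A fit recipe: response, factorial predictors, random structure."""

    name: str
    response: str
    factors: tuple[str, ...]
    covariates: tuple[str, ...] = ()
    random: tuple[RandomTermSpec, ...] = ()
    subset: str = "all"              # regular_syllables | tacks | lines | all
    df_method: str = "satterthwaite"
    #: pairs of predictors whose mutual interactions are dropped (e.g.
    #: musical x instruction, whose cells are empty by design)
    exclude_pairs: tuple[tuple[str, str], ...] = ()

    def with_df_method(self, df_method: str) -> "MixedModelSpec":
        return MixedModelSpec(**{**asdict_shallow(self), "df_method": df_method})


def asdict_shallow(spec: MixedModelSpec) -> dict:
    return {
        "name": spec.name, "response": spec.response, "factors": spec.factors,
        "covariates": spec.covariates, "random": spec.random,
        "subset": spec.subset, "df_method": spec.df_method,
        "exclude_pairs": spec.exclude_pairs,
    }


def _drop_excluded_interactions(X: pd.DataFrame, pairs) -> pd.DataFrame:
    def involves(component: str, factor: str) -> bool:
        return component == factor or component.startswith(factor + "[")

    drop = []
    for col in X.columns:
        parts = col.split(":")
        for a, b in pairs:
            if any(involves(c, a) for c in parts) and any(involves(c, b) for c in parts):
                drop.append(col)
                break
    return X.drop(columns=drop)


def regular_syllable_spec(response: str = "soi_ms",
                          with_instruction: bool = False) -> MixedModelSpec:
    factors = ("stress", "musical", "meter")
    if with_instruction:
        factors = factors + ("instruction",)
    return MixedModelSpec(
        name=f"regular-{'soi' if response == 'soi_ms' else 'intensity'}",
        response=response,
        factors=factors,
        random=(RandomTermSpec("participant_id", ("stress",)),
                RandomTermSpec("syllable_type")),
        subset="regular_syllables",
        exclude_pairs=(("musical", "instruction"),) if with_instruction else (),
    )


def tack_spec(response: str = "soi_ms",
              with_instruction: bool = False) -> MixedModelSpec:
    factors = ("stress", "musical", "meter")
    if with_instruction:
        factors = factors + ("instruction",)
    return MixedModelSpec(
        name=f"tack-{'soi' if response == 'soi_ms' else 'intensity'}",
        response=response,
        factors=factors,
        covariates=("tack_index",),
        random=(RandomTermSpec("participant_id", ("stress",)),),
        subset="tacks",
        exclude_pairs=(("musical", "instruction"),) if with_instruction else (),
    )


def line_spec(response: str = "npvi_soi", predictor: str = "tacks_per_line",
              with_instruction: bool = False) -> MixedModelSpec:
    if predictor not in ("tacks_per_line", "tack_line"):
        raise ValueError(f"unknown line predictor {predictor!r}")
    factors: tuple[str, ...] = ("musical", "meter")
    covariates: tuple[str, ...] = ()
    if predictor == "tack_line":
        factors = ("tack_line",) + factors
    else:
        covariates = ("tacks_per_line",)
    if with_instruction:
        factors = factors + ("instruction",)
    return MixedModelSpec(
        name=f"line-{response}-{predictor.replace('_', '-')}",
        response=response,
        factors=factors,
        covariates=covariates,
        random=(RandomTermSpec("participant_id", (predictor,)),
                RandomTermSpec("poem_id")),
        subset="lines",
        exclude_pairs=(("musical", "instruction"),) if with_instruction else (),
    )


def CANONICAL_SPECS() -> dict[str, MixedModelSpec]:
    return {
        "regular-soi": regular_syllable_spec("soi_ms"),
        "regular-intensity": regular_syllable_spec("i_mean_db"),
        "tack-soi": tack_spec("soi_ms"),
        "tack-intensity": tack_spec("i_mean_db"),
        "line-npvi-soi": line_spec("npvi_soi", "tacks_per_line"),
        "line-npvi-intensity": line_spec("npvi_i_mean", "tacks_per_line"),
        "line-npvi-soi-tackline": line_spec("npvi_soi", "tack_line"),
        "line-npvi-intensity-tackline": line_spec("npvi_i_mean", "tack_line"),
    }


# ---------------------------------------------------------------------------
# Fitting


@dataclass
class ModelFit:
    """Coefficient table plus variance components for one fitted model."""

    spec: MixedModelSpec
    coefficients: pd.DataFrame        # beta, se, df, t, p, d
    sigma2: float
    vcomp: list[dict]
    icc: float
    n_obs: int
    n_groups: dict[str, int]
    r2_marginal: float
    r2_conditional: float
    aic: float
    singular: bool
    coding: dict = field(default_factory=dict)
    result: LMMResult = field(repr=False, default=None)

    @property
    def residuals(self) -> np.ndarray:
        return self.result.resid


def _prepare(table: pd.DataFrame, spec: MixedModelSpec) -> pd.DataFrame:
    df = table
    if spec.subset == "regular_syllables":
        df = df[~df["is_tack"].astype(bool)]
    elif spec.subset == "tacks":
        df = df[df["is_tack"].astype(bool)]
    if "excluded" in df.columns and spec.subset != "lines":
        df = df[~df["excluded"].astype(bool)]
    df = df.dropna(subset=[spec.response]).copy()
    # centre continuous covariates once, before any outlier pass
    for cov in spec.covariates:
        x = df[cov].astype(float)
        df[cov] = x - x.mean()
    return df


def _fit_prepared(df: pd.DataFrame, spec: MixedModelSpec) -> ModelFit:
    X = build_design(df, list(spec.factors), list(spec.covariates))
    if spec.exclude_pairs:
        X = _drop_excluded_interactions(X, spec.exclude_pairs)
    aux = pd.DataFrame(index=df.index)
    for term in spec.random:
        aux[term.group] = df[term.group].to_numpy()
        for s in term.slopes:
            if s in SUM_CODES or s in spec.factors:
                aux[s] = code_factor(df[s], s).to_numpy()
            else:
                aux[s] = df[s].astype(float).to_numpy()
    res = fit_lmm(df[spec.response].to_numpy(dtype=float), X, aux,
                  list(spec.random), df_method=spec.df_method)
    coef = res.summary_frame()
    coef["d"] = 2.0 * coef["t"] / np.sqrt(coef["df"])
    coding = {f: SUM_CODES.get(f) for f in spec.factors}
    return ModelFit(
        spec=spec,
        coefficients=coef,
        sigma2=res.sigma2,
        vcomp=res.vcomp,
        icc=res.icc,
        n_obs=res.n_obs,
        n_groups=res.n_groups,
        r2_marginal=res.r2_marginal,
        r2_conditional=res.r2_conditional,
        aic=res.aic,
        singular=res.singular,
        coding={k: ({str(a): b for a, b in v.items()} if v else None)
                for k, v in coding.items()},
        result=res,
    )


def fit_mixed(table: pd.DataFrame, spec: MixedModelSpec) -> ModelFit:
    """Fit one model spec (single pass) on its subset of the table."""
    return _fit_prepared(_prepare(table, spec), spec)


def tukey_fences(values: np.ndarray, k: float = 1.5) -> tuple[float, float]:
    """Boxplot fences: [Q1 - k IQR, Q3 + k IQR] of ``values``."""
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    return q1 - k * iqr, q3 + k * iqr


def two_pass_outlier_fit(
    table: pd.DataFrame, spec: MixedModelSpec, k: float = 1.5,
) -> tuple[ModelFit, pd.DataFrame, ModelFit]:
    """Fit, drop residual outliers beyond the Tukey fences, refit.

    Pass 1 fits ``spec`` on all (subset) rows; rows whose conditional
    residual falls outside [Q1 - k IQR, Q3 + k IQR] of the pass-1 residual
    distribution are removed; pass 2 on the remainder is the reported fit.
    Returns (first_fit, retained_table, final_fit).
    """
    prepared = _prepare(table, spec)
    first = _fit_prepared(prepared, spec)
    lo, hi = tukey_fences(first.residuals, k)
    keep = (first.residuals >= lo) & (first.residuals <= hi)
    if not keep.any():
        raise ValueError("outlier filter removed every row")
    retained = prepared.loc[keep]
    final = first if keep.all() else _fit_prepared(retained, spec)
    return first, retained, final


# ---------------------------------------------------------------------------
# Reporting


def report_table(fit: ModelFit, d_threshold: float = 0.1) -> str:
    """Human-readable coefficient and variance-component table."""
    lines = [f"Model: {fit.spec.name}   response: {fit.spec.response}"]
    coef = fit.coefficients.copy()
    coef["d"] = coef["d"].where(coef["d"].abs() > d_threshold)
    with pd.option_context("display.float_format", "{:0.3f}".format):
        lines.append(coef.to_string())
    lines.append("Random effects")
    lines.append(f"  sigma^2      {fit.sigma2:0.2f}")
    for vc in fit.vcomp:
        S = vc["Sigma"]
        lines.append(f"  tau00 {vc['group']:<16s} {S[0, 0]:0.2f}")
        for j, nm in enumerate(vc["names"][1:], start=1):
            lines.append(f"  tau11 {vc['group']}.{nm:<10s} {S[j, j]:0.2f}")
            denom = np.sqrt(S[0, 0] * S[j, j])
            if denom > 0:
                lines.append(f"  rho01 {vc['group']:<16s} {S[0, j] / denom:0.2f}")
    lines.append(f"  ICC          {fit.icc:0.2f}")
    for g, n in fit.n_groups.items():
        lines.append(f"  N {g:<14s} {n}")
    lines.append(f"Observations   {fit.n_obs}")
    lines.append(
        f"Marginal R2 / Conditional R2  {fit.r2_marginal:0.3f}/{fit.r2_conditional:0.3f}"
    )
    lines.append(f"AIC            {fit.aic:0.3f}")
    if fit.singular:
        lines.append("note: singular fit (variance or correlation at boundary)")
    return "\n".join(lines)


def fit_metadata(fit: ModelFit) -> dict:
    """JSON-serialisable run metadata for one fit (coding, sizes, flags)."""
    return {
        "model": fit.spec.name,
        "response": fit.spec.response,
        "factors": list(fit.spec.factors),
        "covariates": list(fit.spec.covariates),
        "df_method": fit.spec.df_method,
        "coding": fit.coding,
        "n_obs": fit.n_obs,
        "n_groups": fit.n_groups,
        "singular": fit.singular,
        "aic": fit.aic,
    }


def fits_to_json(fits: dict[str, ModelFit]) -> str:
    return json.dumps({k: fit_metadata(v) for k, v in fits.items()}, indent=2)
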
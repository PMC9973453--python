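"""Synthetic oral readings of metered poems.

No public corpus of tack-manipulated poetry recordings exists, so every
downstream stage is exercised against a generative mirror of the study's
hierarchical models: per-syllable onset intervals (ms) and mean intensities
(dB) are drawn from sum-coded Gaussian linear mixed structures with
participant random intercepts and stress slopes (correlated), syllable-type
random intercepts for regular syllables (tack rows share none, mirroring
the tack-model structure), and Gaussian residuals.  Line-level nPVI
observations are drawn from the corresponding line models with participant
and poem intercepts and a participant slope on the tack covariate.

Default parameter sets reproduce published mixed-model estimates from oral
reading of German iambic and trochaic poetry (13 readers, six poems, the
syllable "tack" substituted at random grid positions), so fitting the
corresponding model to generated data at study scale recovers those
estimates within sampling error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import annotation_io
from .coding import build_design
from .stimulus_model import PoemSpec, study_poems

__all__ = [
    "ParticipantProfile",
    "GenerativeParams",
    "PauseModel",
    "default_participants",
    "simulate_syllables",
    "simulate_intensity_table",
    "simulate_lines",
    "inject_pauses",
    "tokens_to_textgrids",
    "REGULAR_SOI_PARAMS",
    "REGULAR_INTENSITY_PARAMS",
    "TACK_SOI_PARAMS",
    "TACK_INTENSITY_PARAMS",
    "LINE_NPVI_SOI_PARAMS",
    "LINE_NPVI_INTENSITY_PARAMS",
    "LINE_TACKLINE_SOI_PARAMS",
    "LINE_TACKLINE_INTENSITY_PARAMS",
]

NOT_AT_ALL = "Not at all"

#: floor for generated SOIs when laying out a timeline, ms
MIN_SOI_MS = 10.0


@dataclass(frozen=True)
class ParticipantProfile:
    """One reader: musical-activity answers and instruction group."""

    participant_id: str
    musa_q4: str                      # "yes"/"no": ever musically active
    musa_instrument: str = NOT_AT_ALL  # frequency category, last 12 months
    musa_singing: str = NOT_AT_ALL
    instruction: str = "no_instruction"  # no_instruction | rhythmic | on_beat

    @property
    def musical(self) -> str:
        from .inference import code_musical  # single source of the coding rule

        return code_musical(self)


def default_participants() -> list[ParticipantProfile]:
    """The 13-reader default panel: 6 musically active, 7 not active.

    Instruction groups reproduce the study's confounded assignment:
    active readers received no_instruction (3) or rhythmic (3); inactive
    readers received no_instruction (1), rhythmic (2) or on_beat (4).
    """
    panel = []
    active_instr = ["no_instruction"] * 3 + ["rhythmic"] * 3
    inactive_instr = ["no_instruction"] + ["rhythmic"] * 2 + ["on_beat"] * 4
    for i, instr in enumerate(active_instr, start=1):
        panel.append(ParticipantProfile(
            participant_id=f"P{i:02d}", musa_q4="yes",
            musa_instrument="1 time per week", instruction=instr,
        ))
    for i, instr in enumerate(inactive_instr, start=len(active_instr) + 1):
        panel.append(ParticipantProfile(
            participant_id=f"P{i:02d}", musa_q4="no", instruction=instr,
        ))
    return panel


def participants_to_table(participants: list[ParticipantProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.participant_id, p.musa_q4, p.musa_instrument, p.musa_singing,
          p.instruction, p.musical) for p in participants],
        columns=["participant_id", "musa_q4", "musa_instrument",
                 "musa_singing", "instruction", "musical"],
    )


def participants_from_table(table: pd.DataFrame | str) -> list[ParticipantProfile]:
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep="\t")
    return [
        ParticipantProfile(
            participant_id=str(r.participant_id), musa_q4=str(r.musa_q4),
            musa_instrument=str(r.musa_instrument),
            musa_singing=str(r.musa_singing), instruction=str(r.instruction),
        )
        for r in table.itertuples()
    ]


@dataclass(frozen=True)
class PauseModel:
    """Line-final pauses and occasional long within-line pauses.

    Line-final pauses are lognormal with the given mean/sd (ms); they are
    excluded from SOIs by construction of the feature step.  With
    probability ``long_pause_prob`` a within-line syllable is followed by
    an extra pause of at least ``long_pause_min_ms`` (plus an exponential
    tail), which the 2000 ms SOI filter is meant to catch.
    """

    line_final_mean_ms: float = 300.0
    line_final_sd_ms: float = 150.0
    long_pause_prob: float = 0.0
    long_pause_min_ms: float = 2500.0
    long_pause_tail_ms: float = 200.0


@dataclass(frozen=True)
class GenerativeParams:
    """Fixed effects and variance components of one response's model.

    ``fixed_effects`` maps design-column names (sum-coded factors and their
    ``:``-joined interactions, centred covariates, and ``(Intercept)``) to
    values on the response scale (ms or dB).  Random-effect SDs are on the
    same scale; ``participant_corr`` is the intercept/slope correlation.
    ``participant_slope_on`` names the design column the participant slope
    multiplies.
    """

    fixed_effects: dict[str, float]
    resid_sd: float
    participant_intercept_sd: float = 0.0
    participant_slope_sd: float = 0.0
    participant_corr: float = 0.0
    participant_slope_on: str = "stress"
    syllable_intercept_sd: float = 0.0
    poem_intercept_sd: float = 0.0
    pause_model: PauseModel = field(default_factory=PauseModel)

    def __post_init__(self) -> None:
        for name in ("resid_sd", "participant_intercept_sd",
                     "participant_slope_sd", "syllable_intercept_sd",
                     "poem_intercept_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not -1.0 <= self.participant_corr <= 1.0:
            raise ValueError("participant_corr must be in [-1, 1]")


def _sq(x: float) -> float:
    return math.sqrt(x)


# --- default generative parameters --------------------------------------
# Published estimates from the oral-poetry-reading study this generator
# emulates; response scales: SOI in ms, mean intensity in dB, nPVI unitless.

REGULAR_SOI_PARAMS = GenerativeParams(
    fixed_effects={
        "(Intercept)": 254.16, "stress": 20.54, "musical": 3.31,
        "meter": 2.13, "stress:musical": 3.63, "stress:meter": -0.12,
        "musical:meter": -0.70, "stress:musical:meter": 0.06,
    },
    resid_sd=_sq(2623.56),
    participant_intercept_sd=_sq(406.63),
    participant_slope_sd=_sq(21.53),
    participant_corr=0.81,
    syllable_intercept_sd=_sq(5982.17),
)

REGULAR_INTENSITY_PARAMS = GenerativeParams(
    fixed_effects={
        "(Intercept)": 65.72, "stress": 0.37, "musical": -0.67,
        "meter": -0.08, "stress:musical": -0.01, "stress:meter": 0.09,
        "musical:meter": -0.06, "stress:musical:meter": -0.02,
    },
    resid_sd=_sq(8.31),
    participant_intercept_sd=_sq(11.23),
    participant_slope_sd=_sq(0.14),
    participant_corr=-0.02,
    syllable_intercept_sd=_sq(6.29),
)

TACK_SOI_PARAMS = GenerativeParams(
    fixed_effects={
        "(Intercept)": 286.85, "stress": -9.85, "musical": -3.14,
        "meter": -14.61, "tack_index": 7.92, "stress:musical": 10.33,
        "stress:meter": -2.19, "musical:meter": 13.01,
        "stress:tack_index": -1.25, "musical:tack_index": -4.70,
        "meter:tack_index": 1.89, "stress:musical:meter": -11.86,
        "stress:musical:tack_index": -0.18, "stress:meter:tack_index": 3.47,
        "musical:meter:tack_index": -2.64,
        "stress:musical:meter:tack_index": 3.17,
    },
    resid_sd=_sq(6803.36),
    participant_intercept_sd=_sq(905.91),
    participant_slope_sd=_sq(144.96),
    participant_corr=-0.72,
)

TACK_INTENSITY_PARAMS = GenerativeParams(
    fixed_effects={
        "(Intercept)": 66.57, "stress": 0.66, "musical": 0.36,
        "meter": -0.17, "tack_index": -1.01, "stress:musical": 0.28,
        "stress:meter": -0.21, "musical:meter": -0.34,
        "stress:tack_index": -0.23, "musical:tack_index": -0.56,
        "meter:tack_index": -0.06, "stress:musical:meter": -0.24,
        "stress:musical:tack_index": 0.01, "stress:meter:tack_index": 0.07,
        "musical:meter:tack_index": -0.04,
        "stress:musical:meter:tack_index": 0.11,
    },
    resid_sd=_sq(9.26),
    participant_intercept_sd=_sq(9.15),
    participant_slope_sd=_sq(0.05),
    participant_corr=0.80,
)

LINE_NPVI_SOI_PARAMS = GenerativeParams(
    fixed_effects={
        "(Intercept)": 51.88, "tacks_per_line": -1.49, "musical": -0.18,
        "meter": 0.36, "tacks_per_line:musical": -0.84,
        "tacks_per_line:meter": 0.06, "musical:meter": 0.79,
        "tacks_per_line:musical:meter": -0.08,
    },
    resid_sd=_sq(282.25),
    participant_intercept_sd=_sq(2.43),
    participant_slope_sd=_sq(0.13),
    participant_corr=-0.02,
    participant_slope_on="tacks_per_line",
    poem_intercept_sd=_sq(11.81),
)

LINE_NPVI_INTENSITY_PARAMS = GenerativeParams(
    fixed_effects={
        "(Intercept)": 5.31, "tacks_per_line": 0.04, "musical": 0.17,
        "meter": 0.29, "tacks_per_line:musical": 0.14,
        "tacks_per_line:meter": 0.04, "musical:meter": -0.02,
        "tacks_per_line:musical:meter": 0.00,
    },
    resid_sd=_sq(3.20),
    participant_intercept_sd=_sq(0.54),
    participant_slope_sd=_sq(0.07),
    participant_corr=-0.17,
    participant_slope_on="tacks_per_line",
    poem_intercept_sd=_sq(0.12),
)

LINE_TACKLINE_SOI_PARAMS = GenerativeParams(
    fixed_effects={
        "(Intercept)": 51.93, "tack_line": 2.58, "musical": -0.18,
        "meter": 0.46, "tack_line:musical": 1.04, "tack_line:meter": -0.22,
        "musical:meter": 0.86, "tack_line:musical:meter": 0.07,
    },
    resid_sd=_sq(281.64),
    participant_intercept_sd=_sq(2.44),
    participant_slope_sd=_sq(0.01),
    participant_corr=0.99,   # reported at the +1 boundary; kept inside it
    participant_slope_on="tack_line",
    poem_intercept_sd=_sq(13.72),
)

LINE_TACKLINE_INTENSITY_PARAMS = GenerativeParams(
    fixed_effects={
        "(Intercept)": 5.31, "tack_line": -0.10, "musical": 0.17,
        "meter": 0.29, "tack_line:musical": -0.23, "tack_line:meter": -0.08,
        "musical:meter": -0.04, "tack_line:musical:meter": 0.03,
    },
    resid_sd=_sq(3.22),
    participant_intercept_sd=_sq(0.54),
    participant_slope_sd=_sq(0.13),
    participant_corr=0.18,
    participant_slope_on="tack_line",
    poem_intercept_sd=_sq(0.12),
)


# --- generation ----------------------------------------------------------


def _draw_pair(rng, n, sd0, sd1, corr):
    """Correlated (intercept, slope) pairs; degenerate SDs of 0 allowed."""
    z = rng.standard_normal((n, 2))
    out = np.empty((n, 2))
    out[:, 0] = sd0 * z[:, 0]
    out[:, 1] = sd1 * (corr * z[:, 0] + math.sqrt(max(0.0, 1.0 - corr ** 2)) * z[:, 1])
    return out


def _linear_predictor(df: pd.DataFrame, params: GenerativeParams,
                      factors: list[str], covariates: list[str]) -> np.ndarray:
    X = build_design(df, factors, covariates)
    # interaction names match regardless of component order
    norm = lambda name: ":".join(sorted(name.split(":")))  # noqa: E731
    effects = {norm(k): v for k, v in params.fixed_effects.items()}
    missing = [c for c in X.columns if norm(c) not in effects]
    if missing:
        raise KeyError(
            f"generative fixed_effects is missing terms {missing}; "
            f"it has {sorted(params.fixed_effects)}"
        )
    beta = np.array([effects[norm(c)] for c in X.columns])
    return X.to_numpy() @ beta


def _token_frame(poems: list[PoemSpec], participants) -> pd.DataFrame:
    """One row per (participant, syllable slot), with coded metadata."""
    slot_rows = []
    for poem in poems:
        for line_no, j, k, slot in poem.iter_slots():
            # the slot label IS the lexical identity the syllable random
            # intercept groups over ("tack" for tack slots)
            syll_type = slot.label
            slot_rows.append((
                poem.poem_id, poem.meter.value, line_no, slot.word_idx, j, k,
                slot.label, slot.stress.value, slot.is_tack, syll_type,
            ))
    slots = pd.DataFrame(slot_rows, columns=[
        "poem_id", "meter", "line_no", "word_idx", "syll_idx_in_line",
        "syll_idx_in_poem", "label", "stress", "is_tack", "syllable_type",
    ])
    # 1-based tack ordinal within each line
    grp = slots.groupby(["poem_id", "line_no"], sort=False)["is_tack"]
    slots["tack_index"] = grp.cumsum().where(slots["is_tack"]).astype("Int64")
    frames = []
    for p in participants:
        f = slots.copy()
        f.insert(0, "participant_id", p.participant_id)
        f["musical"] = p.musical
        f["instruction"] = p.instruction
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


def _simulate_response(
    tokens: pd.DataFrame,
    participants,
    params_regular: GenerativeParams,
    params_tack: GenerativeParams | None,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw one response column for a token frame (regular + tack rows)."""
    if params_tack is None:
        params_tack = params_regular
    pids = [p.participant_id for p in participants]
    pid_idx = pd.Categorical(tokens["participant_id"], categories=pids).codes
    is_tack = tokens["is_tack"].to_numpy(bool)
    y = np.empty(len(tokens))

    # regular rows: fixed effects + participant (1 + stress) + syllable + resid
    reg = tokens[~is_tack].copy()
    lp = _linear_predictor(reg, params_regular, ["stress", "musical", "meter"], [])
    pr = _draw_pair(rng, len(pids), params_regular.participant_intercept_sd,
                    params_regular.participant_slope_sd, params_regular.participant_corr)
    types = pd.unique(reg["syllable_type"])
    u_syll = dict(zip(types, rng.normal(0.0, params_regular.syllable_intercept_sd, len(types))))
    stress_code = np.where(reg["stress"].to_numpy() == "s", 1.0, -1.0)
    ridx = pid_idx[~is_tack]
    y[~is_tack] = (
        lp + pr[ridx, 0] + pr[ridx, 1] * stress_code
        + reg["syllable_type"].map(u_syll).to_numpy()
        + rng.normal(0.0, params_regular.resid_sd, len(reg))
    )

    # tack rows: centred tack index enters the fixed part; no syllable effect
    if is_tack.any():
        tk = tokens[is_tack].copy()
        ti = tk["tack_index"].astype(float)
        tk["tack_index"] = ti - ti.mean()
        lp_t = _linear_predictor(
            tk, params_tack, ["stress", "musical", "meter"], ["tack_index"]
        )
        pt = _draw_pair(rng, len(pids), params_tack.participant_intercept_sd,
                        params_tack.participant_slope_sd, params_tack.participant_corr)
        stress_t = np.where(tk["stress"].to_numpy() == "s", 1.0, -1.0)
        tidx = pid_idx[is_tack]
        y[is_tack] = (
            lp_t + pt[tidx, 0] + pt[tidx, 1] * stress_t
            + rng.normal(0.0, params_tack.resid_sd, len(tk))
        )
    return y


def _layout_timeline(tokens: pd.DataFrame, soi_ms: np.ndarray,
                     pause: PauseModel, rng: np.random.Generator) -> pd.DataFrame:
    """Assign onset/offset times so that onset spacing reproduces the SOIs.

    Within a line, consecutive onsets are SOI apart and syllables abut
    (duration = SOI); the line-final syllable's duration equals its own SOI
    and is followed by a lognormal line-final pause.  Generated SOIs are
    floored at MIN_SOI_MS to keep the timeline monotone.
    """
    df = tokens.copy()
    df["soi_ms"] = np.maximum(soi_ms, MIN_SOI_MS)
    mu = math.log(pause.line_final_mean_ms ** 2 /
                  math.sqrt(pause.line_final_mean_ms ** 2 + pause.line_final_sd_ms ** 2))
    sig = math.sqrt(math.log(1.0 + (pause.line_final_sd_ms / pause.line_final_mean_ms) ** 2))
    onsets = np.empty(len(df))
    offsets = np.empty(len(df))
    for (_pid, _poem), grp in df.groupby(["participant_id", "poem_id"], sort=False):
        t = 0.2  # leading silence, s
        for _line, lg in grp.groupby("line_no", sort=True):
            sois = lg["soi_ms"].to_numpy() / 1000.0
            start = t + np.concatenate([[0.0], np.cumsum(sois[:-1])])
            onsets[lg.index] = start
            offsets[lg.index] = start + sois  # duration = SOI, incl. final
            t = start[-1] + sois[-1] + rng.lognormal(mu, sig) / 1000.0
    df["onset_s"] = onsets
    df["offset_s"] = offsets
    return df


def simulate_syllables(
    poems: list[PoemSpec] | None = None,
    participants: list[ParticipantProfile] | None = None,
    params_regular: GenerativeParams = REGULAR_SOI_PARAMS,
    params_tack: GenerativeParams | None = TACK_SOI_PARAMS,
    seed: int | np.random.Generator = 0,
    layout: bool = True,
) -> pd.DataFrame:
    """Generate a per-syllable SOI table for all participants and poems.

    Returns the syllable-token schema plus ``syllable_type``, ``musical``,
    ``instruction`` and ``soi_ms`` (the generated SOI, floored at
    MIN_SOI_MS when ``layout``); with ``layout`` the tokens also carry a
    consistent onset/offset timeline whose onset spacing reproduces the
    SOIs exactly, so the feature step can recompute them.  Deterministic
    under a fixed seed.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if poems is None:
        poems = study_poems(seed=rng)
    if participants is None:
        participants = default_participants()
    tokens = _token_frame(poems, participants)
    soi = _simulate_response(tokens, participants, params_regular, params_tack, rng)
    if layout:
        return _layout_timeline(tokens, soi, params_regular.pause_model, rng)
    tokens = tokens.copy()
    tokens["soi_ms"] = soi
    return tokens


def simulate_intensity_table(
    tokens: pd.DataFrame,
    participants: list[ParticipantProfile],
    params_regular: GenerativeParams = REGULAR_INTENSITY_PARAMS,
    params_tack: GenerativeParams | None = TACK_INTENSITY_PARAMS,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Per-interval mean intensity (dB), keyed like the feature join expects."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    vals = _simulate_response(tokens, participants, params_regular, params_tack, rng)
    out = tokens[["participant_id", "poem_id", "syll_idx_in_poem"]].copy()
    out["i_mean_db"] = vals
    return out


def inject_pauses(
    tokens: pd.DataFrame,
    pause: PauseModel,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Insert long within-line pauses into a laid-out token table.

    Each non-line-final syllable independently gets, with probability
    ``pause.long_pause_prob``, an extra gap of ``long_pause_min_ms`` plus
    an exponential tail; all later syllables of the recording shift back,
    so only the chosen syllable's SOI grows.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    df = tokens.copy()
    if pause.long_pause_prob <= 0:
        return df
    line_key = ["participant_id", "poem_id", "line_no"]
    is_final = df.groupby(line_key, sort=False).cumcount(ascending=False) == 0
    hit = (~is_final) & (rng.random(len(df)) < pause.long_pause_prob)
    gaps_ms = np.where(
        hit, pause.long_pause_min_ms + rng.exponential(pause.long_pause_tail_ms, len(df)), 0.0
    )
    for (_pid, _poem), grp in df.groupby(["participant_id", "poem_id"], sort=False):
        shift = np.concatenate([[0.0], np.cumsum(gaps_ms[grp.index.to_numpy()][:-1])]) / 1000.0
        df.loc[grp.index, "onset_s"] += shift
        df.loc[grp.index, "offset_s"] += shift
    if "soi_ms" in df.columns:
        df.loc[hit, "soi_ms"] += gaps_ms[hit]
    return df


def tokens_to_textgrids(tokens: pd.DataFrame, out_dir, dialect: str = "long",
                        encoding: str = "utf-8") -> list:
    """Emit one TextGrid per participant x poem with a syllable tier.

    Pauses appear as empty-label intervals between syllables; returns the
    written paths.  Together with read_textgrid/build_syllable_table this
    closes the ingestion loop over the synthetic reading.
    """
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for (pid, poem), grp in tokens.groupby(["participant_id", "poem_id"], sort=False):
        intervals = []
        t = 0.0
        for r in grp.itertuples():
            on, off = round(r.onset_s, 6), round(r.offset_s, 6)
            if on > t + 1e-9:
                intervals.append((t, on, ""))
            intervals.append((on, off, r.label))
            t = off
        intervals.append((t, t + 0.5, ""))
        tier = annotation_io.IntervalTier(name="syllables", intervals=intervals)
        path = out_dir / f"{pid}_{poem}.TextGrid"
        annotation_io.write_textgrid([tier], path, dialect=dialect, encoding=encoding)
        paths.append(path)
    return paths


def simulate_lines(
    participants: list[ParticipantProfile] | None = None,
    poems: list[PoemSpec] | None = None,
    params: GenerativeParams = LINE_NPVI_SOI_PARAMS,
    seed: int | np.random.Generator = 0,
    response: str = "npvi_soi",
) -> pd.DataFrame:
    """Generate a line-level nPVI table directly from the line model.

    One row per participant x verse line (120 lines per participant with
    the default poems).  The participant slope and the tack fixed effects
    act on the centred tack covariate named by ``params.participant_slope_on``
    ("tacks_per_line" or "tack_line"); poem and participant intercepts and
    Gaussian residuals complete the draw.  Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if poems is None:
        poems = study_poems(seed=rng)
    if participants is None:
        participants = default_participants()
    line_rows = []
    for poem in poems:
        for line_no, line in enumerate(poem.lines, start=1):
            n_tacks = sum(s.is_tack for s in line.slots)
            line_rows.append((poem.poem_id, poem.meter.value, line_no,
                              n_tacks, len(line.slots)))
    lines = pd.DataFrame(line_rows, columns=[
        "poem_id", "meter", "line_no", "tacks_per_line", "n_sylls"])
    frames = []
    for p in participants:
        f = lines.copy()
        f.insert(0, "participant_id", p.participant_id)
        f["musical"] = p.musical
        f["instruction"] = p.instruction
        frames.append(f)
    df = pd.concat(frames, ignore_index=True)
    df["tack_line"] = df["tacks_per_line"] > 0

    tackvar = params.participant_slope_on
    work = df.copy()
    if tackvar == "tacks_per_line":
        cov = df["tacks_per_line"].astype(float)
        cov = cov - cov.mean()
        work["tacks_per_line"] = cov
        lp = _linear_predictor(work, params, ["musical", "meter"], ["tacks_per_line"])
        slope_cov = cov.to_numpy()
    elif tackvar == "tack_line":
        lp = _linear_predictor(work, params, ["tack_line", "musical", "meter"], [])
        slope_cov = np.where(df["tack_line"].to_numpy(), -1.0, 1.0)
    else:
        raise ValueError(f"unsupported participant_slope_on {tackvar!r}")

    pids = [p.participant_id for p in participants]
    pid_idx = pd.Categorical(df["participant_id"], categories=pids).codes
    pr = _draw_pair(rng, len(pids), params.participant_intercept_sd,
                    params.participant_slope_sd, params.participant_corr)
    poem_ids = [p.poem_id for p in poems]
    poem_idx = pd.Categorical(df["poem_id"], categories=poem_ids).codes
    u_poem = rng.normal(0.0, params.poem_intercept_sd, len(poem_ids))
    df[response] = (
        lp + pr[pid_idx, 0] + pr[pid_idx, 1] * slope_cov + u_poem[poem_idx]
        + rng.normal(0.0, params.resid_sd, len(df))
    )
    return df
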
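"""End-to-end orchestration of the rhythm analysis.

A study run is a fixed stage order: syllable table -> SOI computation ->
2000 ms filter -> intensity join -> syllable-level two-pass fits -> nPVI
aggregation -> centring -> line-level two-pass fits.  Two entry modes share
that tail: ``simulate`` draws a synthetic reading, ``ingest`` reads Praat
TextGrids plus a poem specification, participant metadata and an intensity
table.  Every stochastic step is seeded from the single run seed, so a run
is byte-reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotation_io import build_syllable_table, read_textgrid
from .inference import CANONICAL_SPECS, ModelFit, report_table, fit_metadata, two_pass_outlier_fit
from .npvi_metrics import aggregate_lines, center_covariates
from .rhythm_features import attach_intensity, compute_soi, filter_max_soi
from .stimulus_model import poems_from_table, study_poems
from .synthetic_reader import (
    PauseModel,
    default_participants,
    inject_pauses,
    participants_from_table,
    participants_to_table,
    simulate_intensity_table,
    simulate_syllables,
)

__all__ = ["RunConfig", "run_study"]

log = logging.getLogger(__name__)

DEFAULT_MODELS = (
    "regular-soi", "regular-intensity", "tack-soi", "tack-intensity",
    "line-npvi-soi", "line-npvi-intensity",
)


@dataclass
class RunConfig:
    """Configuration of one study run; serialisable via dataclasses.asdict."""

    mode: str = "simulate"
    seed: int = 1
    out_dir: str | None = None
    models: tuple[str, ...] = DEFAULT_MODELS
    df_method: str = "satterthwaite"
    max_soi_ms: float = 2000.0
    # simulate mode
    tack_rate: float = 0.17
    long_pause_prob: float = 0.005
    # ingest mode
    textgrid_dir: str | None = None
    poem_table: str | None = None
    participant_table: str | None = None
    intensity_table: str | None = None
    strict: bool = True
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        known = set(CANONICAL_SPECS())
        unknown = [m for m in self.models if m not in known]
        if unknown:
            raise ValueError(f"unknown model name(s) {unknown}; known: {sorted(known)}")
        if self.mode not in ("simulate", "ingest"):
            raise ValueError(f"mode must be simulate or ingest, got {self.mode!r}")
        if self.mode == "ingest":
            for attr in ("textgrid_dir", "poem_table", "participant_table",
                         "intensity_table"):
                if getattr(self, attr) is None:
                    raise ValueError(f"ingest mode requires {attr}")


def _simulate_inputs(config: RunConfig):
    rng = np.random.default_rng(config.seed)
    poems = study_poems(tack_rate=config.tack_rate, seed=rng)
    participants = default_participants()
    tokens = simulate_syllables(poems, participants, seed=rng)
    if config.long_pause_prob > 0:
        tokens = inject_pauses(
            tokens, PauseModel(long_pause_prob=config.long_pause_prob), seed=rng
        )
    intensity = simulate_intensity_table(tokens, participants, seed=rng)
    return tokens.drop(columns=["soi_ms"]), intensity, participants


def _ingest_inputs(config: RunConfig):
    poems = {p.poem_id: p for p in poems_from_table(config.poem_table)}
    participants = participants_from_table(config.participant_table)
    by_id = {p.participant_id: p for p in participants}
    frames = []
    for path in sorted(Path(config.textgrid_dir).glob("*.TextGrid")):
        pid, poem_id = path.stem.split("_", 1)
        if poem_id not in poems:
            raise ValueError(f"{path.name}: unknown poem {poem_id!r}")
        if pid not in by_id:
            raise ValueError(f"{path.name}: unknown participant {pid!r}")
        tiers = read_textgrid(path)
        frames.append(build_syllable_table(tiers, poems[poem_id], pid,
                                           strict=config.strict))
    tokens = pd.concat(frames, ignore_index=True)
    tokens["syllable_type"] = tokens["label"]
    prof = participants_to_table(participants).set_index("participant_id")
    tokens["musical"] = tokens["participant_id"].map(prof["musical"])
    tokens["instruction"] = tokens["participant_id"].map(prof["instruction"])
    intensity = pd.read_csv(config.intensity_table, sep="\t")
    return tokens, intensity, participants


def run_study(config: RunConfig) -> dict:
    """Run the full analysis; returns the result bundle and writes out_dir.

    The bundle maps stage names to tables and fits: ``features`` (syllable
    level), ``lines`` (nPVI level), ``fits``/``first_fits`` (two-pass
    results per model name) and ``metadata``.
    """
    config.validate()
    stage = "inputs"
    try:
        if config.mode == "simulate":
            tokens, intensity, _participants = _simulate_inputs(config)
        else:
            tokens, intensity, _participants = _ingest_inputs(config)

        stage = "features"
        features = compute_soi(tokens)
        features = filter_max_soi(features, max_ms=config.max_soi_ms)
        features = attach_intensity(features, intensity)

        stage = "lines"
        lines = aggregate_lines(features)
        lines = center_covariates(
            lines, ["tacks_per_line", "line_no", "n_sylls"], standardize=False
        )

        specs = CANONICAL_SPECS()
        fits: dict[str, ModelFit] = {}
        first_fits: dict[str, ModelFit] = {}
        for name in config.models:
            stage = f"fit:{name}"
            spec = specs[name].with_df_method(config.df_method)
            table = lines if spec.subset == "lines" else features
            first, _retained, final = two_pass_outlier_fit(table, spec)
            fits[name] = final
            first_fits[name] = first
    except Exception as err:
        raise RuntimeError(f"study run failed at stage {stage!r}: {err}") from err

    metadata = {
        "version": __version__,
        "mode": config.mode,
        "seed": config.seed,
        "max_soi_ms": config.max_soi_ms,
        "tack_rate": config.tack_rate,
        "df_method": config.df_method,
        "covariate_centering": "center-only (scale(..., scale=FALSE))",
        "n_feature_rows": int(len(features)),
        "n_excluded": int(features["excluded"].sum()),
        "n_lines": int(len(lines)),
        "models": {name: fit_metadata(fit) for name, fit in fits.items()},
    }
    bundle = {"features": features, "lines": lines, "fits": fits,
              "first_fits": first_fits, "metadata": metadata}
    if config.out_dir:
        _write_bundle(bundle, Path(config.out_dir))
    return bundle


def _write_bundle(bundle: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle["features"].to_csv(out_dir / "syllable_features.tsv", sep="\t", index=False)
    bundle["lines"].to_csv(out_dir / "line_records.tsv", sep="\t", index=False)
    for name, fit in bundle["fits"].items():
        fit.coefficients.to_csv(out_dir / f"fit_{name}.tsv", sep="\t")
        (out_dir / f"fit_{name}.txt").write_text(report_table(fit) + "\n")
    (out_dir / "run_metadata.json").write_text(
        json.dumps(bundle["metadata"], indent=2) + "\n"
    )
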
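import numpy as np
import pandas as pd
import pytest
from scipy import stats

from verserhythm.rhythm_features import compute_soi, filter_max_soi
from verserhythm.stimulus_model import build_grid
from verserhythm.synthetic_reader import (
    GenerativeParams,
    PauseModel,
    _draw_pair,
    default_participants,
    inject_pauses,
    simulate_intensity_table,
    simulate_lines,
    simulate_syllables,
)

FLAT = {"(Intercept)": 254.0, "stress": 0.0, "musical": 0.0, "meter": 0.0,
        "stress:musical": 0.0, "stress:meter": 0.0, "musical:meter": 0.0,
        "stress:musical:meter": 0.0}


def _plain_poems():
    return [build_grid("iambic", 4, 8, poem_id="I1"),
            build_grid("trochaic", 4, 8, poem_id="T1")]


def test_default_panel_composition():
    panel = default_participants()
    assert len(panel) == 13
    musical = [p.musical for p in panel]
    assert musical.count("active") == 6 and musical.count("not_active") == 7
    instr = pd.crosstab(pd.Series(musical), pd.Series([p.instruction for p in panel]))
    assert instr.loc["active", "no_instruction"] == 3
    assert instr.loc["not_active", "on_beat"] == 4


def test_degenerate_all_zero_gives_intercept(small_panel):
    params = GenerativeParams(fixed_effects=FLAT, resid_sd=0.0)
    tokens = simulate_syllables(_plain_poems(), small_panel, params, None,
                                seed=0, layout=False)
    assert np.allclose(tokens["soi_ms"], 254.0)


def test_stress_difference_is_twice_beta(small_panel):
    b = 7.3
    params = GenerativeParams(fixed_effects={**FLAT, "stress": b}, resid_sd=0.0)
    tokens = simulate_syllables(_plain_poems(), small_panel, params, None,
                                seed=0, layout=False)
    for _pid, grp in tokens.groupby("participant_id"):
        strong = grp.loc[grp["stress"] == "s", "soi_ms"].mean()
        weak = grp.loc[grp["stress"] == "w", "soi_ms"].mean()
        assert strong - weak == pytest.approx(2 * b, abs=1e-9)


def test_missing_fixed_effect_named():
    params = GenerativeParams(fixed_effects={"(Intercept)": 254.0}, resid_sd=1.0)
    with pytest.raises(KeyError, match="stress"):
        simulate_syllables(_plain_poems(), default_participants(), params, None,
                           seed=0, layout=False)


def test_monte_carlo_mean_converges(small_panel):
    params = GenerativeParams(fixed_effects={**FLAT, "stress": 10.0}, resid_sd=30.0)
    frames = [simulate_syllables(_plain_poems(), small_panel, params, None,
                                 seed=s, layout=False) for s in range(40)]
    tokens = pd.concat(frames)
    n = len(tokens)
    coded = np.where(tokens["stress"] == "s", 1.0, -1.0)
    est = (tokens["soi_ms"] * coded).sum() / (coded ** 2).sum()
    # standard error of the contrast mean is resid_sd / sqrt(n)
    assert est == pytest.approx(10.0, abs=4 * 30.0 / np.sqrt(n))


def test_participant_pair_correlation_converges():
    rng = np.random.default_rng(8)
    pairs = _draw_pair(rng, 4000, 5.0, 2.0, 0.81)
    r = np.corrcoef(pairs[:, 0], pairs[:, 1])[0, 1]
    assert r == pytest.approx(0.81, abs=0.03)
    assert pairs[:, 0].std() == pytest.approx(5.0, rel=0.05)
    assert pairs[:, 1].std() == pytest.approx(2.0, rel=0.05)


def test_simulation_deterministic_under_seed():
    a = simulate_syllables(seed=99)
    b = simulate_syllables(seed=99)
    pd.testing.assert_frame_equal(a, b)
    la = simulate_lines(seed=99)
    lb = simulate_lines(seed=99)
    pd.testing.assert_frame_equal(la, lb)
    c = simulate_syllables(seed=100)
    assert not np.allclose(a["soi_ms"], c["soi_ms"])


def test_simulate_lines_shape_and_noise_free_regression():
    lines = simulate_lines(seed=0)
    assert len(lines) == 13 * 120
    assert set(lines["tacks_per_line"]) <= set(range(6))
    params = GenerativeParams(
        fixed_effects={"(Intercept)": 50.0, "tacks_per_line": -2.5,
                       "musical": 0.0, "meter": 0.0, "tacks_per_line:musical": 0.0,
                       "tacks_per_line:meter": 0.0, "musical:meter": 0.0,
                       "tacks_per_line:musical:meter": 0.0},
        resid_sd=0.0, participant_slope_on="tacks_per_line")
    nf = simulate_lines(params=params, seed=0)
    x = nf["tacks_per_line"] - nf["tacks_per_line"].mean()
    slope = (nf["npvi_soi"] * x).sum() / (x ** 2).sum()
    assert slope == pytest.approx(-2.5, abs=1e-9)


def test_intensity_table_keys_match_tokens(small_panel):
    tokens = simulate_syllables(_plain_poems(), small_panel, seed=1)
    inten = simulate_intensity_table(tokens, small_panel, seed=2)
    assert len(inten) == len(tokens)
    assert inten["i_mean_db"].mean() == pytest.approx(65.7, abs=2.0)


def test_timeline_reproduces_generated_sois(small_panel):
    tokens = simulate_syllables(_plain_poems(), small_panel, seed=5)
    feats = compute_soi(tokens.drop(columns=["soi_ms"]))
    assert np.allclose(feats["soi_ms"], tokens["soi_ms"], atol=1e-9)


def test_inject_pauses_zero_prob_identity(small_panel):
    tokens = simulate_syllables(_plain_poems(), small_panel, seed=3)
    out = inject_pauses(tokens, PauseModel(long_pause_prob=0.0), seed=4)
    pd.testing.assert_frame_equal(out, tokens)


def test_inject_pauses_prob_one_floods_within_line(small_panel):
    tokens = simulate_syllables(_plain_poems(), small_panel, seed=3)
    out = inject_pauses(tokens, PauseModel(long_pause_prob=1.0,
                                           long_pause_min_ms=2500.0), seed=4)
    feats = filter_max_soi(compute_soi(out.drop(columns=["soi_ms"])))
    line_key = ["participant_id", "poem_id", "line_no"]
    is_final = feats.groupby(line_key, sort=False).cumcount(ascending=False) == 0
    assert feats.loc[~is_final, "excluded"].all()
    assert not feats.loc[is_final, "excluded"].any()


def test_inject_pauses_binomial_rate():
    tokens = simulate_syllables(seed=6)  # 12,883 rows, 120 lines/participant
    prob = 0.01
    out = inject_pauses(tokens, PauseModel(long_pause_prob=prob,
                                           long_pause_min_ms=2500.0), seed=7)
    feats = filter_max_soi(compute_soi(out.drop(columns=["soi_ms"])))
    line_key = ["participant_id", "poem_id", "line_no"]
    eligible = (feats.groupby(line_key, sort=False).cumcount(ascending=False) > 0)
    base = filter_max_soi(compute_soi(tokens.drop(columns=["soi_ms"])))
    extra = int(feats["excluded"].sum() - base["excluded"].sum())
    n = int(eligible.sum()) - int(base.loc[eligible.to_numpy(), "excluded"].sum())
    lo, hi = stats.binom.ppf([0.0005, 0.9995], n, prob)
    assert lo <= extra <= hi
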
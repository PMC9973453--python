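import numpy as np
import pandas as pd
import pytest

from verserhythm.coding import build_design
from verserhythm.inference import (
    cohens_d,
    code_musical,
    fit_mixed,
    icc_from_components,
    line_spec,
    regular_syllable_spec,
    sum_code,
    tack_spec,
    tukey_fences,
    two_pass_outlier_fit,
)
from verserhythm.synthetic_reader import (
    GenerativeParams,
    ParticipantProfile,
    simulate_lines,
    simulate_syllables,
)


# --- musical-activity coding ------------------------------------------------

def _profile(q4, instrument="Not at all", singing="Not at all"):
    return ParticipantProfile("p", musa_q4=q4, musa_instrument=instrument,
                              musa_singing=singing)


@pytest.mark.parametrize(
    "profile, expected",
    [
        (_profile("no"), "not_active"),
        (_profile("yes", instrument="2-3 times a month"), "active"),
        (_profile("yes", singing="daily"), "active"),
        (_profile("yes"), "not_active"),
    ],
)
def test_code_musical_rule(profile, expected):
    assert code_musical(profile) == expected


def test_code_musical_missing_answers():
    class Incomplete:
        musa_q4 = "yes"
        musa_instrument = None
        musa_singing = None

    with pytest.raises(ValueError, match="incomplete"):
        code_musical(Incomplete())


# --- sum coding -------------------------------------------------------------

def test_sum_code_levels_and_interactions():
    df = pd.DataFrame({
        "stress": ["s", "w", "s", "w"],
        "meter": ["iambic", "iambic", "trochaic", "trochaic"],
    })
    X = sum_code(df, ["stress", "meter"])
    assert X["stress"].tolist() == [1.0, -1.0, 1.0, -1.0]
    assert X["meter"].tolist() == [1.0, 1.0, -1.0, -1.0]
    assert (X["stress:meter"] == X["stress"] * X["meter"]).all()
    assert (X["(Intercept)"] == 1.0).all()


def test_sum_code_rejects_many_levels():
    df = pd.DataFrame({"f": ["a", "b", "c"]})
    with pytest.raises(ValueError, match="two-level"):
        sum_code(df, ["f"])


def test_sum_coded_intercept_is_grand_mean_of_cell_means():
    # balanced 2x2 with known cell means: intercept must equal their mean
    cells = {("s", "iambic"): 10.0, ("s", "trochaic"): 20.0,
             ("w", "iambic"): 30.0, ("w", "trochaic"): 100.0}
    rows = [(st, m, v) for (st, m), v in cells.items() for _ in range(5)]
    df = pd.DataFrame(rows, columns=["stress", "meter", "y"])
    X = sum_code(df, ["stress", "meter"])
    beta = np.linalg.lstsq(X.to_numpy(), df["y"].to_numpy(), rcond=None)[0]
    assert beta[0] == pytest.approx(np.mean(list(cells.values())))


def test_two_beta_identity_for_binary_factor():
    """Predicted strong-minus-weak difference equals twice the coefficient."""
    rng = np.random.default_rng(3)
    df = pd.DataFrame({
        "stress": rng.choice(["s", "w"], 200),
        "meter": rng.choice(["iambic", "trochaic"], 200),
    })
    X = sum_code(df, ["stress", "meter"])
    beta = rng.normal(size=X.shape[1])
    Xs = X.copy()
    Xs["stress"] = 1.0
    Xs["stress:meter"] = Xs["meter"]
    Xw = X.copy()
    Xw["stress"] = -1.0
    Xw["stress:meter"] = -Xw["meter"]
    diff = Xs.to_numpy() @ beta - Xw.to_numpy() @ beta
    expected = 2 * (beta[list(X.columns).index("stress")]
                    + beta[list(X.columns).index("stress:meter")] * X["meter"].to_numpy())
    assert np.allclose(diff, expected)


def test_three_level_factor_contr_sum_columns():
    df = pd.DataFrame({"instruction": ["no_instruction", "on_beat", "rhythmic"]})
    X = build_design(df, ["instruction"])
    cols = [c for c in X.columns if c != "(Intercept)"]
    assert len(cols) == 2
    assert X[cols].sum(axis=0).tolist() == pytest.approx([0.0, 0.0])


# --- effect sizes and variance identities ------------------------------------

def test_cohens_d_values():
    assert cohens_d(3.09, 16.53) == pytest.approx(1.52, abs=0.005)
    assert cohens_d(0.0, 10.0) == 0.0
    assert cohens_d(11.99, 23.98) == pytest.approx(4.90, abs=0.005)
    with pytest.raises(ValueError):
        cohens_d(1.0, 0.0)


def test_icc_from_components():
    assert icc_from_components([5982.17, 406.63], 2623.56) == pytest.approx(0.709, abs=5e-4)


# --- two-pass outlier procedure ----------------------------------------------

def _line_table(seed=0, noise=GenerativeParams(
        fixed_effects={"(Intercept)": 50.0, "tacks_per_line": -1.5,
                       "musical": 0.0, "meter": 0.0,
                       "tacks_per_line:musical": 0.0, "tacks_per_line:meter": 0.0,
                       "musical:meter": 0.0, "tacks_per_line:musical:meter": 0.0},
        resid_sd=5.0, participant_intercept_sd=2.0, participant_slope_sd=0.3,
        participant_slope_on="tacks_per_line", poem_intercept_sd=1.0)):
    return simulate_lines(params=noise, seed=seed)


def test_two_pass_no_outliers_keeps_first_fit():
    lines = _line_table(seed=4)
    spec = line_spec("npvi_soi", "tacks_per_line").with_df_method("residual")
    first, retained, final = two_pass_outlier_fit(lines, spec, k=50.0)  # huge fences
    assert len(retained) == len(lines)
    pd.testing.assert_frame_equal(first.coefficients, final.coefficients)


def test_two_pass_drops_gross_outlier_and_matches_fence_oracle():
    lines = _line_table(seed=5)
    idx = lines.index[37]
    lines.loc[idx, "npvi_soi"] += 50.0  # +10 residual SD
    spec = line_spec("npvi_soi", "tacks_per_line").with_df_method("residual")
    first, retained, final = two_pass_outlier_fit(lines, spec)
    dropped = set(lines.index) - set(retained.index)
    assert idx in dropped
    # oracle: direct fence computation on the pass-1 residuals
    lo, hi = np.percentile(first.residuals, [25, 75])
    iqr = hi - lo
    keep_oracle = (first.residuals >= lo - 1.5 * iqr) & (first.residuals <= hi + 1.5 * iqr)
    assert set(retained.index) == set(lines.index[keep_oracle])


def test_two_pass_fences_are_location_invariant():
    lines = _line_table(seed=6)
    spec = line_spec("npvi_soi", "tacks_per_line").with_df_method("residual")
    _, retained_a, _ = two_pass_outlier_fit(lines, spec)
    shifted = lines.assign(npvi_soi=lines["npvi_soi"] + 1000.0)
    _, retained_b, _ = two_pass_outlier_fit(shifted, spec)
    assert retained_a.index.tolist() == retained_b.index.tolist()


def test_tukey_fences_direct():
    x = np.array([1.0, 2.0, 3.0, 4.0, 100.0])
    lo, hi = tukey_fences(x)
    q1, q3 = np.percentile(x, [25, 75])
    assert (lo, hi) == (q1 - 1.5 * (q3 - q1), q3 + 1.5 * (q3 - q1))


# --- canonical fits on noise-free generators ---------------------------------

def test_regular_spec_noise_free_exact(small_panel):
    from verserhythm.stimulus_model import build_grid

    poems = [build_grid("iambic", 4, 8, poem_id="I1"),
             build_grid("trochaic", 4, 8, poem_id="T1")]
    params = GenerativeParams(
        fixed_effects={"(Intercept)": 254.0, "stress": 20.0, "musical": 3.0,
                       "meter": 2.0, "stress:musical": 3.6, "stress:meter": -0.1,
                       "musical:meter": -0.7, "stress:musical:meter": 0.1},
        resid_sd=0.0)
    tokens = simulate_syllables(poems, small_panel, params, None,
                                seed=1, layout=False)
    tokens["excluded"] = False
    spec = regular_syllable_spec("soi_ms").with_df_method("residual")
    fit = fit_mixed(tokens, spec)
    got = fit.coefficients["beta"]
    assert got["(Intercept)"] == pytest.approx(254.0, abs=1e-5)
    assert got["stress"] == pytest.approx(20.0, abs=1e-5)
    assert got["stress:musical"] == pytest.approx(3.6, abs=1e-5)


def test_tack_spec_noise_free_recovers_tack_index(small_panel):
    from verserhythm.stimulus_model import build_grid, place_tacks

    # dense tacks so the tack index varies within every design cell
    poems = [place_tacks(build_grid("iambic", 8, 8, poem_id="I1"), 0.5, seed=5),
             place_tacks(build_grid("trochaic", 8, 8, poem_id="T1"), 0.5, seed=7)]
    effects = {"(Intercept)": 280.0, "stress": -9.0, "musical": -3.0,
               "meter": -14.0, "tack_index": 7.92}
    for a in ("stress", "musical", "meter"):
        effects[f"{a}:tack_index"] = 0.0
    effects.update({"stress:musical": 0.0, "stress:meter": 0.0,
                    "musical:meter": 0.0, "stress:musical:meter": 0.0,
                    "stress:musical:tack_index": 0.0,
                    "stress:meter:tack_index": 0.0,
                    "musical:meter:tack_index": 0.0,
                    "stress:musical:meter:tack_index": 0.0})
    params = GenerativeParams(fixed_effects=effects, resid_sd=0.0)
    tokens = simulate_syllables(poems, small_panel, params, params,
                                seed=2, layout=False)
    tokens["excluded"] = False
    fit = fit_mixed(tokens, tack_spec("soi_ms").with_df_method("residual"))
    assert fit.coefficients["beta"]["tack_index"] == pytest.approx(7.92, abs=1e-5)
    assert fit.n_obs == int(tokens["is_tack"].sum())


def test_line_spec_noise_free_recovers_slope():
    params = GenerativeParams(
        fixed_effects={"(Intercept)": 51.0, "tacks_per_line": -1.49,
                       "musical": 0.0, "meter": 0.0,
                       "tacks_per_line:musical": 0.0, "tacks_per_line:meter": 0.0,
                       "musical:meter": 0.0, "tacks_per_line:musical:meter": 0.0},
        resid_sd=0.0, participant_slope_on="tacks_per_line")
    lines = simulate_lines(params=params, seed=3)
    fit = fit_mixed(lines, line_spec("npvi_soi", "tacks_per_line").with_df_method("residual"))
    assert fit.coefficients["beta"]["tacks_per_line"] == pytest.approx(-1.49, abs=1e-6)
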
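import shutil
import subprocess
import sys

import numpy as np
import pandas as pd
import pytest

from verserhythm.lmm import RandomTermSpec, SingularFitWarning, fit_lmm


def _sim_crossed(rng, ng=15, ns=40, beta=(100.0, 5.0), cov=((25.0, 8.0), (8.0, 4.0)),
                 syll_sd=3.0, resid_sd=4.0):
    n = ng * ns
    g = np.repeat(np.arange(ng), ns)
    s = np.tile(np.arange(ns), ng)
    x = rng.choice([-1.0, 1.0], n)
    L = np.linalg.cholesky(np.asarray(cov))
    bi = rng.standard_normal((ng, 2)) @ L.T
    u = rng.normal(0, syll_sd, ns)
    y = beta[0] + beta[1] * x + bi[g, 0] + bi[g, 1] * x + u[s] + rng.normal(0, resid_sd, n)
    data = pd.DataFrame({"g": g, "s": s, "x": x})
    X = pd.DataFrame({"(Intercept)": np.ones(n), "x": x})
    return y, X, data


def test_noise_free_exact_recovery(rng):
    n = 240
    x1 = rng.choice([-1.0, 1.0], n)
    x2 = rng.choice([-1.0, 1.0], n)
    X = pd.DataFrame({"(Intercept)": np.ones(n), "x1": x1, "x2": x2,
                      "x1:x2": x1 * x2})
    y = X.to_numpy() @ np.array([250.0, 20.0, 3.0, -0.5])
    data = pd.DataFrame({"g": np.arange(n) % 6, "x1": x1})
    res = fit_lmm(y, X, data, [RandomTermSpec("g", ("x1",))], df_method="residual")
    assert np.allclose(res.params.to_numpy(), [250.0, 20.0, 3.0, -0.5], atol=1e-6)


def test_zero_variance_generator_matches_ols(rng):
    """With no group effects the fit collapses to OLS fixed effects."""
    n = 400
    x = rng.choice([-1.0, 1.0], n)
    y = 10.0 + 2.0 * x + rng.normal(0, 1.5, n)
    X = pd.DataFrame({"(Intercept)": np.ones(n), "x": x})
    data = pd.DataFrame({"g": np.arange(n) % 8})
    with pytest.warns(SingularFitWarning):
        res = fit_lmm(y, X, data, [RandomTermSpec("g")], df_method="residual")
    ols = np.linalg.lstsq(X.to_numpy(), y, rcond=None)[0]
    assert np.allclose(res.params.to_numpy(), ols, atol=1e-4)
    assert res.vcomp[0]["Sigma"][0, 0] < 0.05
    assert res.singular


def test_rank_deficient_design_rejected(rng):
    n = 60
    x = rng.choice([-1.0, 1.0], n)
    X = pd.DataFrame({"(Intercept)": np.ones(n), "x": x, "x_copy": x})
    data = pd.DataFrame({"g": np.arange(n) % 5})
    with pytest.raises(ValueError, match="aliased.*x_copy"):
        fit_lmm(x + 1.0, X, data, [RandomTermSpec("g")])


def test_matches_statsmodels_random_intercept(rng):
    """Single random intercept: REML estimates agree with MixedLM."""
    import statsmodels.formula.api as smf

    ng, m = 25, 12
    g = np.repeat(np.arange(ng), m)
    x = rng.choice([-1.0, 1.0], ng * m)
    y = 50 + 3 * x + rng.normal(0, 5, ng)[g] + rng.normal(0, 2, ng * m)
    df = pd.DataFrame({"y": y, "x": x, "g": g})
    sm_fit = smf.mixedlm("y ~ x", df, groups=df["g"], re_formula="1").fit(reml=True)
    X = pd.DataFrame({"(Intercept)": np.ones(len(df)), "x": x})
    res = fit_lmm(y, X, df, [RandomTermSpec("g")], df_method="residual")
    assert res.params["(Intercept)"] == pytest.approx(sm_fit.params["Intercept"], abs=1e-4)
    assert res.params["x"] == pytest.approx(sm_fit.params["x"], abs=1e-4)
    assert res.se["x"] == pytest.approx(sm_fit.bse["x"], rel=1e-3)
    assert res.sigma2 == pytest.approx(sm_fit.scale, rel=1e-3)
    assert res.vcomp[0]["Sigma"][0, 0] == pytest.approx(
        float(sm_fit.cov_re.iloc[0, 0]), rel=1e-2
    )


def test_matches_lme4_crossed_with_correlated_slope(rng, tmp_path):
    """Full structure (crossed factors, correlated slope, Satterthwaite df)
    agrees with the reference R implementation (lme4 + lmerTest)."""
    if shutil.which("Rscript") is None:
        pytest.fail("Rscript not available for the oracle comparison")
    y, X, data = _sim_crossed(rng)
    res = fit_lmm(y, X, data, [RandomTermSpec("g", ("x",)), RandomTermSpec("s")])
    csv = tmp_path / "d.csv"
    pd.concat([pd.Series(y, name="y"), data], axis=1).to_csv(csv, index=False)
    rcode = f"""
    suppressMessages({{library(lme4); library(lmerTest)}})
    d <- read.csv("{csv}"); d$g <- factor(d$g); d$s <- factor(d$s)
    m <- lmer(y ~ x + (1 + x | g) + (1 | s), data = d, REML = TRUE)
    co <- summary(m)$coefficients
    vc <- as.data.frame(VarCorr(m))
    cat(co[,"Estimate"], co[,"Std. Error"], co[,"df"], sep="\\n")
    cat("\\n"); cat(sigma(m)^2, "\\n"); cat(REMLcrit(m), "\\n")
    """
    out = subprocess.run(["Rscript", "-"], input=rcode, text=True,
                         capture_output=True, check=True)
    vals = [float(v) for v in out.stdout.split()]
    est, se, df = vals[0:2], vals[2:4], vals[4:6]
    sigma2_r, reml_r = vals[6], vals[7]
    assert res.params.to_numpy() == pytest.approx(est, rel=1e-4)
    assert res.se.to_numpy() == pytest.approx(se, rel=1e-3)
    assert res.df.to_numpy() == pytest.approx(df, rel=5e-3)
    assert res.sigma2 == pytest.approx(sigma2_r, rel=1e-3)
    assert res.reml_criterion == pytest.approx(reml_r, abs=1e-2)


def test_variance_components_recovered_at_scale():
    """Large-sample REML recovers the generating variance components."""
    rng = np.random.default_rng(77)
    y, X, data = _sim_crossed(rng, ng=60, ns=80)
    res = fit_lmm(y, X, data, [RandomTermSpec("g", ("x",)), RandomTermSpec("s")],
                  df_method="residual")
    Sg = res.vcomp[0]["Sigma"]
    assert Sg[0, 0] == pytest.approx(25.0, rel=0.5)
    assert Sg[1, 1] == pytest.approx(4.0, rel=0.5)
    assert Sg[0, 1] / np.sqrt(Sg[0, 0] * Sg[1, 1]) == pytest.approx(0.8, abs=0.2)
    assert res.vcomp[1]["Sigma"][0, 0] == pytest.approx(9.0, rel=0.4)
    assert res.sigma2 == pytest.approx(16.0, rel=0.1)
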
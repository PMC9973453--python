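"""Gaussian linear mixed models by profiled REML, with Satterthwaite df.

The estimation problem here is small in the random-effects dimension (a few
hundred levels across crossed grouping factors) but needs features that a
single-grouping fitter cannot provide: crossed random factors (participant
and syllable type, or participant and poem) and a correlated
intercept+slope block per participant.  The implementation follows the
standard profiled-REML formulation: the random-effect covariance of each
term is parameterised by a lower-triangular relative Cholesky factor
``Lambda`` (so ``cov = sigma^2 * Lambda @ Lambda.T``), beta and sigma^2 are
profiled out, and the profiled criterion is minimised over the Cholesky
entries with a derivative-free bounded optimiser.

All linear algebra is dense in the q x q random-effects dimension (q below
~500 for every model used here), so a criterion evaluation is a single
Cholesky factorisation.  Satterthwaite denominator degrees of freedom are
obtained from finite-difference derivatives of the coefficient covariance
with respect to the variance parameters, with the variance-parameter
covariance taken from the finite-difference Hessian of the (unprofiled)
REML criterion -- the same construction lmerTest uses.

Degenerate fits (a variance at zero, a correlation at +-1) are reported
through ``singular=True`` and a warning; estimates are still returned.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.optimize
import scipy.sparse as sp
from scipy import stats

__all__ = ["RandomTermSpec", "LMMResult", "fit_lmm", "SingularFitWarning"]

log = logging.getLogger(__name__)

_OPT_TOL = 1e-8


class SingularFitWarning(UserWarning):
    """The REML estimate sits on the boundary of the parameter space."""


@dataclass(frozen=True)
class RandomTermSpec:
    """One random-effects term: a grouping factor, optional slope columns.

    ``group`` names a column of the data frame whose levels get independent
    effects; a random intercept is always included, plus one random slope
    per column named in ``slopes``, with a fully parameterised (correlated)
    covariance block.
    """

    group: str
    slopes: tuple[str, ...] = ()

    @property
    def k(self) -> int:
        return 1 + len(self.slopes)


@dataclass
class LMMResult:
    """REML fit of a Gaussian linear mixed model."""

    terms: list[RandomTermSpec]
    params: pd.Series
    se: pd.Series
    df: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    sigma2: float
    vcomp: list[dict]            # per term: group, names, Sigma (k x k)
    n_obs: int
    n_groups: dict[str, int]
    reml_criterion: float
    aic: float
    r2_marginal: float
    r2_conditional: float
    converged: bool
    singular: bool
    df_method: str
    resid: np.ndarray = field(repr=False, default=None)
    fittedvalues: np.ndarray = field(repr=False, default=None)
    ranef: list[np.ndarray] = field(repr=False, default=None)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"beta": self.params, "se": self.se, "df": self.df,
             "t": self.tvalues, "p": self.pvalues}
        )

    @property
    def icc(self) -> float:
        """Share of total variance due to the random intercepts."""
        tau00 = sum(vc["Sigma"][0, 0] for vc in self.vcomp)
        return tau00 / (tau00 + self.sigma2)


class _Workspace:
    """Precomputed cross-products; evaluates the profiled REML criterion."""

    def __init__(self, y, X, Z_parts, term_ks, n_levels):
        self.y = y
        self.X = X
        self.n, self.p = X.shape
        self.term_ks = term_ks          # effects per level, per term
        self.n_levels = n_levels        # levels per term
        self.Z = sp.hstack(Z_parts, format="csr") if Z_parts else None
        q = self.Z.shape[1]
        self.q = q
        Zd = self.Z
        self.ZtZ = (Zd.T @ Zd).toarray()
        self.ZtX = Zd.T @ X
        self.Zty = Zd.T @ y
        self.XtX = X.T @ X
        self.Xty = X.T @ y

    def lambda_full(self, theta: np.ndarray) -> np.ndarray:
        """Assemble the block-diagonal relative Cholesky factor."""
        blocks = []
        pos = 0
        for k, m in zip(self.term_ks, self.n_levels):
            nth = k * (k + 1) // 2
            Lt = np.zeros((k, k))
            Lt[np.tril_indices(k)] = theta[pos:pos + nth]
            pos += nth
            blocks.append(np.kron(np.eye(m), Lt))
        return sla.block_diag(*blocks)

    def decompose(self, theta: np.ndarray):
        Lam = self.lambda_full(theta)
        A = Lam.T @ self.ZtZ @ Lam + np.eye(self.q)
        L = sla.cholesky(A, lower=True)
        RZX = sla.solve_triangular(L, Lam.T @ self.ZtX, lower=True)
        RXtRX = self.XtX - RZX.T @ RZX
        LX = sla.cholesky(RXtRX, lower=True)
        cu = sla.solve_triangular(L, Lam.T @ self.Zty, lower=True)
        rhs = self.Xty - RZX.T @ cu
        beta = sla.cho_solve((LX, True), rhs)
        u = sla.solve_triangular(L.T, cu - RZX @ beta, lower=False)
        fitted_re = self.Z @ (Lam @ u)
        resid = self.y - self.X @ beta - fitted_re
        pwrss = resid @ resid + u @ u
        logdet_A = 2.0 * np.log(np.diag(L)).sum()
        logdet_RX = 2.0 * np.log(np.diag(LX)).sum()
        return {
            "Lam": Lam, "beta": beta, "u": u, "resid": resid,
            "fitted_re": fitted_re, "pwrss": pwrss,
            "logdet_A": logdet_A, "logdet_RX": logdet_RX, "RXtRX": RXtRX,
        }

    def profiled_criterion(self, theta: np.ndarray) -> float:
        """-2 restricted log-likelihood, beta and sigma^2 profiled out."""
        try:
            d = self.decompose(theta)
        except np.linalg.LinAlgError:
            return np.inf
        ndf = self.n - self.p
        return (
            d["logdet_A"] + d["logdet_RX"]
            + ndf * (1.0 + np.log(2.0 * np.pi * d["pwrss"] / ndf))
        )

    def criterion(self, theta: np.ndarray, sigma2: float) -> float:
        """-2 restricted log-likelihood at (theta, sigma^2), beta profiled."""
        d = self.decompose(theta)
        ndf = self.n - self.p
        return (
            self.n * np.log(sigma2) + d["logdet_A"] + d["logdet_RX"]
            - self.p * np.log(sigma2) + d["pwrss"] / sigma2
            + ndf * np.log(2.0 * np.pi)
        )

    def cov_beta(self, theta: np.ndarray, sigma2: float) -> np.ndarray:
        d = self.decompose(theta)
        return sigma2 * sla.inv(d["RXtRX"])


def _theta_layout(terms: list[RandomTermSpec]):
    """Start values, bounds, and diagonal-entry mask for theta."""
    start, lower, diag_mask = [], [], []
    for t in terms:
        k = t.k
        for col in range(k):
            for row in range(col, k):
                on_diag = row == col
                start.append(1.0 if on_diag else 0.0)
                lower.append(0.0 if on_diag else -np.inf)
                diag_mask.append(on_diag)
    return np.array(start), np.array(lower), np.array(diag_mask)


def _satterthwaite_df(ws: _Workspace, theta, sigma2, singular):
    """Per-coefficient denominator df from finite-difference derivatives."""
    p = ws.p
    phi = np.append(theta, np.log(sigma2))
    m = phi.size
    h = 1e-4 * np.maximum(np.abs(phi), 1.0)

    def crit(v):
        return ws.criterion(v[:-1], np.exp(v[-1]))

    # Hessian of the REML criterion (-2 logLik): cov(phi_hat) ~ 2 H^{-1}
    H = np.empty((m, m))
    f0 = crit(phi)
    for i in range(m):
        for j in range(i, m):
            ei = np.zeros(m); ei[i] = h[i]
            ej = np.zeros(m); ej[j] = h[j]
            if i == j:
                fpp = crit(phi + ei); fmm = crit(phi - ei)
                H[i, i] = (fpp - 2 * f0 + fmm) / h[i] ** 2
            else:
                fpp = crit(phi + ei + ej); fpm = crit(phi + ei - ej)
                fmp = crit(phi - ei + ej); fmm = crit(phi - ei - ej)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    try:
        cov_phi = 2.0 * sla.pinvh(H)
    except np.linalg.LinAlgError:
        return np.full(p, np.nan)

    def var_diag(v):
        return np.diag(ws.cov_beta(v[:-1], np.exp(v[-1])))

    grads = np.empty((m, p))
    for i in range(m):
        ei = np.zeros(m); ei[i] = h[i]
        grads[i] = (var_diag(phi + ei) - var_diag(phi - ei)) / (2 * h[i])
    f = var_diag(phi)
    var_f = np.einsum("ip,ij,jp->p", grads, cov_phi, grads)
    with np.errstate(divide="ignore", invalid="ignore"):
        df = 2.0 * f ** 2 / var_f
    ndf = ws.n - p
    bad = ~np.isfinite(df) | (df <= 0) | (df > ndf)
    if bad.any() and singular:
        log.debug("Satterthwaite df clamped for %d terms (boundary fit)", bad.sum())
    df[bad] = ndf
    return df


def fit_lmm(
    y,
    X: pd.DataFrame,
    data: pd.DataFrame,
    terms: list[RandomTermSpec],
    df_method: str = "satterthwaite",
) -> LMMResult:
    """Fit a Gaussian LMM by REML.

    Parameters
    ----------
    y : array-like (n,)
        Response.
    X : DataFrame (n, p)
        Fixed-effects design matrix (already contrast-coded), full rank.
    data : DataFrame
        Source of grouping-factor and slope columns named by ``terms``.
    terms : list of RandomTermSpec
        Random-effects structure; factors may be crossed.
    df_method : {"satterthwaite", "residual"}
        Denominator df for the coefficient t statistics.
    """
    if df_method not in ("satterthwaite", "residual"):
        raise ValueError(f"unknown df_method {df_method!r}")
    y = np.asarray(y, dtype=float)
    Xcols = list(X.columns)
    Xm = np.asarray(X, dtype=float)
    n, p = Xm.shape
    rank = np.linalg.matrix_rank(Xm)
    if rank < p:
        _, R = np.linalg.qr(Xm)
        aliased = [Xcols[i] for i in range(p) if abs(R[i, i]) < 1e-8 * abs(R[0, 0])]
        raise ValueError(f"fixed-effects design is rank deficient; aliased terms: {aliased}")

    Z_parts, term_ks, n_levels, level_maps = [], [], [], []
    for t in terms:
        codes, levels = pd.factorize(data[t.group], sort=True)
        m = len(levels)
        k = t.k
        cols = np.ones((n, k))
        for j, s in enumerate(t.slopes, start=1):
            cols[:, j] = np.asarray(data[s], dtype=float)
        rows = np.repeat(np.arange(n), k)
        col_idx = (codes[:, None] * k + np.arange(k)[None, :]).ravel()
        Z_parts.append(
            sp.csr_matrix((cols.ravel(), (rows, col_idx)), shape=(n, m * k))
        )
        term_ks.append(k)
        n_levels.append(m)
        level_maps.append(levels)

    ws = _Workspace(y, Xm, Z_parts, term_ks, n_levels)
    theta0, lower, diag_mask = _theta_layout(terms)
    bounds = [(lo, None) for lo in lower]
    res = scipy.optimize.minimize(
        ws.profiled_criterion, theta0, method="Powell", bounds=bounds,
        options={"xtol": _OPT_TOL, "ftol": _OPT_TOL, "maxiter": 10000},
    )
    theta = np.maximum(res.x, np.where(diag_mask, 0.0, -np.inf))
    dec = ws.decompose(theta)
    sigma2 = dec["pwrss"] / (n - p)
    beta = dec["beta"]
    cov = ws.cov_beta(theta, sigma2)
    se = np.sqrt(np.diag(cov))

    singular = bool(np.any(theta[diag_mask] < 1e-4))
    # correlations at the boundary also count as singular
    vcomp = []
    pos = 0
    for t, k, m, levels in zip(terms, term_ks, n_levels, level_maps):
        nth = k * (k + 1) // 2
        Lt = np.zeros((k, k))
        Lt[np.tril_indices(k)] = theta[pos:pos + nth]
        pos += nth
        Sigma = sigma2 * (Lt @ Lt.T)
        if k > 1:
            sd = np.sqrt(np.diag(Sigma))
            with np.errstate(divide="ignore", invalid="ignore"):
                corr = Sigma / np.outer(sd, sd)
            off = corr[np.tril_indices(k, -1)]
            if np.any(np.abs(off[np.isfinite(off)]) > 1 - 1e-4):
                singular = True
        vcomp.append({
            "group": t.group,
            "names": ("intercept",) + t.slopes,
            "Sigma": Sigma,
            "n_levels": m,
            "levels": levels,
        })
    if singular:
        warnings.warn(
            "REML estimate is singular (a variance or correlation at the "
            "boundary); estimates returned as-is",
            SingularFitWarning,
        )

    if df_method == "satterthwaite":
        df = _satterthwaite_df(ws, theta, sigma2, singular)
    else:
        df = np.full(p, float(n - p))
    tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)

    # Nakagawa-style variance partitioning for R^2
    fit_fixed = Xm @ beta
    var_f = float(np.var(fit_fixed))
    var_re = 0.0
    for t, vc in zip(terms, vcomp):
        k = t.k
        W = np.ones((n, k))
        for j, s in enumerate(t.slopes, start=1):
            W[:, j] = np.asarray(data[s], dtype=float)
        var_re += float(np.einsum("ij,jk,ik->i", W, vc["Sigma"], W).mean())
    total = var_f + var_re + sigma2
    n_theta = theta.size
    crit = ws.profiled_criterion(theta)
    aic = crit + 2.0 * (p + n_theta + 1)

    # BLUPs per term, on the original (not relative) scale
    b = dec["Lam"] @ dec["u"]
    ranef, pos = [], 0
    for k, m in zip(term_ks, n_levels):
        ranef.append(b[pos:pos + m * k].reshape(m, k))
        pos += m * k

    idx = pd.Index(Xcols, name="term")
    return LMMResult(
        terms=terms,
        params=pd.Series(beta, index=idx),
        se=pd.Series(se, index=idx),
        df=pd.Series(df, index=idx),
        tvalues=pd.Series(tvals, index=idx),
        pvalues=pd.Series(pvals, index=idx),
        sigma2=float(sigma2),
        vcomp=vcomp,
        n_obs=n,
        n_groups={t.group: m for t, m in zip(terms, n_levels)},
        reml_criterion=float(crit),
        aic=float(aic),
        r2_marginal=var_f / total,
        r2_conditional=(var_f + var_re) / total,
        converged=bool(res.success),
        singular=singular,
        df_method=df_method,
        resid=dec["resid"],
        fittedvalues=y - dec["resid"],
        ranef=ranef,
    )
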
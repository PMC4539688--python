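"""Quasi-negative-binomial GLM testing for differential interactions.

Counts for bin pair b in library i follow a quasi-NB model: NB-distributed
with abundance-dependent dispersion phi_b capturing biological variability
between replicates (sqrt(phi) is the biological coefficient of variation),
plus a bin-pair-specific quasi-likelihood dispersion sigma2_b scaling the
variance around the NB law:

    var(y_bi) = sigma2_b * (mu_bi + phi_b * mu_bi^2)
    log mu_bi = sum_j x_ij beta_bj + o_bi

The offsets o_bi absorb sequencing depth and normalization factors.
phi_b is estimated by maximizing a Cox-Reid adjusted profile likelihood
within abundance bins and smoothing across abundance; sigma2_b by an
empirical-Bayes procedure that squeezes per-bin-pair deviance-based
estimates towards an abundance trend, with the prior degrees of freedom
set by moment matching of the scaled-F spread.  Differences between
conditions are assessed with a quasi-likelihood F-test and corrected by
Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

LN2 = np.log(2.0)
_MIN_MU = 1e-10


def design_matrix(groups) -> tuple[np.ndarray, list[str]]:
    """Intercept + treatment one-hot design from group labels.

    The first level (in order of appearance) is the baseline; each later
    level gets an indicator column whose coefficient is the log-fold
    change of that group over the baseline.
    """
    levels = list(dict.fromkeys(groups))
    X = np.ones((len(groups), len(levels)))
    for j, lev in enumerate(levels[1:], start=1):
        X[:, j] = [1.0 if g == lev else 0.0 for g in groups]
    labels = ["intercept"] + [f"{lev}_vs_{levels[0]}" for lev in levels[1:]]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is not of full column rank")
    return X, labels


def _as_offsets(offsets, n, s) -> np.ndarray:
    o = np.asarray(offsets, dtype=float)
    if o.ndim < 2:
        o = np.broadcast_to(o, (n, s))
    return np.ascontiguousarray(o)


def nb_deviance(y: np.ndarray, mu: np.ndarray, phi) -> np.ndarray:
    """Per-bin-pair NB deviance (rows summed over libraries); Poisson at phi=0."""
    phi = np.broadcast_to(np.asarray(phi, dtype=float)[..., None], y.shape)
    mu = np.maximum(mu, _MIN_MU)
    with np.errstate(divide="ignore", invalid="ignore"):
        yl = np.where(y > 0, y * np.log(np.maximum(y, _MIN_MU) / mu), 0.0)
        small = phi < 1e-10
        pois = y - mu
        nb = np.where(small, 0.0,
                      (y + 1.0 / np.where(small, 1.0, phi))
                      * np.log((1.0 + phi * y) / (1.0 + phi * mu)))
        unit = 2.0 * (yl - np.where(small, pois, nb))
    return np.maximum(unit, 0.0).sum(axis=1)


def nb_loglik(y: np.ndarray, mu: np.ndarray, phi) -> np.ndarray:
    """Per-bin-pair NB log-likelihood (summed over libraries)."""
    phi = np.broadcast_to(np.asarray(phi, dtype=float)[..., None], y.shape)
    mu = np.maximum(mu, _MIN_MU)
    small = phi < 1e-10
    phin = np.where(small, 1.0, phi)
    r = 1.0 / phin
    nb = (special.gammaln(y + r) - special.gammaln(r) - special.gammaln(y + 1)
          + y * np.log(phin * mu / (1 + phin * mu)) - r * np.log1p(phin * mu))
    pois = y * np.log(mu) - mu - special.gammaln(y + 1)
    return np.where(small, pois, nb).sum(axis=1)


@dataclass
class GLMFit:
    """Per-bin-pair NB GLM fit sharing one design across bin pairs."""

    coef: np.ndarray        # (n, p)
    mu: np.ndarray          # (n, s) fitted means
    deviance: np.ndarray    # (n,)
    design: np.ndarray      # (s, p)
    offsets: np.ndarray     # (n, s), natural log
    dispersion: np.ndarray  # (n,) NB dispersion used
    counts: np.ndarray      # (n, s)
    converged: np.ndarray   # (n,) bool
    labels: list[str] = field(default_factory=list)

    @property
    def resid_df(self) -> int:
        return self.design.shape[0] - self.design.shape[1]


def fit_nb_glm(counts, design, offsets=0.0, dispersions=0.0, max_iter: int = 100,
               tol: float = 1e-8, labels: list[str] | None = None) -> GLMFit:
    """Fit one NB GLM with log link per bin pair (vectorized Fisher scoring).

    ``counts`` may be a CountMatrix or an (n, s) array; ``offsets`` are on
    the natural-log scale, scalar, per-library or per-observation;
    ``dispersions`` is the NB dispersion phi, scalar or per bin pair.
    Damped Fisher scoring (step halving when the deviance worsens) with a
    relative-deviance convergence tolerance.  Non-converged bin pairs are
    flagged and the last iterate returned.
    """
    from hicdelta.interaction_counts import CountMatrix

    if isinstance(counts, CountMatrix):
        counts = counts.counts
    y = np.asarray(counts, dtype=float)
    X = np.asarray(design, dtype=float)
    n, s = y.shape
    p = X.shape[1]
    o = _as_offsets(offsets, n, s)
    phi = np.broadcast_to(np.asarray(dispersions, dtype=float), (n,)).copy()

    # working-response least-squares start
    z = np.log(y + 0.5) - o
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ z.T).T

    mu = np.maximum(np.exp(beta @ X.T + o), _MIN_MU)
    dev = nb_deviance(y, mu, phi)
    active = np.ones(n, dtype=bool)
    converged = np.zeros(n, dtype=bool)

    for _ in range(max_iter):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        mu_a, y_a, phi_a = mu[idx], y[idx], phi[idx]
        w = mu_a / (1.0 + phi_a[:, None] * mu_a)             # Fisher weights
        score = ((y_a - mu_a) / (1.0 + phi_a[:, None] * mu_a)) @ X
        info = np.einsum("ns,sp,sq->npq", w, X, X)
        info[:, np.arange(p), np.arange(p)] += 1e-8 * (1.0 + info[:, np.arange(p), np.arange(p)])
        step = np.linalg.solve(info, score[..., None])[..., 0]

        # step halving for bin pairs whose deviance worsens
        factor = np.ones(len(idx))
        new_beta = beta[idx] + step
        for _half in range(15):
            mu_new = np.maximum(np.exp(new_beta @ X.T + o[idx]), _MIN_MU)
            dev_new = nb_deviance(y_a, mu_new, phi_a)
            worse = dev_new > dev[idx] * (1 + 1e-12) + 1e-12
            if not worse.any():
                break
            factor[worse] *= 0.5
            new_beta[worse] = beta[idx][worse] + factor[worse, None] * step[worse]
        beta[idx] = new_beta
        mu[idx] = mu_new
        rel = np.abs(dev[idx] - dev_new) / (np.abs(dev[idx]) + 0.1)
        dev[idx] = dev_new
        done = rel < tol
        converged[idx[done]] = True
        active[idx[done]] = False

    return GLMFit(coef=beta, mu=mu, deviance=dev, design=X, offsets=o,
                  dispersion=phi, counts=y, converged=converged | ~active,
                  labels=labels or [f"b{j}" for j in range(p)])


def _cox_reid_adjustment(mu: np.ndarray, phi: np.ndarray, X: np.ndarray) -> np.ndarray:
    """0.5*logdet of the Fisher information, per bin pair."""
    w = mu / (1.0 + phi[:, None] * mu)
    info = np.einsum("ns,sp,sq->npq", w, X, X)
    sign, logdet = np.linalg.slogdet(info + 1e-12 * np.eye(X.shape[1]))
    return 0.5 * logdet


@dataclass
class DispersionFit:
    """Abundance-dependent NB dispersion trend."""

    abundance: np.ndarray      # per bin pair
    trended: np.ndarray        # phi_b per bin pair
    bin_abundance: np.ndarray  # knots: mean abundance of each estimation bin
    bin_phi: np.ndarray        # knots: APL-maximizing phi per bin

    @property
    def bcv(self) -> np.ndarray:
        return np.sqrt(self.trended)

    def at(self, abundance) -> np.ndarray:
        """Evaluate the smoothed trend at arbitrary abundances (clamped)."""
        return np.interp(abundance, self._knots_x, self._knots_y)


def estimate_dispersion_trend(counts, design, offsets=0.0, abundance=None,
                              n_abundance_bins: int = 20,
                              grid: np.ndarray | None = None,
                              span: float = 0.5) -> DispersionFit:
    """Trended NB dispersion by binned Cox-Reid adjusted profile likelihood.

    For each candidate phi on a log-spaced grid, all GLMs are refitted and
    the adjusted profile log-likelihood (NB log-likelihood minus half the
    log-determinant of the Fisher information, which accounts for the
    coefficients being estimated) is accumulated within abundance bins.
    Each bin's maximizing phi (with quadratic interpolation between grid
    points) is then smoothed against abundance by lowess and evaluated per
    bin pair.  Requires replication: residual df must be >= 1.
    """
    from hicdelta.interaction_counts import CountMatrix, average_abundance

    if isinstance(counts, CountMatrix):
        if abundance is None:
            abundance = average_abundance(counts)
        counts = counts.counts
    y = np.asarray(counts, dtype=float)
    X = np.asarray(design, dtype=float)
    n, s = y.shape
    if s - X.shape[1] < 1:
        raise ValueError("no residual degrees of freedom: replication is required to estimate dispersion")
    if abundance is None:
        abundance = np.log2(y.mean(axis=1) + 0.5)
    abundance = np.asarray(abundance, dtype=float)
    if grid is None:
        grid = np.concatenate(([1e-6], np.logspace(-4, np.log10(5.0), 24)))

    # equal-occupancy abundance bins (rank-based, so none is empty)
    n_bins = max(1, min(n_abundance_bins, n // 50))
    ranks = np.argsort(np.argsort(abundance, kind="stable"), kind="stable")
    bin_of = (ranks * n_bins) // n

    apl = np.empty((len(grid), n))
    for g, phi in enumerate(grid):
        fit = fit_nb_glm(y, X, offsets, phi)
        apl[g] = nb_loglik(y, fit.mu, fit.dispersion) - _cox_reid_adjustment(fit.mu, fit.dispersion, X)

    logphi = np.log(grid)
    bin_phi = np.empty(n_bins)
    bin_ab = np.empty(n_bins)
    for b in range(n_bins):
        members = bin_of == b
        bin_ab[b] = abundance[members].mean()
        total = apl[:, members].sum(axis=1)
        k = int(np.argmax(total))
        if 0 < k < len(grid) - 1:
            # quadratic interpolation on log(phi)
            x0, x1, x2 = logphi[k - 1: k + 2]
            y0, y1, y2 = total[k - 1: k + 2]
            denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
            a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
            bcoef = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
            xopt = -bcoef / (2 * a) if a < 0 else logphi[k]
            bin_phi[b] = float(np.exp(np.clip(xopt, logphi[k - 1], logphi[k + 1])))
        else:
            bin_phi[b] = float(grid[k])

    order = np.argsort(bin_ab)
    if n_bins >= 4:
        sm = lowess(np.log(bin_phi[order]), bin_ab[order], frac=span, return_sorted=True)
        knots_x, knots_y = sm[:, 0], np.exp(sm[:, 1])
    else:
        knots_x, knots_y = bin_ab[order], bin_phi[order]
    trended = np.interp(abundance, knots_x, knots_y)
    fitobj = DispersionFit(abundance=abundance, trended=trended,
                           bin_abundance=bin_ab[order], bin_phi=bin_phi[order])
    fitobj._knots_x, fitobj._knots_y = knots_x, knots_y
    return fitobj


@dataclass
class QLFit:
    """Per-bin-pair quasi-likelihood dispersions with EB moderation."""

    raw: np.ndarray        # deviance / residual df
    trend: np.ndarray      # abundance trend of sigma2
    squeezed: np.ndarray   # posterior sigma2
    prior_df: float
    resid_df: int

    @property
    def total_df(self) -> float:
        return self.resid_df + self.prior_df


def _winsorized_logf_moments(df: int, d0: float, winsor: tuple[float, float],
                             grid: int = 4000) -> tuple[float, float]:
    """Mean and variance of the winsorized, centred log of an F(df, d0) draw.

    Computed by quadrature on the probability scale; ``d0 = inf`` uses the
    chi-squared limit.  Winsorization clips at the same quantile levels
    applied to the data, so observed and theoretical moments are
    commensurable.
    """
    u = (np.arange(grid) + 0.5) / grid
    if np.isinf(d0):
        lf = np.log(stats.chi2.ppf(u, df) / df)
    else:
        lf = np.log(stats.f.ppf(u, df, d0))
    r = lf - lf.mean()
    lo = r[int(np.floor(winsor[0] * grid))]
    hi = r[min(grid - 1, int(np.ceil((1.0 - winsor[1]) * grid)))]
    rw = np.clip(r, lo, hi)
    return float(rw.mean()), float(rw.var())


def _match_prior_df(observed_var: float, df: int, winsor: tuple[float, float] | None) -> float:
    """Prior df whose theoretical (winsorized) log-F spread matches the data.

    The spread of log raw dispersions around their trend decreases as the
    prior df grows; bisection on log d0 inverts that relationship.  If the
    observed spread does not exceed the pure-chi-squared limit (d0 = inf),
    the prior is infinite.
    """
    w = winsor or (0.0, 0.0)
    _, v_inf = _winsorized_logf_moments(df, np.inf, w)
    if observed_var <= v_inf * (1 + 1e-6):
        return np.inf
    lo, hi = np.log(0.05), np.log(1e7)
    _, v_lo = _winsorized_logf_moments(df, np.exp(lo), w)
    if observed_var >= v_lo:
        return float(np.exp(lo))
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        _, v_mid = _winsorized_logf_moments(df, np.exp(mid), w)
        if v_mid > observed_var:
            lo = mid
        else:
            hi = mid
    return float(np.exp(0.5 * (lo + hi)))


def ql_dispersions(glmfit: GLMFit, abundance: np.ndarray, robust: bool = True,
                   span: float = 0.4, winsor: tuple[float, float] = (0.05, 0.1)) -> QLFit:
    """Estimate and squeeze QL dispersions via empirical Bayes.

    Raw sigma2_b = deviance / residual df at the trended NB dispersion.
    Under the model the raw values are distributed as trend * F(df, d0)
    around their abundance trend; the trend is a plain (non-robust) local
    mean of log raw values with the log-F mean bias removed, and the prior
    df d0 is found by matching the observed spread of the log residuals to
    the theoretical log-F spread.  Each raw value is then squeezed towards
    the trend with weight d0/(d0 + df).  Robust mode winsorizes the
    residuals and matches winsorized moments (correcting both mean and
    variance with the corresponding theoretical winsorized moments), so
    dispersion outliers do not inflate d0 and deflate everyone's error
    bars.
    """
    df = glmfit.resid_df
    if df < 1:
        raise ValueError("no residual degrees of freedom for QL dispersion estimation")
    abundance = np.asarray(abundance, dtype=float)
    raw = glmfit.deviance / df

    # floor exact-zero deviances (ties across libraries) for the log scale
    positive = raw[raw > 0]
    floor = 1e-3 * np.median(positive) if positive.size else 1e-8
    e = np.log(np.maximum(raw, floor)) - special.digamma(df / 2.0) + np.log(df / 2.0)

    wins = winsor if robust else None
    if robust:
        lo_q, hi_q = np.quantile(e, [winsor[0], 1.0 - winsor[1]])
        e_fit = np.clip(e, lo_q, hi_q)
    else:
        e_fit = e
    if len(e) >= 10 and np.ptp(abundance) > 0:
        sm = lowess(e_fit, abundance, frac=span, it=0, return_sorted=True,
                    delta=0.01 * np.ptp(abundance))
        etrend_w = np.interp(abundance, sm[:, 0], sm[:, 1])
    else:
        etrend_w = np.full_like(e, e_fit.mean())
    resid = e_fit - etrend_w
    evar = float(np.var(resid, ddof=1)) if len(resid) > 1 else 0.0
    d0 = _match_prior_df(evar, df, wins)

    # remove the winsorization bias of the local mean at the fitted d0
    m_w, _ = _winsorized_logf_moments(df, d0 if np.isfinite(d0) else np.inf, wins or (0.0, 0.0))
    etrend = etrend_w - m_w
    if np.isfinite(d0):
        trend = np.exp(etrend + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
        squeezed = (d0 * trend + df * raw) / (d0 + df)
    else:
        trend = np.exp(etrend)
        squeezed = trend.copy()
    return QLFit(raw=raw, trend=trend, squeezed=squeezed, prior_df=d0, resid_df=df)


def _null_design(X: np.ndarray, contrast: np.ndarray) -> np.ndarray:
    """Design spanning the subspace where contrast'beta = 0."""
    c = np.atleast_2d(np.asarray(contrast, dtype=float))
    _, _, vh = np.linalg.svd(c)
    null_basis = vh[np.linalg.matrix_rank(c):].T
    return X @ null_basis


@dataclass
class TestResult:
    """Per-bin-pair differential-interaction test."""

    table: pd.DataFrame  # logFC, F, pvalue, fdr

    def __getitem__(self, col):
        return self.table[col].to_numpy()


def ql_f_test(glmfit: GLMFit, qlfit: QLFit, contrast) -> TestResult:
    """Quasi-likelihood F-test of a contrast, per bin pair.

    F = (deviance drop under the null / contrast df) / squeezed sigma2,
    referred to an F distribution on (contrast df, residual df + prior df).
    The prior df earned by EB moderation buys denominator df, which is what
    makes the test usable with as few as two replicates per group.
    """
    X = glmfit.design
    c = np.atleast_2d(np.asarray(contrast, dtype=float))
    if c.shape[1] != X.shape[1]:
        raise ValueError("contrast length does not match the number of design columns")
    q = np.linalg.matrix_rank(c)
    Xn = _null_design(X, c)
    null_fit = fit_nb_glm(glmfit.counts, Xn, glmfit.offsets, glmfit.dispersion)
    drop = np.maximum(null_fit.deviance - glmfit.deviance, 0.0)
    denom = np.maximum(qlfit.squeezed, 1e-10)
    F = drop / q / denom
    df2 = qlfit.total_df
    if np.isinf(df2):
        pvals = stats.chi2.sf(F * q, q)
    else:
        pvals = stats.f.sf(F, q, df2)
    logfc = (glmfit.coef @ c[0]) / LN2 if q == 1 else np.full(len(F), np.nan)
    table = pd.DataFrame({
        "logFC": logfc,
        "F": F,
        "pvalue": np.clip(pvals, 0.0, 1.0),
    })
    table["fdr"] = bh_adjust(table["pvalue"].to_numpy())
    return TestResult(table=table)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
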
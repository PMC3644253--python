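"""Shared statistical machinery.

This module hosts the numerical core used by the higher-level analysis
modules:

* a balanced-ANOVA engine that computes sums of squares for arbitrary
  crossed/nested factorial terms, derives expected-mean-square (EMS)
  coefficients by the containment rule, and solves for variance components
  (the method-of-moments solution, which coincides with REML on balanced
  designs with interior estimates);
* a dense restricted-maximum-likelihood (REML) fitter for small mixed
  models, used both as the primary estimator on unbalanced data and as the
  cross-check for the EMS path;
* synthesized (Satterthwaite) F tests for variance components;
* Benjamini-Hochberg step-up q-values;
* vectorized one-way ANOVA scans over many genotype columns at once.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve


@dataclass(frozen=True)
class Term:
    """One model term: a name, the factor columns it groups by, random flag.

    Nesting is expressed through the column set: a line factor nested in
    block carries both the block and the line columns, so containment of
    terms reduces to subset inclusion of their column sets.
    """

    name: str
    cols: tuple[str, ...]
    random: bool = True

    @property
    def colset(self) -> frozenset:
        return frozenset(self.cols)


@dataclass
class AnovaTable:
    """Result of a balanced-ANOVA decomposition."""

    terms: list
    ss: dict
    df: dict
    ms: dict
    components: dict          # raw (possibly negative) estimates, incl. "residual"
    pvalues: dict             # synthesized-F p per random term
    n_obs: int
    grand_mean: float

    def component(self, name: str, truncate: bool = True) -> float:
        v = self.components[name]
        if truncate and np.isfinite(v):
            return max(v, 0.0)
        return v


class UnbalancedDesignError(ValueError):
    pass


class SingularDesignError(ValueError):
    pass


def _check_design(df: pd.DataFrame, terms) -> None:
    all_cols = sorted({c for t in terms for c in t.cols})
    for t in terms:
        n_levels = df.groupby(list(t.cols), observed=True).ngroups
        if n_levels < 2:
            raise SingularDesignError(
                f"term {t.name!r} has a single level; design is singular"
            )
    counts = df.groupby(all_cols, observed=True).size()
    if counts.nunique() > 1:
        raise UnbalancedDesignError(
            "cell counts are unequal; the EMS decomposition requires a "
            "balanced design (use the REML fitter instead)"
        )


def balanced_anova(df: pd.DataFrame, response: str, terms,
                   check: bool = True) -> AnovaTable:
    """Balanced factorial ANOVA with EMS-based variance components.

    Sums of squares use the classical marginal-means recursion
    ``SS(T) = U(T) - CF - sum(SS(S) for S strictly contained in T)`` with
    ``U(G) = sum_g n_g * mean_g**2``.  EMS coefficients follow the
    unrestricted-model containment rule: component C appears in E[MS(T)]
    with coefficient N / #levels(C) whenever cols(T) is a subset of
    cols(C); the residual appears everywhere with coefficient 1.
    """
    if check:
        _check_design(df, terms)
    y = df[response].to_numpy(dtype=float)
    n = y.size
    grand = float(y.mean())
    cf = n * grand * grand
    total_ss = float(y @ y) - cf

    u_val: dict = {}
    n_groups: dict = {}
    for t in terms:
        g = df.groupby(list(t.cols), observed=True)[response]
        cnt = g.size().to_numpy(dtype=float)
        mean = g.mean().to_numpy(dtype=float)
        u_val[t.name] = float(cnt @ (mean * mean))
        n_groups[t.name] = cnt.size

    order = sorted(terms, key=lambda t: len(t.cols))
    ss: dict = {}
    dof: dict = {}
    for t in order:
        inner = [s for s in order if s.name != t.name and s.colset < t.colset]
        ss[t.name] = u_val[t.name] - cf - sum(ss[s.name] for s in inner)
        dof[t.name] = n_groups[t.name] - 1 - sum(dof[s.name] for s in inner)

    ss_res = total_ss - sum(ss.values())
    df_res = n - 1 - sum(dof.values())
    # numerical guard: tiny negative SS from cancellation
    ss = {k: (0.0 if -1e-8 < v < 0 else v) for k, v in ss.items()}
    ss_res = 0.0 if -1e-8 < ss_res < 0 else ss_res

    ms = {k: (ss[k] / dof[k] if dof[k] > 0 else np.nan) for k in ss}
    ms_res = ss_res / df_res if df_res > 0 else np.nan

    random_terms = [t for t in order if t.random]
    names = [t.name for t in random_terms] + ["residual"]
    k = len(names)
    A = np.zeros((k, k))
    for i, ti in enumerate(random_terms):
        for j, tj in enumerate(random_terms):
            if ti.colset <= tj.colset:
                A[i, j] = n / n_groups[tj.name]
        A[i, -1] = 1.0
    A[-1, -1] = 1.0
    b = np.array([ms[t.name] for t in random_terms] + [ms_res])

    components: dict = {}
    if np.all(np.isfinite(b)):
        est, *_ = np.linalg.lstsq(A, b, rcond=None)
        for name, v in zip(names, est):
            components[name] = float(v)
    else:
        for name in names:
            components[name] = np.nan

    pvalues = _synthesized_f_tests(names, A, b, dof, df_res, random_terms)
    ss["residual"] = ss_res
    dof["residual"] = df_res
    ms["residual"] = ms_res
    return AnovaTable(terms=list(terms), ss=ss, df=dof, ms=ms,
                      components=components, pvalues=pvalues,
                      n_obs=n, grand_mean=grand)


def _synthesized_f_tests(names, A, b, dof, df_res, random_terms) -> dict:
    """Quasi-F test of each variance component against zero.

    For component i the denominator is a linear combination of the other
    mean squares whose expectation matches E[MS_i] under H0 (its own
    coefficient zeroed); negative-weight mean squares move to the numerator
    side, and both sides get Satterthwaite degrees of freedom.
    """
    k = len(names)
    ms_vec = b
    df_vec = np.array([dof[t.name] for t in random_terms] + [df_res], float)
    pvalues: dict = {}
    for i in range(k - 1):  # residual not tested
        name = names[i]
        if not np.all(np.isfinite(ms_vec)) or df_vec[i] <= 0:
            pvalues[name] = np.nan
            continue
        target = A[i].copy()
        target[i] = 0.0
        rows = [j for j in range(k) if j != i]
        M = A[rows]  # (k-1, k)
        w, _, _, _ = np.linalg.lstsq(M.T, target, rcond=None)
        if not np.allclose(M.T @ w, target, atol=1e-8):
            # no exact synthesis available; fall back to residual MS
            w = np.zeros(k - 1)
            w[-1] = 1.0
        num_parts = [(1.0, ms_vec[i], df_vec[i])]
        den_parts = []
        for wj, j in zip(w, rows):
            if abs(wj) < 1e-12:
                continue
            part = (abs(wj), ms_vec[j], df_vec[j])
            (den_parts if wj > 0 else num_parts).append(part)
        num = sum(c * m for c, m, _ in num_parts)
        den = sum(c * m for c, m, _ in den_parts)
        if den <= 0 or not den_parts:
            pvalues[name] = np.nan if num <= 0 else 0.0
            continue
        if num <= 0:
            pvalues[name] = 1.0
            continue
        df_num = _satterthwaite(num_parts)
        df_den = _satterthwaite(den_parts)
        fstat = num / den
        pvalues[name] = float(stats.f.sf(fstat, df_num, df_den))
    return pvalues


def _satterthwaite(parts) -> float:
    total = sum(c * m for c, m, _ in parts)
    denom = sum((c * m) ** 2 / d for c, m, d in parts if d > 0)
    if denom <= 0:
        return 1.0
    return max(total * total / denom, 1.0)


# ---------------------------------------------------------------------------
# dense REML


def design_matrices(df: pd.DataFrame, terms):
    """Indicator matrices Z (one per random term) and fixed-effect X."""
    zs = []
    x_cols = [np.ones((len(df), 1))]
    for t in sorted(terms, key=lambda t: len(t.cols)):
        codes = pd.Categorical(
            df[list(t.cols)].astype(str).agg("|".join, axis=1)
        ).codes
        z = np.zeros((len(df), codes.max() + 1))
        z[np.arange(len(df)), codes] = 1.0
        if t.random:
            zs.append(z)
        else:
            x_cols.append(z[:, 1:])  # drop one level: reference coding
    X = np.hstack(x_cols)
    return X, zs


def reml_fit(y: np.ndarray, X: np.ndarray, zs, start=None,
             maxiter: int = 500):
    """REML estimation of variance components for y ~ X beta + sum Z_i u_i + e.

    Returns ``(sigma2, loglik)`` where ``sigma2`` has one entry per Z plus
    the residual last.  Optimization is on log-variances with analytic
    gradients; suitable for the small tables this package fits directly.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n = y.size
    k = len(zs)
    gs = [np.asarray(z, float) @ np.asarray(z, float).T for z in zs]
    gs.append(np.eye(n))
    vy = float(np.var(y)) or 1.0
    if start is None:
        start = np.full(k + 1, vy / (k + 1))
    start = np.clip(np.asarray(start, float), vy * 1e-6, None)

    def negll_and_grad(logth):
        th = np.exp(logth)
        V = th[-1] * np.eye(n)
        for i in range(k):
            V += th[i] * gs[i]
        try:
            c = cho_factor(V, lower=True)
        except np.linalg.LinAlgError:
            return 1e10, np.zeros_like(logth)
        logdet_v = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
        vi_y = cho_solve(c, y)
        vi_x = cho_solve(c, X)
        xtvx = X.T @ vi_x
        cx = cho_factor(xtvx, lower=True)
        logdet_x = 2.0 * float(np.sum(np.log(np.diag(cx[0]))))
        beta = cho_solve(cx, X.T @ vi_y)
        py = vi_y - vi_x @ beta
        nll = 0.5 * (logdet_v + logdet_x + float(y @ py))
        grad = np.empty(k + 1)
        for i, g in enumerate(gs):
            vig = cho_solve(c, g)
            tr1 = float(np.trace(vig))
            m = vi_x.T @ (g @ vi_x)
            tr2 = float(np.trace(cho_solve(cx, m)))
            quad = float(py @ (g @ py))
            grad[i] = 0.5 * (tr1 - tr2 - quad) * th[i]
        return nll, grad

    res = optimize.minimize(
        negll_and_grad, np.log(start), jac=True, method="L-BFGS-B",
        bounds=[(np.log(vy) - 40.0, np.log(vy) + 40.0)] * (k + 1),
        options={"maxiter": maxiter, "ftol": 1e-15, "gtol": 1e-12},
    )
    sigma2 = np.exp(res.x)
    return sigma2, -res.fun


def reml_loglik(y, X, zs, sigma2) -> float:
    """REML log-likelihood at fixed variance components (constant dropped)."""
    y = np.asarray(y, float)
    n = y.size
    V = sigma2[-1] * np.eye(n)
    for i, z in enumerate(zs):
        zz = np.asarray(z, float)
        V += sigma2[i] * (zz @ zz.T)
    c = cho_factor(V, lower=True)
    logdet_v = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
    vi_y = cho_solve(c, y)
    vi_x = cho_solve(c, X)
    xtvx = X.T @ vi_x
    cx = cho_factor(xtvx, lower=True)
    logdet_x = 2.0 * float(np.sum(np.log(np.diag(cx[0]))))
    beta = cho_solve(cx, X.T @ vi_y)
    py = vi_y - vi_x @ beta
    return -0.5 * (logdet_v + logdet_x + float(y @ py))


def reml_lrt_pvalue(ll_full: float, ll_reduced: float) -> float:
    """Boundary-corrected LRT p for H0: one variance component equals zero.

    Uses the 0.5*(chi2_0 + chi2_1) mixture reference distribution.
    """
    stat = 2.0 * (ll_full - ll_reduced)
    if stat <= 0:
        return 1.0
    return float(0.5 * stats.chi2.sf(stat, 1))


# ---------------------------------------------------------------------------
# BH FDR


def bh_qvalues(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, clipped to [0, 1])."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


# ---------------------------------------------------------------------------
# vectorized one-way ANOVA scans


def oneway_scan(y: np.ndarray, genotypes: np.ndarray) -> dict:
    """One-way ANOVA of ``y`` across the two genotype classes of each site.

    Parameters
    ----------
    y : (L,) response per line
    genotypes : (S, L) or (L,) array coded 0/1 with -1 for missing;
        missing entries are dropped per site (complete-case).

    Returns a dict of per-site arrays: F, p, df_between, df_within,
    mean0, mean1, n0, n1, ss_between, ss_within.
    """
    y = np.asarray(y, dtype=float)
    g = np.atleast_2d(np.asarray(genotypes))
    is1 = (g == 1)
    is0 = (g == 0)
    n1 = is1.sum(axis=1).astype(float)
    n0 = is0.sum(axis=1).astype(float)
    n = n0 + n1
    y2 = y * y
    s1 = is1 @ y
    s0 = is0 @ y
    q1 = is1 @ y2
    q0 = is0 @ y2
    with np.errstate(divide="ignore", invalid="ignore"):
        m1 = np.where(n1 > 0, s1 / np.maximum(n1, 1), np.nan)
        m0 = np.where(n0 > 0, s0 / np.maximum(n0, 1), np.nan)
        grand = (s0 + s1) / n
    ssw = (q0 - n0 * np.nan_to_num(m0) ** 2) + (q1 - n1 * np.nan_to_num(m1) ** 2)
    ssb = (n0 * (np.nan_to_num(m0) - grand) ** 2
           + n1 * (np.nan_to_num(m1) - grand) ** 2)
    ssw = np.maximum(ssw, 0.0)
    ssb = np.maximum(ssb, 0.0)
    dfw = n - 2
    mono = (n0 < 1) | (n1 < 1) | (dfw < 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fstat = np.where(ssw > 0, ssb / np.where(ssw > 0, ssw / np.maximum(dfw, 1), 1.0),
                         np.where(ssb > 0, np.inf, 0.0))
    p = np.where(np.isinf(fstat), 0.0, stats.f.sf(np.nan_to_num(fstat), 1, np.maximum(dfw, 1)))
    p = np.where((ssb <= 0) | mono, 1.0, p)
    fstat = np.where(mono, 0.0, fstat)
    return {
        "F": fstat, "p": p, "df_between": np.ones_like(n), "df_within": dfw,
        "mean0": m0, "mean1": m1, "n0": n0, "n1": n1,
        "ss_between": ssb, "ss_within": ssw,
    }
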
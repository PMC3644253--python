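"""Iterative additive multi-SNP modelling by forward selection.

At each step the candidate with the smallest partial-F p-value given the
sites already in the model is added (ties broken by genomic order).  Raw
R^2 is monotone in additions, so the default stop rule is the first step
at which adjusted R^2 would decrease; a partial-F p-value stop is exposed
as an alternative.  The fraction of genetic variance explained divides
the final adjusted R^2 by the trait's broad-sense heritability.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class MultiSNPModel:
    trait: str
    sex: str
    sites: list
    steps: pd.DataFrame         # step, site_id, partial_p, r2, adj_r2
    r2: float
    adj_r2: float
    fraction_vg: float = np.nan

    def __post_init__(self):
        if len(set(self.sites)) != len(self.sites):
            raise ValueError("selected sites must be distinct")


def forward_select(line_means, genotypes, site_ids=None,
                   stop_rule: str = "adjusted-r2", alpha_stop: float = 0.05,
                   max_steps=None, trait: str = "", sex: str = "") -> MultiSNPModel:
    """Forward-selection additive model on per-sex line means.

    Parameters
    ----------
    line_means : (L,) response vector
    genotypes : (S, L) candidate matrix coded 0/1 (-1 excludes the site)
    stop_rule : "adjusted-r2" (default) or "partial-f"
    """
    if stop_rule not in ("adjusted-r2", "partial-f"):
        raise ValueError("stop_rule must be 'adjusted-r2' or 'partial-f'")
    y = np.asarray(line_means, dtype=float)
    g = np.atleast_2d(np.asarray(genotypes, dtype=float))
    n = y.size
    n_sites = g.shape[0]
    if site_ids is None:
        site_ids = [f"site{j}" for j in range(n_sites)]
    usable = ~np.any(g < 0, axis=1)
    if max_steps is None:
        max_steps = n - 3

    empty = pd.DataFrame(columns=["step", "site_id", "partial_p", "r2", "adj_r2"])
    if not usable.any() or n < 3:
        return MultiSNPModel(trait=trait, sex=sex, sites=[], steps=empty,
                             r2=0.0, adj_r2=0.0)

    resid_c = g.T.copy()                      # (L, S) candidate residuals
    resid_c -= resid_c.mean(axis=0)           # project out the intercept
    e = y - y.mean()
    tss = float(e @ e)
    if tss <= 0:
        return MultiSNPModel(trait=trait, sex=sex, sites=[], steps=empty,
                             r2=0.0, adj_r2=0.0)
    rss = tss
    available = usable.copy()
    selected: list = []
    records = []
    adj_prev = 0.0

    while len(selected) < max_steps:
        p_params = 1 + len(selected) + 1      # intercept + chosen + candidate
        df_resid = n - p_params
        if df_resid < 1:
            break
        norms = np.einsum("ij,ij->j", resid_c, resid_c)
        proj = resid_c.T @ e
        with np.errstate(divide="ignore", invalid="ignore"):
            delta = np.where(norms > 1e-10 * n, proj * proj / norms, 0.0)
        delta[~available] = 0.0
        if not np.any(delta > 1e-12 * tss):
            break
        best_delta = delta.max()
        ties = np.flatnonzero(delta >= best_delta * (1 - 1e-12))
        j = int(ties.min())                   # genomic order breaks ties
        rss_new = rss - delta[j]
        fstat = delta[j] / (rss_new / df_resid) if rss_new > 0 else np.inf
        partial_p = float(stats.f.sf(fstat, 1, df_resid)) if np.isfinite(fstat) else 0.0
        r2 = 1.0 - rss_new / tss
        adj = 1.0 - (1.0 - r2) * (n - 1) / df_resid

        if stop_rule == "adjusted-r2" and adj < adj_prev:
            break
        if stop_rule == "partial-f" and partial_p > alpha_stop:
            break

        # accept: orthogonalize remaining candidates against the new column
        qcol = resid_c[:, j] / np.sqrt(norms[j])
        resid_c -= np.outer(qcol, qcol @ resid_c)
        e = e - qcol * (qcol @ e)
        rss = rss_new
        available[j] = False
        selected.append(j)
        adj_prev = adj
        records.append({"step": len(selected), "site_id": site_ids[j],
                        "partial_p": partial_p, "r2": r2, "adj_r2": adj})

    steps = pd.DataFrame(records) if records else empty
    r2_final = float(records[-1]["r2"]) if records else 0.0
    adj_final = float(records[-1]["adj_r2"]) if records else 0.0
    return MultiSNPModel(trait=trait, sex=sex,
                         sites=[site_ids[j] for j in selected],
                         steps=steps, r2=r2_final, adj_r2=adj_final)


def refit_r2(line_means, genotypes, selected_sites, site_ids) -> float:
    """R^2 of an OLS refit on exactly the selected sites (sanity check)."""
    y = np.asarray(line_means, dtype=float)
    idx = [list(site_ids).index(s) for s in selected_sites]
    if not idx:
        return 0.0
    X = np.column_stack([np.ones(y.size)]
                        + [np.asarray(genotypes, float)[j] for j in idx])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    tss = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - float(resid @ resid) / tss if tss > 0 else 0.0


def genetic_variance_explained(adj_r2: float, h2: float) -> float:
    """Fraction of genetic variance explained: adj R^2 / H^2, capped at 1.

    Undefined (NaN) when H^2 is not positive.
    """
    if not np.isfinite(h2) or h2 <= 0:
        logger.warning("H^2 not positive; fraction of V_G undefined")
        return np.nan
    frac = adj_r2 / h2
    if frac > 1.0:
        logger.warning("adj R^2 exceeds H^2 (%.3f > %.3f); capping at 1",
                       adj_r2, h2)
        return 1.0
    return float(frac)
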
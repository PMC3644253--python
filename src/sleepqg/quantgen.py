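"""Variance partitioning and quantitative-genetic summaries.

The observational model for a trait measured on individual flies is

    Y = mu + B + S + L(B) + S*L(B) + R(B) + S*R(B) + R*L(B) + S*R*L(B) + e

with sex fixed and every block/line/replicate term random.  Reduced models
drop sex and its interactions (per-sex fits) or the replicate-by-line
strata (CV_E tables, whose unit of observation is the line/sex/replicate
cell).  On balanced designs components come from the expected-mean-square
decomposition, which coincides with REML at interior estimates; a dense
REML fitter handles small or unbalanced tables and powers the
likelihood-ratio component tests.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import (AnovaTable, SingularDesignError, Term,
                     UnbalancedDesignError, balanced_anova, design_matrices,
                     oneway_scan, reml_fit, reml_loglik, reml_lrt_pvalue)

GENETIC_COMPONENTS = ("line", "sex_line")

_TERMS = {
    ("mean", "pooled"): [
        Term("block", ("block",)),
        Term("sex", ("sex",), random=False),
        # closes the containment lattice (sex x block subspace); absorbed
        # into S x L(B) when omitted, which biases the EMS solution
        Term("sex_block", ("sex", "block")),
        Term("line", ("block", "line")),
        Term("sex_line", ("sex", "block", "line")),
        Term("rep", ("block", "replicate")),
        Term("sex_rep", ("sex", "block", "replicate")),
        Term("rep_line", ("block", "replicate", "line")),
        Term("sex_rep_line", ("sex", "block", "replicate", "line")),
    ],
    ("mean", "per-sex"): [
        Term("block", ("block",)),
        Term("line", ("block", "line")),
        Term("rep", ("block", "replicate")),
        Term("rep_line", ("block", "replicate", "line")),
    ],
    ("cve", "pooled"): [
        Term("block", ("block",)),
        Term("sex", ("sex",), random=False),
        Term("sex_block", ("sex", "block")),
        Term("line", ("block", "line")),
        Term("sex_line", ("sex", "block", "line")),
        Term("rep", ("block", "replicate")),
        Term("sex_rep", ("sex", "block", "replicate")),
    ],
    ("cve", "per-sex"): [
        Term("block", ("block",)),
        Term("line", ("block", "line")),
        Term("rep", ("block", "replicate")),
    ],
}


@dataclass
class VarianceComponents:
    """Estimated variance components of one observational-model fit."""

    trait: str
    scale: str           # "mean" | "cve"
    mode: str            # "pooled" | "M" | "F"
    components: dict     # raw estimates (may be negative), incl. "residual"
    pvalues: dict
    n_obs: int
    method: str
    loglik: float = np.nan

    def component(self, name: str, truncate: bool = True) -> float:
        v = self.components.get(name, 0.0)
        if truncate and np.isfinite(v):
            return max(v, 0.0)
        return v

    def environmental_sum(self, truncate: bool = True) -> float:
        """Sum of every non-genetic variance source (the H^2 denominator tail)."""
        return float(sum(self.component(k, truncate) for k in self.components
                         if k not in GENETIC_COMPONENTS))


def fit_variance_model(table: pd.DataFrame, response: str,
                       mode: str = "pooled", scale: str = "mean",
                       method: str = "auto") -> VarianceComponents:
    """Partition the variance of ``response`` under the observational model.

    mode "pooled" fits the full model on both sexes; "M"/"F" fit the
    reduced per-sex model on that sex's rows.  ``method`` is "ems"
    (balanced decomposition), "reml" (dense restricted maximum
    likelihood), or "auto" (ems when the design is balanced, reml
    otherwise).
    """
    if mode not in ("pooled", "M", "F"):
        raise ValueError("mode must be pooled, M, or F")
    df = table.dropna(subset=[response]).copy()
    if mode == "pooled":
        if df["sex"].nunique() < 2:
            raise SingularDesignError("pooled fit requires both sexes")
        terms = _TERMS[(scale, "pooled")]
    else:
        df = df[df["sex"] == mode]
        terms = _TERMS[(scale, "per-sex")]
    if df["line"].nunique() < 2:
        raise SingularDesignError("need at least two lines")
    if df["replicate"].nunique() < 2:
        raise SingularDesignError("need at least two replicates")
    # drop terms that the table cannot support (e.g. one obs per cell)
    terms = [t for t in terms
             if df.groupby(list(t.cols), observed=True).ngroups < len(df)
             or not t.random]
    if method == "auto":
        try:
            tab = balanced_anova(df, response, terms)
            method = "ems"
        except UnbalancedDesignError:
            method = "reml"
    if method == "ems":
        tab = balanced_anova(df, response, terms)
        return VarianceComponents(
            trait=response, scale=scale, mode=mode,
            components=dict(tab.components), pvalues=dict(tab.pvalues),
            n_obs=tab.n_obs, method="ems")
    if method != "reml":
        raise ValueError(f"unknown method {method!r}")
    return _fit_reml(df, response, terms, scale, mode)


def _fit_reml(df, response, terms, scale, mode) -> VarianceComponents:
    y = df[response].to_numpy(dtype=float)
    if y.size > 4000:
        raise ValueError(
            "dense REML is limited to small tables; use a balanced design "
            "with method='ems' for large panels")
    X, zs = design_matrices(df, terms)
    random_names = [t.name for t in sorted(terms, key=lambda t: len(t.cols))
                    if t.random]
    start = None
    try:
        tab = balanced_anova(df, response, terms)
        start = np.array([max(tab.components[n], 1e-6 * (np.var(y) or 1.0))
                          for n in random_names + ["residual"]])
    except (UnbalancedDesignError, SingularDesignError):
        pass
    sigma2, ll = reml_fit(y, X, zs, start=start)
    components = dict(zip(random_names, sigma2[:-1].tolist()))
    components["residual"] = float(sigma2[-1])
    pvalues = {}
    if y.size <= 600:  # LRT refits are O(n^3) per component
        for i, name in enumerate(random_names):
            zs_red = [z for j, z in enumerate(zs) if j != i]
            _, ll_red = reml_fit(y, X, zs_red)
            pvalues[name] = reml_lrt_pvalue(ll, ll_red)
    else:
        pvalues = {name: np.nan for name in random_names}
    return VarianceComponents(
        trait=response, scale=scale, mode=mode, components=components,
        pvalues=pvalues, n_obs=y.size, method="reml", loglik=ll)


def heritability(vc: VarianceComponents) -> float:
    """Broad-sense heritability from a fitted component set.

    Pooled: (sigma2_L + sigma2_SL) / (sigma2_L + sigma2_SL + sigma2_E),
    where sigma2_E sums every other source of variation.  Per sex:
    sigma2_L / (sigma2_L + sigma2_E).  Negative raw components are
    truncated to zero inside the ratio.
    """
    line = vc.component("line")
    sexline = vc.component("sex_line") if vc.mode == "pooled" else 0.0
    genetic = line + sexline
    denom = genetic + vc.environmental_sum()
    if denom <= 0:
        return np.nan
    return genetic / denom


def cross_sex_rg(vc_pooled: VarianceComponents, vc_m: VarianceComponents,
                 vc_f: VarianceComponents):
    """Cross-sex genetic correlation r_MF = s2_L / sqrt(s2_LM * s2_LF).

    Returns ``(clipped, raw)``; undefined (NaN) when either per-sex line
    variance is zero.
    """
    if not (vc_pooled.trait == vc_m.trait == vc_f.trait
            and vc_pooled.scale == vc_m.scale == vc_f.scale):
        raise ValueError("all three fits must be on the same trait and scale")
    s2l = vc_pooled.component("line")
    s2m = vc_m.component("line")
    s2f = vc_f.component("line")
    if s2m <= 0 or s2f <= 0:
        return np.nan, np.nan
    raw = s2l / np.sqrt(s2m * s2f)
    return float(np.clip(raw, -1.0, 1.0)), float(raw)


def trait_rg(line_means_1, line_means_2) -> float:
    """Genetic correlation between two traits from their line means.

    Product-moment correlation of line means (sexes averaged), i.e.
    cov12 / sqrt(s2_1 * s2_2) with moments taken across lines.
    """
    s1 = pd.Series(line_means_1).dropna()
    s2 = pd.Series(line_means_2).dropna()
    common = s1.index.intersection(s2.index)
    if len(common) < 3:
        raise ValueError("need at least 3 common lines")
    a = s1.loc[common].to_numpy(dtype=float)
    b = s2.loc[common].to_numpy(dtype=float)
    if np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def line_means_by_line(line_sex_means: pd.DataFrame, trait: str) -> pd.Series:
    """Sex-averaged line means of one trait, indexed by line."""
    return line_sex_means.groupby("line", observed=True)[trait].mean()


def wolbachia_adjust(line_sex_means: pd.DataFrame, infection_status,
                     traits, alpha: float = 0.05):
    """Test and remove an infection-status shift from line means.

    Fits the infection model on line x sex means (infection fixed, lines
    the error stratum) overall and per sex.  Where the per-sex test is
    significant at ``alpha`` the that-sex line means are centered within
    infection class, preserving the grand mean exactly.  Returns
    ``(adjusted line_sex_means, report DataFrame)``.
    """
    status = pd.Series(infection_status)
    df = line_sex_means.copy()
    missing = set(df["line"]) - set(status.index)
    if missing:
        raise ValueError(f"infection status missing for lines: {sorted(missing)[:5]}")
    if status.loc[df["line"].unique()].nunique() < 2:
        report = pd.DataFrame(
            [{"trait": t, "p_overall": np.nan, "p_interaction": np.nan,
              "p_M": np.nan, "p_F": np.nan, "adjusted_M": False,
              "adjusted_F": False, "note": "single infection class"}
             for t in traits])
        return df, report

    wide = df.pivot(index="line", columns="sex")
    lines = wide.index
    inf = status.loc[lines].to_numpy(dtype=np.int8)
    rows = []
    for trait in traits:
        m = wide[(trait, "M")].to_numpy(dtype=float)
        f = wide[(trait, "F")].to_numpy(dtype=float)
        t = (m + f) / 2.0
        d = (m - f) / 2.0
        p_overall = float(oneway_scan(t, inf)["p"][0])
        p_int = float(oneway_scan(d, inf)["p"][0])
        p_m = float(oneway_scan(m, inf)["p"][0])
        p_f = float(oneway_scan(f, inf)["p"][0])
        adjusted = {}
        for sex, vals, p_sex in (("M", m, p_m), ("F", f, p_f)):
            if p_sex < alpha:
                grand = vals.mean()
                centered = vals.copy()
                for cls in (0, 1):
                    sel = inf == cls
                    centered[sel] = vals[sel] - vals[sel].mean() + grand
                mapping = dict(zip(lines, centered))
                df.loc[df["sex"] == sex, trait] = (
                    df.loc[df["sex"] == sex, "line"].map(mapping))
                adjusted[sex] = True
            else:
                adjusted[sex] = False
        rows.append({"trait": trait, "p_overall": p_overall,
                     "p_interaction": p_int, "p_M": p_m, "p_F": p_f,
                     "adjusted_M": adjusted["M"], "adjusted_F": adjusted["F"],
                     "note": ""})
    return df, pd.DataFrame(rows)


CONTROL_TERMS = [
    Term("block", ("block",)),
    Term("sex", ("sex",), random=False),
    Term("block_sex", ("block", "sex")),
    Term("rep", ("block", "replicate")),
    Term("sex_rep", ("sex", "block", "replicate")),
]


def control_block_check(control_table: pd.DataFrame, response: str) -> dict:
    """Block-effect diagnostics on the control line.

    Fits Y = mu + B + S + B*S + R(B) + S*R(B) + e and returns the
    synthesized-F p-values for the block-related random terms.  A design
    with a single block is rejected.
    """
    if control_table["block"].nunique() < 2:
        raise SingularDesignError("control check needs the line in >= 2 blocks")
    tab = balanced_anova(control_table.dropna(subset=[response]),
                         response, CONTROL_TERMS)
    return {name: tab.pvalues[name]
            for name in ("block", "block_sex", "rep", "sex_rep")}


def quantgen_report(phenotypes: pd.DataFrame, cve: pd.DataFrame,
                    traits) -> pd.DataFrame:
    """Components, heritabilities and r_MF for every trait and scale."""
    rows = []
    for scale, tab in (("mean", phenotypes), ("cve", cve)):
        for trait in traits:
            if trait not in tab.columns:
                continue
            fits = {}
            for mode in ("pooled", "M", "F"):
                try:
                    fits[mode] = fit_variance_model(tab, trait, mode=mode,
                                                    scale=scale)
                except (SingularDesignError, ValueError):
                    fits[mode] = None
            if fits["pooled"] is None:
                continue
            h2 = {m: (heritability(v) if v else np.nan)
                  for m, v in fits.items()}
            if fits["M"] and fits["F"]:
                rmf, rmf_raw = cross_sex_rg(fits["pooled"], fits["M"], fits["F"])
            else:
                rmf, rmf_raw = np.nan, np.nan
            row = {"trait": trait, "scale": scale,
                   "h2_pooled": h2["pooled"], "h2_M": h2["M"], "h2_F": h2["F"],
                   "r_MF": rmf, "r_MF_raw": rmf_raw}
            for name, v in fits["pooled"].components.items():
                row[f"vc_{name}"] = v
                row[f"p_{name}"] = fits["pooled"].pvalues.get(name, np.nan)
            rows.append(row)
    return pd.DataFrame(rows)
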
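"""Linkage disequilibrium among significant sites, inversion association,
and proxy-SNP collapsing.

For fully homozygous 0/1-coded lines the haplotype-frequency measure
D^2/(p1 q1 p2 q2) equals the squared Pearson correlation of the two
genotype columns, so r^2 is computed as the latter (pairwise-complete
over lines).  Local LD blocks are single-linkage chains of significant
sites with r^2 at or above a threshold and, optionally, a maximum
inter-site gap; the collapsed tally replaces every
significant site inside a trait-associated inversion or LD block with a
single proxy (smallest pooled p, ties to the smaller position).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import oneway_scan

logger = logging.getLogger(__name__)


@dataclass
class LDBlock:
    arm: str
    site_ids: list
    span: int
    proxy: str
    kind: str = "local_LD"  # or "inversion"
    mean_r2: float = np.nan


def pairwise_r2(genotypes) -> np.ndarray:
    """Symmetric r^2 matrix across sites (rows) over lines (columns).

    Missing genotypes (-1) are dropped pairwise; monomorphic pairs yield
    NaN.  The diagonal is 1 for polymorphic sites.
    """
    g = np.asarray(genotypes, dtype=float)
    if g.ndim != 2 or g.shape[0] < 2:
        raise ValueError("need at least two sites")
    g = np.where(g < 0, np.nan, g)
    k = g.shape[0]
    if not np.isnan(g).any():
        sd = g.std(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.corrcoef(g)
        r2 = c * c
        r2[sd == 0, :] = np.nan
        r2[:, sd == 0] = np.nan
        np.fill_diagonal(r2, np.where(sd > 0, 1.0, np.nan))
        return r2
    r2 = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i, k):
            ok = ~np.isnan(g[i]) & ~np.isnan(g[j])
            if ok.sum() < 2:
                continue
            a, b = g[i, ok], g[j, ok]
            if a.std() == 0 or b.std() == 0:
                continue
            r = np.corrcoef(a, b)[0, 1]
            r2[i, j] = r2[j, i] = r * r
    return r2


def find_ld_blocks(r2: np.ndarray, sites: pd.DataFrame,
                   r2_threshold: float = 0.8, max_gap=None,
                   pvalues=None) -> list:
    """Single-linkage LD blocks among (significant) sites.

    Two sites chain together when they share an arm, r^2 >= threshold and
    (when ``max_gap`` is given) their positions differ by at most that
    many bp; blocks are the transitive closures with >= 2 members.  The
    proxy is the member with the smallest p-value (ties to the smaller
    position) when p-values are supplied, else the first member.
    """
    n = len(sites)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    arms = sites["arm"].to_numpy()
    pos = sites["pos"].to_numpy()
    for i in range(n):
        for j in range(i + 1, n):
            if arms[i] != arms[j]:
                continue
            if max_gap is not None and abs(int(pos[j]) - int(pos[i])) > max_gap:
                continue
            if np.isfinite(r2[i, j]) and r2[i, j] >= r2_threshold:
                union(i, j)

    groups: dict = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    blocks = []
    for members in groups.values():
        if len(members) < 2:
            continue
        members = sorted(members, key=lambda i: int(pos[i]))
        ids = [sites["site_id"].iloc[i] for i in members]
        if pvalues is not None:
            pv = np.asarray(pvalues, dtype=float)
            proxy_i = min(members, key=lambda i: (pv[i], int(pos[i])))
        else:
            proxy_i = members[0]
        sub = np.ix_(members, members)
        off_diag = r2[sub][~np.eye(len(members), dtype=bool)]
        blocks.append(LDBlock(
            arm=str(arms[members[0]]), site_ids=ids,
            span=int(pos[members[-1]] - pos[members[0]]),
            proxy=str(sites["site_id"].iloc[proxy_i]),
            mean_r2=float(np.nanmean(off_diag)) if off_diag.size else np.nan,
        ))
    blocks.sort(key=lambda b: (b.arm, b.site_ids[0]))
    return blocks


def test_inversion(karyotype, line_sex_means: pd.DataFrame, trait: str):
    """Fixed two-way ANOVA Y = mu + Inv + S + Inv*S + e on line x sex means.

    ``karyotype`` is the per-line 0/1 carrier vector aligned with the
    sorted unique lines of the table.  Returns (p_inv, p_interaction), or
    (nan, nan) when one karyotype class has fewer than two lines.
    """
    lines = sorted(line_sex_means["line"].unique())
    kv = np.asarray(karyotype)
    if kv.size != len(lines):
        raise ValueError("karyotype length does not match line count")
    wide = line_sex_means.pivot(index="line", columns="sex", values=trait)
    wide = wide.reindex(lines)
    m = wide["M"].to_numpy(dtype=float)
    f = wide["F"].to_numpy(dtype=float)
    n1 = int((kv == 1).sum())
    n0 = int((kv == 0).sum())
    if n1 < 2 or n0 < 2:
        logger.info("inversion skipped: a karyotype class has < 2 lines")
        return np.nan, np.nan
    t = (m + f) / 2.0
    d = (m - f) / 2.0
    res_t = oneway_scan(t, kv)
    res_d = oneway_scan(d, kv)
    # pooled residual over both orthogonal halves of the line x sex table
    ss_res = 2.0 * (res_t["ss_within"][0] + res_d["ss_within"][0])
    df_res = 2 * (len(lines) - 2)
    if ss_res <= 0 or df_res <= 0:
        return 1.0, 1.0
    ms_res = ss_res / df_res
    f_inv = 2.0 * res_t["ss_between"][0] / ms_res
    f_int = 2.0 * res_d["ss_between"][0] / ms_res
    return (float(stats.f.sf(f_inv, 1, df_res)),
            float(stats.f.sf(f_int, 1, df_res)))


def collapse_proxies(assoc: pd.DataFrame, blocks, inversion_results,
                     alpha_inv: float = 0.05):
    """Collapse significant sites to proxies within inversions and LD blocks.

    ``assoc`` is one trait's association table (must carry site_id, arm,
    pos, p_pooled and a ``significant`` flag).  ``inversion_results`` maps
    karyotypes to their association p-values as an iterable of
    ``(InversionKaryotype, p_inv)``.  Inversions significant at
    ``alpha_inv`` collapse every significant site inside their interval
    to one proxy; each LD block then collapses to its most significant
    remaining member.  Returns (annotated table, counts dict).
    """
    out = assoc.copy()
    out["block_id"] = ""
    out["proxy_flag"] = False
    sig = out[out["significant"]]
    raw_count = int(len(sig))
    assigned = pd.Series("", index=out.index)

    def _proxy(rows):
        best = rows.sort_values(["p_pooled", "pos"]).iloc[0]
        return best.name

    for inv, p_inv in inversion_results or []:
        if not (np.isfinite(p_inv) and p_inv <= alpha_inv):
            continue
        sel = (out["significant"] & (out["arm"] == inv.arm)
               & (out["pos"] >= inv.start) & (out["pos"] <= inv.end)
               & (assigned == ""))
        if not sel.any():
            continue
        rows = out[sel]
        proxy_idx = _proxy(rows)
        assigned[sel] = f"inv:{inv.name}"
        out.loc[sel, "block_id"] = f"inv:{inv.name}"
        out.loc[proxy_idx, "proxy_flag"] = True

    for b_i, block in enumerate(blocks or []):
        sel = (out["significant"] & out["site_id"].isin(block.site_ids)
               & (assigned == ""))
        if not sel.any():
            continue
        rows = out[sel]
        proxy_idx = _proxy(rows)
        bid = f"ld:{block.arm}:{b_i}"
        assigned[sel] = bid
        out.loc[sel, "block_id"] = bid
        out.loc[proxy_idx, "proxy_flag"] = True

    free = out["significant"] & (assigned == "")
    out.loc[free, "proxy_flag"] = True
    collapsed = int(out["proxy_flag"].sum())
    return out, {"raw": raw_count, "collapsed": collapsed}
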
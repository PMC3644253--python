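"""Single-SNP genome-wide association on line means.

The observational unit is the line x sex mean (pooled model) or the
per-sex line mean (reduced model); per-fly data never enter the scans.
The pooled model is Y = mu + SNP + S + SNP*S + L(SNP) + e with lines the
error stratum for the SNP term: because each line contributes exactly one
male and one female mean, the decomposition splits orthogonally into the
sex-average and the sex-difference of each line, so F(SNP) is the one-way
ANOVA of sex-averaged line means across genotype classes against
MS(L(SNP)), and F(SNP*S) is the one-way ANOVA of the line sex-differences
against the residual.  The per-sex reduced model Y = mu + SNP + e is a
one-way ANOVA of that sex's line means.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ._stats import bh_qvalues, oneway_scan
from .datatypes import GenotypeMatrix

logger = logging.getLogger(__name__)

SEX_CLASSES = ("specific", "biased", "antagonistic", "equal", "NA")


def filter_snps(gm: GenotypeMatrix, min_minor_lines: int = 4,
                coverage_gt: int = 2, coverage_lt: int = 30) -> GenotypeMatrix:
    """Retain biallelic sites with the minor allele in >= ``min_minor_lines``
    non-missing lines and coverage strictly between the bounds."""
    minor = gm.minor_line_counts()
    cov = gm.sites["coverage"].to_numpy()
    keep = (minor >= min_minor_lines) & (cov > coverage_gt) & (cov < coverage_lt)
    return gm.subset(keep)


def _sex_matrices(line_sex_means: pd.DataFrame, trait: str, lines):
    wide = line_sex_means.pivot(index="line", columns="sex", values=trait)
    wide = wide.reindex(lines)
    m = wide["M"].to_numpy(dtype=float)
    f = wide["F"].to_numpy(dtype=float)
    return m, f


def test_snp_pooled(line_sex_means: pd.DataFrame, genotype_column,
                    trait: str = "value"):
    """Pooled-sex mixed ANOVA for one SNP; returns (p_pooled, p_interaction).

    ``line_sex_means`` must have columns line, sex and the trait; the
    genotype column is aligned with the sorted unique lines of the table.
    Monomorphic columns yield p = 1 with a warning.
    """
    lines = sorted(line_sex_means["line"].unique())
    g = np.asarray(genotype_column)
    if g.size != len(lines):
        raise ValueError("genotype column length does not match line count")
    m, f = _sex_matrices(line_sex_means, trait, lines)
    t = (m + f) / 2.0
    d = (m - f) / 2.0
    res_t = oneway_scan(t, g)
    res_d = oneway_scan(d, g)
    if res_t["n0"][0] < 1 or res_t["n1"][0] < 1:
        logger.warning("monomorphic genotype column; returning p = 1")
    return float(res_t["p"][0]), float(res_d["p"][0])


def test_snp_sex(per_sex_line_means, genotype_column) -> float:
    """Reduced per-sex model: one-way ANOVA across the two genotype classes."""
    y = np.asarray(per_sex_line_means, dtype=float)
    res = oneway_scan(y, np.asarray(genotype_column))
    if res["n0"][0] < 1 or res["n1"][0] < 1:
        logger.warning("monomorphic genotype column; returning p = 1")
    return float(res["p"][0])


def bh_fdr(pvalues, threshold: float = 0.01):
    """BH step-up q-values and the significant set at ``threshold``."""
    q = bh_qvalues(pvalues)
    return q, q <= threshold


def effect_and_variance(mean_major: float, mean_minor: float,
                        p_major: float, q_minor: float, sigma_p: float):
    """Effect size and genetic variance of one SNP.

    a is half the major-minus-minor difference of class means (signed);
    the standardized effect is a / sigma_P; V_G = 4 p q a^2 with p, q the
    major/minor line frequencies.
    """
    if sigma_p is not None and sigma_p <= 0:
        raise ValueError("sigma_p must be positive")
    a = (mean_major - mean_minor) / 2.0
    a_std = a / sigma_p if sigma_p else np.nan
    v_g = 4.0 * p_major * q_minor * a * a
    return a, a_std, v_g


def classify_sex_effect(q_m: float, q_f: float, a_m: float, a_f: float,
                        p_interaction: float, fdr: float = 0.01,
                        alpha_int: float = 0.05) -> str:
    """Sex-effect class of an FDR-significant site.

    specific: significant in exactly one sex; antagonistic: significant in
    both with opposite effect signs; biased: both, same sign, SNP-by-sex
    interaction p < alpha_int; equal: both, same sign, interaction
    non-significant; NA: significant in neither sex.
    """
    sig_m = np.isfinite(q_m) and q_m <= fdr
    sig_f = np.isfinite(q_f) and q_f <= fdr
    if not sig_m and not sig_f:
        return "NA"
    if sig_m != sig_f:
        return "specific"
    if a_m * a_f < 0:
        return "antagonistic"
    if np.isfinite(p_interaction) and p_interaction < alpha_int:
        return "biased"
    return "equal"


def scan_trait(gm: GenotypeMatrix, line_sex_means: pd.DataFrame, trait: str,
               fdr: float = 0.01, alpha_int: float = 0.05) -> pd.DataFrame:
    """Vectorized single-SNP association of one trait across all sites."""
    m, f = _sex_matrices(line_sex_means, trait, gm.lines)
    if np.any(~np.isfinite(m)) or np.any(~np.isfinite(f)):
        raise ValueError("line x sex means contain missing values")
    t = (m + f) / 2.0
    d = (m - f) / 2.0
    g = gm.genotypes
    res_t = oneway_scan(t, g)
    res_d = oneway_scan(d, g)
    res_m = oneway_scan(m, g)
    res_f = oneway_scan(f, g)

    n0, n1 = res_t["n0"], res_t["n1"]
    n = n0 + n1
    # orientation: the rarer class among non-missing lines is "minor"
    swap = n1 > n0
    with np.errstate(invalid="ignore"):
        q_freq = np.where(swap, n0, n1) / n
    p_freq = 1.0 - q_freq

    def _a(res):
        maj = np.where(swap, res["mean1"], res["mean0"])
        mino = np.where(swap, res["mean0"], res["mean1"])
        return (maj - mino) / 2.0

    a = _a(res_t)
    a_m_arr = _a(res_m)
    a_f_arr = _a(res_f)
    values = pd.concat([pd.Series(m), pd.Series(f)]).to_numpy()
    sigma_p = float(np.std(values, ddof=1))
    a_std = a / sigma_p if sigma_p > 0 else np.full_like(a, np.nan)
    v_g = 4.0 * p_freq * q_freq * a * a

    q_pooled = bh_qvalues(res_t["p"])
    q_int = bh_qvalues(res_d["p"])
    q_m = bh_qvalues(res_m["p"])
    q_f = bh_qvalues(res_f["p"])

    out = gm.sites[["site_id", "arm", "pos"]].copy()
    out["maf"] = q_freq
    out["p_pooled"] = res_t["p"]
    out["p_int"] = res_d["p"]
    out["p_M"] = res_m["p"]
    out["p_F"] = res_f["p"]
    out["q_pooled"] = q_pooled
    out["q_int"] = q_int
    out["q_M"] = q_m
    out["q_F"] = q_f
    out["a"] = a
    out["a_M"] = a_m_arr
    out["a_F"] = a_f_arr
    out["a_over_sigmaP"] = a_std
    out["v_g"] = v_g
    out["significant"] = np.minimum(np.minimum(q_pooled, q_m), q_f) <= fdr
    out["sex_class"] = [
        classify_sex_effect(qm, qf, am, af, pi, fdr=fdr, alpha_int=alpha_int)
        if sig else "NA"
        for qm, qf, am, af, pi, sig in zip(q_m, q_f, a_m_arr, a_f_arr,
                                           res_d["p"], out["significant"])
    ]
    out["trait"] = trait
    out["block_id"] = ""
    out["proxy_flag"] = False
    return out


def associate(gm: GenotypeMatrix, line_sex_means: pd.DataFrame, traits,
              fdr: float = 0.01, alpha_int: float = 0.05) -> dict:
    """Scan every trait; q-values are computed per trait separately."""
    return {trait: scan_trait(gm, line_sex_means, trait, fdr=fdr,
                              alpha_int=alpha_int)
            for trait in traits}


def qq_table(pvalues) -> pd.DataFrame:
    """Expected vs observed -log10 p for a Q-Q plot."""
    p = np.sort(np.asarray(pvalues, dtype=float))
    m = p.size
    expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    observed = -np.log10(np.clip(p, 1e-300, 1.0))
    return pd.DataFrame({"expected": expected, "observed": observed})


# ---------------------------------------------------------------------------
# site-class annotation

_UTR_TYPES = {"five_prime_UTR": "5'UTR", "three_prime_UTR": "3'UTR"}


def load_annotation(gff_path):
    """In-memory annotation database from a GFF3 file."""
    import gffutils

    return gffutils.create_db(str(gff_path), ":memory:", force=True,
                              keep_order=True,
                              merge_strategy="create_unique")


def annotate_site_class(sites: pd.DataFrame, db) -> pd.DataFrame:
    """Class (intergenic/intron/CDS/5'UTR/3'UTR) and gene ids per site.

    Class precedence is CDS > UTR > intron > intergenic; every overlapping
    gene is reported.  Sites on unannotated arms fall back to intergenic
    with a warning.
    """
    known_arms = {f.seqid for f in db.all_features()}
    classes, genes = [], []
    for _, row in sites.iterrows():
        if row.arm not in known_arms:
            logger.warning("site %s beyond annotated arms; calling intergenic",
                           row.site_id)
            classes.append("intergenic")
            genes.append("")
            continue
        feats = list(db.region(seqid=row.arm, start=int(row.pos),
                               end=int(row.pos)))
        types = {f.featuretype for f in feats}
        gene_ids = sorted({f.id for f in feats if f.featuretype == "gene"})
        if "CDS" in types:
            cls = "CDS"
        elif types & set(_UTR_TYPES):
            utr = sorted(types & set(_UTR_TYPES))[0]
            cls = _UTR_TYPES[utr]
        elif gene_ids:
            cls = "intron"
        else:
            cls = "intergenic"
        classes.append(cls)
        genes.append(",".join(gene_ids))
    out = sites.copy()
    out["site_class"] = classes
    out["gene_ids"] = genes
    return out
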
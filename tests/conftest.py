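"""Shared fixtures and independent oracles for the test suite."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sleepqg.synthetic import SimConfig, simulate_genotypes, simulate_phenotypes


@pytest.fixture
def rng():
    return np.random.default_rng(20260904)


@pytest.fixture
def small_config():
    return SimConfig(n_lines=16, n_blocks=2, n_reps_per_block=2,
                     flies_per_sex_per_rep=3, n_snps=120, seed=7,
                     traits=("night_sleep",))


@pytest.fixture
def small_panel(small_config):
    gm, truth_g = simulate_genotypes(small_config)
    phen, truth_p = simulate_phenotypes(gm, small_config)
    return gm, phen, truth_g, truth_p


# ---------------------------------------------------------------------------
# brute-force oracles (kept deliberately naive)


def zero_run_oracle(counts, min_bout=5):
    """Enumerate zero runs by scanning minute by minute."""
    runs = []
    start = None
    for i, c in enumerate(list(counts) + [1]):  # sentinel to close a final run
        if c == 0 and start is None:
            start = i
        elif c != 0 and start is not None:
            if i - start >= min_bout:
                runs.append((start, i - start))
            start = None
    return runs


def suffix_dead_oracle(counts, window=1440):
    tail = list(counts)[-window:]
    return all(c == 0 for c in tail)


def site_filter_oracle(gm, min_minor=4, cov_gt=2, cov_lt=30):
    keep = []
    for i in range(gm.n_sites):
        col = [g for g in gm.genotypes[i] if g >= 0]
        ones = sum(1 for g in col if g == 1)
        minor = min(ones, len(col) - ones)
        cov = int(gm.sites["coverage"].iloc[i])
        keep.append(minor >= min_minor and cov_gt < cov < cov_lt)
    return np.array(keep)


def haplotype_r2_oracle(a, b):
    """D^2 / (p1 q1 p2 q2) from haplotype (line) frequencies."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    p1, p2 = a.mean(), b.mean()
    d = np.mean(a * b) - p1 * p2
    denom = p1 * (1 - p1) * p2 * (1 - p2)
    return d * d / denom


GFF_GENES = [
    # (gene_id, arm, start, end, [(feature, start, end), ...])
    ("gene1", "2L", 1000, 5000,
     [("five_prime_UTR", 1000, 1199), ("CDS", 1200, 2500),
      ("three_prime_UTR", 4500, 5000)]),
    ("gene2", "2L", 4800, 9000, [("CDS", 6000, 7000)]),
    ("gene3", "3R", 100, 800, []),
]


@pytest.fixture(scope="session")
def gff_file(tmp_path_factory):
    path = tmp_path_factory.mktemp("annot") / "genes.gff3"
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gid, arm, start, end, feats in GFF_GENES:
            fh.write(f"{arm}\ttest\tgene\t{start}\t{end}\t.\t+\t.\tID={gid}\n")
            for k, (ftype, fs, fe) in enumerate(feats):
                fh.write(f"{arm}\ttest\t{ftype}\t{fs}\t{fe}\t.\t+\t.\t"
                         f"ID={gid}.{ftype}.{k};Parent={gid}\n")
    return path


def site_class_oracle(arm, pos):
    """All-intervals scan with precedence CDS > UTR > intron > intergenic."""
    cls = "intergenic"
    genes = []
    rank = {"intergenic": 0, "intron": 1, "3'UTR": 2, "5'UTR": 2, "CDS": 3}
    names = {"five_prime_UTR": "5'UTR", "three_prime_UTR": "3'UTR"}
    for gid, g_arm, g_start, g_end, feats in GFF_GENES:
        if g_arm != arm or not (g_start <= pos <= g_end):
            continue
        genes.append(gid)
        if rank[cls] < rank["intron"]:
            cls = "intron"
        for ftype, fs, fe in feats:
            if fs <= pos <= fe:
                f_cls = names.get(ftype, "CDS")
                if rank[f_cls] > rank[cls]:
                    cls = f_cls
    return cls, sorted(genes)
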
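"""Core domain containers shared across the pipeline stages."""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SITE_COLUMNS = ["site_id", "arm", "pos", "ref", "alt", "coverage"]


@dataclass
class GenotypeMatrix:
    """Homozygous biallelic genotypes for a panel of inbred lines.

    ``genotypes`` is sites x lines, coded 0 (major homozygote),
    1 (minor homozygote) and -1 (missing).  ``sites`` carries one row per
    site with columns ``site_id, arm, pos, ref, alt, coverage``.
    """

    sites: pd.DataFrame
    genotypes: np.ndarray
    lines: list

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.sites), len(self.lines)):
            raise ValueError("genotype matrix shape does not match sites/lines")
        bad = ~np.isin(self.genotypes, (-1, 0, 1))
        if bad.any():
            raise ValueError("genotypes must be coded -1/0/1")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    def minor_line_counts(self) -> np.ndarray:
        """Number of non-missing lines carrying the rarer allele, per site."""
        valid = self.genotypes >= 0
        ones = ((self.genotypes == 1) & valid).sum(axis=1)
        n = valid.sum(axis=1)
        return np.minimum(ones, n - ones)

    def maf(self) -> np.ndarray:
        valid = (self.genotypes >= 0).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(valid > 0, self.minor_line_counts() / valid, np.nan)

    def validate(self) -> None:
        for arm, grp in self.sites.groupby("arm"):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on arm {arm}")

    def subset(self, mask) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            sites=self.sites.loc[mask].reset_index(drop=True),
            genotypes=self.genotypes[mask],
            lines=list(self.lines),
        )

    # -- TSV round trip ----------------------------------------------------
    def to_tsv(self, path) -> None:
        out = self.sites[SITE_COLUMNS].copy()
        geno = pd.DataFrame(self.genotypes, columns=self.lines)
        pd.concat([out, geno], axis=1).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t")
        lines = [c for c in df.columns if c not in SITE_COLUMNS]
        return cls(sites=df[SITE_COLUMNS].copy(),
                   genotypes=df[lines].to_numpy(dtype=np.int8),
                   lines=lines)

    # -- minimal VCF (uncompressed text, haploid-style GT per line) --------
    def to_vcf(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Coverage">\n')
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            for arm in self.sites["arm"].unique():
                length = int(self.sites.loc[self.sites.arm == arm, "pos"].max()) + 1000
                fh.write(f"##contig=<ID={arm},length={length}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(map(str, self.lines)) + "\n")
            for i, row in self.sites.iterrows():
                gts = ["." if g < 0 else str(int(g)) for g in self.genotypes[i]]
                fh.write(f"{row.arm}\t{int(row.pos)}\t{row.site_id}\t{row.ref}\t"
                         f"{row.alt}\t.\tPASS\tDP={int(row.coverage)}\tGT\t"
                         + "\t".join(gts) + "\n")

    @classmethod
    def from_vcf(cls, path) -> "GenotypeMatrix":
        import pysam

        vf = pysam.VariantFile(str(path))
        lines = list(vf.header.samples)
        recs, geno = [], []
        for rec in vf:
            recs.append({
                "site_id": rec.id or f"{rec.chrom}_{rec.pos}",
                "arm": rec.chrom, "pos": rec.pos,
                "ref": rec.ref, "alt": rec.alts[0] if rec.alts else ".",
                "coverage": int(rec.info.get("DP", 0)),
            })
            row = []
            for s in lines:
                gt = rec.samples[s].get("GT")
                allele = gt[0] if gt else None
                row.append(-1 if allele is None else int(allele))
            geno.append(row)
        return cls(sites=pd.DataFrame(recs),
                   genotypes=np.array(geno, dtype=np.int8),
                   lines=lines)


@dataclass
class TruthRecord:
    """Ground truth emitted by the simulator for recovery tests."""

    causal_mean: pd.DataFrame = field(default_factory=pd.DataFrame)
    causal_var: pd.DataFrame = field(default_factory=pd.DataFrame)
    variance_targets: dict = field(default_factory=dict)
    line_values: pd.DataFrame = field(default_factory=pd.DataFrame)
    ld_blocks: list = field(default_factory=list)
    inversions: pd.DataFrame = field(default_factory=pd.DataFrame)
    karyotypes: list = field(default_factory=list)

    def to_dir(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.causal_mean.to_csv(directory / "truth_causal_mean.tsv", sep="\t", index=False)
        self.causal_var.to_csv(directory / "truth_causal_var.tsv", sep="\t", index=False)
        self.line_values.to_csv(directory / "truth_line_values.tsv", sep="\t", index=False)
        if len(self.inversions):
            self.inversions.to_csv(directory / "truth_inversions.tsv", sep="\t", index=False)
        pd.DataFrame([self.variance_targets]).to_csv(
            directory / "truth_variance_targets.tsv", sep="\t", index=False)


@dataclass
class InversionKaryotype:
    """Presence/absence of one segregating inversion across the panel."""

    name: str
    arm: str
    start: int
    end: int
    carriers: dict  # line id -> 0/1

    def carrier_vector(self, lines) -> np.ndarray:
        return np.array([self.carriers.get(l, 0) for l in lines], dtype=np.int8)


def write_inversions_bed(karyotypes, bed_path, carriers_tsv) -> None:
    """BED intervals (name in column 4) plus a carrier-line sidecar TSV."""
    with open(bed_path, "w") as fh:
        for k in karyotypes:
            fh.write(f"{k.arm}\t{k.start}\t{k.end}\t{k.name}\n")
    rows = []
    for k in karyotypes:
        for line, flag in k.carriers.items():
            rows.append({"inversion": k.name, "line": line, "carrier": int(flag)})
    pd.DataFrame(rows).to_csv(carriers_tsv, sep="\t", index=False)


def read_inversions_bed(bed_path, carriers_tsv) -> list:
    bed = pd.read_csv(bed_path, sep="\t", header=None,
                      names=["arm", "start", "end", "name"])
    side = pd.read_csv(carriers_tsv, sep="\t")
    out = []
    for _, row in bed.iterrows():
        sub = side[side.inversion == row["name"]]
        carriers = dict(zip(sub.line, sub.carrier.astype(int)))
        out.append(InversionKaryotype(name=row["name"], arm=row.arm,
                                      start=int(row.start), end=int(row.end),
                                      carriers=carriers))
    return out
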
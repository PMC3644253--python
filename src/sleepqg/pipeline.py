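"""Pipeline orchestration: simulate -> phenotype -> quantgen -> gwas -> ld
-> multisnp, driven by one config and one seed, with a manifest recording
every file the run produced.  Stages communicate exclusively through TSV
files in the run directory, so any stage can be re-run or replaced by an
externally supplied table.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datatypes import GenotypeMatrix, read_inversions_bed, write_inversions_bed
from .gwa_multi import forward_select, genetic_variance_explained
from .gwa_single import associate, filter_snps, qq_table
from .ld_structure import collapse_proxies, find_ld_blocks, pairwise_r2, test_inversion
from .quantgen import quantgen_report
from .sleep_metrics import cve_table, line_sex_means, read_dam_dir, summarize_streams
from .synthetic import SimConfig, simulate_activity, simulate_genotypes, simulate_phenotypes

logger = logging.getLogger(__name__)

STAGES = ("simulate", "phenotype", "quantgen", "gwas", "ld", "multisnp")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Run-level options; ``sim`` holds SimConfig field overrides."""

    seed: int = 0
    sim: dict = field(default_factory=dict)
    stages: tuple = STAGES
    fdr: float = 0.01
    alpha: float = 0.05
    alpha_int: float = 0.05
    r2_threshold: float = 0.8
    max_gap: int | None = None
    stop_rule: str = "adjusted-r2"
    max_steps: int = 10
    min_bout: int = 5
    dead_window: int = 1440
    lights_on: str = "08:00"
    use_activity: bool = False
    phenotype_tsv: str | None = None
    max_ld_sites: int = 2000

    def __post_init__(self):
        if not 0 < self.fdr <= 1 or not 0 < self.alpha <= 1:
            raise ValueError("thresholds must lie in (0, 1]")
        if not 0 <= self.r2_threshold <= 1:
            raise ValueError("r2_threshold must lie in [0, 1]")
        if self.min_bout < 1:
            raise ValueError("min_bout must be >= 1")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @property
    def lights_on_minute(self) -> int:
        hh, mm = self.lights_on.split(":")
        return int(hh) * 60 + int(mm)

    def sim_config(self) -> SimConfig:
        return SimConfig(seed=self.seed,
                         lights_on_minute=self.lights_on_minute, **self.sim)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        if "sim" in data:
            for key in ("ld_block_spec", "inversion_spec", "traits",
                        "effect_sizes_mean", "effect_sizes_var"):
                if key in data["sim"] and data["sim"][key] is not None:
                    data["sim"][key] = tuple(
                        tuple(v) if isinstance(v, (list, tuple)) else v
                        for v in data["sim"][key])
        return cls(**data)


def _require(out_dir: Path, name: str, stage: str) -> Path:
    path = out_dir / name
    if not path.exists():
        raise PipelineError(f"stage {stage!r}: missing upstream output {name}")
    return path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def stage_simulate(cfg: RunConfig, out_dir: Path) -> None:
    sim = cfg.sim_config()
    gm, truth_g = simulate_genotypes(sim)
    gm.to_tsv(out_dir / "genotypes.tsv")
    phen, truth_p = simulate_phenotypes(gm, sim)
    phen.to_csv(out_dir / "phenotypes.tsv", sep="\t", index=False)
    truth_p.ld_blocks = truth_g.ld_blocks
    truth_p.inversions = truth_g.inversions
    truth_p.to_dir(out_dir / "truth")
    if truth_g.karyotypes:
        write_inversions_bed(truth_g.karyotypes, out_dir / "inversions.bed",
                             out_dir / "inversion_carriers.tsv")
    if cfg.use_activity:
        from .sleep_metrics import write_dam_files

        streams = simulate_activity(sim)
        write_dam_files(streams, out_dir / "dam")


def stage_phenotype(cfg: RunConfig, out_dir: Path) -> None:
    if cfg.use_activity:
        dam = _require(out_dir, "dam", "phenotype")
        streams = read_dam_dir(dam)
        table = summarize_streams(streams, min_bout=cfg.min_bout,
                                  dead_window=cfg.dead_window)
    elif cfg.phenotype_tsv:
        table = pd.read_csv(cfg.phenotype_tsv, sep="\t")
    else:
        table = pd.read_csv(_require(out_dir, "phenotypes.tsv", "phenotype"),
                            sep="\t")
    traits = [t for t in cfg.sim_config().traits if t in table.columns]
    table.to_csv(out_dir / "phenotype_table.tsv", sep="\t", index=False)
    cve = cve_table(table, traits)
    cve.to_csv(out_dir / "cve.tsv", sep="\t", index=False)
    line_sex_means(table, traits).to_csv(
        out_dir / "line_sex_means.tsv", sep="\t", index=False)
    cve_lsm = (cve.groupby(["line", "sex"], observed=True)[traits]
               .mean().reset_index())
    cve_lsm.to_csv(out_dir / "cve_line_sex_means.tsv", sep="\t", index=False)


def stage_quantgen(cfg: RunConfig, out_dir: Path) -> None:
    table = pd.read_csv(_require(out_dir, "phenotype_table.tsv", "quantgen"),
                        sep="\t")
    cve = pd.read_csv(_require(out_dir, "cve.tsv", "quantgen"), sep="\t")
    traits = [t for t in cfg.sim_config().traits if t in table.columns]
    report = quantgen_report(table, cve, traits)
    report.to_csv(out_dir / "quantgen.tsv", sep="\t", index=False)


def _scale_means(out_dir: Path, scale: str, stage: str) -> pd.DataFrame:
    name = ("line_sex_means.tsv" if scale == "mean"
            else "cve_line_sex_means.tsv")
    return pd.read_csv(_require(out_dir, name, stage), sep="\t")


def stage_gwas(cfg: RunConfig, out_dir: Path) -> None:
    gm = GenotypeMatrix.from_tsv(_require(out_dir, "genotypes.tsv", "gwas"))
    gm = filter_snps(gm)
    traits = list(cfg.sim_config().traits)
    for scale in ("mean", "cve"):
        lsm = _scale_means(out_dir, scale, "gwas")
        usable = [t for t in traits
                  if t in lsm.columns and lsm[t].notna().all()]
        results = associate(gm, lsm, usable, fdr=cfg.fdr,
                            alpha_int=cfg.alpha_int)
        for trait, df in results.items():
            df["scale"] = scale
            df.to_csv(out_dir / f"gwas_{scale}_{trait}.tsv", sep="\t",
                      index=False)
            qq_table(df["p_pooled"]).to_csv(
                out_dir / f"qq_{scale}_{trait}.tsv", sep="\t", index=False)


def stage_ld(cfg: RunConfig, out_dir: Path) -> None:
    gm = GenotypeMatrix.from_tsv(_require(out_dir, "genotypes.tsv", "ld"))
    karyotypes = []
    if (out_dir / "inversions.bed").exists():
        karyotypes = read_inversions_bed(out_dir / "inversions.bed",
                                         out_dir / "inversion_carriers.tsv")
    summary = []
    site_index = {s: i for i, s in enumerate(gm.sites["site_id"])}
    for path in sorted(out_dir.glob("gwas_*.tsv")):
        assoc = pd.read_csv(path, sep="\t")
        trait = assoc["trait"].iloc[0]
        scale = assoc["scale"].iloc[0]
        lsm = _scale_means(out_dir, scale, "ld")
        lines = sorted(lsm["line"].unique())
        inv_results = []
        for inv in karyotypes:
            p_inv, p_int = test_inversion(inv.carrier_vector(lines), lsm, trait)
            inv_results.append((inv, p_inv))
            summary.append({"trait": trait, "scale": scale, "kind": "inversion",
                            "name": inv.name, "p_inv": p_inv, "p_int": p_int})
        sig = assoc[assoc["significant"]]
        if len(sig) > cfg.max_ld_sites:
            logger.warning("%s: %d significant sites, LD restricted to the "
                           "top %d by pooled p", path.name, len(sig),
                           cfg.max_ld_sites)
            sig = sig.nsmallest(cfg.max_ld_sites, "p_pooled")
        blocks = []
        if len(sig) >= 2:
            rows = [site_index[s] for s in sig["site_id"]]
            r2 = pairwise_r2(gm.genotypes[rows])
            blocks = find_ld_blocks(r2, sig.reset_index(drop=True),
                                    r2_threshold=cfg.r2_threshold,
                                    max_gap=cfg.max_gap,
                                    pvalues=sig["p_pooled"].to_numpy())
        annotated, counts = collapse_proxies(assoc, blocks, inv_results,
                                             alpha_inv=cfg.alpha)
        annotated.to_csv(path, sep="\t", index=False)
        block_rows = [{"trait": trait, "scale": scale, "arm": b.arm,
                       "n_members": len(b.site_ids), "span": b.span,
                       "proxy": b.proxy, "mean_r2": b.mean_r2,
                       "members": ",".join(b.site_ids)} for b in blocks]
        pd.DataFrame(block_rows, columns=["trait", "scale", "arm", "n_members",
                                          "span", "proxy", "mean_r2",
                                          "members"]).to_csv(
            out_dir / f"ld_blocks_{scale}_{trait}.tsv", sep="\t", index=False)
        summary.append({"trait": trait, "scale": scale, "kind": "counts",
                        "name": "", "n_raw": counts["raw"],
                        "n_collapsed": counts["collapsed"]})
    pd.DataFrame(summary).to_csv(out_dir / "ld_summary.tsv", sep="\t",
                                 index=False)


def stage_multisnp(cfg: RunConfig, out_dir: Path) -> None:
    gm = GenotypeMatrix.from_tsv(_require(out_dir, "genotypes.tsv", "multisnp"))
    gm = filter_snps(gm)
    quant = pd.read_csv(_require(out_dir, "quantgen.tsv", "multisnp"), sep="\t")
    rows = []
    for scale in ("mean", "cve"):
        lsm = _scale_means(out_dir, scale, "multisnp")
        traits = [c for c in lsm.columns if c not in ("line", "sex")]
        for trait in traits:
            if lsm[trait].isna().any():
                continue
            for sex in ("M", "F"):
                sub = lsm[lsm["sex"] == sex].set_index("line")
                y = sub[trait].reindex(gm.lines).to_numpy(dtype=float)
                model = forward_select(
                    y, gm.genotypes, site_ids=list(gm.sites["site_id"]),
                    stop_rule=cfg.stop_rule, alpha_stop=cfg.alpha,
                    max_steps=cfg.max_steps, trait=trait, sex=sex)
                h2_col = f"h2_{sex}"
                match = quant[(quant["trait"] == trait)
                              & (quant["scale"] == scale)]
                h2 = float(match[h2_col].iloc[0]) if len(match) else np.nan
                frac = genetic_variance_explained(model.adj_r2, h2)
                for _, step in model.steps.iterrows():
                    rows.append({"trait": trait, "scale": scale, "sex": sex,
                                 "step": int(step["step"]),
                                 "site_id": step["site_id"],
                                 "partial_p": step["partial_p"],
                                 "r2": step["r2"], "adj_r2": step["adj_r2"],
                                 "h2": h2, "fraction_vg": frac})
                if model.steps.empty:
                    rows.append({"trait": trait, "scale": scale, "sex": sex,
                                 "step": 0, "site_id": "", "partial_p": np.nan,
                                 "r2": 0.0, "adj_r2": 0.0, "h2": h2,
                                 "fraction_vg": np.nan})
    pd.DataFrame(rows).to_csv(out_dir / "multisnp.tsv", sep="\t", index=False)


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "phenotype": stage_phenotype,
    "quantgen": stage_quantgen,
    "gwas": stage_gwas,
    "ld": stage_ld,
    "multisnp": stage_multisnp,
}


def run_pipeline(cfg: RunConfig, out_dir) -> Path:
    """Run the enabled stages into ``out_dir`` and write a manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for stage in STAGES:
        if stage not in cfg.stages:
            continue
        logger.info("running stage %s", stage)
        _STAGE_FUNCS[stage](cfg, out_dir)
    files = {}
    for path in sorted(out_dir.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            files[str(path.relative_to(out_dir))] = _sha256(path)
    manifest = {
        "config": dataclasses.asdict(cfg),
        "seed": cfg.seed,
        "version": __version__,
        "files": files,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return out_dir
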
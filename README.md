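# sleepqg

Quantitative genetics of sleep in fully inbred line panels: a tested,
reusable pipeline covering

- **synthetic data** — genotypes with a low-frequency-skewed site spectrum
  (minor allele in ≥ 4 lines), local LD blocks, inversion karyotypes, and
  per-fly phenotypes / minute-binned activity streams generated from the
  observational model the analyses assume, including genetic variance in
  the residual standard deviation (variance-QTLs) with a configurable
  mean–log σ_E genetic correlation;
- **sleep metrics** — activity-monitor text → per-fly night/day sleep
  duration, bout number, average bout length and waking activity, with
  the five-minute inactivity rule, dead-fly exclusion (terminal 24 h of
  inactivity), and the per line/sex/replicate coefficient of
  environmental variation CV_E = (SD/mean) × 100;
- **quantgen** — variance partitioning under
  `Y = μ + B + S + L(B) + S×L(B) + R(B) + S×R(B) + R×L(B) + S×R×L(B) + ε`
  (EMS decomposition on balanced designs, dense REML otherwise; the two
  agree at interior optima), broad-sense heritability for trait means and
  CV_E, cross-sex and cross-trait genetic correlations, an
  infection-status correction, and a control-line block check;
- **gwa_single** — per-SNP mixed ANOVA on line×sex means (pooled +
  SNP×sex interaction) and per-sex one-way ANOVA on line means,
  Benjamini–Hochberg FDR per trait, standardized effects a/σ_P,
  V_G = 4pqa², sex-effect classification
  (specific/biased/antagonistic/equal), and GFF3 site-class annotation;
- **ld_structure** — pairwise r² (equals the haplotype-frequency D²
  formula for homozygous lines), single-linkage LD blocks, inversion
  association, and proxy-SNP collapsing;
- **gwa_multi** — forward-selection additive multi-SNP models with an
  adjusted-R² (or partial-F) stop and fraction of genetic variance
  explained;
- **cli_pipeline** — `sleepqg` orchestrating
  simulate → phenotype → quantgen → gwas → ld → multisnp with a single
  YAML config, one seed, TSV stage contracts, and a hashed manifest.

## CLI

```sh
# everything, end to end
sleepqg all -c config.yaml -o runs/demo --seed 1

# or stage by stage
sleepqg simulate  -c config.yaml -o runs/demo
sleepqg phenotype -c config.yaml -o runs/demo
sleepqg quantgen  -c config.yaml -o runs/demo
sleepqg gwas      -c config.yaml -o runs/demo
sleepqg ld        -c config.yaml -o runs/demo
sleepqg multisnp  -c config.yaml -o runs/demo
```

Example `config.yaml`:

```yaml
seed: 1
fdr: 0.01
r2_threshold: 0.8
stop_rule: adjusted-r2
sim:
  n_lines: 168
  n_snps: 25000
  n_causal_mean: 4
  n_causal_var: 4
  var_log_sigma: 0.04
  traits: [night_sleep, day_sleep, waking_activity]
  ld_block_spec: [["2L", 100000, 8, 0.98]]
  inversion_spec: [["3R", 5000000, 15000000, 0.3]]
```

Outputs land in the run directory as TSVs (`genotypes.tsv`,
`phenotype_table.tsv`, `cve.tsv`, `quantgen.tsv`,
`gwas_<scale>_<trait>.tsv`, `qq_*.tsv`, `ld_blocks_*.tsv`,
`ld_summary.tsv`, `multisnp.tsv`) plus `manifest.json` with a SHA-256 of
every file; identical config + seed reproduce identical manifests.

## Notes

- Heritability denominators follow the "sum of all other sources of
  variation" convention: every fitted random component other than line
  and sex×line, with negative raw estimates truncated to zero inside
  ratios only.
- GWA operates exclusively on line×sex means (pooled) and per-sex line
  means (reduced model); per-fly records never enter the scans.
- Waking activity is computed whole-record by default; a per-phase
  variant is available via `summarize_fly(..., per_phase_waking=True)`.
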
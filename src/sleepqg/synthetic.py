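"""Synthetic panel generator.

Produces genotypes, inversion karyotypes, per-fly phenotypes and
minute-binned activity streams with the statistical structure the
downstream analyses assume: a low-frequency-skewed site spectrum with the
minor allele in at least four lines, local LD blocks made by copying a
template column with per-line flip noise, binary inversion karyotypes,
sex-modulated SNP effects, and genetic variance in the residual standard
deviation (on the log scale) with a configurable correlation between a
line's genetic mean and its log sigma_E.

All randomness flows from a single integer seed; sub-streams use fixed
offsets so each product is independently reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, InversionKaryotype, TruthRecord

DEFAULT_TRAITS = (
    "night_sleep", "day_sleep", "night_bout_n", "day_bout_n",
    "night_avg_bout_len", "day_avg_bout_len", "waking_activity",
)

_RNG_GENO, _RNG_PHENO, _RNG_ACT = 11, 23, 37


@dataclass
class SimConfig:
    """All knobs of the simulated panel; one global seed drives everything."""

    n_lines: int = 168
    n_blocks: int = 4
    n_reps_per_block: int = 4
    flies_per_sex_per_rep: int = 8
    n_snps: int = 1000
    sfs_shape: float = 1.5
    min_minor_lines: int = 4
    n_causal_mean: int = 0
    n_causal_var: int = 0
    effect_sizes_mean: tuple = (0.3, 0.5, 0.7)   # a / sigma_P units
    effect_sizes_var: tuple = (1.4,)             # multiplicative sigma_E effects
    frac_sex_specific: float = 0.0
    frac_sex_antagonistic: float = 0.0
    var_line: float = 100.0
    var_sexline: float = 25.0
    var_env_mean: float = 400.0
    var_block: float = 0.0
    var_sexblock: float = 0.0
    var_rep: float = 0.0
    var_sexrep: float = 0.0
    var_repline: float = 0.0
    var_sexrepline: float = 0.0
    var_log_sigma: float = 0.0
    rho_mean_sigmaE: float = -0.8
    mu: float = 500.0
    sex_diff: float = 0.0
    ld_block_spec: tuple = ()     # (arm, span_bp, n_snps, copy_fidelity)
    inversion_spec: tuple = ()    # (arm, start_bp, end_bp, carrier_fraction)
    inversion_fidelity: float = 0.9
    markov_rates: dict = field(default_factory=lambda: {
        "day": {"wake_to_sleep": 0.05, "sleep_to_wake": 0.25},
        "night": {"wake_to_sleep": 0.25, "sleep_to_wake": 0.05},
    })
    activity_rate: float = 1.0
    dead_fraction: float = 0.0
    n_days: int = 7
    lights_on_minute: int = 480
    traits: tuple = DEFAULT_TRAITS
    arms: tuple = ("X", "2L", "2R", "3L", "3R")
    arm_length: int = 25_000_000
    seed: int = 0

    def validate(self) -> None:
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if self.n_lines < 8:
            raise ValueError("n_lines must be >= 8")
        if self.min_minor_lines < 4 or self.min_minor_lines > self.n_lines // 2:
            raise ValueError("minor-line counts must lie in [4, n_lines/2]")
        for phase, rates in self.markov_rates.items():
            for key, p in rates.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"markov rate {phase}/{key} outside [0, 1]")
        if not -1.0 <= self.rho_mean_sigmaE <= 1.0:
            raise ValueError("rho_mean_sigmaE must lie in [-1, 1]")
        if not 0.0 <= self.dead_fraction < 1.0:
            raise ValueError("dead_fraction must lie in [0, 1)")

    def line_ids(self) -> list:
        return [f"L{i + 1:03d}" for i in range(self.n_lines)]

    def line_blocks(self) -> dict:
        """Lines partitioned into disjoint consecutive blocks."""
        per = self.n_lines // self.n_blocks
        assign = {}
        for i, line in enumerate(self.line_ids()):
            assign[line] = f"B{min(i // per, self.n_blocks - 1) + 1}"
        return assign


def _rng(config: SimConfig, stream: int, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng((int(config.seed), stream, extra))


def sample_minor_line_counts(rng, n, kmin, kmax, shape) -> np.ndarray:
    """Minor-line counts from the truncated power-law P(k) ~ k**-shape."""
    ks = np.arange(kmin, kmax + 1)
    w = ks.astype(float) ** (-shape)
    w /= w.sum()
    return rng.choice(ks, size=n, p=w)


def _normalize_minor(col: np.ndarray, rng, kmin: int) -> np.ndarray:
    """Code 1 as the minor allele and guarantee >= kmin minor lines."""
    n = col.size
    if col.sum() > n // 2:
        col = 1 - col
    deficit = kmin - int(col.sum())
    if deficit > 0:
        zeros = np.flatnonzero(col == 0)
        col = col.copy()
        col[rng.choice(zeros, size=deficit, replace=False)] = 1
    return col


def simulate_genotypes(config: SimConfig):
    """Lines x sites homozygous genotype matrix plus generator ground truth."""
    config.validate()
    rng = _rng(config, _RNG_GENO)
    L, S = config.n_lines, config.n_snps
    kmin, kmax = config.min_minor_lines, L // 2

    # per-arm site layout, sorted positions
    arm_of = np.array([config.arms[i % len(config.arms)] for i in range(S)])
    order = np.argsort(arm_of, kind="mergesort")
    arm_of = arm_of[order]
    pos = np.empty(S, dtype=np.int64)
    for arm in config.arms:
        idx = np.flatnonzero(arm_of == arm)
        if idx.size == 0:
            continue
        p = np.unique(rng.integers(1, config.arm_length, size=2 * idx.size + 16))
        while p.size < idx.size:
            extra = rng.integers(1, config.arm_length, size=idx.size)
            p = np.unique(np.concatenate([p, extra]))
        p = np.sort(rng.choice(p, size=idx.size, replace=False))
        pos[idx] = p

    ks = sample_minor_line_counts(rng, S, kmin, kmax, config.sfs_shape)
    ranks = rng.random((S, L)).argsort(axis=1).argsort(axis=1)
    geno = (ranks < ks[:, None]).astype(np.int8)

    # local LD blocks: template column copied with per-line flip noise
    ld_truth = []
    for arm, span, n_block, fidelity in config.ld_block_spec:
        idx = np.flatnonzero(arm_of == arm)
        if idx.size < n_block:
            raise ValueError(f"arm {arm} has fewer than {n_block} sites")
        start = rng.integers(0, idx.size - n_block + 1)
        members = idx[start:start + n_block]
        # block templates tag common haplotypes: a skewed-SFS template plus
        # per-line flip noise could not reach high pairwise r^2
        k_t = int(rng.integers(max(kmin, L // 3), kmax + 1))
        template = np.zeros(L, dtype=np.int8)
        template[rng.choice(L, size=k_t, replace=False)] = 1
        # compress member positions into the requested span when it fits
        lo = pos[members[0]]
        hi_cap = (pos[members[-1] + 1] - 1 if members[-1] + 1 in set(idx)
                  else config.arm_length - 1)
        if lo + span <= hi_cap and n_block > 1:
            pos[members] = lo + np.round(
                np.linspace(0, span, n_block)).astype(np.int64)
        for m in members:
            flips = rng.random(L) < (1.0 - fidelity)
            geno[m] = np.where(flips, 1 - template, template)
        ld_truth.append({"arm": arm, "members": members.copy(),
                         "fidelity": fidelity})

    # inversions: per-line karyotype; interior sites track the karyotype
    karyotypes, inv_rows = [], []
    line_ids = config.line_ids()
    for j, (arm, start_bp, end_bp, frac) in enumerate(config.inversion_spec):
        carriers = (rng.random(L) < frac).astype(np.int8)
        while carriers.sum() < 4 or (L - carriers.sum()) < 4:
            carriers = (rng.random(L) < frac).astype(np.int8)
        name = f"In_{arm}_{j + 1}"
        inside = np.flatnonzero((arm_of == arm) & (pos >= start_bp) & (pos <= end_bp))
        for m in inside:
            flips = rng.random(L) < (1.0 - config.inversion_fidelity)
            geno[m] = np.where(flips, 1 - carriers, carriers)
        karyotypes.append(InversionKaryotype(
            name=name, arm=arm, start=int(start_bp), end=int(end_bp),
            carriers=dict(zip(line_ids, carriers.astype(int)))))
        inv_rows.append({"name": name, "arm": arm, "start": int(start_bp),
                         "end": int(end_bp), "carrier_fraction": frac,
                         "n_carriers": int(carriers.sum())})

    for i in range(S):
        geno[i] = _normalize_minor(geno[i], rng, kmin)

    bases = np.array(list("ACGT"))
    ref = rng.choice(bases, size=S)
    alt = np.array([rng.choice(bases[bases != r]) for r in ref])
    sites = pd.DataFrame({
        "site_id": [f"{a}_{p}" for a, p in zip(arm_of, pos)],
        "arm": arm_of, "pos": pos, "ref": ref, "alt": alt,
        "coverage": rng.integers(3, 30, size=S),
    })
    gm = GenotypeMatrix(sites=sites, genotypes=geno, lines=line_ids)
    gm.validate()
    truth = TruthRecord(
        ld_blocks=[{"arm": t["arm"], "fidelity": t["fidelity"],
                    "site_ids": [sites.site_id.iloc[m] for m in t["members"]]}
                   for t in ld_truth],
        inversions=pd.DataFrame(inv_rows),
        karyotypes=karyotypes,
    )
    return gm, truth


def _standardized(rng, n, sd) -> np.ndarray:
    """Normal draws rescaled to exact sample SD (n-1 denominator).

    Pinning the realized sample variance removes one layer of sampling
    noise from recovery tests; the n-1 convention matches what the ANOVA
    and REML estimators are unbiased for.
    """
    if sd <= 0 or n < 2:
        return np.zeros(n)
    z = rng.standard_normal(n)
    z = (z - z.mean()) / z.std(ddof=1)
    return z * sd


def simulate_phenotypes(gm: GenotypeMatrix, config: SimConfig):
    """Per-fly trait values from the forward observational model.

    Each value is mu + block + sex + causal SNP effects (optionally
    sex-modulated) + polygenic line effect + sex-by-line + replicate terms
    + a residual whose per-line SD is exp(line log-sigma value); log sigma
    carries its own genetic component, correlated ``rho_mean_sigmaE`` with
    the polygenic mean value.
    """
    config.validate()
    if gm.n_lines != config.n_lines:
        raise ValueError("genotype matrix and config disagree on line count")
    line_ids = config.line_ids()
    blocks = config.line_blocks()
    L = config.n_lines
    sexes = ["F", "M"]
    reps = [f"R{r + 1}" for r in range(config.n_reps_per_block)]
    f = config.flies_per_sex_per_rep

    rows_line = np.repeat(np.arange(L), 2 * len(reps) * f)
    rows_sex = np.tile(np.repeat(np.arange(2), len(reps) * f), L)
    rows_rep = np.tile(np.repeat(np.arange(len(reps)), f), L * 2)
    n_rows = rows_line.size
    block_idx = np.array([int(blocks[l][1:]) - 1 for l in line_ids])
    rows_block = block_idx[rows_line]

    table = pd.DataFrame({
        "fly_id": [f"{line_ids[l]}_{sexes[s]}_{reps[r]}_{i % f + 1}"
                   for i, (l, s, r) in
                   enumerate(zip(rows_line, rows_sex, rows_rep))],
        "line": np.array(line_ids)[rows_line],
        "sex": np.array(sexes)[rows_sex],
        "block": np.array([f"B{b + 1}" for b in range(config.n_blocks)])[rows_block],
        "replicate": np.array(reps)[rows_rep],
    })

    sigma_p = np.sqrt(config.var_line + config.var_sexline
                      + config.var_env_mean)
    causal_mean_rows, causal_var_rows, line_rows = [], [], []
    targets = {}
    for t_i, trait in enumerate(config.traits):
        rng = _rng(config, _RNG_PHENO, t_i)

        # --- causal mean effects
        g_causal = np.zeros(L)
        sl_causal = np.zeros((L, 2))  # per line x sex additions
        chosen_mean = (rng.choice(gm.n_sites, size=config.n_causal_mean,
                                  replace=False)
                       if config.n_causal_mean else np.array([], dtype=int))
        for j, site in enumerate(chosen_mean):
            a = config.effect_sizes_mean[j % len(config.effect_sizes_mean)] * sigma_p
            x = gm.genotypes[site].astype(float)
            x = np.where(x < 0, 0.0, x)
            centered = 2.0 * a * (x - x.mean())
            u = rng.random()
            if u < config.frac_sex_specific:
                sex = rng.integers(0, 2)
                mode = "male" if sex == 1 else "female"
                sl_causal[:, sex] += centered
            elif u < config.frac_sex_specific + config.frac_sex_antagonistic:
                mode = "antagonistic"
                sl_causal[:, 0] -= centered
                sl_causal[:, 1] += centered
            else:
                mode = "both"
                g_causal += centered
            causal_mean_rows.append({
                "trait": trait, "site_id": gm.sites.site_id.iloc[site],
                "a": a, "a_over_sigma_p": a / sigma_p, "sex_mode": mode,
                "maf": float(gm.maf()[site])})

        # --- causal variance effects (log sigma_E multipliers)
        h_causal = np.zeros(L)
        chosen_var = (rng.choice(gm.n_sites, size=config.n_causal_var,
                                 replace=False)
                      if config.n_causal_var else np.array([], dtype=int))
        for j, site in enumerate(chosen_var):
            mult = config.effect_sizes_var[j % len(config.effect_sizes_var)]
            x = gm.genotypes[site].astype(float)
            x = np.where(x < 0, 0.0, x)
            h_causal += np.log(mult) * (x - x.mean())
            causal_var_rows.append({
                "trait": trait, "site_id": gm.sites.site_id.iloc[site],
                "sigma_multiplier": mult, "maf": float(gm.maf()[site])})

        # --- polygenic mean and correlated log sigma
        var_poly = max(config.var_line - float(np.var(g_causal)), 0.0)
        g_poly = _standardized(rng, L, np.sqrt(var_poly))
        w = rng.standard_normal(L)
        if var_poly > 0:
            g_std = g_poly / np.sqrt(var_poly)
            z = (config.rho_mean_sigmaE * g_std
                 + np.sqrt(max(1 - config.rho_mean_sigmaE ** 2, 0.0)) * w)
        else:
            z = w
        if config.var_log_sigma > 0:
            z = (z - z.mean()) / (z.std(ddof=0) or 1.0)
            h_poly = z * np.sqrt(config.var_log_sigma)
        else:
            h_poly = np.zeros(L)
        h = h_causal + h_poly
        h = h - h.mean() - np.var(h)      # keeps E[exp(2h)] near 1
        sigma_line = np.sqrt(config.var_env_mean) * np.exp(h)

        g_line = g_causal + g_poly
        sl = (_standardized(rng, 2 * L, np.sqrt(config.var_sexline))
              .reshape(L, 2) + sl_causal)
        b_eff = _standardized(rng, config.n_blocks, np.sqrt(config.var_block))
        sb_eff = (_standardized(rng, 2 * config.n_blocks,
                                np.sqrt(config.var_sexblock))
                  .reshape(2, config.n_blocks))
        r_eff = rng.normal(0.0, np.sqrt(config.var_rep) if config.var_rep > 0 else 0.0,
                           size=(config.n_blocks, len(reps)))
        sr_eff = rng.normal(0.0, np.sqrt(config.var_sexrep) if config.var_sexrep > 0 else 0.0,
                            size=(2, config.n_blocks, len(reps)))
        rl_eff = rng.normal(0.0, np.sqrt(config.var_repline) if config.var_repline > 0 else 0.0,
                            size=(L, len(reps)))
        srl_eff = rng.normal(0.0, np.sqrt(config.var_sexrepline) if config.var_sexrepline > 0 else 0.0,
                             size=(2, L, len(reps)))
        if config.var_rep <= 0:
            r_eff[:] = 0.0
        if config.var_sexrep <= 0:
            sr_eff[:] = 0.0
        if config.var_repline <= 0:
            rl_eff[:] = 0.0
        if config.var_sexrepline <= 0:
            srl_eff[:] = 0.0

        sex_term = np.where(rows_sex == 1, config.sex_diff / 2.0,
                            -config.sex_diff / 2.0)
        values = (config.mu
                  + b_eff[rows_block]
                  + sb_eff[rows_sex, rows_block]
                  + sex_term
                  + g_line[rows_line]
                  + sl[rows_line, rows_sex]
                  + r_eff[rows_block, rows_rep]
                  + sr_eff[rows_sex, rows_block, rows_rep]
                  + rl_eff[rows_line, rows_rep]
                  + srl_eff[rows_sex, rows_line, rows_rep]
                  + rng.standard_normal(n_rows) * sigma_line[rows_line])
        table[trait] = values

        var_l = float(np.var(g_line, ddof=1))
        var_sl = float(np.var(sl, ddof=1))
        var_e = float(config.var_env_mean * np.mean(np.exp(2 * h)))
        env_sum = (var_e + config.var_block + config.var_sexblock
                   + config.var_rep + config.var_sexrep + config.var_repline
                   + config.var_sexrepline)
        targets[trait] = {
            "var_line": var_l, "var_sexline": var_sl,
            "var_env_mean": var_e,
            "h2_pooled": ((var_l + var_sl) / (var_l + var_sl + env_sum)
                          if (var_l + var_sl + env_sum) > 0 else np.nan),
            "var_log_sigma": float(np.var(h, ddof=1)),
            "rho_mean_sigmaE": config.rho_mean_sigmaE,
        }
        for i, line in enumerate(line_ids):
            line_rows.append({"trait": trait, "line": line,
                              "g_mean": g_line[i], "log_sigma": h[i],
                              "sigma_e": sigma_line[i],
                              "sl_F": sl[i, 0], "sl_M": sl[i, 1]})

    truth = TruthRecord(
        causal_mean=pd.DataFrame(causal_mean_rows),
        causal_var=pd.DataFrame(causal_var_rows),
        variance_targets=targets,
        line_values=pd.DataFrame(line_rows),
    )
    return table, truth


def simulate_activity(config: SimConfig, line_rates: Optional[dict] = None,
                      initial_state: str = "stationary"):
    """Two-state (sleep/wake) Markov streams for every fly in the design.

    ``line_rates`` optionally maps line id -> phase -> (wake_to_sleep,
    sleep_to_wake), overriding the global ``config.markov_rates``.  Wake
    minutes carry counts >= 1; sleep minutes carry 0.  A ``dead_fraction``
    of flies receives an all-zero suffix of at least 24 h.
    """
    from .sleep_metrics import ActivityStream

    config.validate()
    rng = _rng(config, _RNG_ACT)
    line_ids = config.line_ids()
    blocks = config.line_blocks()
    sexes = ["F", "M"]
    reps = [f"R{r + 1}" for r in range(config.n_reps_per_block)]
    f = config.flies_per_sex_per_rep

    meta = []
    for line in line_ids:
        for rep in reps:
            for sex in sexes:
                for i in range(f):
                    meta.append((line, sex, rep, i))
    n_flies = len(meta)
    total = config.n_days * 1440

    def _rates(line, phase):
        if line_rates and line in line_rates:
            return line_rates[line][phase]
        r = config.markov_rates[phase]
        return r["wake_to_sleep"], r["sleep_to_wake"]

    p_ws = np.empty((n_flies, 2))  # [:, 0]=day, [:, 1]=night
    p_sw = np.empty((n_flies, 2))
    for i, (line, _, _, _) in enumerate(meta):
        for j, phase in enumerate(("day", "night")):
            p_ws[i, j], p_sw[i, j] = _rates(line, phase)

    # streams start at lights-on, so phase is a pure function of the minute
    phase_night = (np.arange(total) % 1440) >= 720
    start_phase = int(phase_night[0])
    denom = p_ws[:, start_phase] + p_sw[:, start_phase]
    stationary = np.divide(p_ws[:, start_phase], denom,
                           out=np.zeros(n_flies), where=denom > 0)
    if initial_state == "sleep":
        asleep = np.ones(n_flies, dtype=bool)
    elif initial_state == "wake":
        asleep = np.zeros(n_flies, dtype=bool)
    else:
        asleep = rng.random(n_flies) < stationary

    sleep_mat = np.empty((n_flies, total), dtype=bool)
    for m in range(total):
        ph = int(phase_night[m])
        sleep_mat[:, m] = asleep
        u = rng.random(n_flies)
        asleep = np.where(asleep, u >= p_sw[:, ph], u < p_ws[:, ph])

    counts = np.where(sleep_mat, 0,
                      1 + rng.poisson(config.activity_rate,
                                      size=(n_flies, total)))

    n_dead = int(round(config.dead_fraction * n_flies))
    if n_dead:
        dead_idx = rng.choice(n_flies, size=n_dead, replace=False)
        for i in dead_idx:
            cut = int(rng.integers(1440, max(total - 1440, 1441)))
            counts[i, total - cut:] = 0

    streams = []
    for i, (line, sex, rep, k) in enumerate(meta):
        monitor = f"{line}_{rep}"
        channel = (0 if sex == "F" else f) + k
        streams.append(ActivityStream(
            fly_id=f"{line}_{sex}_{rep}_{k + 1}", line=line, sex=sex,
            block=blocks[line], replicate=rep, counts=counts[i],
            channel=channel, monitor=monitor,
            start_minute_of_day=config.lights_on_minute,
            lights_on_minute=config.lights_on_minute,
        ))
    return streams


def config_for_heritability(h2: float, config: Optional[SimConfig] = None,
                            sexline_ratio: float = 0.25,
                            **overrides) -> SimConfig:
    """Config whose polygenic variances hit a target pooled heritability.

    Solves (VL + VSL) / (VL + VSL + VE) = h2 with VSL = sexline_ratio * VL
    and VE the sum of the non-genetic variance sources.
    """
    if not 0 < h2 < 1:
        raise ValueError("h2 must lie in (0, 1)")
    base = config if config is not None else SimConfig()
    base = replace(base, **overrides)
    env = (base.var_env_mean + base.var_block + base.var_sexblock
           + base.var_rep + base.var_sexrep + base.var_repline
           + base.var_sexrepline)
    total_g = h2 / (1.0 - h2) * env
    var_line = total_g / (1.0 + sexline_ratio)
    return replace(base, var_line=var_line,
                   var_sexline=sexline_ratio * var_line)
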
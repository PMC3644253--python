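"""Variance partitioning, heritability and genetic correlations."""
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from sleepqg._stats import SingularDesignError
from sleepqg.quantgen import (VarianceComponents, control_block_check,
                              cross_sex_rg, fit_variance_model, heritability,
                              line_means_by_line, trait_rg, wolbachia_adjust)
from sleepqg.sleep_metrics import cve_table, line_sex_means
from sleepqg.synthetic import (SimConfig, config_for_heritability,
                               simulate_genotypes, simulate_phenotypes)


def _vc(components, mode="pooled"):
    return VarianceComponents(trait="t", scale="mean", mode=mode,
                              components=components, pvalues={}, n_obs=0,
                              method="test")


def _sim(cfg):
    gm, _ = simulate_genotypes(cfg)
    return simulate_phenotypes(gm, cfg)


class TestFitVarianceModel:
    def test_balanced_toy_matches_hand_ems(self, rng):
        # 2 blocks x 2 lines x 2 reps x 2 flies, per-sex reduced model:
        # solve the EMS equations independently from group mean squares
        rows = []
        for b in range(2):
            for l in range(2):
                for r in range(2):
                    for i in range(2):
                        for sex in ("M",):
                            rows.append({
                                "block": f"B{b}", "line": f"L{b}{l}",
                                "replicate": f"R{r}", "sex": sex,
                                "y": rng.normal(100 + 10 * b + 5 * l, 2.0)})
        df = pd.DataFrame(rows)
        vc = fit_variance_model(df, "y", mode="M", method="ems")

        grand = df["y"].mean()
        n = len(df)
        u = {}
        for name, cols in (("b", ["block"]), ("l", ["block", "line"]),
                           ("r", ["block", "replicate"]),
                           ("rl", ["block", "replicate", "line"])):
            g = df.groupby(cols)["y"]
            u[name] = float((g.size() * g.mean() ** 2).sum())
        cf = n * grand ** 2
        ss_b = u["b"] - cf
        ss_l = u["l"] - cf - ss_b
        ss_r = u["r"] - cf - ss_b
        ss_rl = u["rl"] - cf - ss_b - ss_l - ss_r
        ss_e = float((df["y"] ** 2).sum()) - cf - ss_b - ss_l - ss_r - ss_rl
        ms = {"b": ss_b / 1, "l": ss_l / 2, "r": ss_r / 2, "rl": ss_rl / 2,
              "e": ss_e / 8}
        s_e = ms["e"]
        s_rl = (ms["rl"] - s_e) / 2
        s_r = (ms["r"] - s_e - 2 * s_rl) / 4
        s_l = (ms["l"] - s_e - 2 * s_rl) / 4
        s_b = (ms["b"] - s_e - 2 * s_rl - 4 * s_r - 4 * s_l) / 8
        assert vc.components["residual"] == pytest.approx(s_e)
        assert vc.components["rep_line"] == pytest.approx(s_rl)
        assert vc.components["rep"] == pytest.approx(s_r)
        assert vc.components["line"] == pytest.approx(s_l)
        assert vc.components["block"] == pytest.approx(s_b)

    def test_identical_flies_give_zero_components(self):
        cfg = SimConfig(n_lines=8, n_blocks=2, n_reps_per_block=2,
                        flies_per_sex_per_rep=2, n_snps=10, var_line=0,
                        var_sexline=0, var_env_mean=0, seed=1,
                        traits=("night_sleep",))
        phen, _ = _sim(cfg)
        vc = fit_variance_model(phen, "night_sleep")
        for v in vc.components.values():
            assert v == pytest.approx(0.0, abs=1e-9)

    def test_null_line_variance_rarely_significant(self):
        cfg = SimConfig(n_lines=16, n_blocks=2, n_reps_per_block=2,
                        flies_per_sex_per_rep=4, n_snps=10, var_line=0,
                        var_sexline=0, var_env_mean=100.0,
                        traits=("night_sleep",))
        hits, est = 0, []
        for seed in range(50):
            phen, _ = _sim(replace(cfg, seed=seed))
            vc = fit_variance_model(phen, "night_sleep")
            est.append(vc.component("line"))
            if vc.pvalues["line"] < 0.05:
                hits += 1
        assert hits <= 5          # >= 90% non-significant at alpha = 0.05
        assert abs(np.mean(est)) < 5.0

    def test_reml_matches_ems_on_interior_balanced_fit(self):
        cfg = SimConfig(n_lines=16, n_blocks=4, n_reps_per_block=3,
                        flies_per_sex_per_rep=3, n_snps=10, seed=5,
                        traits=("night_sleep",), var_block=3000,
                        var_sexblock=800, var_rep=500, var_sexrep=400,
                        var_repline=300, var_sexrepline=350, var_line=800,
                        var_sexline=600, var_env_mean=50)
        phen, _ = _sim(cfg)
        ems = fit_variance_model(phen, "night_sleep", method="ems")
        assert min(ems.components.values()) > 0  # interior solution
        reml = fit_variance_model(phen, "night_sleep", method="reml")
        for name, v in ems.components.items():
            assert reml.components[name] == pytest.approx(v, rel=1e-6)

    def test_singular_designs_rejected(self):
        df = pd.DataFrame({"block": ["B1"] * 4, "line": ["L1"] * 4,
                           "sex": ["M", "F"] * 2,
                           "replicate": ["R1", "R1", "R2", "R2"],
                           "y": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(SingularDesignError):
            fit_variance_model(df, "y")

    def test_component_recovery_at_panel_design(self):
        cfg = config_for_heritability(0.54, n_lines=168, n_snps=10,
                                      traits=("night_sleep",))
        ests = {"line": [], "sex_line": [], "residual": []}
        for seed in range(8):
            phen, truth = _sim(replace(cfg, seed=seed))
            vc = fit_variance_model(phen, "night_sleep")
            for k in ests:
                ests[k].append(vc.components[k])
        t = {"line": cfg.var_line, "sex_line": cfg.var_sexline,
             "residual": cfg.var_env_mean}
        for k, vals in ests.items():
            assert abs(np.mean(vals) - t[k]) <= 0.05 * t[k]


class TestHeritability:
    def test_half(self):
        vc = _vc({"line": 1.0, "sex_line": 0.0, "residual": 1.0})
        assert heritability(vc) == pytest.approx(0.5)

    def test_zero_line_variance(self):
        vc = _vc({"line": 0.0, "sex_line": 0.0, "residual": 1.0})
        assert heritability(vc) == 0.0

    def test_negative_components_truncated(self):
        vc = _vc({"line": 1.0, "sex_line": -0.5, "residual": 1.0})
        assert heritability(vc) == pytest.approx(0.5)

    def test_undefined_when_all_zero(self):
        assert np.isnan(heritability(_vc({"line": 0.0, "residual": 0.0})))

    def test_affine_invariance(self):
        cfg = SimConfig(n_lines=12, n_blocks=2, n_reps_per_block=2,
                        flies_per_sex_per_rep=3, n_snps=10, seed=9,
                        traits=("night_sleep",))
        phen, _ = _sim(cfg)
        h0 = heritability(fit_variance_model(phen, "night_sleep"))
        shifted = phen.copy()
        shifted["night_sleep"] = 3.7 * shifted["night_sleep"] + 123.0
        h1 = heritability(fit_variance_model(shifted, "night_sleep"))
        assert h1 == pytest.approx(h0, rel=1e-9)

    def test_per_sex_formula(self):
        vc = _vc({"line": 2.0, "rep": 1.0, "residual": 1.0}, mode="M")
        assert heritability(vc) == pytest.approx(0.5)


class TestCrossSexRg:
    def _fits(self, cfg):
        phen, _ = _sim(cfg)
        return (fit_variance_model(phen, "night_sleep", mode="pooled"),
                fit_variance_model(phen, "night_sleep", mode="M"),
                fit_variance_model(phen, "night_sleep", mode="F"))

    def test_identical_sex_effects_give_unity(self):
        cfg = SimConfig(n_lines=40, n_blocks=2, n_reps_per_block=2,
                        flies_per_sex_per_rep=8, n_snps=10, seed=3,
                        var_line=200.0, var_sexline=0.0, var_env_mean=50.0,
                        traits=("night_sleep",))
        r, raw = cross_sex_rg(*self._fits(cfg))
        assert r == pytest.approx(1.0, abs=0.05)

    def test_independent_sex_effects_give_zero(self):
        cfg = SimConfig(n_lines=40, n_blocks=2, n_reps_per_block=2,
                        flies_per_sex_per_rep=8, n_snps=10, var_line=0.0,
                        var_sexline=300.0, var_env_mean=50.0,
                        traits=("night_sleep",))
        vals = [cross_sex_rg(*self._fits(replace(cfg, seed=s)))[1]
                for s in range(20)]
        assert abs(np.nanmean(vals)) < 0.12

    def test_recovers_planted_value(self):
        # r_MF = VL / (VL + VSL); plant VSL for a 0.84 design point
        target = 0.84
        vl = 300.0
        vsl = vl * (1 / target - 1)
        cfg = SimConfig(n_lines=100, n_blocks=2, n_reps_per_block=2,
                        flies_per_sex_per_rep=8, n_snps=10, var_line=vl,
                        var_sexline=vsl, var_env_mean=100.0,
                        traits=("night_sleep",))
        vals = [cross_sex_rg(*self._fits(replace(cfg, seed=s)))[0]
                for s in range(10)]
        assert np.mean(vals) == pytest.approx(target, abs=0.1)

    def test_mismatched_fits_rejected(self):
        a = _vc({"line": 1.0})
        b = VarianceComponents(trait="other", scale="mean", mode="M",
                               components={"line": 1.0}, pvalues={}, n_obs=0,
                               method="test")
        with pytest.raises(ValueError):
            cross_sex_rg(a, b, b)


class TestTraitRg:
    def test_proportional_traits(self, rng):
        x = pd.Series(rng.normal(size=20),
                      index=[f"L{i}" for i in range(20)])
        assert trait_rg(x, 2 * x) == pytest.approx(1.0)

    def test_independent_traits_near_zero(self, rng):
        vals = []
        for _ in range(20):
            x = pd.Series(rng.normal(size=50),
                          index=[f"L{i}" for i in range(50)])
            y = pd.Series(rng.normal(size=50), index=x.index)
            vals.append(trait_rg(x, y))
        assert abs(np.mean(vals)) < 0.1

    def test_zero_variance_undefined(self):
        x = pd.Series([1.0, 1.0, 1.0], index=list("abc"))
        y = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        assert np.isnan(trait_rg(x, y))

    def test_too_few_lines_rejected(self):
        x = pd.Series([1.0, 2.0], index=list("ab"))
        with pytest.raises(ValueError):
            trait_rg(x, x)

    def test_mean_cve_correlation_recovered(self):
        cfg = SimConfig(n_lines=168, n_snps=10, var_line=2500.0,
                        var_sexline=100.0, var_env_mean=10000.0,
                        var_log_sigma=0.09, rho_mean_sigmaE=-0.8,
                        traits=("night_sleep",))
        vals = []
        for seed in range(5):
            c = replace(cfg, seed=seed)
            gm, _ = simulate_genotypes(c)
            phen, _ = simulate_phenotypes(gm, c)
            lsm = line_sex_means(phen, ["night_sleep"])
            cve = cve_table(phen, ["night_sleep"])
            cve_means = cve.groupby("line")["night_sleep"].mean()
            vals.append(trait_rg(line_means_by_line(lsm, "night_sleep"),
                                 cve_means))
        # oracle: line-level draws with finite-sample CV over 8-fly cells
        orng = np.random.default_rng(5150)
        oracle = []
        for _ in range(60):
            g = orng.normal(0, 50.0, 168)
            z = (-0.8 * g / 50.0
                 + np.sqrt(1 - 0.64) * orng.standard_normal(168))
            h = z * 0.3
            h = h - h.mean() - np.var(h)
            sigma = 100.0 * np.exp(h)
            cvs = np.empty((168, 8))
            for cell in range(8):  # 2 sexes x 4 reps
                draws = (500.0 + g[:, None]
                         + sigma[:, None] * orng.standard_normal((168, 8)))
                cvs[:, cell] = 100.0 * draws.std(axis=1, ddof=1) / draws.mean(axis=1)
            oracle.append(np.corrcoef(500.0 + g, cvs.mean(axis=1))[0, 1])
        assert np.mean(vals) < -0.4
        assert np.mean(vals) == pytest.approx(np.mean(oracle), abs=0.15)


class TestWolbachia:
    def _lsm(self, rng, n_lines=30, shift_m=0.0):
        lines = [f"L{i:03d}" for i in range(n_lines)]
        status = {l: int(i < n_lines // 2) for i, l in enumerate(lines)}
        rows = []
        for l in lines:
            for sex in ("F", "M"):
                v = rng.normal(500, 10)
                if sex == "M" and status[l]:
                    v += shift_m
                rows.append({"line": l, "sex": sex, "night_sleep": v})
        return pd.DataFrame(rows), status

    def test_planted_male_shift_is_removed(self, rng):
        lsm, status = self._lsm(rng, shift_m=40.0)
        adj, report = wolbachia_adjust(lsm, status, ["night_sleep"])
        rep = report.iloc[0]
        assert rep["adjusted_M"]
        males = adj[adj.sex == "M"].set_index("line")["night_sleep"]
        inf = pd.Series(status)
        class_means = males.groupby(inf.loc[males.index].values).mean()
        assert class_means[0] == pytest.approx(class_means[1], abs=1e-9)

    def test_grand_mean_preserved_exactly(self, rng):
        lsm, status = self._lsm(rng, shift_m=40.0)
        adj, _ = wolbachia_adjust(lsm, status, ["night_sleep"])
        for sex in ("M", "F"):
            assert (adj[adj.sex == sex]["night_sleep"].mean()
                    == pytest.approx(lsm[lsm.sex == sex]["night_sleep"].mean()))

    def test_null_rarely_adjusts(self, rng):
        adjusted = 0
        for _ in range(50):
            lsm, status = self._lsm(rng)
            _, report = wolbachia_adjust(lsm, status, ["night_sleep"])
            adjusted += int(report["adjusted_M"].iloc[0]
                            or report["adjusted_F"].iloc[0])
        assert adjusted <= 8  # ~2 * alpha * 50 with slack

    def test_single_class_skipped(self, rng):
        lsm, _ = self._lsm(rng)
        status = {l: 1 for l in lsm["line"].unique()}
        adj, report = wolbachia_adjust(lsm, status, ["night_sleep"])
        assert report["note"].iloc[0] == "single infection class"
        pd.testing.assert_frame_equal(adj, lsm)


class TestControlBlockCheck:
    def _control(self, seed, block_shift=0.0):
        cfg = SimConfig(n_lines=8, n_blocks=4, n_reps_per_block=2,
                        flies_per_sex_per_rep=4, n_snps=10, seed=seed,
                        var_line=0.0, var_sexline=0.0, var_env_mean=100.0,
                        traits=("night_sleep",))
        phen, _ = _sim(cfg)
        # collapse to a single "control line" measured in every block
        phen = phen.copy()
        phen["line"] = "control"
        if block_shift:
            shift = phen["block"].map(
                lambda b: block_shift * 10.0 * int(b[1:]))
            phen["night_sleep"] = phen["night_sleep"] + shift
        return phen

    def test_null_blocks_rarely_significant(self):
        hits = 0
        for seed in range(50):
            p = control_block_check(self._control(seed), "night_sleep")
            if p["block"] < 0.05:
                hits += 1
        assert hits <= 7

    def test_planted_block_shift_detected(self):
        hits = 0
        for seed in range(20):
            p = control_block_check(self._control(seed, block_shift=1.0),
                                    "night_sleep")
            if p["block"] < 0.05:
                hits += 1
        assert hits >= 18

    def test_single_block_rejected(self):
        df = self._control(0)
        df = df[df.block == "B1"]
        with pytest.raises(SingularDesignError):
            control_block_check(df, "night_sleep")
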
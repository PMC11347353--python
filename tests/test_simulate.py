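"""Tests for the synthetic-data generator."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pulsechase import screens, simulate as sim
from pulsechase.assays import StandardSeries, fit_standard_curve, quantify_sugar
from pulsechase.isotope import allocation_table
from pulsechase.pipeline import build_sugar_profiles

ORGANS = {
    "leaves": sim.OrganSpec(40.0, 0.45),
    "branches": sim.OrganSpec(30.0, 0.47),
    "peels": sim.OrganSpec(25.0, 0.44),
    "seed_kernels": sim.OrganSpec(15.0, 0.50),
}


def _cfg(**kw):
    months = kw.pop(
        "months",
        {"Aug": sim.MonthSpec(target_allocation_percent=dict(
            branches=7.70, leaves=54.55, peels=16.54, seed_kernels=21.21))},
    )
    defaults = dict(organs=ORGANS, months=months, noise_sd_delta=0.0, assay_noise_cv=0.0)
    defaults.update(kw)
    return sim.SimConfig(**defaults)


class TestPulseChase:
    def test_conservation_at_every_timestep(self):
        cfg = _cfg(timepoints_h=tuple(float(t) for t in range(0, 73, 4)))
        _, _, truth = sim.simulate_pulse_chase(cfg)
        organs = truth.isotope.groupby(["month", "time_h"])["excess13c_mg"].sum()
        merged = organs.reset_index().merge(truth.respired, on=["month", "time_h"])
        total = merged["excess13c_mg"] + merged["respired_mg"]
        pulse = truth.pulse_mg["Aug"]
        assert np.max(np.abs(total / pulse - 1)) < 1e-9

    def test_all_rates_zero_keeps_label_in_source(self):
        cfg = _cfg(months={"Aug": sim.MonthSpec(
            transfer_rates_per_h={}, source_respiration_per_h=0.0)})
        _, _, truth = sim.simulate_pulse_chase(cfg)
        end = truth.isotope[truth.isotope.time_h == 72.0].set_index("organ")
        assert end.loc["leaves", "allocation_percent"] == pytest.approx(100.0)
        for organ in ("branches", "peels", "seed_kernels"):
            assert end.loc[organ, "excess13c_mg"] == 0.0

    def test_symmetric_sinks_approach_equal_thirds(self):
        rates = {o: 0.05 for o in ("branches", "peels", "seed_kernels")}
        cfg = _cfg(
            months={"Aug": sim.MonthSpec(transfer_rates_per_h=rates,
                                         source_respiration_per_h=0.0)},
            timepoints_h=(0.0, 400.0),
        )
        _, _, truth = sim.simulate_pulse_chase(cfg)
        end = truth.isotope[truth.isotope.time_h == 400.0].set_index("organ")
        for organ in rates:
            assert end.loc[organ, "allocation_percent"] == pytest.approx(100 / 3, abs=0.01)

    def test_unstable_step_rejected(self):
        cfg = _cfg(
            months={"Aug": sim.MonthSpec(
                transfer_rates_per_h={"branches": 50.0},
                source_respiration_per_h=0.0)},
        )
        with pytest.raises(ValueError, match="stability"):
            sim.simulate_pulse_chase(cfg)

    def test_noiseless_readings_recover_target_allocation(self):
        cfg = _cfg()
        readings, pools, _ = sim.simulate_pulse_chase(cfg)
        table = allocation_table(readings, pools, cfg.constants).set_index("organ")
        target = dict(branches=7.70, leaves=54.55, peels=16.54, seed_kernels=21.21)
        for organ, pct in target.items():
            assert table.loc[organ, "allocation_percent"] == pytest.approx(pct, abs=0.05)

    def test_determinism_byte_identical(self, cfg):
        out1 = sim.simulate_pulse_chase(cfg)[0].to_csv(index=False)
        out2 = sim.simulate_pulse_chase(cfg)[0].to_csv(index=False)
        assert out1 == out2

    def test_different_seeds_differ(self, cfg):
        a = sim.simulate_pulse_chase(cfg)[0]
        b = sim.simulate_pulse_chase(cfg.with_(seed=cfg.seed + 1))[0]
        assert not a.equals(b)


class TestRateSolver:
    def test_solution_reproduces_targets_in_closed_form(self):
        targets = dict(branches=7.70, leaves=54.55, peels=16.54, seed_kernels=21.21)
        rates, r_leaf = sim.transfer_rates_for_allocation(targets, "leaves")
        K = r_leaf + sum(rates.values())
        f = np.exp(-K * 72.0)
        organs_share = f + (1 - f) * sum(rates.values()) / K
        assert f / organs_share * 100 == pytest.approx(54.55, rel=1e-9)
        for organ, k in rates.items():
            share = (1 - f) * k / K / organs_share * 100
            assert share == pytest.approx(targets[organ], rel=1e-9)

    def test_requires_source_in_targets(self):
        with pytest.raises(ValueError):
            sim.transfer_rates_for_allocation({"branches": 50, "peels": 50}, "leaves")


class TestAssaySimulation:
    def test_zero_content_zero_noise_hits_calibration_zero(self):
        truth = pd.DataFrame(
            [("leaves", "Jul", 0.0, 0.0, 0.0, 0.0, 0.0)],
            columns=["organ", "month", "sucrose", "glucose", "fructose",
                     "soluble_sugar", "starch"],
        )
        cfg = _cfg(n_replicates=1)
        col, _, _ = sim.simulate_assays(truth, cfg)
        sugar = col[col.assay == "soluble_sugar"].iloc[0]
        starch = col[col.assay == "starch"].iloc[0]
        assert sugar.absorbance_620 == pytest.approx(-0.07, abs=1e-12)
        assert starch.absorbance_620 == pytest.approx(-0.0295, abs=1e-12)

    def test_zero_noise_round_trip_recovers_contents(self):
        cfg = _cfg()
        col, std, hplc = sim.simulate_assays(None, cfg)
        profiles = build_sugar_profiles(col, std, hplc)
        merged = profiles.merge(
            sim.DEFAULT_SUGAR_TRUTH, on=["organ", "month"], suffixes=("", "_true")
        )
        for c in ("sucrose", "glucose", "fructose", "soluble_sugar", "starch"):
            assert np.abs(merged[c] - merged[f"{c}_true"]).max() < 1e-9

    def test_september_seed_sucrose_peak_round_trips(self):
        # the 25.93 mg/g FW fixture value survives the full quantify path
        cfg = _cfg()
        col, std, hplc = sim.simulate_assays(None, cfg)
        profiles = build_sugar_profiles(col, std, hplc)
        sep = profiles[(profiles.organ == "seed_kernels") & (profiles.month == "Sep")]
        assert sep["sucrose"].iloc[0] == pytest.approx(25.93, abs=1e-9)

    def test_noisy_recovery_within_three_sigma_of_injected_noise(self):
        # within the calibration range (extract conc >= lowest standard,
        # i.e. content >= 6.25 mg/g at the default bookkeeping); below it
        # the intercept uncertainty inflates the relative error
        cfg = _cfg(assay_noise_cv=0.02)
        col, std, hplc = sim.simulate_assays(None, cfg)
        profiles = build_sugar_profiles(col, std, hplc)
        merged = profiles.merge(
            sim.DEFAULT_SUGAR_TRUTH, on=["organ", "month"], suffixes=("", "_true")
        )
        rel = []
        for c in ("sucrose", "glucose", "fructose"):
            in_range = merged[merged[f"{c}_true"] >= 6.25]
            rel.append(np.abs(in_range[c] / in_range[f"{c}_true"] - 1))
        rel = pd.concat(rel)
        assert rel.mean() < 3 * 0.02


class TestExpressionSimulation:
    SUCROSE = {"Jul": 4.2, "Aug": 9.8, "Sep": 25.93, "Oct": 22.5}

    def test_near_perfect_target_gives_near_unit_sample_r(self):
        cfg = _cfg()
        expr, planted = sim.simulate_expression(
            cfg, self.SUCROSE, n_genes=5, n_planted=5, target_r=0.999
        )
        out = screens.gene_sucrose_screen(expr, self.SUCROSE)
        assert out["r"].min() > 0.99

    def test_planted_mean_r_near_target(self):
        # Monte-Carlo over seeds: mild attenuation from the exp transform
        rs = []
        for seed in range(20):
            cfg = _cfg(seed=seed)
            expr, planted = sim.simulate_expression(
                cfg, self.SUCROSE, n_genes=30, n_planted=10, target_r=0.9
            )
            out = screens.gene_sucrose_screen(expr, self.SUCROSE).set_index("gene_id")
            rs.extend(out.loc[planted, "r"].to_list())
        assert np.mean(rs) == pytest.approx(0.9, abs=0.1)

    def test_background_null_matches_t_distribution(self):
        cfg = _cfg()
        expr, planted = sim.simulate_expression(
            cfg, self.SUCROSE, n_genes=800, n_planted=0, target_r=0.5
        )
        out = screens.gene_sucrose_screen(expr, self.SUCROSE)
        n = 4 * cfg.n_expr_replicates
        q95_obs = np.quantile(np.abs(out["r"]), 0.95)
        t975 = stats.t.ppf(0.975, n - 2)
        q95_null = t975 / np.sqrt(t975**2 + n - 2)
        assert q95_obs == pytest.approx(q95_null, abs=0.08)

    def test_planted_exceeds_genes_rejected(self):
        with pytest.raises(ValueError):
            sim.simulate_expression(_cfg(), self.SUCROSE, n_genes=5, n_planted=6)


class TestEnzymeSimulation:
    def test_zero_cv_reproduces_profiles_exactly(self):
        cfg = _cfg(n_replicates=3)
        panels = sim.simulate_enzyme_panels(cfg)
        sep_seed = panels[(panels.organ == "seed_kernels") & (panels.month == "Sep")]
        assert (sep_seed["SuSy_II"] == 2071.62).all()

    def test_missing_assay_stays_missing(self):
        panels = sim.simulate_enzyme_panels(_cfg())
        assert panels.loc[panels.organ == "peels", "NI"].isna().all()

    def test_monotone_profile_monotone_means(self):
        prof = pd.DataFrame(
            dict(organ=["x"] * 4, month=["Jul", "Aug", "Sep", "Oct"],
                 SuSy_II=[1.0, 2.0, 3.0, 4.0])
        )
        panels = sim.simulate_enzyme_panels(_cfg(), prof)
        means = panels.groupby("month", sort=False)["SuSy_II"].mean()
        assert means.is_monotonic_increasing

    def test_fixture_peak_survives_letters_and_correlation(self):
        cfg = _cfg(assay_noise_cv=0.05)
        panels = sim.simulate_enzyme_panels(cfg)
        sub = panels[panels.organ == "seed_kernels"]
        groups = {m: g["SuSy_II"].to_numpy() for m, g in sub.groupby("month")}
        letters = screens.anova_lsd_letters(groups)
        assert set(letters) == {"Jul", "Aug", "Sep", "Oct"}
        col, std, hplc = sim.simulate_assays(None, cfg)
        profiles = build_sugar_profiles(col, std, hplc)
        profiles["replicate"] = (
            profiles["sample_id"].str.extract(r"r(\d+)$")[0].astype(int)
        )
        mats = screens.enzyme_sugar_matrix(panels, profiles)
        assert "seed_kernels" in mats and not mats["seed_kernels"].empty
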
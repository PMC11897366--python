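"""Log-response ratios, BCa intervals, the stability mixed model, BACI, contrasts."""

import numpy as np
import pandas as pd
import pytest

import biofilmstab as bs
from biofilmstab.config import (
    BiomassEffects,
    RegimeDesign,
    SyntheticWorldConfig,
    TreatmentEffects,
)
from biofilmstab.errors import InsufficientDataError, ValidationError
from biofilmstab.stability import (
    _dimensions_from_params,
    _fast_reml,
    artifact_control_test,
    baci_analysis,
    bca_interval,
    control_vs_extreme_prephase,
    extract_dimensions,
    fit_stability_model,
    log_response_ratio,
    phase1_trend_contrasts,
)
from biofilmstab.synthesis import generate_biomass


def _biomass_frame(rows):
    return pd.DataFrame(rows, columns=["plot_id", "subplot_id", "treatment", "date", "phase", "biomass"])


def _simple_biomass(treated_value, control_value=10.0, dates=(0, 7)):
    rows = []
    for d in dates:
        for p in ("c1", "c2"):
            rows.append([p, "s1", "control", d, "post", control_value])
        rows.append(["t1", "s1", "warmed", d, "post", treated_value])
    return _biomass_frame(rows)


class TestLogResponseRatio:
    def test_treated_equal_to_control_mean_gives_zero(self):
        lrr = log_response_ratio(_simple_biomass(10.0))
        assert np.allclose(lrr.loc[lrr["treatment"] == "warmed", "lrr"], 0.0)

    def test_doubled_biomass_gives_log_two(self):
        lrr = log_response_ratio(_simple_biomass(20.0))
        assert np.allclose(lrr.loc[lrr["treatment"] == "warmed", "lrr"], np.log(2))

    def test_antisymmetry_when_roles_swap(self):
        bio = _simple_biomass(20.0)
        fwd = log_response_ratio(bio, baseline="control")
        swapped = bio.copy()
        swapped["treatment"] = swapped["treatment"].map(
            {"control": "warmed", "warmed": "control"}
        )
        # with a single plot per role the baseline mean equals the plot value
        bwd = log_response_ratio(swapped[swapped["plot_id"].isin(["t1", "c1"])])
        v_f = fwd.loc[fwd["plot_id"] == "t1", "lrr"].iloc[0]
        v_b = bwd.loc[bwd["plot_id"] == "c1", "lrr"].iloc[0]
        assert v_f == pytest.approx(-v_b)

    def test_control_plots_scatter_around_zero(self, minimal_stability_world):
        design, world, _ = minimal_stability_world
        lrr = log_response_ratio(generate_biomass(design, world, seed=3))
        ctrl = lrr[lrr["treatment"] == "control"]
        assert abs(ctrl["lrr"].mean()) < 0.05

    def test_nonpositive_biomass_rejected(self):
        bad = _simple_biomass(0.0)
        with pytest.raises(ValidationError):
            log_response_ratio(bad)

    def test_missing_control_date_rejected(self):
        bio = _simple_biomass(12.0)
        bio = bio[~((bio["treatment"] == "control") & (bio["date"] == 7))]
        with pytest.raises(ValidationError):
            log_response_ratio(bio)


class TestBcaInterval:
    def test_degenerate_sample_is_flagged_zero_width(self):
        ci = bca_interval(np.full(10, 3.3), n_boot=100, seed=0)
        assert ci.degenerate and ci.low == ci.high == 3.3

    def test_symmetric_sample_matches_percentile_interval(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, size=400)
        ci = bca_interval(x, n_boot=2000, seed=2)
        boots = np.array(
            [rng.choice(x, size=x.size).mean() for _ in range(2000)]
        )
        lo, hi = np.quantile(boots, [0.025, 0.975])
        width = hi - lo
        assert ci.low == pytest.approx(lo, abs=0.15 * width)
        assert ci.high == pytest.approx(hi, abs=0.15 * width)

    def test_coverage_on_skewed_samples(self):
        """BCa intervals of the mean of a log-normal, n=24 as in field panels."""
        rng = np.random.default_rng(3)
        true_mean = np.exp(0.5 * 0.7**2)
        hits, n_sim = 0, 300
        for s in range(n_sim):
            x = rng.lognormal(0.0, 0.7, size=24)
            ci = bca_interval(x, n_boot=500, seed=s)
            hits += ci.low <= true_mean <= ci.high
        assert 0.88 <= hits / n_sim <= 0.99

    def test_small_sample_rejected(self):
        with pytest.raises(InsufficientDataError):
            bca_interval([1.0, 2.0], n_boot=10, seed=0)


class TestStabilityModel:
    def test_fast_reml_matches_statsmodels(self, minimal_stability_world):
        design, world, _ = minimal_stability_world
        lrr = log_response_ratio(generate_biomass(design, world, seed=11))
        post = lrr[lrr["phase"] == "post"]
        fit = fit_stability_model(post)
        fast = _fast_reml(
            post["lrr"].to_numpy(), fit.exog, fit.groups, fit.time_c, fit.random_slope
        )
        assert np.allclose(fast.fe_params, np.asarray(fit.result.fe_params), atol=1e-6)
        assert fast.sigma2 == pytest.approx(fit.sigma2, rel=1e-3)

    def test_planted_offset_recovered_without_noise(self):
        design = RegimeDesign(treatments=("control", "extreme-only"))
        effects = {
            "control": BiomassEffects(0, 0, 0, 0, 0, 0, 0),
            "extreme-only": BiomassEffects(-0.4, 0.0, 0.0, 0, 0, 0, 0),
        }
        world = SyntheticWorldConfig(
            n_mags=5,
            treatment_effects={t: TreatmentEffects() for t in design.treatments},
            biomass_effects=effects,
        )
        lrr = log_response_ratio(generate_biomass(design, world, seed=0))
        fit = fit_stability_model(lrr[lrr["phase"] == "post"])
        assert fit.fe_params["sens[extreme-only]"] == pytest.approx(-0.4, abs=1e-8)
        assert fit.fe_params["resil[extreme-only]"] == pytest.approx(0.0, abs=1e-8)

    def test_null_world_estimates_center_on_zero(self, minimal_stability_world):
        design, _, _ = minimal_stability_world
        world = SyntheticWorldConfig(
            n_mags=5,
            treatment_effects={t: TreatmentEffects() for t in design.treatments},
            biomass_effects={t: BiomassEffects() for t in design.treatments},
        )
        sens, resil = [], []
        for s in range(20):
            lrr = log_response_ratio(generate_biomass(design, world, seed=200 + s))
            fit = fit_stability_model(lrr[lrr["phase"] == "post"])
            sens.append(fit.fe_params["sens[extreme-only]"])
            resil.append(fit.fe_params["resil[extreme-only]"])
        assert abs(np.mean(sens)) < 3 * np.std(sens) / np.sqrt(20) + 0.02
        assert abs(np.mean(resil)) < 3 * np.std(resil) / np.sqrt(20) + 0.002

    def test_temporal_stability_is_reciprocal_residual_sd(self):
        resid = np.array([-0.2, 0.2, -0.2, 0.2, -0.2, 0.2])
        sd = resid.std(ddof=1)
        dims = _dimensions_from_params(
            fe=np.array([0.0, 0.0, -0.1, 0.01]),
            names=["intercept", "time", "sens[w]", "resil[w]"],
            treatments=["w"],
            t_last_c=28.0,
            resid=resid,
            treat_of_row=np.array(["w"] * 6),
            baseline="control",
        )
        row = dims[dims["treatment"] == "w"].iloc[0]
        assert row["temporal_stability"] == pytest.approx(1 / sd)
        assert row["recovery"] == pytest.approx(-0.1 + 0.01 * 28)

    def test_insufficient_data_rejected(self):
        df = pd.DataFrame(
            {
                "plot_id": ["a", "b", "c", "d"],
                "treatment": ["control", "control", "w", "w"],
                "date": [0, 0, 0, 0],
                "lrr": [0.0, 0.1, -0.2, -0.1],
            }
        )
        with pytest.raises(InsufficientDataError):
            fit_stability_model(df)


class TestExtractDimensions:
    def test_bootstrap_ci_brackets_planted_sensitivity(self, minimal_stability_world):
        design, world, effect = minimal_stability_world
        lrr = log_response_ratio(generate_biomass(design, world, seed=21))
        fit = fit_stability_model(lrr[lrr["phase"] == "post"])
        dims = extract_dimensions(fit, n_boot=100, seed=1)
        sub = dims[(dims["treatment"] == "extreme-only")].set_index("dimension")
        assert sub.loc["sensitivity", "ci_low"] < effect.sensitivity_lrr < sub.loc[
            "sensitivity", "ci_high"
        ]
        for dim in ("sensitivity", "resilience", "recovery", "temporal_stability"):
            row = sub.loc[dim]
            assert row["ci_low"] - 1e-9 <= row["estimate"] <= row["ci_high"] + 1e-9

    def test_bootstrap_se_shrinks_with_more_plots(self):
        ses = {}
        for n_plots in (4, 16):
            design = RegimeDesign(
                treatments=("control", "extreme-only"), plots_per_treatment=n_plots
            )
            world = SyntheticWorldConfig(
                n_mags=5,
                treatment_effects={t: TreatmentEffects() for t in design.treatments},
                biomass_effects={
                    "control": BiomassEffects(),
                    "extreme-only": BiomassEffects(sensitivity_lrr=-0.5),
                },
            )
            lrr = log_response_ratio(generate_biomass(design, world, seed=9))
            fit = fit_stability_model(lrr[lrr["phase"] == "post"])
            dims = extract_dimensions(fit, n_boot=150, seed=2)
            ses[n_plots] = dims[
                (dims["treatment"] == "extreme-only") & (dims["dimension"] == "sensitivity")
            ]["se"].iloc[0]
        # 4x the plots should roughly halve the SE
        assert ses[16] < 0.75 * ses[4]


class TestBaci:
    @staticmethod
    def _balanced_table(delta):
        rows = []
        for treat, plots in (("control", ("c1", "c2")), ("w", ("w1", "w2"))):
            for plot in plots:
                for phase, dates in (("pre", (0, 7)), ("post", (14, 21))):
                    for d in dates:
                        base = 1.0 if phase == "pre" else 1.5
                        y = base + (delta if (treat == "w" and phase == "post") else 0.0)
                        rows.append(
                            {"plot_id": plot, "treatment": treat, "phase": phase, "date": d, "lrr": y}
                        )
        return pd.DataFrame(rows)

    def test_matches_difference_in_differences_oracle(self):
        delta = 0.37
        table = self._balanced_table(delta)
        res = baci_analysis(table)
        # closed form in the balanced noise-free limit
        means = table.groupby(["treatment", "phase"])["lrr"].mean()
        did = (means["w", "post"] - means["w", "pre"]) - (
            means["control", "post"] - means["control", "pre"]
        )
        assert res["baci_effect"].iloc[0] == pytest.approx(did, abs=1e-6)
        assert res["baci_effect"].iloc[0] == pytest.approx(delta, abs=1e-6)

    def test_no_impact_gives_zero_interaction(self):
        res = baci_analysis(self._balanced_table(0.0))
        assert res["baci_effect"].iloc[0] == pytest.approx(0.0, abs=1e-8)

    def test_control_only_rejected(self):
        table = self._balanced_table(0.1)
        with pytest.raises(ValidationError):
            baci_analysis(table[table["treatment"] == "control"])

    def test_missing_period_rejected(self):
        table = self._balanced_table(0.1)
        with pytest.raises(ValidationError):
            baci_analysis(table[table["phase"] == "post"])


def _metric_table(effects: dict[str, float], slope_effects: dict[str, float] | None = None,
                  noise: float = 0.0, seed: int = 0):
    rng = np.random.default_rng(seed)
    slope_effects = slope_effects or {}
    rows = []
    for treat, n in (("control", 3), ("fixed", 3), ("fluct-s1", 3), ("fluct-s2", 3)):
        for p in range(n):
            base = rng.normal(0.0, noise)
            for d in (0, 14, 28, 42):
                y = (
                    10.0
                    + effects.get(treat, 0.0)
                    + slope_effects.get(treat, 0.0) * d
                    + base
                    + rng.normal(0.0, noise)
                )
                rows.append(
                    {"plot_id": f"{treat}_p{p}", "treatment": treat, "date": d, "value": y}
                )
    return pd.DataFrame(rows)


class TestPhase1Contrasts:
    def test_identical_metric_gives_null_contrasts(self):
        table = _metric_table({}, noise=0.0)
        res = phase1_trend_contrasts(table)
        assert np.allclose(res["estimate"], 0.0, atol=1e-7)

    def test_planted_fixed_trend_detected_at_last_date(self):
        table = _metric_table({}, slope_effects={"fixed": 0.05}, noise=0.05, seed=1)
        res = phase1_trend_contrasts(table)
        row = res[
            (res["center"] == "last") & (res["contrast"] == "fixed_vs_fluct") & (res["type"] == "level")
        ].iloc[0]
        assert row["estimate"] > 0
        assert row["p_fdr"] < 0.05

    def test_single_fluct_sequence_pooling_is_identity(self):
        table = _metric_table({}, noise=0.02, seed=2)
        table = table[table["treatment"] != "fluct-s2"]
        res = phase1_trend_contrasts(table)
        assert set(res["contrast"]) == {"control_vs_fluct", "fixed_vs_fluct"}

    def test_missing_level_rejected(self):
        table = _metric_table({}, noise=0.02, seed=3)
        with pytest.raises(ValidationError):
            phase1_trend_contrasts(table[table["treatment"] != "fixed"])


class TestAuxiliaryModels:
    def test_prephase_null_comparison(self):
        rng = np.random.default_rng(4)
        rows = []
        for treat in ("control", "extreme-only"):
            for p in range(3):
                for d in (0, 14, 28):
                    rows.append(
                        {
                            "plot_id": f"{treat}{p}",
                            "treatment": treat,
                            "date": d,
                            "value": 5.0 + rng.normal(0, 0.1),
                        }
                    )
        res = control_vs_extreme_prephase(pd.DataFrame(rows))
        assert (res["p"] > 0.05).all()

    def test_artifact_control_detects_planted_shading_effect(self):
        rng = np.random.default_rng(5)
        rows = []
        for treat, off in (("control", 0.0), ("artifact-control", 1.0)):
            for p in range(4):
                for d in (0, 14):
                    rows.append(
                        {
                            "plot_id": f"{treat}{p}",
                            "treatment": treat,
                            "date": d,
                            "value": 5.0 + off + rng.normal(0, 0.05),
                        }
                    )
        res = artifact_control_test(pd.DataFrame(rows))
        assert res["estimate"].iloc[0] == pytest.approx(1.0, abs=0.1)
        assert res["p"].iloc[0] < 0.001
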
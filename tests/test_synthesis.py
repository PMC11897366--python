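"""Generator contracts: moment matching, determinism, closure, planted effects."""

import numpy as np
import pandas as pd
import pytest

from biofilmstab.config import (
    UNBINNED_ID,
    BiomassEffects,
    RegimeDesign,
    SyntheticWorldConfig,
    TreatmentEffects,
)
from biofilmstab.errors import InvalidDesignError, ValidationError
from biofilmstab.functional import community_weighted_trait
from biofilmstab.stability import log_response_ratio
from biofilmstab.stochasticity import patristic_matrix
from biofilmstab.synthesis import (
    generate_abundances,
    generate_biomass,
    generate_regime,
    generate_traits,
    generate_tree,
    generate_world,
    moment_matched_sequence,
)


class TestRegime:
    def test_fluctuating_sequences_have_exact_moments(self, default_design):
        regime = generate_regime(default_design, seed=1)
        fluct = {t: v for t, v in regime["pulses"].items() if t.startswith("fluct")}
        assert len(fluct) == 3
        for vec in fluct.values():
            assert len(vec) == 6
            assert vec.mean() == pytest.approx(12.0, abs=1e-12)
            assert vec.std(ddof=1) == pytest.approx(5.0, abs=1e-12)
        keys = [tuple(v) for v in fluct.values()]
        assert len(set(keys)) == 3  # pairwise distinct ordered vectors

    def test_fixed_regime_constant_and_controls_empty(self, default_design):
        regime = generate_regime(default_design, seed=5)
        assert np.allclose(regime["pulses"]["fixed"], 12.0)
        for t in ("control", "extreme-only", "artifact-control"):
            assert regime["pulses"][t].size == 0

    def test_extreme_schedule(self, default_design):
        regime = generate_regime(default_design, seed=0)
        ext = regime["extremes"]["fixed"]
        assert len(ext) == 2
        assert all(e["temp_C"] == 60.0 and e["duration_min"] == 120.0 for e in ext)
        assert ext[1]["day"] - ext[0]["day"] == 4
        assert ext[0]["day"] > max(regime["pulse_days"])
        assert regime["extremes"]["control"] == []
        assert regime["extremes"]["artifact-control"] == []
        assert len(regime["extremes"]["extreme-only"]) == 2

    def test_degenerate_sd_equals_fixed(self):
        rng = np.random.default_rng(0)
        vec = moment_matched_sequence(6, 12.0, 0.0, rng)
        assert np.array_equal(vec, np.full(6, 12.0))

    def test_invalid_designs_rejected(self):
        with pytest.raises(InvalidDesignError):
            RegimeDesign(n_pulses=1, pulse_days=(7,), pulse_sd_dT=5.0)
        with pytest.raises(InvalidDesignError):
            RegimeDesign(pulse_sd_dT=-1.0)
        rng = np.random.default_rng(0)
        with pytest.raises(InvalidDesignError):
            moment_matched_sequence(1, 12.0, 5.0, rng)


class TestTree:
    def test_minimal_tree(self):
        tree = generate_tree(2, seed=0)
        assert len(tree.leaf_nodes()) == 2

    def test_determinism(self):
        s1 = generate_tree(50, seed=9).as_string(schema="newick")
        s2 = generate_tree(50, seed=9).as_string(schema="newick")
        assert s1 == s2

    def test_patristic_matrix_is_a_premetric(self):
        D, labels = patristic_matrix(generate_tree(50, seed=3))
        assert D.shape == (50, 50)
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0.0)
        off = D[~np.eye(50, dtype=bool)]
        assert (off > 0).all()

    def test_too_few_tips_rejected(self):
        with pytest.raises(InvalidDesignError):
            generate_tree(1, seed=0)


class TestTraits:
    def test_null_slope_gives_no_correlation(self):
        t = generate_traits(500, tradeoff_slope=0.0, trait_noise_sd=1.0, seed=7)
        r = np.corrcoef(t["stress_module_count"], np.log(t["mdt"]))[0, 1]
        assert abs(r) < 0.12

    def test_noise_free_limit_is_monotone(self):
        from scipy.stats import spearmanr

        t = generate_traits(300, tradeoff_slope=6.0, trait_noise_sd=0.0, seed=7)
        rho = spearmanr(t["stress_module_count"], t["mdt"]).statistic
        assert rho > 0.9

    def test_trait_contracts(self):
        t = generate_traits(137, seed=1)
        assert (t["stress_module_count"] >= 0).all()
        assert (t["mdt"] > 0).all()
        assert t["completeness"].between(0, 100).all()
        assert (t["genome_size"] > 0).all()


class TestAbundances:
    def test_compositional_closure(self, small_world):
        sums = small_world["abundances"].groupby(["plot_id", "date"])["tpm"].sum()
        assert np.allclose(sums, 1e6, rtol=1e-6)

    def test_mag_rows_are_a_varying_subcomposition(self, small_world):
        """MAG totals vary by sample (the unbinned pool takes the rest) and
        detection limits leave some genomes absent from some samples."""
        comm = small_world["abundances"]
        mags = comm[comm["mag_id"] != UNBINNED_ID]
        mag_sums = mags.groupby(["plot_id", "date"])["tpm"].sum()
        assert mag_sums.max() < 1e6
        assert mag_sums.std() / mag_sums.mean() > 0.01
        richness = mags.groupby(["plot_id", "date"])["mag_id"].nunique()
        assert richness.min() < small_world["world"].n_mags

    def test_synchrony_is_not_a_closure_artifact(self, small_world):
        """On a sub-compositional table Gross' eta is informative, not -1."""
        from biofilmstab.diversity import synchrony_table

        syn = synchrony_table(small_world["abundances"])
        assert (syn["eta"] > -0.999).any()

    def test_trait_profiles_generate_multiple_functional_entities(self, small_world):
        from biofilmstab.functional import assign_functional_entities

        part = assign_functional_entities(small_world["traits"])
        assert 1 < part.K <= part.S
        prof_cols = [c for c in small_world["traits"].columns if c.startswith("module_")]
        sums = small_world["traits"][prof_cols].sum(axis=1)
        assert (sums == small_world["traits"]["stress_module_count"]).all()

    def test_mag_set_mismatch_rejected(self, default_design):
        world = SyntheticWorldConfig(n_mags=10)
        traits = generate_traits(8, seed=0)
        with pytest.raises(ValidationError):
            generate_abundances(default_design, world, traits, seed=0)

    def test_selection_lowers_community_weighted_mdt(self):
        """Fluctuating warming selects fast growers: CWMDT drops below control."""
        design = RegimeDesign(treatments=("control", "fluct-s1"), plots_per_treatment=2)
        world = SyntheticWorldConfig(
            n_mags=40,
            abundance_noise_sd=0.1,
            treatment_effects={
                "control": TreatmentEffects(),
                "fluct-s1": TreatmentEffects(selection_strength=1.0),
            },
        )
        wins = 0
        n_rep = 30
        for s in range(n_rep):
            traits = generate_traits(40, seed=s)
            comm = generate_abundances(design, world, traits, seed=s)
            comm = comm[comm["mag_id"] != UNBINNED_ID]
            last = comm[comm["date"] == comm["date"].max()]
            mdt = traits.set_index("mag_id")["mdt"]
            cwm = {}
            for treat, sub in last.groupby("treatment"):
                vals = [
                    community_weighted_trait(
                        g["tpm"].to_numpy(), mdt.reindex(g["mag_id"]).to_numpy()
                    )
                    for _, g in sub.groupby("plot_id")
                ]
                cwm[treat] = np.mean(vals)
            wins += cwm["fluct-s1"] < cwm["control"]
        assert wins >= int(0.8 * n_rep)

    def test_neutral_effects_equalize_diversity(self):
        from biofilmstab.diversity import hill_number

        design = RegimeDesign(treatments=("control", "fixed"), plots_per_treatment=3)
        world = SyntheticWorldConfig(
            n_mags=40,
            treatment_effects={"control": TreatmentEffects(), "fixed": TreatmentEffects()},
        )
        diffs = []
        for s in range(10):
            traits = generate_traits(40, seed=s)
            comm = generate_abundances(design, world, traits, seed=s)
            comm = comm[comm["mag_id"] != UNBINNED_ID]
            q1 = {
                treat: np.mean(
                    [
                        hill_number(g["tpm"].to_numpy(), 1)
                        for _, g in sub.groupby(["plot_id", "date"])
                    ]
                )
                for treat, sub in comm.groupby("treatment")
            }
            diffs.append((q1["fixed"] - q1["control"]) / q1["control"])
        assert abs(np.mean(diffs)) < 0.1


class TestBiomass:
    @staticmethod
    def _silent_world(design, **eff):
        effects = {t: BiomassEffects(
            residual_sd=0.0, plot_intercept_sd=0.0, plot_slope_sd=0.0, subplot_sd=0.0,
            **eff.get(t, {}),
        ) for t in design.treatments}
        return SyntheticWorldConfig(
            n_mags=5,
            treatment_effects={t: TreatmentEffects() for t in design.treatments},
            biomass_effects=effects,
        )

    def test_null_noise_free_world_has_zero_lrr(self):
        design = RegimeDesign(treatments=("control", "fixed"))
        world = self._silent_world(design)
        bio = generate_biomass(design, world, seed=0)
        lrr = log_response_ratio(bio)
        assert np.allclose(lrr["lrr"], 0.0, atol=1e-12)

    def test_planted_effect_trajectory_is_exact_without_noise(self):
        design = RegimeDesign(treatments=("control", "extreme-only"))
        world = self._silent_world(
            design,
            **{"extreme-only": dict(sensitivity_lrr=-0.5, recovery_offset=0.2)},
        )
        bio = generate_biomass(design, world, seed=0)
        lrr = log_response_ratio(bio)
        treated = lrr[(lrr["treatment"] == "extreme-only") & (lrr["phase"] == "post")]
        first, last = treated["date"].min(), treated["date"].max()
        assert treated.loc[treated["date"] == first, "lrr"].iloc[0] == pytest.approx(-0.5)
        # recovery offset ramps linearly to its full value at the last date
        assert treated.loc[treated["date"] == last, "lrr"].iloc[0] == pytest.approx(-0.3)

    def test_phase_flags_follow_extreme_schedule(self, small_world):
        bio = small_world["biomass"]
        design = small_world["design"]
        first_extreme = design.extreme_days[0]
        assert (bio.loc[bio["date"] < first_extreme, "phase"] == "pre").all()
        assert (bio.loc[bio["date"] > first_extreme, "phase"] == "post").all()


def test_world_generation_is_deterministic():
    design = RegimeDesign(treatments=("control", "fixed"), plots_per_treatment=2)
    world = SyntheticWorldConfig(n_mags=8, seed=4)
    w1 = generate_world(design, world)
    w2 = generate_world(design, world)
    pd.testing.assert_frame_equal(w1["abundances"], w2["abundances"])
    pd.testing.assert_frame_equal(w1["biomass"], w2["biomass"])
    pd.testing.assert_frame_equal(w1["traits"], w2["traits"])
    assert w1["tree"].as_string(schema="newick") == w2["tree"].as_string(schema="newick")
    for t, v in w1["regime"]["pulses"].items():
        assert np.array_equal(v, w2["regime"]["pulses"][t])
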
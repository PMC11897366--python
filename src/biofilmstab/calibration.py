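"""Simulation studies that verify the pipeline against known ground truth.

Each study generates data under controlled conditions (the design constants
of the warming experiment, phylogeny-random or clade-filtered assembly,
Eq.-1-style biomass with planted effects), runs the corresponding analysis
and summarises how well the known truth is recovered.  The acceptance
machinery and the examples call these; they are ordinary package code and
fully seedable.
"""

from __future__ import annotations

import numpy as np

from .config import (
    BiomassEffects,
    RegimeDesign,
    SyntheticWorldConfig,
    TreatmentEffects,
)
from .stability import extract_dimensions, fit_stability_model, log_response_ratio
from .stochasticity import nst_bootstrap_compare, nst_group, patristic_matrix
from .synthesis import (
    generate_biomass,
    generate_regime,
    generate_tree,
    generate_tree_with_tight_clade,
    simulate_convergent_communities,
    simulate_null_communities,
)

__all__ = [
    "regime_summary",
    "nst_null_calibration",
    "nst_convergent_calibration",
    "stability_coverage_study",
    "stability_null_study",
    "bootstrap_type1_study",
]


def regime_summary(seed: int = 0, design: RegimeDesign | None = None) -> dict:
    """Design constants realised by the regime generator."""
    design = design or RegimeDesign()
    regime = generate_regime(design, seed)
    fluct = {t: v for t, v in regime["pulses"].items() if t.startswith("fluct")}
    ext = regime["extremes"]["fixed"]
    return {
        "fluct_pulse_mean_C": float(np.mean([v.mean() for v in fluct.values()])),
        "fluct_pulse_sd_C": float(np.mean([v.std(ddof=1) for v in fluct.values()])),
        "fixed_pulse_dT_C": float(np.unique(regime["pulses"]["fixed"])[0]),
        "n_phase1_pulses": int(design.n_pulses),
        "extreme_temp_C": float(ext[0]["temp_C"]),
        "extreme_duration_min": float(ext[0]["duration_min"]),
        "n_extreme_events": len(ext),
        "extreme_spacing_days": float(ext[1]["day"] - ext[0]["day"]),
    }


def nst_null_calibration(
    n_reps: int = 100,
    n_mags: int = 137,
    n_plots: int = 3,
    richness: int = 90,
    n_rand: int = 200,
    seed: int = 0,
) -> np.ndarray:
    """Group pNST of phylogeny-random communities, one mean per replicate.

    Under stochastic assembly the observed betaMNTD is a draw from its own
    null distribution, so pNST should sit near the 100% end.
    """
    tree = generate_tree(n_mags, seed=seed)
    dist, _ = patristic_matrix(tree)
    means = np.empty(n_reps)
    for r in range(n_reps):
        comm = simulate_null_communities(n_plots, n_mags, richness, seed=seed + 7919 * r)
        res = nst_group(comm, dist, n_rand=n_rand, seed=seed + r)
        assert ((res.pairwise_values >= 0) & (res.pairwise_values <= 1)).all()
        means[r] = res.group_mean
    return means


def nst_convergent_calibration(
    n_reps: int = 100,
    n_mags: int = 137,
    n_plots: int = 3,
    clade_size: int = 12,
    richness: int = 8,
    n_rand: int = 200,
    seed: int = 0,
) -> np.ndarray:
    """Group pNST of communities deterministically filtered into a tight clade."""
    tree, clade = generate_tree_with_tight_clade(n_mags, clade_size=clade_size, seed=seed)
    dist, labels = patristic_matrix(tree)
    cidx = [labels.index(c) for c in clade]
    means = np.empty(n_reps)
    for r in range(n_reps):
        comm = simulate_convergent_communities(
            cidx, n_plots, n_mags, richness, seed=seed + 104729 * r
        )
        res = nst_group(comm, dist, n_rand=n_rand, seed=seed + r)
        means[r] = res.group_mean
    return means


def _two_treatment_world(effect: BiomassEffects, plots: int = 4):
    design = RegimeDesign(treatments=("control", "extreme-only"), plots_per_treatment=plots)
    world = SyntheticWorldConfig(
        n_mags=5,
        treatment_effects={t: TreatmentEffects() for t in design.treatments},
        biomass_effects={"control": BiomassEffects(), "extreme-only": effect},
    )
    return design, world


def planted_truth(effect: BiomassEffects, design: RegimeDesign, n_control: int = 4) -> dict:
    """Ground-truth stability dimensions implied by a planted effect.

    Temporal stability refers to the effective residual SD of plot-level
    log-response ratios: the plot x date draw, the subplot-averaging
    remainder, and the shared noise of the control baseline mean.
    """
    dates = np.asarray(design.sampling_dates_biomass, float)
    post = dates[dates > design.extreme_days[0]]
    t_last = post.max() - post.min()
    s2 = effect.residual_sd**2 + effect.subplot_sd**2 / 6
    sigma_eff = np.sqrt(s2 + s2 / n_control)
    return {
        "sensitivity": effect.sensitivity_lrr,
        "resilience": effect.resilience_slope,
        "recovery": effect.sensitivity_lrr
        + effect.resilience_slope * t_last
        + effect.recovery_offset,
        "temporal_stability": 1.0 / sigma_eff,
    }


def stability_coverage_study(
    n_reps: int = 200,
    n_boot: int = 200,
    seed: int = 0,
    effect: BiomassEffects | None = None,
) -> dict[str, float]:
    """Coverage of 95% parametric-bootstrap CIs for planted dimensions.

    Data come from the biomass generator (4 plots x 6 subplots x 5
    post-extreme dates per treatment); each replicate refits the stability
    model and checks whether the percentile CI brackets the planted truth.
    """
    effect = effect or BiomassEffects(sensitivity_lrr=-0.5, resilience_slope=0.01)
    design, world = _two_treatment_world(effect)
    truth = planted_truth(effect, design, n_control=design.plots_per_treatment)
    hits = {k: 0 for k in truth}
    for r in range(n_reps):
        bio = generate_biomass(design, world, seed=seed + 1009 * r)
        lrr = log_response_ratio(bio)
        fit = fit_stability_model(lrr[lrr["phase"] == "post"], engine="fast")
        dims = extract_dimensions(fit, n_boot=n_boot, seed=seed + r)
        sub = dims[dims["treatment"] == "extreme-only"].set_index("dimension")
        for k, v in truth.items():
            hits[k] += bool(sub.loc[k, "ci_low"] <= v <= sub.loc[k, "ci_high"])
    return {k: h / n_reps for k, h in hits.items()}


def stability_null_study(n_reps: int = 50, seed: int = 0) -> dict[str, float]:
    """Mean point estimates when no effect is planted (all should be null)."""
    effect = BiomassEffects()  # zero effects, default noise
    design, world = _two_treatment_world(effect)
    acc = {"sensitivity": [], "resilience": [], "recovery": []}
    for r in range(n_reps):
        bio = generate_biomass(design, world, seed=seed + 7 * r)
        lrr = log_response_ratio(bio)
        fit = fit_stability_model(lrr[lrr["phase"] == "post"], engine="fast")
        fe = fit.fe_params
        acc["sensitivity"].append(fe["sens[extreme-only]"])
        acc["resilience"].append(fe["resil[extreme-only]"])
        acc["recovery"].append(
            fe["sens[extreme-only]"] + fe["resil[extreme-only]"] * fit.t_last_c
        )
    return {k: float(np.mean(v)) for k, v in acc.items()}


def bootstrap_type1_study(
    n_sims: int = 500,
    group_size: int = 15,
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Rejection rate of the one-sided bootstrap test under a shared distribution.

    Both groups draw ``group_size`` pairwise-NST-like values from the same
    distribution; the pre-specified one-sided test should reject at ~alpha.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for s in range(n_sims):
        a = rng.beta(5, 2, size=group_size)
        b = rng.beta(5, 2, size=group_size)
        p = nst_bootstrap_compare(a, b, n_boot=n_boot, seed=seed + s, side="greater")
        rejections += p <= alpha
    return rejections / n_sims
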
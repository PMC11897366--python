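"""Synthetic experiment generator.

Emulates the data structures of a two-phase warming experiment on rocky
shore biofilm: moment-matched pulse schedules, a birth-death phylogeny over
metagenome-assembled genomes (MAGs), genome traits with a built-in
tolerance-growth trade-off, compositional TPM abundance tables with
treatment-dependent evenness/selection/richness effects and AR(1) temporal
correlation, and log-scale biomass trajectories with nested plot/subplot
noise and known sensitivity/resilience/recovery effects.

Everything is deterministic given (config, seed); each artefact draws from
an independently salted stream so regenerating one piece never perturbs the
others.
"""

from __future__ import annotations

import random as _random

import dendropy
import numpy as np
import pandas as pd

from .config import (
    UNBINNED_ID,
    RegimeDesign,
    SyntheticWorldConfig,
    mag_ids,
    plot_ids,
    spawn_rng,
)
from .errors import InvalidDesignError, ValidationError

__all__ = [
    "generate_regime",
    "generate_tree",
    "generate_traits",
    "generate_abundances",
    "generate_biomass",
    "generate_world",
]


def moment_matched_sequence(n: int, mean: float, sd: float, rng) -> np.ndarray:
    """Random pulse elevations rescaled to the exact sample mean and SD.

    Uniform base draws are shifted and scaled so the sample mean equals
    ``mean`` and the sample SD (n-1 denominator) equals ``sd`` exactly.
    """
    if sd < 0:
        raise InvalidDesignError("pulse SD must be non-negative")
    if sd == 0:
        return np.full(n, float(mean))
    if n < 2:
        raise InvalidDesignError("a fluctuating sequence needs n >= 2 pulses")
    while True:
        x = rng.uniform(-1.0, 1.0, size=n)
        s = x.std(ddof=1)
        if s > 0:
            break
    return mean + sd * (x - x.mean()) / s


def generate_regime(design: RegimeDesign, seed: int) -> dict:
    """Per-treatment pulse-elevation vectors plus the extreme-event schedule.

    Fluctuating sequences are pairwise distinct (re-drawn in the astronomically
    unlikely event of a collision); fixed warming is constant at the design
    mean; control, extreme-only and artifact-control get empty pulse vectors.
    """
    rng = spawn_rng(seed, "regime")
    pulses: dict[str, np.ndarray] = {}
    seen: set[tuple] = set()
    for t in design.treatments:
        if t == "fixed":
            vec = moment_matched_sequence(design.n_pulses, design.pulse_mean_dT, 0.0, rng)
        elif t.startswith("fluct"):
            while True:
                vec = moment_matched_sequence(
                    design.n_pulses, design.pulse_mean_dT, design.pulse_sd_dT, rng
                )
                key = tuple(np.round(vec, 12))
                if key not in seen or design.pulse_sd_dT == 0:
                    seen.add(key)
                    break
        else:
            vec = np.array([])
        pulses[t] = vec
    extremes = [
        {"day": day, "temp_C": design.extreme_temp_C, "duration_min": design.extreme_duration_min}
        for day in design.extreme_days
    ]
    schedule = {
        t: (extremes if t in design.perturbed_treatments() else [])
        for t in design.treatments
    }
    return {"pulses": pulses, "pulse_days": list(design.pulse_days), "extremes": schedule}


def generate_tree(
    n_mags: int,
    birth_rate: float = 1.0,
    death_rate: float = 0.5,
    seed: int = 0,
) -> dendropy.Tree:
    """Rooted bifurcating birth-death phylogeny with MAG tip labels."""
    if n_mags < 2:
        raise InvalidDesignError("a tree needs at least 2 tips")
    rng = _random.Random(int(spawn_rng(seed, "tree").integers(0, 2**31 - 1)))
    tree = dendropy.model.birthdeath.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=death_rate,
        num_extant_tips=n_mags,
        rng=rng,
    )
    labels = mag_ids(n_mags)
    ns = dendropy.TaxonNamespace()
    for leaf, lab in zip(sorted(tree.leaf_node_iter(), key=lambda n: n.taxon.label), labels):
        leaf.taxon = ns.new_taxon(lab)
    tree.taxon_namespace = ns
    # guard against zero-length edges from the simulator
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length <= 0:
            edge.length = 1e-6
    return tree


def generate_tree_with_tight_clade(
    n_mags: int,
    clade_size: int = 8,
    scale: float = 0.02,
    seed: int = 0,
    birth_rate: float = 1.0,
    death_rate: float = 0.5,
) -> tuple[dendropy.Tree, list[str]]:
    """Birth-death tree with one phylogenetically compressed clade.

    Finds the internal node whose leaf count is closest to ``clade_size``
    (at least 2) and multiplies every edge length inside that subtree by
    ``scale``.  Communities restricted to the clade then emulate strong
    deterministic (environmental-filtering) convergence: their members are
    far closer to each other than a phylogeny-random null expects.
    """
    tree = generate_tree(n_mags, birth_rate, death_rate, seed)
    best, best_gap = None, None
    for node in tree.preorder_internal_node_iter():
        leaves = node.leaf_nodes()
        if len(leaves) < 2 or len(leaves) >= n_mags:
            continue
        gap = abs(len(leaves) - clade_size)
        if best is None or gap < best_gap:
            best, best_gap = node, gap
    for edge in best.preorder_iter():
        for e in edge.child_edges():
            if e.length:
                e.length = e.length * scale
    clade = sorted(leaf.taxon.label for leaf in best.leaf_nodes())
    return tree, clade


def simulate_null_communities(
    n_plots: int, n_mags: int, richness: int, seed: int = 0, labels=None
) -> np.ndarray:
    """Communities assembled with no regard to phylogeny.

    Each plot receives ``richness`` taxa drawn uniformly from the pool with
    log-normal abundances — the stochastic-assembly reference condition for
    the normalised stochasticity ratio.  Returns a plot x taxon matrix
    aligned to the sorted taxon order (or to ``labels`` positions).
    """
    rng = spawn_rng(seed, "null-communities")
    S = n_mags if labels is None else len(labels)
    comm = np.zeros((n_plots, S))
    for i in range(n_plots):
        idx = rng.choice(S, size=min(richness, S), replace=False)
        comm[i, idx] = rng.lognormal(0.0, 1.0, size=idx.size)
    return comm


def simulate_convergent_communities(
    clade_indices, n_plots: int, n_mags: int, richness: int, seed: int = 0
) -> np.ndarray:
    """Communities deterministically filtered into one (tight) clade."""
    rng = spawn_rng(seed, "convergent-communities")
    clade = np.asarray(clade_indices)
    comm = np.zeros((n_plots, n_mags))
    for i in range(n_plots):
        idx = rng.choice(clade, size=min(richness, clade.size), replace=False)
        comm[i, idx] = rng.lognormal(0.0, 1.0, size=idx.size)
    return comm


def generate_traits(
    n_mags: int,
    tradeoff_slope: float = 2.0,
    trait_noise_sd: float = 1.0,
    seed: int = 0,
    n_module_types: int = 15,
) -> pd.DataFrame:
    """Genome trait table with a tolerance-growth trade-off.

    Minimal doubling times are log-normal (hours); the expected
    stress-module count rises linearly with log-MDT at ``tradeoff_slope``
    modules per log-hour, with Gaussian noise on the Poisson rate (counts
    become the rounded expectation in the noise-free limit).  Which of the
    ``n_module_types`` module families a genome carries is a uniform random
    subset of that size, giving the binary profiles that define functional
    entities.  Genome size (bp) and completeness (%) are independent
    covariates.
    """
    if not np.isfinite(tradeoff_slope):
        raise InvalidDesignError("tradeoff_slope must be finite")
    rng = spawn_rng(seed, "traits")
    mdt = np.exp(rng.normal(np.log(3.0), 0.6, size=n_mags))
    genome_size = np.exp(rng.normal(np.log(4e6), 0.3, size=n_mags))
    completeness = rng.uniform(70.0, 100.0, size=n_mags)
    rate = 4.0 + tradeoff_slope * np.log(mdt) + rng.normal(0.0, trait_noise_sd, size=n_mags)
    rate = np.clip(rate, 0.05, None)
    modules = np.rint(rate).astype(int) if trait_noise_sd == 0 else rng.poisson(rate)
    modules = np.minimum(modules, n_module_types).astype(int)
    # module families are strongly uneven in prevalence (a few near-core
    # families, a long tail), so trait combinations recur across genomes
    popularity = 0.75 ** np.arange(n_module_types)
    profiles = np.zeros((n_mags, n_module_types), dtype=int)
    for i, k in enumerate(modules):
        if k > 0:
            chosen = rng.choice(
                n_module_types, size=k, replace=False, p=popularity / popularity.sum()
            )
            profiles[i, chosen] = 1
    out = pd.DataFrame(
        {
            "mag_id": mag_ids(n_mags),
            "stress_module_count": modules,
            "genome_size": genome_size,
            "completeness": completeness,
            "mdt": mdt,
        }
    )
    for m in range(n_module_types):
        out[f"module_{m + 1:02d}"] = profiles[:, m]
    return out


def generate_abundances(
    design: RegimeDesign,
    world: SyntheticWorldConfig,
    traits: pd.DataFrame,
    seed: int = 0,
) -> pd.DataFrame:
    """Long-format TPM community table over plots x community dates.

    Log-abundances start from a shared log-normal baseline.  Per treatment,
    the evenness exponent scales the spread of baseline log-abundances
    (<1 compresses ranks, i.e. higher evenness), selection down-weights
    slow growers (standardised log-MDT) with a linear ramp over the
    experiment, and richness loss removes a configured fraction of rare
    genomes from the second sampling date onward.  An AR(1) process adds
    temporally autocorrelated plot-level noise.

    Each sample closes to the TPM constant over the MAG rows plus one
    ``unbinned`` pseudo-taxon holding the non-MAG fraction (Beta-distributed
    per sample), so MAG abundances form a sub-composition as in real
    metagenome tables; MAGs whose TPM falls below the detection threshold
    are recorded as absent.
    """
    ids = list(traits["mag_id"])
    if len(ids) != world.n_mags or len(set(ids)) != len(ids):
        raise ValidationError("trait table does not cover the configured MAG set")
    rng = spawn_rng(seed, "abundances")
    mu0, sigma0 = world.baseline_lognormal_mu_sigma
    base = rng.normal(mu0, sigma0, size=world.n_mags)
    log_mdt = np.log(traits["mdt"].to_numpy(dtype=float))
    z_mdt = (log_mdt - log_mdt.mean()) / log_mdt.std(ddof=1)
    rare = base < np.quantile(base, 0.25)
    dates = np.asarray(design.sampling_dates_community, dtype=float)
    span = max(dates.max() - dates.min(), 1.0)
    rho = world.abundance_ar1_rho
    rows = []
    for treat, plots in plot_ids(design).items():
        eff = world.treatment_effects.get(treat)
        if eff is None:
            raise ValidationError(f"no treatment effects configured for {treat!r}")
        centered = base - base.mean()
        shaped = base.mean() + centered * eff.evenness_exponent
        for plot in plots:
            lost = rare & (rng.uniform(size=world.n_mags) < eff.richness_loss)
            eps = rng.normal(0.0, world.abundance_noise_sd, size=world.n_mags)
            for di, day in enumerate(dates):
                if di > 0:
                    eps = rho * eps + np.sqrt(1 - rho**2) * rng.normal(
                        0.0, world.abundance_noise_sd, size=world.n_mags
                    )
                ramp = (day - dates.min()) / span
                logs = shaped - eff.selection_strength * ramp * z_mdt + eps
                tpm = np.exp(logs)
                if di > 0:
                    tpm = tpm.copy()
                    tpm[lost] = 0.0
                binned = rng.beta(*world.binned_fraction_beta)
                tpm = tpm / tpm.sum() * world.tpm_total * binned
                tpm[tpm < world.detection_tpm] = 0.0
                # re-close the detected MAGs onto the binned fraction
                tpm = tpm / tpm.sum() * world.tpm_total * binned
                rows.append(
                    pd.DataFrame(
                        {
                            "plot_id": plot,
                            "treatment": treat,
                            "date": int(day),
                            "mag_id": ids + [UNBINNED_ID],
                            "tpm": np.append(tpm, world.tpm_total * (1.0 - binned)),
                        }
                    )
                )
    out = pd.concat(rows, ignore_index=True)
    return out[out["tpm"] > 0].reset_index(drop=True)


def generate_biomass(
    design: RegimeDesign,
    world: SyntheticWorldConfig,
    seed: int = 0,
) -> pd.DataFrame:
    """Plot x subplot x date biomass series generated on the log scale.

    log(biomass) = control trajectory + treatment deviation + plot random
    intercept/slope + residual + subplot noise, exponentiated to ug chl a
    per cm^2.  The treatment deviation is zero before the extremes and,
    afterwards, sensitivity + resilience * (days since first post-extreme
    sampling) + recovery_offset ramping to its full value at the last date.
    Phase flags mark dates before/after the first extreme event.
    """
    rng = spawn_rng(seed, "biomass")
    dates = np.asarray(design.sampling_dates_biomass, dtype=float)
    first_extreme = design.extreme_days[0] if design.n_extremes else np.inf
    post = dates > first_extreme
    if post.any():
        t0 = dates[post].min()
        t_last = dates[post].max() - t0
    else:
        t0, t_last = dates.min(), max(dates.max() - dates.min(), 1.0)
    rows = []
    for treat, plots in plot_ids(design).items():
        eff = world.biomass_effects.get(treat)
        if eff is None:
            raise ValidationError(f"no biomass effects configured for {treat!r}")
        perturbed = treat in design.perturbed_treatments()
        for plot in plots:
            a0 = rng.normal(0.0, eff.plot_intercept_sd)
            b1 = rng.normal(0.0, eff.plot_slope_sd)
            for day in dates:
                tc = day - t0  # centred at first post-extreme sampling date
                log_control = world.control_log_biomass0 + world.control_biomass_slope * day
                dev = 0.0
                if perturbed and day > first_extreme:
                    ramp = tc / t_last if t_last > 0 else 1.0
                    dev = (
                        eff.sensitivity_lrr
                        + eff.resilience_slope * tc
                        + eff.recovery_offset * ramp
                    )
                mu = log_control + dev + a0 + b1 * tc + rng.normal(0.0, eff.residual_sd)
                sub_noise = rng.normal(0.0, eff.subplot_sd, size=world.n_subplots)
                for s in range(world.n_subplots):
                    rows.append(
                        {
                            "plot_id": plot,
                            "subplot_id": f"s{s + 1}",
                            "treatment": treat,
                            "date": int(day),
                            "phase": "post" if day > first_extreme else "pre",
                            "biomass": float(np.exp(mu + sub_noise[s])),
                        }
                    )
    return pd.DataFrame(rows)


def generate_world(
    design: RegimeDesign | None = None,
    world: SyntheticWorldConfig | None = None,
    seed: int | None = None,
) -> dict:
    """Generate the full synthetic bundle (regime, tree, traits, tables)."""
    import dataclasses

    design = design or RegimeDesign()
    world = world or SyntheticWorldConfig()
    seed = world.seed if seed is None else seed
    if world.seed != seed:
        world = dataclasses.replace(world, seed=seed)
    regime = generate_regime(design, seed)
    tree = generate_tree(
        world.n_mags, world.tree_birth_rate, world.tree_death_rate, seed
    )
    traits = generate_traits(
        world.n_mags, world.tradeoff_slope, world.trait_noise_sd, seed,
        n_module_types=world.n_module_types,
    )
    abundances = generate_abundances(design, world, traits, seed)
    biomass = generate_biomass(design, world, seed)
    return {
        "design": design,
        "world": world,
        "seed": seed,
        "regime": regime,
        "tree": tree,
        "traits": traits,
        "abundances": abundances,
        "biomass": biomass,
    }
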
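"""Experimental-design and synthetic-world configuration.

The design constants default to the field experiment this package models: a
rocky-shore biofilm warmed in two phases.  Phase 1 applies six biweekly
temperature pulses of +12 degC above ambient, either with zero variance
("fixed") or with an SD of 5 degC across pulses ("fluct-s1/s2/s3", three
distinct sequences sharing the same mean and SD).  Phase 2 applies two
extreme events of 60 degC for 120 min, four days apart.  Unwarmed controls,
plots receiving only the extremes ("extreme-only") and shaded-but-unwarmed
plots ("artifact-control") complete the layout.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

from .errors import InvalidDesignError

CONTROL = "control"
FIXED = "fixed"
FLUCTUATING = ("fluct-s1", "fluct-s2", "fluct-s3")
EXTREME_ONLY = "extreme-only"
ARTIFACT_CONTROL = "artifact-control"

DEFAULT_TREATMENTS = (CONTROL, FIXED) + FLUCTUATING + (EXTREME_ONLY, ARTIFACT_CONTROL)

#: treatments that never receive phase-2 extreme events
UNPERTURBED = (CONTROL, ARTIFACT_CONTROL)

TPM_TOTAL = 1e6

#: pseudo-taxon carrying the unbinned (non-MAG) fraction of each sample, so
#: the community table closes to the TPM constant while the MAG rows remain
#: a sub-composition, as in real metagenome-assembled-genome tables
UNBINNED_ID = "unbinned"


@dataclass(frozen=True)
class RegimeDesign:
    """Warming-regime schedule: pulse statistics, extremes and sampling dates.

    Dates are integer day offsets from the start of the experiment.  The
    default timeline places the six phase-1 pulses biweekly on days 7..77,
    the two extremes on days 84 and 88, four pre-extreme and five
    post-extreme biomass sampling dates, and four community sampling dates
    (start, end of phase 1, after the extremes, end of study).
    """

    treatments: tuple[str, ...] = DEFAULT_TREATMENTS
    plots_per_treatment: int = 4
    n_pulses: int = 6
    pulse_mean_dT: float = 12.0
    pulse_sd_dT: float = 5.0
    pulse_duration_min: float = 70.0
    pulse_days: tuple[int, ...] = (7, 21, 35, 49, 63, 77)
    extreme_temp_C: float = 60.0
    extreme_duration_min: float = 120.0
    n_extremes: int = 2
    extreme_spacing_days: int = 4
    first_extreme_day: int = 84
    sampling_dates_biomass: tuple[int, ...] = (5, 26, 47, 68, 90, 97, 104, 111, 118)
    sampling_dates_community: tuple[int, ...] = (0, 68, 90, 118)

    def __post_init__(self) -> None:
        if self.pulse_sd_dT < 0:
            raise InvalidDesignError("pulse_sd_dT must be non-negative")
        if self.n_pulses < 2 and self.pulse_sd_dT > 0:
            raise InvalidDesignError(
                "a fluctuating sequence needs n_pulses >= 2 (sample SD undefined)"
            )
        if self.plots_per_treatment < 1:
            raise InvalidDesignError("plots_per_treatment must be >= 1")
        if len(self.pulse_days) != self.n_pulses:
            raise InvalidDesignError(
                f"pulse_days has {len(self.pulse_days)} entries for n_pulses={self.n_pulses}"
            )
        if self.n_extremes > 0 and self.pulse_days and self.first_extreme_day <= max(self.pulse_days):
            raise InvalidDesignError("extreme events must occur after all phase-1 pulses")
        for name, dates in (
            ("sampling_dates_biomass", self.sampling_dates_biomass),
            ("sampling_dates_community", self.sampling_dates_community),
        ):
            if list(dates) != sorted(set(dates)):
                raise InvalidDesignError(f"{name} must be strictly increasing")

    @property
    def extreme_days(self) -> tuple[int, ...]:
        return tuple(
            self.first_extreme_day + k * self.extreme_spacing_days
            for k in range(self.n_extremes)
        )

    @property
    def fluctuating_treatments(self) -> tuple[str, ...]:
        return tuple(t for t in self.treatments if t.startswith("fluct"))

    def perturbed_treatments(self) -> tuple[str, ...]:
        """Treatments that receive the phase-2 extreme events."""
        return tuple(t for t in self.treatments if t not in UNPERTURBED)


@dataclass(frozen=True)
class TreatmentEffects:
    """Phase-1 community effects of one warming treatment.

    evenness_exponent scales the spread of baseline log-abundances: values
    below 1 compress rank differences (higher evenness), above 1 stretch
    them.  selection_strength down-weights slow growers (high minimal
    doubling time) with a ramp over the experiment.  richness_loss is the
    probability that a rare genome drops out of the community after the
    first sampling date.
    """

    evenness_exponent: float = 1.0
    selection_strength: float = 0.0
    richness_loss: float = 0.0


@dataclass(frozen=True)
class BiomassEffects:
    """Stability effects of one treatment on log-biomass, relative to control.

    sensitivity_lrr is the immediate post-extreme deviation (log-response
    ratio), resilience_slope the extra slope (LRR per day) of the return
    toward (or past) control, and recovery_offset an additional deviation
    reached at the last sampling date.  The SDs are the nested noise terms:
    residual (plot x date), plot random intercept/slope, and subplot.
    """

    sensitivity_lrr: float = 0.0
    resilience_slope: float = 0.0
    recovery_offset: float = 0.0
    residual_sd: float = 0.08
    plot_intercept_sd: float = 0.05
    plot_slope_sd: float = 0.002
    subplot_sd: float = 0.10

    def __post_init__(self) -> None:
        for name in ("residual_sd", "plot_intercept_sd", "plot_slope_sd", "subplot_sd"):
            if getattr(self, name) < 0:
                raise InvalidDesignError(f"{name} must be non-negative")


def _default_treatment_effects() -> dict[str, TreatmentEffects]:
    eff = {t: TreatmentEffects() for t in DEFAULT_TREATMENTS}
    # fixed warming raises evenness; fluctuating warming selects against
    # slow growers and erodes rare taxa
    eff[FIXED] = TreatmentEffects(evenness_exponent=0.80)
    for t in FLUCTUATING:
        eff[t] = TreatmentEffects(
            evenness_exponent=1.10, selection_strength=0.8, richness_loss=0.30
        )
    return eff


def _default_biomass_effects() -> dict[str, BiomassEffects]:
    eff = {t: BiomassEffects() for t in DEFAULT_TREATMENTS}
    # warming history buffers the extremes; unprepared plots crash and rebound
    eff[EXTREME_ONLY] = BiomassEffects(sensitivity_lrr=-0.60, resilience_slope=0.018)
    eff[FIXED] = BiomassEffects(sensitivity_lrr=-0.12, resilience_slope=0.0)
    for t in FLUCTUATING:
        eff[t] = BiomassEffects(sensitivity_lrr=-0.05, resilience_slope=0.008)
    return eff


@dataclass(frozen=True)
class SyntheticWorldConfig:
    """Parameters of the synthetic world the generator emulates."""

    n_mags: int = 137
    seed: int = 0
    tpm_total: float = TPM_TOTAL
    baseline_lognormal_mu_sigma: tuple[float, float] = (0.0, 1.5)
    treatment_effects: dict[str, TreatmentEffects] = field(
        default_factory=_default_treatment_effects
    )
    tradeoff_slope: float = 2.0
    trait_noise_sd: float = 1.0
    tree_birth_rate: float = 1.0
    tree_death_rate: float = 0.5
    biomass_effects: dict[str, BiomassEffects] = field(
        default_factory=_default_biomass_effects
    )
    n_subplots: int = 6
    abundance_ar1_rho: float = 0.6
    abundance_noise_sd: float = 0.5
    # MAG reads are a sub-composition: binned fraction ~ Beta(a, b) per
    # sample; MAGs below the detection threshold are recorded as absent
    binned_fraction_beta: tuple[float, float] = (13.0, 7.0)
    detection_tpm: float = 200.0
    n_module_types: int = 15
    control_log_biomass0: float = 2.1
    control_biomass_slope: float = 0.004

    def __post_init__(self) -> None:
        if self.n_mags < 2:
            raise InvalidDesignError("n_mags must be >= 2")
        if self.tpm_total <= 0:
            raise InvalidDesignError("tpm_total must be positive")
        for name in ("trait_noise_sd", "abundance_noise_sd"):
            if getattr(self, name) < 0:
                raise InvalidDesignError(f"{name} must be non-negative")

    def config_hash(self) -> str:
        """Stable SHA-256 over the configuration content."""
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


def mag_ids(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"mag_{i + 1:0{width}d}" for i in range(n)]


def plot_ids(design: RegimeDesign) -> dict[str, list[str]]:
    """Unique plot identifiers per treatment (treatment-prefixed)."""
    out: dict[str, list[str]] = {}
    for t in design.treatments:
        out[t] = [f"{t}_p{i + 1}" for i in range(design.plots_per_treatment)]
    return out


def spawn_rng(seed: int, *key: str):
    """Deterministic child generator for a named component.

    Mixes the component name into the seed so each generated artefact has an
    independent stream while the whole world stays reproducible from one
    integer.
    """
    import numpy as np

    digest = hashlib.sha256("/".join(key).encode()).digest()
    salt = int.from_bytes(digest[:4], "little")
    return np.random.default_rng(np.random.SeedSequence([seed, salt]))
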
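import numpy as np
import pytest

from biofilmstab.config import (
    BiomassEffects,
    RegimeDesign,
    SyntheticWorldConfig,
    TreatmentEffects,
)
from biofilmstab.synthesis import generate_world


@pytest.fixture(scope="session")
def default_design() -> RegimeDesign:
    return RegimeDesign()


@pytest.fixture(scope="session")
def small_world() -> dict:
    """Compact world (4 treatments, 20 MAGs) for integration-style tests."""
    design = RegimeDesign(
        treatments=("control", "fixed", "fluct-s1", "extreme-only"),
        plots_per_treatment=3,
    )
    world = SyntheticWorldConfig(n_mags=20, seed=42)
    return generate_world(design, world, seed=42)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def minimal_stability_world():
    """Control + one perturbed treatment at 4 plots x 6 subplots: the
    smallest design on which all four stability dimensions are estimable."""
    design = RegimeDesign(treatments=("control", "extreme-only"))
    effect = BiomassEffects(sensitivity_lrr=-0.5, resilience_slope=0.01)
    world = SyntheticWorldConfig(
        n_mags=10,
        treatment_effects={t: TreatmentEffects() for t in design.treatments},
        biomass_effects={"control": BiomassEffects(), "extreme-only": effect},
    )
    return design, world, effect
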
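import numpy as np
import pytest

from baropop.registry import (apply_obesity_modifiers, build_registry,
                              registry_defaults)

#: Midpoint multipliers of the obese coefficient ranges - the "mean obese
#: patient" used where a single representative hypertensive model suffices.
OBESE_MIDPOINTS = {
    "salt_intake": 1.0, "renal_mass": 1.0, "cardiac_sna_basal": 1.25,
    "peripheral_sna_basal": 1.25, "renal_sna_basal": 1.5,
    "aldo_secretion_gain": 1.0, "renin_secretion_gain": 1.5,
    "sa_rate": 1.125, "fat_mass": 1.4, "pt_fractional_gain": 1.25,
}


@pytest.fixture(scope="session")
def default_coeffs():
    """Single default (Normal) patient coefficient arrays."""
    return {k: np.array([v]) for k, v in registry_defaults().items()}


@pytest.fixture(scope="session")
def obese_coeffs():
    """Single mean obese hypertensive patient."""
    reg = apply_obesity_modifiers(build_registry())
    return {r.name: np.array([r.default * OBESE_MIDPOINTS.get(r.name, 1.0)])
            for r in reg}


def obese_batch(n):
    """n copies of the mean obese patient (for arm batching)."""
    reg = apply_obesity_modifiers(build_registry())
    return {r.name: np.full(n, r.default * OBESE_MIDPOINTS.get(r.name, 1.0))
            for r in reg}


@pytest.fixture(scope="session")
def normal_steady(default_coeffs):
    """Converged steady state of the default model."""
    from baropop.physiology import run_to_steady_state
    return run_to_steady_state(default_coeffs, max_days=10)


@pytest.fixture(scope="session")
def obese_steady(obese_coeffs):
    """Converged hypertensive steady state of the mean obese patient."""
    from baropop.physiology import run_to_steady_state
    return run_to_steady_state(obese_coeffs, max_days=42)
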
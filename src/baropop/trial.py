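"""BAT simulation protocol and clamp experiments.

The protocol runs every patient to a 4-week baseline steady state, captures
the clamp values, switches on baroreflex activation therapy (+40% carotid
afferent input, held constant), and records the full physiological state at
baseline, 1 hour after BAT onset ("immediate"), and after 4 weeks of BAT.

Clamps freeze a quantity at the patient's own pre-BAT steady-state value:

* ``anp``   - plasma ANP,
* ``rsna``  - the baroreflex component of renal sympathetic nerve activity
  (chemoreceptor and ANG II modulation stay live),
* ``angii`` - plasma ANG II,
* ``ne`` / ``epi`` - circulating catecholamines.

All arms of a trial share patient ids and bit-identical baselines (paired
design); only the clamp set differs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import physiology
from .physiology import PhysState, SlowState, fast_equilibrium, run_for
from .population import Population

#: Clamp sets of the standard trial arms.
ARM_CLAMPS: dict[str, tuple[str, ...]] = {
    "control": (),
    "anp": ("anp",),
    "rsna": ("rsna",),
    "combo": ("anp", "rsna"),
    "full": ("anp", "rsna", "angii", "ne", "epi"),
}

OBSERVATION_TIMES = ("baseline", "bat_1h", "bat_4wk")


@dataclass(frozen=True)
class ProtocolSpec:
    """Timing and stimulation settings of the in silico trial."""

    baseline_days: float = 28.0
    bat_gain: float = 0.40
    bat_days: float = 28.0

    def __post_init__(self):
        if self.baseline_days <= 0 or self.bat_days <= 0:
            raise ValueError("durations must be positive")
        if self.bat_gain < 0:
            raise ValueError("BAT gain must be non-negative")


@dataclass(frozen=True)
class ClampSpec:
    """Which quantities are frozen at their pre-BAT values."""

    quantities: tuple[str, ...] = ()

    def __post_init__(self):
        bad = set(self.quantities) - {"anp", "rsna", "angii", "ne", "epi"}
        if bad:
            raise ValueError(f"unknown clamp quantities: {sorted(bad)}")

    def values_from(self, baseline: PhysState) -> dict[str, np.ndarray]:
        """Capture clamp values from a pre-BAT steady state."""
        source = {"anp": baseline.anp, "rsna": baseline.baro_component,
                  "angii": baseline.angii, "ne": baseline.ne,
                  "epi": baseline.epi}
        return {q: np.array(source[q], dtype=float) for q in self.quantities}


@dataclass
class TrialOutput:
    """Time-resolved record of one arm: states at the observation times."""

    arm: str
    ids: np.ndarray
    states: dict[str, PhysState]
    ok: np.ndarray

    def table(self) -> pd.DataFrame:
        """Tidy table: one row per patient x observation time x variable."""
        frames = []
        for t in OBSERVATION_TIMES:
            st = self.states[t]
            df = pd.DataFrame({k: np.asarray(v) for k, v in st.as_dict().items()
                               if k not in ("converged", "ok")})
            df.insert(0, "time", t)
            df.insert(0, "patient_id", self.ids)
            df.insert(0, "arm", self.arm)
            frames.append(df)
        wide = pd.concat(frames, ignore_index=True)
        return wide.melt(id_vars=["arm", "patient_id", "time"],
                         var_name="variable", value_name="value")

    def percent_change(self, variable: str) -> np.ndarray:
        """100 x (4-week - baseline) / baseline for one state variable."""
        pre = np.asarray(getattr(self.states["baseline"], variable), float)
        post = np.asarray(getattr(self.states["bat_4wk"], variable), float)
        return 100.0 * (post - pre) / pre

    def delta(self, variable: str) -> np.ndarray:
        pre = np.asarray(getattr(self.states["baseline"], variable), float)
        post = np.asarray(getattr(self.states["bat_4wk"], variable), float)
        return post - pre


def run_bat_protocol(pop: Population, protocol: ProtocolSpec | None = None,
                     clamp: ClampSpec | None = None, arm: str = "control",
                     curves=None,
                     baseline_state: tuple[SlowState, PhysState] | None = None
                     ) -> TrialOutput:
    """Run one arm of the BAT protocol on a population.

    ``baseline_state`` may carry a pre-computed (slow state, equilibrium)
    pair so that paired arms share bit-identical baselines.
    """
    protocol = protocol or ProtocolSpec()
    clamp = clamp or ClampSpec()
    curves = curves or physiology.DEFAULT_CURVES
    c = pop.coeffs

    if baseline_state is None:
        slow = SlowState.initial(c)
        slow, _ = run_for(slow, c, protocol.baseline_days * 24, curves=curves)
        base = fast_equilibrium(slow, c, curves=curves)
    else:
        slow, base = baseline_state
        slow = slow.copy()

    clamps = clamp.values_from(base)
    g = protocol.bat_gain
    s1, _ = run_for(slow, c, 1, bat_gain=g, clamps=clamps, curves=curves)
    eq1 = fast_equilibrium(s1, c, g, clamps, curves=curves)
    s4, _ = run_for(s1, c, protocol.bat_days * 24 - 1, bat_gain=g,
                    clamps=clamps, curves=curves)
    eq4 = fast_equilibrium(s4, c, g, clamps, curves=curves)

    return TrialOutput(
        arm=arm, ids=pop.ids,
        states={"baseline": base, "bat_1h": eq1, "bat_4wk": eq4},
        ok=base.ok & eq1.ok & eq4.ok,
    )


def run_trial_arms(pop: Population, protocol: ProtocolSpec | None = None,
                   arms: dict[str, tuple[str, ...]] | None = None,
                   curves=None) -> dict[str, TrialOutput]:
    """Run the standard clamp arms on one population (paired design).

    The baseline is computed once and shared across arms, so baselines are
    bit-for-bit identical and arms differ only through clamp effects.
    """
    protocol = protocol or ProtocolSpec()
    arms = arms if arms is not None else ARM_CLAMPS
    curves = curves or physiology.DEFAULT_CURVES
    c = pop.coeffs
    slow = SlowState.initial(c)
    slow, _ = run_for(slow, c, protocol.baseline_days * 24, curves=curves)
    base = fast_equilibrium(slow, c, curves=curves)
    out = {}
    for arm, quantities in arms.items():
        out[arm] = run_bat_protocol(
            pop, protocol, ClampSpec(tuple(quantities)), arm=arm,
            curves=curves, baseline_state=(slow, base))
    return out
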
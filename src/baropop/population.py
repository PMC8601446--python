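"""Virtual-population generation and batch simulation.

An uncalibrated virtual population is created by sampling every registry
coefficient independently and uniformly within its admissible multiplier
range (within 5% of default for most coefficients; wider for the named
exceptions; shifted upward for the obesity modifiers).  Each draw defines a
virtual patient; the whole population is advanced through the simulation
protocol in lock-step by the vectorized physiology engine.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import physiology
from .physiology import PhysState, SlowState, fast_equilibrium, run_for
from .registry import CoefficientRange, apply_obesity_modifiers, build_registry


@dataclass
class Population:
    """A cohort of virtual patients (coefficient arrays + run outputs).

    Attributes
    ----------
    coeffs : dict[str, np.ndarray]
        Coefficient values, one array entry per patient.
    ids : np.ndarray
        Unique integer patient ids.
    baseline, post_bat : PhysState or None
        Steady states captured at the end of the baseline period and after
        4 weeks of BAT (filled by :func:`run_population`).
    ok : np.ndarray
        Per-patient success flag; failed patients carry no trial outputs.
    """

    coeffs: dict[str, np.ndarray]
    ids: np.ndarray
    seed: int | None = None
    baseline: PhysState | None = None
    immediate: PhysState | None = None
    post_bat: PhysState | None = None
    slow_baseline: SlowState | None = None
    ok: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.ids)

    def subset(self, index: np.ndarray) -> "Population":
        """A new population holding only the indexed patients."""
        sub = Population(
            coeffs={k: v[index] for k, v in self.coeffs.items()},
            ids=self.ids[index], seed=self.seed,
        )
        if self.ok is not None:
            sub.ok = self.ok[index]
        return sub

    def to_frame(self) -> pd.DataFrame:
        """Coefficients as a patients x coefficients table."""
        df = pd.DataFrame(self.coeffs)
        df.insert(0, "patient_id", self.ids)
        return df

    def manifest(self) -> dict:
        blob = json.dumps(
            {k: np.round(v, 12).tolist() for k, v in sorted(self.coeffs.items())}
        ).encode()
        return {
            "n_patients": int(len(self)),
            "seed": self.seed,
            "coeff_hash": hashlib.sha256(blob).hexdigest()[:16],
            "n_failed": int((~self.ok).sum()) if self.ok is not None else None,
            "completion_fraction": (
                float(self.ok.mean()) if self.ok is not None else None),
        }


def sample_population(n: int, seed: int, obesity: bool = True,
                      registry: list[CoefficientRange] | None = None) -> Population:
    """Draw ``n`` virtual patients by independent uniform sampling.

    Deterministic per (registry, n, seed).  ``obesity=True`` applies the
    obesity modifier ranges for fat mass and fractional proximal sodium
    reabsorption.
    """
    if n < 1:
        raise ValueError("population size must be >= 1")
    if registry is None:
        registry = build_registry()
    registry = apply_obesity_modifiers(registry, enabled=obesity)
    rng = np.random.default_rng(seed)
    coeffs = {
        r.name: r.default * rng.uniform(r.low, r.high, n) for r in registry
    }
    return Population(coeffs=coeffs, ids=np.arange(n), seed=seed)


def run_population(pop: Population, baseline_days: int = 28,
                   bat_days: int = 28, bat_gain: float = 0.4,
                   curves=None) -> Population:
    """Run baseline + BAT on every patient (no clamps).

    Fills ``baseline`` (end of the baseline period), ``immediate`` (1 h
    after BAT onset) and ``post_bat`` (end of BAT) states, and the ``ok``
    flag.  Patients whose solution fails anywhere are flagged and excluded
    from downstream selection; the pipeline continues.
    """
    curves = curves or physiology.DEFAULT_CURVES
    c = pop.coeffs
    slow = SlowState.initial(c)
    slow, _ = run_for(slow, c, baseline_days * 24, curves=curves)
    base = fast_equilibrium(slow, c, curves=curves)
    pop.slow_baseline = slow
    pop.baseline = base

    s1, _ = run_for(slow.copy(), c, 1, bat_gain=bat_gain, curves=curves)
    pop.immediate = fast_equilibrium(s1, c, bat_gain, curves=curves)
    s4, _ = run_for(s1, c, bat_days * 24 - 1, bat_gain=bat_gain, curves=curves)
    post = fast_equilibrium(s4, c, bat_gain, curves=curves)
    pop.post_bat = post
    pop.ok = base.ok & post.ok & pop.immediate.ok
    return pop
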
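"""Model/Results facade for the in silico BAT trial.

:class:`BATTrialModel` bundles the experimental cohort data (six animal
target points) with the virtual-population settings; fitting the model
runs the uncalibrated population through the BAT protocol, selects patients
inside each animal's 6-D box, builds the kernel mixture, and draws and
simulates the calibrated population.  The returned
:class:`CalibrationResults` carries the calibrated population, per-animal
diagnostics, and methods for the clamp-arm experiments and summary tables.

Example
-------
>>> from baropop.model import BATTrialModel
>>> model = BATTrialModel(n_uncalibrated=1000, seed=1)
>>> res = model.fit()
>>> print(res.summary())
>>> arms = res.run_trial_arms()
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import calibration as cal
from . import physiology
from .cohort import CohortSpec, TargetPoint, cohort_from_frame, generate_cohort
from .population import Population, run_population, sample_population
from .registry import build_registry, registry_defaults
from .physiology import SlowState, fast_equilibrium
from .trial import ARM_CLAMPS, ProtocolSpec, TrialOutput, run_trial_arms


def normal_reference_state(curves=None):
    """Steady state of the single default ("Normal") model."""
    defaults = {k: np.array([v]) for k, v in registry_defaults().items()}
    res = physiology.run_to_steady_state(defaults, max_days=14, curves=curves
                                         or physiology.DEFAULT_CURVES)
    return res.state


class BATTrialModel:
    """In silico trial of baroreflex activation therapy.

    Parameters
    ----------
    animals : list[TargetPoint], optional
        Experimental cohort target points.  By default a seeded synthetic
        6-animal cohort is generated from the documented cohort statistics.
    n_uncalibrated : int
        Size of the uncalibrated virtual population (desk scale 500-1000;
        full scale 7000).
    seed : int
        Master seed; all stage seeds are derived from it.
    k_per_animal : int
        Virtual patients sampled inside each animal's box.
    kernel_half_width : float
        Re-variation of selected coefficient sets (fraction, default 2.5%).
    box_half_width_sds : float
        Box half-width in per-dimension SDs (1.0 = "within one SD").
    selection : {"random", "nearest"}
        How qualifying patients are sampled from a crowded box.
    """

    def __init__(self, animals: list[TargetPoint] | None = None,
                 n_uncalibrated: int = 1000, seed: int = 0,
                 protocol: ProtocolSpec | None = None, k_per_animal: int = 10,
                 kernel_half_width: float = 0.025,
                 box_half_width_sds: float = 1.0, selection: str = "random",
                 cohort_spec: CohortSpec | None = None, curves=None):
        rng = np.random.default_rng(seed)
        self.seed = int(seed)
        self._stage_seeds = {k: int(v) for k, v in zip(
            ("cohort", "population", "selection", "resample"),
            rng.integers(0, 2 ** 31 - 1, size=4))}
        if animals is None:
            spec = cohort_spec or CohortSpec(seed=self._stage_seeds["cohort"])
            animals = generate_cohort(spec)
        self.animals = animals
        self.n_uncalibrated = int(n_uncalibrated)
        self.protocol = protocol or ProtocolSpec()
        self.k_per_animal = int(k_per_animal)
        self.kernel_half_width = float(kernel_half_width)
        self.box_half_width_sds = float(box_half_width_sds)
        self.selection = selection
        self.curves = curves or physiology.DEFAULT_CURVES
        self.registry = build_registry()

    @classmethod
    def from_dataframe(cls, cohort_df: pd.DataFrame, **kwargs) -> "BATTrialModel":
        """Build the model from a cohort table (see cohort.cohort_frame)."""
        return cls(animals=cohort_from_frame(cohort_df), **kwargs)

    def fit(self, uncalibrated: Population | None = None) -> "CalibrationResults":
        """Run the calibration pipeline; returns the results object."""
        if uncalibrated is None:
            uncalibrated = sample_population(
                self.n_uncalibrated, seed=self._stage_seeds["population"])
            uncalibrated = run_population(
                uncalibrated, self.protocol.baseline_days,
                self.protocol.bat_days, self.protocol.bat_gain,
                curves=self.curves)
        mixture, selected, report = cal.calibrate(
            uncalibrated, self.animals, k=self.k_per_animal,
            seed=self._stage_seeds["selection"],
            half_width=self.kernel_half_width,
            half_width_sds=self.box_half_width_sds, method=self.selection,
            registry=self.registry)
        calibrated = cal.resample_calibrated(
            mixture, n_per_center=1, seed=self._stage_seeds["resample"])
        calibrated = run_population(
            calibrated, self.protocol.baseline_days, self.protocol.bat_days,
            self.protocol.bat_gain, curves=self.curves)
        return CalibrationResults(
            model=self, uncalibrated=uncalibrated, calibrated=calibrated,
            mixture=mixture, selected=selected, selection_report=report)


@dataclass
class CalibrationResults:
    """Fitted calibration: calibrated population + diagnostics."""

    model: BATTrialModel
    uncalibrated: Population
    calibrated: Population
    mixture: cal.MixtureDistribution
    selected: dict[int, np.ndarray]
    selection_report: pd.DataFrame
    _arms: dict[str, TrialOutput] | None = field(default=None, repr=False)
    _normal: physiology.PhysState | None = field(default=None, repr=False)

    @property
    def n_calibrated(self) -> int:
        return len(self.calibrated)

    def features(self, which: str = "calibrated") -> np.ndarray:
        pop = self.calibrated if which == "calibrated" else self.uncalibrated
        return cal.feature_vector(pop)

    def zscores(self, which: str = "calibrated") -> pd.DataFrame:
        pop = self.calibrated if which == "calibrated" else self.uncalibrated
        return cal.zscore_report(pop, self.model.animals)

    @property
    def normal_state(self) -> physiology.PhysState:
        if self._normal is None:
            self._normal = normal_reference_state(self.model.curves)
        return self._normal

    def run_trial_arms(self, arms: dict | None = None) -> dict[str, TrialOutput]:
        """Clamp-arm experiments on the calibrated population (cached)."""
        if self._arms is None or arms is not None:
            self._arms = run_trial_arms(self.calibrated, self.model.protocol,
                                        arms=arms, curves=self.model.curves)
        return self._arms

    def map_reductions(self) -> dict[str, float]:
        """Population-mean MAP fall (baseline - week 4, mmHg) per arm."""
        arms = self.run_trial_arms()
        out = {}
        for name, arm in arms.items():
            ok = arm.ok
            out[name] = float(-arm.delta("map")[ok].mean())
        return out

    def summary_tables(self):
        from .stats import summary_tables
        return summary_tables(self.run_trial_arms()["control"],
                              self.normal_state)

    def spearman_table(self) -> pd.DataFrame:
        from .stats import spearman_table
        return spearman_table(self.run_trial_arms()["control"],
                              coeffs=self.calibrated.coeffs)

    def summary(self) -> str:
        """Human-readable calibration summary."""
        zc = self.zscores("calibrated")
        zu = self.zscores("uncalibrated")
        ok = self.calibrated.ok
        feats = self.features()[ok]
        lines = [
            "In silico BAT trial - calibration results",
            "=" * 57,
            f"uncalibrated population : n = {len(self.uncalibrated)}"
            f" (completed {int(self.uncalibrated.ok.sum())})",
            f"animals                 : {len(self.model.animals)}",
            f"calibrated population   : n = {self.n_calibrated}"
            f" (completed {int(ok.sum())})",
            f"kernel half-width       : {self.mixture.half_width:.3f}",
            "",
            "calibrated baseline:  MAP {:6.1f} +/- {:4.1f} mmHg   GFR {:6.1f}"
            " +/- {:4.1f} mL/min   PRA {:4.2f} +/- {:4.2f}".format(
                feats[:, 0].mean(), feats[:, 0].std(),
                feats[:, 1].mean(), feats[:, 1].std(),
                feats[:, 2].mean(), feats[:, 2].std()),
            "after 4 weeks of BAT: MAP {:6.1f} +/- {:4.1f} mmHg   GFR {:6.1f}"
            " +/- {:4.1f} mL/min   PRA {:4.2f} +/- {:4.2f}".format(
                feats[:, 3].mean(), feats[:, 3].std(),
                feats[:, 4].mean(), feats[:, 4].std(),
                feats[:, 5].mean(), feats[:, 5].std()),
            "",
            "per-animal mean |z| (uncalibrated -> calibrated):",
        ]
        for (_, ru), (_, rc) in zip(zu.iterrows(), zc.iterrows()):
            lines.append(
                f"  animal {int(ru.animal_id)}: {ru.mean_abs_z:6.2f} ->"
                f" {rc.mean_abs_z:6.2f}")
        return "\n".join(lines)
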
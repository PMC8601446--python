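"""Calibration of the virtual population against an experimental cohort.

The calibration coordinates are (MAP, GFR, PRA) measured before and after
BAT - a 6-dimensional space.  A box (parallelepiped) is centred on each
animal's data point; virtual patients falling inside the box in all six
dimensions qualify, and a fixed number are sampled per animal.  A uniform
kernel (+/-2.5% of each coefficient, clipped to the registry ranges) is
centred on every selected patient's coefficient set; the equal-weight
mixture of these kernels replaces the original sampling distribution, and
draws from it form the *calibrated* virtual population.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import FEATURE_NAMES, TargetPoint
from .population import Population
from .registry import CoefficientRange, apply_obesity_modifiers, build_registry


def feature_vector(pop: Population) -> np.ndarray:
    """Per-patient 6-vectors (MAP_pre, GFR_pre, PRA_pre, MAP_post, GFR_post,
    PRA_post) from a run population.

    Raises if the population has not been run through the BAT protocol.
    """
    if pop.baseline is None or pop.post_bat is None:
        raise ValueError("trial outputs missing: run the BAT protocol first")
    b, p = pop.baseline, pop.post_bat
    return np.column_stack([b.map, b.gfr, b.pra, p.map, p.gfr, p.pra])


def box_mask(features: np.ndarray, animal: TargetPoint,
             half_width_sds: float = 1.0) -> np.ndarray:
    """Exhaustive box test: inside the animal's parallelepiped in all 6 dims.

    ``half_width_sds`` is the box half-width in units of the per-dimension
    SD.  The default (1.0) accepts patients within one SD per dimension;
    0.5 gives the stricter box whose side length equals one SD.
    """
    d = np.abs(features - animal.features)
    with np.errstate(invalid="ignore"):
        return np.all(d <= half_width_sds * animal.sds, axis=1) & np.all(
            np.isfinite(features), axis=1)


def select_matches(pop: Population, animal: TargetPoint, k: int = 10,
                   seed: int = 0, half_width_sds: float = 1.0,
                   method: str = "random") -> np.ndarray:
    """Indices of up to ``k`` virtual patients matching one animal.

    Qualifiers are patients inside the animal's box (and flagged ok).  If
    more than ``k`` qualify, ``method="random"`` draws ``k`` uniformly at
    random (seeded); ``method="nearest"`` takes the k nearest by
    SD-normalized Euclidean distance (ties broken by patient id).  Fewer
    than ``k`` qualifiers returns them all with a warning; zero qualifiers
    returns an empty selection with a warning and the animal is skipped.
    """
    feats = feature_vector(pop)
    mask = box_mask(feats, animal, half_width_sds)
    if pop.ok is not None:
        mask &= pop.ok
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        warnings.warn(f"animal {animal.animal_id}: no qualifying patients; skipped")
        return idx
    if idx.size < k:
        warnings.warn(
            f"animal {animal.animal_id}: only {idx.size} qualifiers (< {k})")
        return idx
    if method == "nearest":
        z = (feats[idx] - animal.features) / animal.sds
        d = np.sqrt((z ** 2).sum(axis=1))
        order = np.lexsort((pop.ids[idx], d))
        return idx[order[:k]]
    if method != "random":
        raise ValueError(f"unknown selection method {method!r}")
    rng = np.random.default_rng(seed + 1009 * (animal.animal_id + 1))
    return np.sort(rng.choice(idx, size=k, replace=False))


@dataclass
class MixtureDistribution:
    """Equal-weight mixture of uniform kernels in coefficient space."""

    centers: dict[str, np.ndarray]     # coefficient name -> (n_centers,)
    center_ids: np.ndarray             # originating patient ids
    center_animals: np.ndarray         # animal each center was selected for
    half_width: float = 0.025
    registry: list[CoefficientRange] = field(default_factory=build_registry)

    def __post_init__(self):
        if self.half_width < 0:
            raise ValueError("kernel half-width must be non-negative")

    @property
    def n_centers(self) -> int:
        return len(self.center_ids)

    @property
    def weights(self) -> np.ndarray:
        return np.full(self.n_centers, 1.0 / self.n_centers)

    def sample(self, n: int, seed: int = 0,
               obesity: bool = True) -> tuple[dict[str, np.ndarray], np.ndarray]:
        """Draw ``n`` coefficient sets; returns (coeffs, center assignment).

        Each draw picks a kernel centre uniformly and re-varies every
        coefficient uniformly within +/- half_width of the centre value,
        clipped to the registry's admissible range.
        """
        rng = np.random.default_rng(seed)
        which = rng.integers(0, self.n_centers, size=n)
        reg = apply_obesity_modifiers(self.registry, enabled=obesity)
        coeffs = {}
        for r in reg:
            center = self.centers[r.name][which]
            draw = center * rng.uniform(1.0 - self.half_width,
                                        1.0 + self.half_width, size=n)
            lo, hi = r.sample_bounds()
            coeffs[r.name] = np.clip(draw, lo, hi)
        return coeffs, which


def build_mixture(pop: Population, selected: dict[int, np.ndarray],
                  half_width: float = 0.025,
                  registry: list[CoefficientRange] | None = None) -> MixtureDistribution:
    """Mixture distribution from the selected patients of every animal.

    ``selected`` maps animal id -> patient indices (from
    :func:`select_matches`).  A patient selected for two animals
    contributes two centres.
    """
    order = sorted(selected)
    idx = np.concatenate([np.asarray(selected[a], dtype=int) for a in order]) \
        if order else np.array([], dtype=int)
    animals = np.concatenate([
        np.full(len(selected[a]), a, dtype=int) for a in order
    ]) if order else np.array([], dtype=int)
    if idx.size == 0:
        raise ValueError("no selected patients: cannot build mixture")
    return MixtureDistribution(
        centers={k: v[idx] for k, v in pop.coeffs.items()},
        center_ids=pop.ids[idx],
        center_animals=animals,
        half_width=half_width,
        registry=registry or build_registry(),
    )


def resample_calibrated(mixture: MixtureDistribution, n_per_center: int = 1,
                        seed: int = 0) -> Population:
    """Draw the calibrated population (not yet simulated).

    With ``n_per_center=1`` the draw is stratified: exactly one re-varied
    copy of every kernel centre, preserving the selected set's structure.
    Larger values draw ``n_per_center`` per centre.
    """
    n = mixture.n_centers * n_per_center
    rng = np.random.default_rng(seed)
    reg = apply_obesity_modifiers(mixture.registry)
    which = np.repeat(np.arange(mixture.n_centers), n_per_center)
    coeffs = {}
    for r in reg:
        center = mixture.centers[r.name][which]
        draw = center * rng.uniform(1.0 - mixture.half_width,
                                    1.0 + mixture.half_width, size=n)
        lo, hi = r.sample_bounds()
        coeffs[r.name] = np.clip(draw, lo, hi)
    pop = Population(coeffs=coeffs, ids=np.arange(n), seed=seed)
    pop.source_centers = which  # type: ignore[attr-defined]
    pop.source_animals = mixture.center_animals[which]  # type: ignore[attr-defined]
    return pop


def zscore_report(pop: Population, animals: list[TargetPoint]) -> pd.DataFrame:
    """Mean per-dimension |z| of a run population for each animal."""
    feats = feature_vector(pop)
    ok = pop.ok if pop.ok is not None else np.ones(len(pop), bool)
    rows = []
    for a in animals:
        z = np.abs(feats[ok] - a.features) / a.sds
        row = {"animal_id": a.animal_id, "mean_abs_z": float(np.nanmean(z))}
        row.update({f"z_{n}": float(np.nanmean(z[:, j]))
                    for j, n in enumerate(FEATURE_NAMES)})
        rows.append(row)
    return pd.DataFrame(rows)


def calibrate(pop: Population, animals: list[TargetPoint], k: int = 10,
              seed: int = 0, half_width: float = 0.025,
              half_width_sds: float = 1.0, method: str = "random",
              registry: list[CoefficientRange] | None = None):
    """Full selection + mixture construction.

    Returns ``(mixture, selected, report)`` where ``selected`` maps animal
    id -> chosen patient indices and ``report`` is a per-animal summary
    (qualifier count, selected ids).
    """
    feats = feature_vector(pop)
    ok = pop.ok if pop.ok is not None else np.ones(len(pop), bool)
    selected, rows = {}, []
    for a in animals:
        n_qual = int((box_mask(feats, a, half_width_sds) & ok).sum())
        idx = select_matches(pop, a, k=k, seed=seed,
                             half_width_sds=half_width_sds, method=method)
        if idx.size:
            selected[a.animal_id] = idx
        rows.append({"animal_id": a.animal_id, "n_qualifiers": n_qual,
                     "n_selected": int(idx.size),
                     "selected_ids": ";".join(map(str, pop.ids[idx]))})
    report = pd.DataFrame(rows)
    mixture = build_mixture(pop, selected, half_width=half_width,
                            registry=registry)
    return mixture, selected, report
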
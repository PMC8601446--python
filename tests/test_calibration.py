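"""6-D box selection and kernel-mixture resampling (with exhaustive oracles)."""

import types
import warnings

import numpy as np
import pytest

from baropop.calibration import (MixtureDistribution, box_mask, build_mixture,
                                 calibrate, feature_vector, resample_calibrated,
                                 select_matches)
from baropop.cohort import TargetPoint
from baropop.population import Population
from baropop.registry import apply_obesity_modifiers, build_registry


def toy_population(n=50, seed=0):
    """A population with synthetic (not simulated) trial features."""
    rng = np.random.default_rng(seed)
    reg = apply_obesity_modifiers(build_registry())
    coeffs = {r.name: r.default * rng.uniform(r.low, r.high, n) for r in reg}
    pop = Population(coeffs=coeffs, ids=np.arange(n), seed=seed)
    feats = rng.normal([115, 162, 1.4, 100, 150, 1.1],
                       [6, 17, 0.4, 5, 13, 0.4], size=(n, 6))
    pop.baseline = types.SimpleNamespace(map=feats[:, 0], gfr=feats[:, 1],
                                         pra=feats[:, 2])
    pop.post_bat = types.SimpleNamespace(map=feats[:, 3], gfr=feats[:, 4],
                                         pra=feats[:, 5])
    pop.ok = np.ones(n, dtype=bool)
    return pop, feats


ANIMAL = TargetPoint(0, np.array([115.0, 162.0, 1.4, 100.0, 150.0, 1.1]),
                     np.array([6.0, 17.0, 0.4, 5.0, 13.0, 0.4]))


def test_feature_vector_requires_trial_outputs():
    pop = Population(coeffs={}, ids=np.arange(3))
    with pytest.raises(ValueError, match="trial outputs missing"):
        feature_vector(pop)


def test_feature_vector_ordering_convention():
    pop, feats = toy_population()
    np.testing.assert_array_equal(feature_vector(pop), feats)


def test_selection_agrees_with_exhaustive_box_oracle():
    """select_matches == brute-force membership on a 50-patient toy set."""
    pop, feats = toy_population(50, seed=1)
    oracle = np.array([np.all(np.abs(f - ANIMAL.features) <= ANIMAL.sds)
                       for f in feats])
    idx = select_matches(pop, ANIMAL, k=int(oracle.sum()), seed=0)
    assert set(idx) == set(np.flatnonzero(oracle))
    np.testing.assert_array_equal(box_mask(feats, ANIMAL), oracle)


def test_patient_exactly_at_animal_point_is_always_eligible():
    pop, feats = toy_population(20, seed=2)
    feats[7] = ANIMAL.features
    pop.baseline.map = feats[:, 0]  # refresh views
    pop.baseline.gfr = feats[:, 1]
    pop.baseline.pra = feats[:, 2]
    assert box_mask(feats, ANIMAL)[7]
    z = (feats[7] - ANIMAL.features) / ANIMAL.sds
    assert np.all(z == 0)


def test_crowded_box_draws_k_seeded_and_reproducibly():
    pop, _ = toy_population(400, seed=3)
    a = select_matches(pop, ANIMAL, k=10, seed=5)
    b = select_matches(pop, ANIMAL, k=10, seed=5)
    np.testing.assert_array_equal(a, b)
    assert len(a) == 10
    c = select_matches(pop, ANIMAL, k=10, seed=6)
    assert not np.array_equal(a, c)


def test_nearest_mode_orders_by_normalized_distance():
    pop, feats = toy_population(400, seed=3)
    idx = select_matches(pop, ANIMAL, k=5, seed=0, method="nearest")
    z = np.abs(feats - ANIMAL.features) / ANIMAL.sds
    d = np.sqrt((z ** 2).sum(axis=1))
    inside = np.flatnonzero(box_mask(feats, ANIMAL))
    best = inside[np.argsort(d[inside])][:5]
    assert set(idx) == set(best)


def test_sparse_and_empty_boxes_warn():
    pop, _ = toy_population(5, seed=4)
    with warnings.catch_warnings(record=True) as w:
        warnings.simplefilter("always")
        idx = select_matches(pop, ANIMAL, k=10, seed=0)
        far = TargetPoint(1, ANIMAL.features + 1000.0, ANIMAL.sds)
        empty = select_matches(pop, far, k=10, seed=0)
    assert len(idx) < 10 and len(empty) == 0
    assert any("qualif" in str(x.message) for x in w)


def test_mixture_zero_halfwidth_copies_centers_exactly():
    pop, _ = toy_population(30, seed=5)
    sel = {0: np.array([1, 4, 9])}
    mix = build_mixture(pop, sel, half_width=0.0)
    draws, which = mix.sample(30, seed=0)
    for name in draws:
        np.testing.assert_allclose(draws[name],
                                   mix.centers[name][which])


def test_mixture_draws_stay_within_kernel_and_registry():
    pop, _ = toy_population(30, seed=6)
    sel = {0: np.array([2])}
    mix = build_mixture(pop, sel, half_width=0.025)
    draws, _ = mix.sample(2000, seed=1)
    reg = apply_obesity_modifiers(build_registry())
    for r in reg:
        center = mix.centers[r.name][0]
        lo, hi = r.sample_bounds()
        v = draws[r.name]
        assert np.all(v >= max(center * 0.975, lo) - 1e-12)
        assert np.all(v <= min(center * 1.025, hi) + 1e-12)


def test_center_assignment_frequencies_are_uniform():
    """Multinomial oracle: equal kernel weights at n = 10,000 draws."""
    pop, _ = toy_population(30, seed=7)
    sel = {0: np.arange(5)}
    mix = build_mixture(pop, sel)
    _, which = mix.sample(10_000, seed=2)
    counts = np.bincount(which, minlength=5)
    from scipy import stats as sps
    _, p = sps.chisquare(counts)
    assert p > 1e-4
    assert np.all(np.abs(counts / 10_000 - 0.2) < 0.02)


def test_six_animals_times_ten_gives_sixty_centers():
    pop, _ = toy_population(30, seed=8)
    sel = {a: np.arange(10) for a in range(6)}
    mix = build_mixture(pop, sel)
    assert mix.n_centers == 60
    assert mix.weights.sum() == pytest.approx(1.0)
    calib = resample_calibrated(mix, n_per_center=1, seed=3)
    assert len(calib) == 60
    again = resample_calibrated(mix, n_per_center=1, seed=3)
    for k in calib.coeffs:
        np.testing.assert_array_equal(calib.coeffs[k], again.coeffs[k])


def test_calibrate_report_lists_qualifiers_and_selected_ids():
    pop, _ = toy_population(400, seed=9)
    animals = [ANIMAL, TargetPoint(1, ANIMAL.features, ANIMAL.sds)]
    mix, sel, report = calibrate(pop, animals, k=10, seed=0)
    assert set(report.columns) >= {"animal_id", "n_qualifiers", "n_selected"}
    assert (report.n_selected == 10).all()
    assert mix.n_centers == 20
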
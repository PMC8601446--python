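"""Core physiology: normal anchors, conservation, stepping contracts."""

import dataclasses

import numpy as np
import pytest

import baropop.physiology as ph
from baropop.physiology import (SlowState, advance, anp_secretion,
                                autonomic_outflow, carotid_baroreceptor_activity,
                                catecholamines, fast_equilibrium,
                                fluid_compartments, glomerular_filtration,
                                renal_function_curve,
                                renin_angiotensin_aldosterone,
                                run_to_steady_state, tgf_signal)


# -------------------------------------------------------------- anchors
NORMAL_ANCHORS = [
    ("map", 92.0), ("hr", 72.0), ("tpr", 0.018), ("gfr", 123.0),
    ("rbf", 1025.0), ("ptnar", 10.0), ("anp", 25.0), ("ne", 234.0),
]


@pytest.mark.parametrize("var,expected", NORMAL_ANCHORS)
def test_default_model_reproduces_normal_operating_point(normal_steady, var, expected):
    """The default coefficient set sits at the Normal table values (2%)."""
    value = float(np.asarray(getattr(normal_steady.state, var))[0])
    assert value == pytest.approx(expected, rel=0.02)


def test_normal_volumes_and_hormones(normal_steady):
    st = normal_steady.state
    assert float(st.ecfv[0]) == pytest.approx(15.4, rel=0.02)
    assert float(st.blood_volume[0]) == pytest.approx(5700.0, rel=0.02)
    assert float(st.co[0]) == pytest.approx(5200.0, rel=0.02)
    assert float(st.renin_secretion[0]) == pytest.approx(80.0, rel=0.02)
    assert float(st.angii[0]) == pytest.approx(11.0, rel=0.02)
    assert float(st.aldo[0]) == pytest.approx(272.0, rel=0.02)
    assert float(st.aa_resistance[0]) == pytest.approx(0.063, rel=0.02)
    assert float(np.asarray(st.sna_renal)[0]) == pytest.approx(1.5, rel=0.02)


def test_tpr_identity_and_positivity(normal_steady, obese_steady):
    """TPR = (MAP - RAP)/CO within solver tolerance; all states positive."""
    for res in (normal_steady, obese_steady):
        st = res.state
        assert float(st.tpr[0]) == pytest.approx(
            float((st.map[0] - st.rap[0]) / st.co[0]), rel=1e-8)
        for name in ("map", "hr", "co", "blood_volume", "ecfv", "gfr",
                     "anp", "ne", "aldo", "ff"):
            assert np.all(np.asarray(getattr(st, name)) > 0), name


def test_sodium_mass_conservation_at_steady_state(normal_steady, obese_steady,
                                                  default_coeffs, obese_coeffs):
    """|excretion - intake|/intake < 0.1% at any converged steady state."""
    for res, coeffs in ((normal_steady, default_coeffs),
                        (obese_steady, obese_coeffs)):
        intake = float(coeffs["salt_intake"][0]) / 1440.0
        una = float(res.state.na_excretion[0])
        assert abs(una - intake) / intake < 1e-3
        assert bool(res.converged[0])


def test_obese_midpoint_coefficients_are_hypertensive(obese_steady):
    """Obesity modifiers at range midpoints produce MAP > 100 mmHg."""
    assert float(obese_steady.state.map[0]) > 100.0


def test_nephron_arithmetic(normal_steady):
    """GFR = SNGFR x nephron count: 123 mL/min over 2.4M -> ~51 nL/min."""
    st = normal_steady.state
    assert float(st.sngfr[0]) == pytest.approx(
        float(st.gfr[0]) / 2.4, rel=1e-9)
    assert float(st.sngfr[0]) == pytest.approx(51.25, rel=0.02)


# -------------------------------------------------------------- stepping
def test_advance_at_steady_state_leaves_state_unchanged(normal_steady,
                                                        default_coeffs):
    slow = normal_steady.slow.copy()
    # polish the hormone pools onto the exact fixed point first
    for _ in range(12):
        slow, _ = advance(slow, default_coeffs, 1.0, solver_tol=1e-13)
    new, _ = advance(slow.copy(), default_coeffs, 1.0, solver_tol=1e-13)
    for f in dataclasses.fields(SlowState):
        a = np.asarray(getattr(slow, f.name), float)
        b = np.asarray(getattr(new, f.name), float)
        assert np.all(np.abs(b - a) / np.maximum(np.abs(a), 1e-9) < 1e-10), f.name


def test_step_halving_agreement_over_seven_days(obese_coeffs):
    """Full steps vs half steps agree within 1e-4 relative on slow states."""
    from baropop.physiology import run_for

    a = SlowState.initial(obese_coeffs)
    b = a.copy()
    a, _ = run_for(a, obese_coeffs, 7 * 24, dt_hours=1.0)
    b, _ = run_for(b, obese_coeffs, 7 * 24, dt_hours=0.5)
    for f in dataclasses.fields(SlowState):
        x = np.asarray(getattr(a, f.name), float)
        y = np.asarray(getattr(b, f.name), float)
        assert np.all(np.abs(x - y) / np.maximum(np.abs(x), 1e-9) < 1e-4), f.name


def test_trajectories_are_deterministic(obese_coeffs):
    from baropop.physiology import run_for

    s1, e1 = run_for(SlowState.initial(obese_coeffs), obese_coeffs, 48)
    s2, e2 = run_for(SlowState.initial(obese_coeffs), obese_coeffs, 48)
    assert np.array_equal(s1.na, s2.na)
    assert np.array_equal(e1.map, e2.map)


def test_nan_state_is_flagged_not_silent(default_coeffs):
    slow = SlowState.initial(default_coeffs)
    slow.na = np.array([np.nan])
    eq = fast_equilibrium(slow, default_coeffs)
    assert not bool(eq.ok[0])


def test_pathological_coefficients_flagged_not_crashed(default_coeffs):
    """Zero salt intake drains sodium: flagged non-physical, no exception."""
    bad = {k: v.copy() for k, v in default_coeffs.items()}
    bad["salt_intake"] = np.array([0.0])
    res = run_to_steady_state(bad, max_days=20)
    assert res.state.ok.shape == (1,)
    assert not bool(res.converged[0]) or float(res.state.map[0]) < 80.0


# -------------------------------------------------------------- reflex ops
def test_carotid_afferent_normalization_and_bat_gain():
    assert carotid_baroreceptor_activity(92.0, 92.0) == pytest.approx(1.0)
    assert carotid_baroreceptor_activity(92.0, 92.0, bat_gain=0.4) == pytest.approx(1.4)
    # monotone increasing in MAP
    lo, hi = carotid_baroreceptor_activity(np.array([80.0, 120.0]), 92.0)
    assert hi > lo
    with pytest.raises(ValueError):
        carotid_baroreceptor_activity(np.nan, 92.0)


def test_bat_input_does_not_adapt(obese_coeffs, obese_steady):
    """The +40% afferent multiplier is chronically sustained."""
    from baropop.physiology import run_for

    slow = obese_steady.slow.copy()
    slow, _ = run_for(slow, obese_coeffs, 28 * 24, bat_gain=0.4)
    eq = fast_equilibrium(slow, obese_coeffs, bat_gain=0.4)
    base = eq.afferent / (1.0 + 0.4)
    assert float(eq.afferent[0]) == pytest.approx(float(base[0]) * 1.4, rel=1e-12)
    # partial resetting: setpoint moved toward prevailing MAP but not fully
    assert float(slow.setpoint[0]) < float(obese_steady.slow.setpoint[0])
    assert float(slow.setpoint[0]) > float(eq.map[0]) - 0.95 * abs(
        float(eq.map[0]) - 92.0)


def test_autonomic_outflow_anchor_and_suppression():
    out = autonomic_outflow(1.0)
    for k in ("cardiac", "renal", "peripheral", "adrenal"):
        assert float(out[k]) == pytest.approx(1.5, rel=1e-9)
    sup = autonomic_outflow(1.4)
    for k in ("cardiac", "renal", "peripheral", "adrenal"):
        assert float(sup[k]) < 1.5


def test_rsna_clamp_leaves_chemo_and_angii_modulation_live():
    """Frozen baroreflex component: residual RSNA change < 5%."""
    free = autonomic_outflow(1.4, chemo=1.05, angii=14.0)
    frozen = autonomic_outflow(1.4, chemo=1.05, angii=14.0,
                               baro_override=1.0)
    assert float(frozen["renal"]) == pytest.approx(1.5 * 1.05 * (1 + 0.05 * 3 / 11),
                                                   rel=1e-9)
    # modulation is small relative to the baroreflex component
    assert abs(float(frozen["renal"]) / 1.5 - 1.0) < 0.10
    assert float(free["renal"]) < float(frozen["renal"])


# -------------------------------------------------------------- hormone ops
def test_raas_anchor_and_multiplicative_structure():
    out = renin_angiotensin_aldosterone(ph.MD_N, 1.0, ph.ANP_N)
    assert float(out["renin_secretion"]) == pytest.approx(80.0, rel=1e-9)
    assert float(out["angii"]) == pytest.approx(11.0, rel=1e-9)
    assert float(out["aldosterone"]) == pytest.approx(272.0, rel=1e-9)
    doubled = renin_angiotensin_aldosterone(ph.MD_N, 1.0, ph.ANP_N,
                                            renin_gain=2.0)
    assert float(doubled["renin_secretion"]) == pytest.approx(160.0, rel=1e-9)


def test_anp_secretion_anchor_and_monotonicity():
    assert float(anp_secretion(1.0)) == pytest.approx(25.0, rel=1e-9)
    assert float(anp_secretion(1.4)) > float(anp_secretion(1.0))
    with pytest.raises(ValueError):
        anp_secretion(np.nan)


def test_catecholamines_anchor_and_floor():
    sna = {"peripheral": 1.5, "adrenal": 1.5}
    out = catecholamines(sna)
    assert float(out["norepinephrine"]) == pytest.approx(234.0, rel=1e-9)
    zero = catecholamines({"peripheral": 0.0, "adrenal": 0.0})
    assert 0.0 < float(zero["norepinephrine"]) < 234.0


def test_tgf_signal_anchor_saturation_and_modulation():
    assert float(tgf_signal(ph.MD_N)) == pytest.approx(1.0, abs=1e-12)
    assert float(tgf_signal(0.0)) < 1.0
    assert float(tgf_signal(2 * ph.MD_N)) > 1.0
    # ANG II steepens, ANP blunts the deviation from 1
    high = tgf_signal(1.5 * ph.MD_N)
    assert float(tgf_signal(1.5 * ph.MD_N, angii=2 * ph.ANGII_N)) > float(high)
    assert float(tgf_signal(1.5 * ph.MD_N, anp=2 * ph.ANP_N)) < float(high)


# -------------------------------------------------------------- glomerulus
def test_glomerular_filtration_scalar_solver_matches_engine(normal_steady):
    """Bracketed scalar solve agrees with the vectorized equilibrium."""
    st = normal_steady.state
    out = glomerular_filtration(float(st.p_c[0]), float(st.rpf[0]))
    assert out["gfr"] == pytest.approx(float(st.gfr[0]), rel=1e-5)
    assert out["ff"] == pytest.approx(float(st.ff[0]), rel=1e-5)
    assert 0.0 < out["ff"] < 1.0


def test_glomerular_filtration_zero_kf_limit():
    out = glomerular_filtration(60.0, 560.0, kf_gain=1e-12)
    assert out["sngfr"] == pytest.approx(0.0, abs=1e-6)
    with pytest.raises(ValueError):
        glomerular_filtration(60.0, -1.0)


# -------------------------------------------------------------- pressure
def test_pressure_natriuresis_is_strictly_increasing():
    """At fixed neurohumoral inputs, excretion rises with perfusion pressure."""
    grid = np.linspace(75.0, 160.0, 35)
    una = renal_function_curve(grid)
    assert np.all(np.diff(una) > 0)
    assert renal_function_curve([92.0])[0] == pytest.approx(ph.UNA_N, rel=1e-6)


def test_myogenic_tone_resets_within_two_days(obese_coeffs, obese_steady):
    """A perturbed myogenic reference relaxes back: effect 1.00 +/- 0.005."""
    from baropop.physiology import run_for

    slow = obese_steady.slow.copy()
    slow.pref = slow.pref - 25.0  # myogenic effect jumps to ~1.1
    eq0 = fast_equilibrium(slow, obese_coeffs)
    assert float(eq0.e_myo_aa[0]) > 1.05
    slow, _ = run_for(slow, obese_coeffs, 48)
    eq = fast_equilibrium(slow, obese_coeffs)
    assert float(eq.e_myo_aa[0]) == pytest.approx(1.0, abs=0.005)


def test_fluid_compartments_anchor_and_monotonicity():
    out = fluid_compartments(ph.NA_N, ph.MAP_N)
    assert float(out["ecfv"]) == pytest.approx(15.4, rel=1e-9)
    assert float(out["blood_volume"]) == pytest.approx(5700.0, rel=1e-9)
    more = fluid_compartments(ph.NA_N * 1.05, ph.MAP_N)
    assert float(more["blood_volume"]) > 5700.0
    assert float(more["rifp"]) > float(out["rifp"])
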
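"""Reduced whole-body cardiovascular-renal model.

The model follows the long-term (Guytonian) view of arterial-pressure
regulation: the fast circulation (heart, vascular tree, autonomic reflexes)
is in quasi-steady state at every instant, while chronic mean arterial
pressure (MAP) is set by renal sodium balance - the kidney excretes sodium
at a rate that depends on perfusion pressure (pressure natriuresis) and on
neurohumoral modifiers, and extracellular volume integrates intake minus
excretion until the two match.

State is split accordingly:

* **slow states** (integrated in time): extracellular sodium mass, the
  baroreceptor afferent setpoint (partial resetting), the myogenic pressure
  reference of the afferent arteriole, and first-order hormone pools for
  plasma renin activity (PRA) and aldosterone.
* **fast states** (solved algebraically each step): MAP, cardiac output,
  right atrial pressure, heart rate, the sympathetic channels, hormones
  slaved to the fast states (ANP, catecholamines, ANG II from the PRA
  pool), and the full renal sub-state (glomerular filtration with an
  implicit filtration-fraction equation, tubuloglomerular feedback, and
  segmental sodium reabsorption).

Everything is vectorized over patients: coefficients arrive as a mapping of
name -> ndarray and all operations broadcast, so a whole virtual population
advances in lock-step.

Baroreflex activation therapy (BAT) enters as a multiplicative gain on the
carotid afferent *after* setpoint adaptation, so a +40% input is sustained
chronically.  Clamp experiments freeze ANP, the baroreflex component of
renal sympathetic nerve activity (RSNA), ANG II, norepinephrine, and/or
epinephrine at externally supplied (pre-intervention) values.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .effects import EffectSpec, effect_multiplier
from .effects import _eval as _em

# --------------------------------------------------------------------------
# Normal operating-point anchors (model units).  The default coefficient set
# reproduces these exactly at steady state; every effect curve is normalized
# to 1 at the corresponding anchor input.
# --------------------------------------------------------------------------
MAP_N = 92.0            # mmHg
RAP_N = 1.0             # mmHg
CO_N = 5110.0           # mL/min
HR_N = 72.0             # bpm
SV_N = CO_N / HR_N      # mL
BV_N = 5700.0           # mL
ECFV_N = 15.4           # L
NA_CONC = 136.0         # mmol/L plasma sodium (held by ad-libitum water)
NA_N = NA_CONC * ECFV_N  # mmol extracellular sodium
MSFP_N = 7.0            # mmHg mean systemic filling pressure
HCT_N = 0.45
GFR_N = 123.0           # mL/min
RBF_N = 1025.0          # mL/min
RPF_N = RBF_N * (1.0 - HCT_N)
FF_N = GFR_N / RPF_N
NEPH_N = 2.4            # million nephrons
SNGFR_N = GFR_N / NEPH_N  # nL/min
P_BC_N = 14.0           # mmHg Bowman's capsule pressure
PI_N = 28.0             # mmHg mean glomerular oncotic pressure
P_C_N = MAP_N - 0.5 * RBF_N * 0.063   # 59.7125 mmHg glomerular pressure
KF_SN = SNGFR_N / (P_C_N - P_BC_N - PI_N)  # nL/min/mmHg single-nephron Kf
FL_N = GFR_N * NA_CONC / 1000.0  # mmol/min filtered sodium load (16.728)
PTNAR_N = 10.0          # mmol/min proximal reabsorption
UNA_N = 139.0 / 1440.0  # mmol/min excretion at normal intake
LOOP_FRAC = 0.67
DT_FRAC = 0.62
_D1_N = FL_N - PTNAR_N
_MD_N = _D1_N * (1.0 - LOOP_FRAC)          # 2.22024 mmol/min macula densa
_DT_N = DT_FRAC * _MD_N
_CDLOAD_N = _MD_N - _DT_N
CD_FRAC = (_CDLOAD_N - UNA_N) / _CDLOAD_N  # collecting-duct fraction
MD_N = _MD_N
NE_N = 234.0            # pg/mL
EPI_N = 40.0            # pg/mL
ANP_N = 25.0            # pMol/L
RS_N = 80.0             # model units renin secretion
ANGII_N = 11.0          # pg/mL
ALDO_N = 272.0          # pMol/L
RIFP_N = 4.0            # mmHg renal interstitial fluid pressure
LAP_N = 5.0             # mmHg

SNA_KEYS = ("cardiac", "renal", "peripheral", "adrenal")


# --------------------------------------------------------------------------
# Structural curve constants.  Slopes were tuned once so that the calibrated
# hypertensive population reproduces the documented baseline/BAT operating
# anchors; they are fixed model structure (per-patient variability acts via
# the registry sensitivity coefficients that scale them).
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class Curves:
    baro_slope: float = 0.03          # /mmHg carotid afferent slope
    symp_cardiac: EffectSpec = EffectSpec(0.20, 1.70, -2.10, 1.0)
    symp_renal: EffectSpec = EffectSpec(0.20, 1.70, -1.75, 1.0)
    symp_peripheral: EffectSpec = EffectSpec(0.25, 1.65, -1.85, 1.0)
    symp_adrenal: EffectSpec = EffectSpec(0.20, 1.70, -2.00, 1.0)
    hr: EffectSpec = EffectSpec(0.45, 1.20, 2.00, 1.5)
    inotropy: EffectSpec = EffectSpec(0.60, 1.35, 0.90, 1.5)
    venous_tone_slope: float = 0.15   # unstressed volume per unit SNA fall
    ne_exponent: float = 0.90
    ne_floor: float = 0.04
    anp_secretion: EffectSpec = EffectSpec(0.20, 2.33, 4.75, RAP_N)
    lap_slope: float = 2.5            # mmHg LAP per mmHg RAP
    md_renin: EffectSpec = EffectSpec(0.30, 2.00, -2.00, 1.0)
    b1_renin: EffectSpec = EffectSpec(0.25, 2.30, 1.85, 1.0)
    b1_rsna_weight: float = 0.40      # share of beta1 drive from RSNA vs NE
    ne_pt_exp: float = 0.60           # circulating-NE effect on PT reabsorption
    anp_renin: EffectSpec = EffectSpec(0.50, 1.50, -0.25, 1.0)
    angii_aldo: EffectSpec = EffectSpec(0.40, 2.00, 0.55, 1.0)
    angii_ea: EffectSpec = EffectSpec(0.40, 2.80, 1.60, 1.0)
    angii_pt: EffectSpec = EffectSpec(0.60, 1.80, 1.10, 1.0)
    sna_pt: EffectSpec = EffectSpec(0.60, 1.32, 5.50, 1.5)
    anp_pt: EffectSpec = EffectSpec(0.70, 1.30, -0.70, 1.0)
    ifp_pt: EffectSpec = EffectSpec(0.10, 1.01, -0.90, RIFP_N)
    ifp_pressure_exp: float = 3.0
    ifp_volume_exp: float = 0.2
    tgf: EffectSpec = EffectSpec(0.45, 1.80, 2.20, MD_N)
    tgf_angii_exp: float = 0.25
    tgf_anp_exp: float = 0.20
    rifp_cd_exp: float = 0.12         # direct pressure diuresis at the CD
    cd_load_exp: float = 0.60         # fractional CD reabsorption vs delivered load
    loop_load_exp: float = 1.20       # loop reabsorption vs delivered load
    loop_tm_cap: float = 2.5          # loop transport maximum (x normal)
    anp_aa: EffectSpec = EffectSpec(0.75, 1.15, -0.45, 1.0)
    sna_aa: EffectSpec = EffectSpec(0.80, 1.30, 0.60, 1.5)
    myogenic_slope: float = 0.004     # /mmHg
    autoreg_exp: float = 1.30         # non-resetting renal autoregulation
    viscosity_exp: float = 0.66       # AA resistance vs hematocrit
    chemo_slope: float = 0.25         # RSNA drive per unit fat-mass excess
    angii_rsna_slope: float = 0.05
    sna_vasc: EffectSpec = EffectSpec(0.55, 1.45, -0.55, 1.5)
    angii_vasc: EffectSpec = EffectSpec(0.70, 1.40, 0.50, 1.0)
    aldo_dt: EffectSpec = EffectSpec(0.50, 1.60, 0.30, 1.0)
    aldo_cd: EffectSpec = EffectSpec(0.50, 1.60, 0.50, 1.0)
    anp_cd: EffectSpec = EffectSpec(0.55, 1.35, -0.58, 1.0)
    pt_load_exp: float = 1.00         # glomerulotubular-balance saturation
    pt_obesity_exp: float = 0.25
    pbc_exp: float = 2.00             # tubular pressure vs SNGFR
    oncotic_ff_slope: float = 0.35
    ace_exp: float = 0.80             # saturating PRA -> ANG II conversion    # mean oncotic pressure vs FF
    bv_ecfv_exp: float = 1.534        # blood volume compliance exponents
    bv_map_exp: float = 0.42
    adapt_ref: float = MAP_N          # baroreceptor structural reference
    tau_setpoint_h: float = 72.0      # baroreflex resetting time constant
    tau_myogenic_h: float = 12.0
    tau_pra_h: float = 0.5
    tau_aldo_h: float = 3.0
    tau_rifp_h: float = 18.0
    pra_scale: float = 0.80           # PRA units per unit normalized renin secretion


DEFAULT_CURVES = Curves()


# --------------------------------------------------------------------------
# Containers
# --------------------------------------------------------------------------
@dataclass
class SlowState:
    """Integrated (slow) model states, one entry per patient."""

    na: np.ndarray        # mmol extracellular sodium
    setpoint: np.ndarray  # mmHg baroreceptor afferent setpoint
    pref: np.ndarray      # mmHg myogenic pressure reference
    pra: np.ndarray       # PRA pool (normal = 1)
    aldo: np.ndarray      # pMol/L aldosterone pool
    rifp: np.ndarray      # mmHg renal interstitial fluid pressure (slow)

    def copy(self) -> "SlowState":
        return SlowState(*(np.array(getattr(self, f.name)) for f in dataclasses.fields(self)))

    @classmethod
    def initial(cls, coeffs: dict[str, np.ndarray]) -> "SlowState":
        """Start every patient at the normal operating point."""
        n = np.broadcast(*coeffs.values()).shape or (1,)
        ones = np.ones(n)
        return cls(
            na=NA_N * ones,
            setpoint=MAP_N * ones,
            pref=MAP_N * ones,
            pra=np.ones_like(ones),
            aldo=ALDO_N * np.asarray(coeffs["aldo_secretion_gain"], dtype=float) * ones,
            rifp=RIFP_N * ones,
        )


@dataclass
class PhysState:
    """Full physiological state at one time point (arrays over patients)."""

    map: np.ndarray
    hr: np.ndarray
    co: np.ndarray
    tpr: np.ndarray
    rap: np.ndarray
    lap: np.ndarray
    msfp: np.ndarray
    blood_volume: np.ndarray
    plasma_volume: np.ndarray
    vein_volume: np.ndarray
    ecfv: np.ndarray
    hct: np.ndarray
    plasma_na: np.ndarray
    rifp: np.ndarray
    afferent: np.ndarray
    baro_component: np.ndarray
    atrial_activity: np.ndarray
    sna_cardiac: np.ndarray
    sna_renal: np.ndarray
    sna_peripheral: np.ndarray
    sna_adrenal: np.ndarray
    ne: np.ndarray
    epi: np.ndarray
    anp: np.ndarray
    pra: np.ndarray
    angii: np.ndarray
    aldo: np.ndarray
    renin_secretion: np.ndarray
    # renal sub-state
    gfr: np.ndarray
    sngfr: np.ndarray
    ff: np.ndarray
    rbf: np.ndarray
    rpf: np.ndarray
    kf: np.ndarray
    p_c: np.ndarray
    p_bc: np.ndarray
    p_osm: np.ndarray
    aa_resistance: np.ndarray
    ea_resistance: np.ndarray
    md_na: np.ndarray
    tgf: np.ndarray
    filtered_load: np.ndarray
    ptnar: np.ndarray
    loopnar: np.ndarray
    dtnar: np.ndarray
    cdnar: np.ndarray
    total_nar: np.ndarray
    na_excretion: np.ndarray
    # effect multipliers (reported in the renal table)
    e_md_renin: np.ndarray
    e_b1_renin: np.ndarray
    e_angii_pt: np.ndarray
    e_sna_pt: np.ndarray
    e_anp_pt: np.ndarray
    e_ifp_pt: np.ndarray
    e_tgf: np.ndarray
    e_visc_aa: np.ndarray
    e_anp_aa: np.ndarray
    e_sna_aa: np.ndarray
    e_myo_aa: np.ndarray
    # bookkeeping
    converged: np.ndarray = field(default=None)
    ok: np.ndarray = field(default=None)

    def as_dict(self) -> dict[str, np.ndarray]:
        return {f.name: getattr(self, f.name) for f in dataclasses.fields(self)}


@dataclass
class SteadyStateResult:
    """Outcome of :func:`run_to_steady_state`."""

    state: PhysState
    slow: SlowState
    converged: np.ndarray
    days: float
    max_rel_daily_change: np.ndarray


# --------------------------------------------------------------------------
# Elementary operations (shared by the vectorized engine and usable alone)
# --------------------------------------------------------------------------
def carotid_baroreceptor_activity(map_mmhg, setpoint, bat_gain=0.0,
                                  gain=1.0, curves: Curves = DEFAULT_CURVES):
    """Normalized carotid afferent input to the CNS.

    A logistic function of MAP around the (slowly adapting) setpoint,
    multiplied by ``1 + bat_gain`` so device stimulation raises the input
    by a sustained fraction regardless of resetting.
    """
    map_mmhg = np.asarray(map_mmhg, dtype=float)
    if not np.all(np.isfinite(map_mmhg)):
        raise ValueError("non-finite MAP")
    if np.any(map_mmhg <= 0):
        raise ValueError("MAP must be positive")
    u = np.clip(curves.baro_slope * gain * (map_mmhg - setpoint), -60.0, 60.0)
    return (2.0 / (1.0 + np.exp(-u))) * (1.0 + bat_gain)


def autonomic_outflow(afferent, chemo=1.0, angii=ANGII_N,
                      basal=(1.5, 1.5, 1.5, 1.5), gains=(1.0, 1.0, 1.0, 1.0),
                      curves: Curves = DEFAULT_CURVES,
                      baro_override=None):
    """Sympathetic outflow (Hz) per channel for a given afferent input.

    Each channel falls monotonically with afferent activity.  The renal
    channel is additionally (weakly) driven by chemoreceptor input and
    circulating ANG II; ``baro_override`` replaces its baroreflex component
    (the RSNA clamp contract - chemo/ANG II modulation stays live).
    """
    afferent = np.asarray(afferent, dtype=float)
    if np.any(afferent <= 0):
        raise ValueError("afferent activity must be positive")
    bc, br, bp, ba = basal
    gc, gr, gp, ga = gains
    renal_baro = effect_multiplier(afferent, curves.symp_renal, gr)
    if baro_override is not None:
        renal_baro = np.asarray(baro_override, dtype=float)
    e_angii = 1.0 + curves.angii_rsna_slope * (np.asarray(angii, float) / ANGII_N - 1.0)
    return {
        "cardiac": bc * effect_multiplier(afferent, curves.symp_cardiac, gc),
        "renal": br * renal_baro * np.asarray(chemo, float) * e_angii,
        "peripheral": bp * effect_multiplier(afferent, curves.symp_peripheral, gp),
        "adrenal": ba * effect_multiplier(afferent, curves.symp_adrenal, ga),
        "renal_baro_component": renal_baro,
    }


def catecholamines(sna, ne_gain=1.0, epi_gain=1.0, curves: Curves = DEFAULT_CURVES):
    """Circulating norepinephrine / epinephrine from sympathetic outflow.

    NE follows spillover from the peripheral channel with a saturating
    power law and a strictly positive floor; the adrenal channel drives
    epinephrine.
    """
    p = np.asarray(sna["peripheral"], dtype=float)
    a = np.asarray(sna["adrenal"], dtype=float)
    fl = curves.ne_floor
    ne = NE_N * ne_gain * (fl + (1 - fl) * np.maximum(p / 1.5, 0.0) ** curves.ne_exponent)
    epi = EPI_N * epi_gain * (fl + (1 - fl) * np.maximum(a / 1.5, 0.0))
    return {"norepinephrine": ne, "epinephrine": epi}


def anp_secretion(rap, lap=None, gain=1.0, curves: Curves = DEFAULT_CURVES):
    """Plasma ANP (pMol/L) as a saturating function of atrial pressure.

    Secretion rises with atrial stretch; normal pressures give 25 pMol/L.
    The left atrium tracks the right in this reduced circulation, so the
    right atrial pressure carries the signal; a supplied LAP contributes a
    small additive stretch term.
    """
    rap = np.asarray(rap, dtype=float)
    if not np.all(np.isfinite(rap)):
        raise ValueError("non-finite atrial pressure")
    drive = rap
    if lap is not None:
        drive = rap + 0.2 * (np.asarray(lap, float) - LAP_N) / curves.lap_slope
    return ANP_N * gain * effect_multiplier(drive, curves.anp_secretion)


def renin_angiotensin_aldosterone(md_na, b1_drive, anp,
                                  renin_gain=1.0, aldo_gain=1.0, ace_gain=1.0,
                                  md_sens=1.0, b1_sens=1.0, anp_sens=1.0,
                                  aldo_sens=1.0,
                                  curves: Curves = DEFAULT_CURVES):
    """Renin-angiotensin-aldosterone cascade.

    Renin secretion is the product of a basal gain and three normalized
    effects: macula-densa sodium delivery (inverse), beta1-adrenergic drive
    (RSNA + circulating catecholamines), and ANP (inhibitory).  PRA is
    proportional to secretion at steady state, ANG II to PRA, and
    aldosterone follows ANG II.
    """
    md_na = np.asarray(md_na, dtype=float)
    e_md = effect_multiplier(md_na / MD_N, curves.md_renin, md_sens)
    e_b1 = effect_multiplier(b1_drive, curves.b1_renin, b1_sens)
    e_anp = effect_multiplier(np.asarray(anp, float) / ANP_N, curves.anp_renin, anp_sens)
    rs = RS_N * renin_gain * e_md * e_b1 * e_anp
    pra_norm = rs / RS_N
    pra = curves.pra_scale * pra_norm
    angii = ANGII_N * ace_gain * np.maximum(pra_norm, 1e-6) ** curves.ace_exp
    aldo = ALDO_N * aldo_gain * effect_multiplier(
        angii / ANGII_N, curves.angii_aldo, aldo_sens)
    return {
        "renin_secretion": rs, "pra": pra, "angii": angii, "aldosterone": aldo,
        "e_md": e_md, "e_b1": e_b1, "e_anp": e_anp,
    }


def tgf_signal(md_na, angii=ANGII_N, anp=ANP_N, gain=1.0,
               angii_sens=1.0, anp_sens=1.0, curves: Curves = DEFAULT_CURVES):
    """Tubuloglomerular feedback multiplier on afferent resistance.

    Monotone increasing in macula-densa sodium delivery, equal to 1 at the
    normal delivery; ANG II steepens and ANP blunts the deviation from 1.
    """
    md_na = np.asarray(md_na, dtype=float)
    if np.any(md_na < 0):
        raise ValueError("macula densa delivery must be non-negative")
    base = effect_multiplier(md_na, curves.tgf, gain)
    mod = ((np.asarray(angii, float) / ANGII_N) ** (curves.tgf_angii_exp * angii_sens)
           * (np.asarray(anp, float) / ANP_N) ** (-curves.tgf_anp_exp * anp_sens))
    return np.clip(1.0 + (base - 1.0) * mod, 0.40, 2.00)


def glomerular_filtration(p_c, rpf, nephrons=NEPH_N, kf_gain=1.0, hct=HCT_N,
                          curves: Curves = DEFAULT_CURVES, label=None):
    """Solve the implicit single-nephron filtration system (scalar oracle).

    SNGFR = Kf (P_C - P_BC(SNGFR) - pi(FF)) with FF = SNGFR / single-nephron
    plasma flow, solved by bracketed iteration (brentq) to 1e-8 relative.
    Raises on non-convergence, naming the offending patient.
    """
    from scipy.optimize import brentq

    if rpf <= 0 or kf_gain <= 0:
        raise ValueError("RPF and Kf must be positive")
    rpf_sn = rpf / nephrons  # nL/min per nephron when rpf in mL, nephrons 1e6

    def resid(sngfr):
        ff = sngfr / rpf_sn
        pi = PI_N * (1.0 + curves.oncotic_ff_slope * (ff / FF_N - 1.0))
        pbc = P_BC_N * (sngfr / SNGFR_N) ** curves.pbc_exp
        return sngfr - KF_SN * kf_gain * (p_c - pbc - pi)

    hi = max(KF_SN * kf_gain * p_c, 1e-6)
    if resid(1e-12) > 0:
        return {"sngfr": 0.0, "gfr": 0.0, "ff": 0.0, "p_osm": PI_N, "p_bc": 0.0}
    try:
        sngfr = brentq(resid, 1e-12, hi, rtol=1e-10)
    except ValueError as exc:
        who = f" (patient {label})" if label is not None else ""
        raise RuntimeError(f"glomerular filtration failed to converge{who}") from exc
    ff = sngfr / rpf_sn
    return {
        "sngfr": sngfr,
        "gfr": sngfr * nephrons,
        "ff": ff,
        "p_osm": PI_N * (1.0 + curves.oncotic_ff_slope * (ff / FF_N - 1.0)),
        "p_bc": P_BC_N * (sngfr / SNGFR_N) ** curves.pbc_exp,
    }


def fluid_compartments(na, map_mmhg, bv_gain=1.0, rbc_volume=2565.0,
                       curves: Curves = DEFAULT_CURVES):
    """Volumes from extracellular sodium (water ad libitum).

    Plasma sodium is held at its normal concentration, so ECFV is slaved to
    sodium mass; blood volume follows ECFV through a compliance power law
    and shifts into the vasculature as capillary pressure (tracking MAP)
    falls.  Renal interstitial pressure rises with perfusion pressure and
    volume - the physical factor behind pressure natriuresis.
    """
    na = np.asarray(na, dtype=float)
    ecfv = na / NA_CONC
    bv = (BV_N * bv_gain * (ecfv / ECFV_N) ** curves.bv_ecfv_exp
          * (np.asarray(map_mmhg, float) / MAP_N) ** (-curves.bv_map_exp))
    hct = np.clip(rbc_volume / np.maximum(bv, 1e-9), 0.05, 0.80)
    rifp = (RIFP_N * (np.asarray(map_mmhg, float) / MAP_N) ** curves.ifp_pressure_exp
            * (ecfv / ECFV_N) ** curves.ifp_volume_exp)
    return {"ecfv": ecfv, "blood_volume": bv, "hct": hct, "rifp": rifp,
            "plasma_volume": bv * (1.0 - hct), "vein_volume": 0.65 * bv}


# --------------------------------------------------------------------------
# Vectorized fast equilibrium
# --------------------------------------------------------------------------
def _as_arrays(coeffs: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    return {k: np.asarray(v, dtype=float) for k, v in coeffs.items()}



def _clamped(clamps, key, computed):
    """Apply a per-patient clamp; NaN entries leave the computed value."""
    if clamps is None or key not in clamps:
        return computed
    v = np.asarray(clamps[key], dtype=float)
    return np.where(np.isnan(v), computed, v)

def fast_equilibrium(slow: SlowState, coeffs: dict[str, np.ndarray],
                     bat_gain=0.0, clamps: dict[str, np.ndarray] | None = None,
                     curves: Curves = DEFAULT_CURVES,
                     warm: dict[str, np.ndarray] | None = None,
                     max_iter: int = 400, tol: float = 1e-10) -> PhysState:
    """Solve the fast circulation to equilibrium for the given slow state.

    Damped fixed-point iteration on (MAP, filtration fraction, TGF signal);
    deterministic, vectorized over patients.  Returns the full
    :class:`PhysState`; patients whose iteration fails to converge or
    leaves the physical domain are flagged ``ok=False``.
    """
    c = _as_arrays(coeffs)
    clamps = clamps or {}
    cur = curves

    na = np.asarray(slow.na, dtype=float)
    n = na.shape
    ecfv = na / NA_CONC

    map_ = np.array(warm["map"], dtype=float) if warm else np.full(n, MAP_N)
    ff = np.array(warm["ff"], dtype=float) if warm else np.full(n, FF_N)
    tgf = np.array(warm["tgf"], dtype=float) if warm else np.ones(n)

    angii_pool = _clamped(clamps, "angii", ANGII_N * c["ace_gain"]
                          * np.maximum(slow.pra, 1e-6) ** curves.ace_exp)
    aldo = np.asarray(slow.aldo, dtype=float)

    rv = c["venous_return_resistance"]
    svc = 2.0 * SV_N * c["sv_scale"]
    o = c["starling_offset"]
    ks = c["starling_k"]
    e_chemo = 1.0 + cur.chemo_slope * c["chemo_gain"] * (c["fat_mass"] - 15.0) / 15.0
    e_angii_rsna = 1.0 + cur.angii_rsna_slope * (angii_pool / ANGII_N - 1.0)
    g_kf = KF_SN * c["kf_gain"]
    neph = c["renal_mass"]
    ones = np.ones(n)

    map_prev = None
    res_prev = None
    with np.errstate(all="ignore"):
        for it in range(max_iter):
            # volumes (blood volume shifts with capillary pressure ~ MAP)
            bv = (BV_N * c["blood_volume_gain"] * (ecfv / ECFV_N) ** cur.bv_ecfv_exp
                  * np.maximum(map_ / MAP_N, 0.1) ** (-cur.bv_map_exp))
            hct = np.clip(c["rbc_volume"] / np.maximum(bv, 1e-9), 0.05, 0.80)

            # baroreflex and sympathetic channels
            u = np.clip(cur.baro_slope * c["baro_gain"] * (map_ - slow.setpoint), -60, 60)
            baro = 2.0 / (1.0 + np.exp(-u))
            aff = baro * (1.0 + bat_gain)
            sna_c = c["cardiac_sna_basal"] * _em(aff, cur.symp_cardiac)
            sna_p = c["peripheral_sna_basal"] * _em(aff, cur.symp_peripheral)
            sna_a = c["adrenal_sna_basal"] * _em(aff, cur.symp_adrenal)
            rsna_baro = _clamped(clamps, "rsna", _em(aff, cur.symp_renal))
            sna_r = c["renal_sna_basal"] * rsna_baro * e_chemo * e_angii_rsna

            fl_ne = cur.ne_floor
            ne = _clamped(clamps, "ne", NE_N * c["ne_gain"]
                          * (fl_ne + (1 - fl_ne) * (sna_p / 1.5) ** cur.ne_exponent))
            epi = _clamped(clamps, "epi", EPI_N * c["epi_gain"]
                           * (fl_ne + (1 - fl_ne) * (sna_a / 1.5)))

            # heart and venous return
            hr = c["sa_rate"] * _em(sna_c, cur.hr, c["hr_sna_sensitivity"])
            ino = _em(sna_c, cur.inotropy, c["inotropy_sensitivity"])
            vu = c["unstressed_volume"] * np.clip(
                1.0 + cur.venous_tone_slope * c["venous_tone_sensitivity"]
                * (1.0 - sna_p / 1.5), 0.70, 1.30)
            msfp = np.maximum((bv - vu) / c["systemic_compliance"], 0.2)
            a_h = hr * svc * ino
            bq = o + ks - msfp + a_h * rv
            cq = a_h * rv * o - msfp * (o + ks)
            rap = 0.5 * (-bq + np.sqrt(np.maximum(bq * bq - 4.0 * cq, 0.0)))
            co = np.maximum((msfp - rap) / rv, 1.0)
            lap = LAP_N + cur.lap_slope * (rap - RAP_N)

            anp = _clamped(clamps, "anp", ANP_N * c["anp_secretion_gain"]
                           * _em(rap, cur.anp_secretion))

            # kidney
            m_myo = np.clip(1.0 + cur.myogenic_slope * c["myogenic_gain"]
                            * (map_ - slow.pref), 0.70, 1.30)
            e_visc = (hct / HCT_N) ** cur.viscosity_exp
            e_anp_aa = _em(anp / ANP_N, cur.anp_aa, c["anp_aa_sensitivity"])
            e_sna_aa = _em(sna_r, cur.sna_aa, c["sna_aa_sensitivity"])
            r_aa = (c["aa_resistance"] * tgf * e_visc * e_anp_aa * e_sna_aa
                    * m_myo * np.maximum(map_ / MAP_N, 0.1) ** cur.autoreg_exp)
            e_angii_ea = _em(angii_pool / ANGII_N, cur.angii_ea,
                                           c["angii_ea_sensitivity"])
            r_ea = c["ea_resistance"] * e_angii_ea
            r_kid = r_aa + r_ea + c["renal_venous_resistance"]
            grad = np.maximum(map_ - RAP_N, 1.0)
            rbf = 2.0 * grad / r_kid
            p_c = map_ - 0.5 * rbf * r_aa
            rpf = rbf * (1.0 - hct)
            rpf_sn = rpf / neph

            # implicit filtration fraction (damped inner update)
            sngfr = ff * rpf_sn
            pi = PI_N * (1.0 + cur.oncotic_ff_slope * (ff / FF_N - 1.0))
            pbc = P_BC_N * np.maximum(sngfr / SNGFR_N, 1e-9) ** cur.pbc_exp
            sngfr_new = np.maximum(g_kf * (p_c - pbc - pi), 0.0)
            ff_new = np.clip(sngfr_new / rpf_sn, 1e-6, 0.60)
            ff = ff + 0.5 * (ff_new - ff)
            sngfr = ff * rpf_sn
            gfr = ff * rpf

            # tubule
            filtered = gfr * NA_CONC / 1000.0
            rifp = np.asarray(slow.rifp, dtype=float)
            e_angii_pt = _em(angii_pool / ANGII_N, cur.angii_pt,
                                           c["angii_pt_sensitivity"])
            e_sna_pt = _em(sna_r, cur.sna_pt, c["sna_pt_sensitivity"])
            e_ne_pt = (ne / NE_N) ** cur.ne_pt_exp
            e_anp_pt = _em(anp / ANP_N, cur.anp_pt, c["anp_pt_sensitivity"])
            e_ifp_pt = _em(rifp, cur.ifp_pt, c["ifp_sensitivity"])
            pt = (PTNAR_N * c["pt_fractional_gain"] ** cur.pt_obesity_exp
                  * np.maximum(filtered / FL_N, 1e-9) ** cur.pt_load_exp
                  * e_angii_pt * e_sna_pt * e_ne_pt * e_anp_pt * e_ifp_pt)
            pt = np.minimum(pt, 0.98 * filtered)
            d1 = filtered - pt
            loop = np.minimum(np.minimum(
                LOOP_FRAC * c["loop_fraction"] * _D1_N
                * np.maximum(d1 / _D1_N, 1e-9) ** cur.loop_load_exp,
                cur.loop_tm_cap * LOOP_FRAC * c["loop_fraction"] * _D1_N),
                0.97 * d1)
            md = d1 - loop

            tgf_base = _em(md, cur.tgf, c["tgf_gain"])
            tgf_mod = ((angii_pool / ANGII_N) ** (cur.tgf_angii_exp * c["angii_tgf_sensitivity"])
                       * (anp / ANP_N) ** (-cur.tgf_anp_exp * c["anp_tgf_sensitivity"]))
            tgf_new = np.clip(1.0 + (tgf_base - 1.0) * tgf_mod, 0.40, 2.00)
            tgf = tgf + 0.45 * (tgf_new - tgf)

            e_aldo_dt = _em(aldo / ALDO_N, cur.aldo_dt, c["aldo_dt_sensitivity"])
            e_aldo_cd = _em(aldo / ALDO_N, cur.aldo_cd, c["aldo_cd_sensitivity"])
            e_anp_cd = _em(anp / ANP_N, cur.anp_cd, c["anp_cd_sensitivity"])
            dt_r = np.minimum(DT_FRAC * c["dt_fraction"] * e_aldo_dt, 0.95) * md
            cdload = md - dt_r
            e_rifp_cd = np.maximum(rifp / RIFP_N, 0.1) ** (-cur.rifp_cd_exp)
            e_load_cd = np.maximum(cdload / _CDLOAD_N, 1e-6) ** (-cur.cd_load_exp)
            cd_r = np.minimum(
                CD_FRAC * c["cd_fraction"] * e_aldo_cd * e_anp_cd * e_rifp_cd
                * e_load_cd, 0.995) * cdload
            una = np.maximum(cdload - cd_r, 0.0)

            # systemic conductances and pressure closure
            e_vs = _em(sna_p, cur.sna_vasc, c["sna_vasc_sensitivity"])
            e_av = _em(angii_pool / ANGII_N, cur.angii_vasc,
                                     c["angii_vasc_sensitivity"])
            g_nr = (c["muscle_flow"] * e_vs * e_av
                    + c["gi_flow"] * e_vs * e_av
                    + c["brain_flow"] * ones
                    + c["skin_flow"] * e_vs
                    + c["bone_flow"] * ones
                    + c["other_flow"] * ones
                    + c["fat_flow_per_kg"] * c["fat_mass"] * e_vs * e_av
                    ) / (MAP_N - RAP_N)
            g_tot = g_nr + rbf / np.maximum(map_ - rap, 1.0)
            tpr = 1.0 / g_tot
            map_new = rap + co * tpr

            res = map_new - map_
            err = np.abs(res) / np.maximum(map_, 1.0)
            err_ff = np.abs(ff_new - ff)
            err_tg = np.abs(tgf_new - tgf)
            # secant acceleration on the MAP residual (damped fallback)
            step = 0.6 * res
            if map_prev is not None:
                dm = map_ - map_prev
                dr = res - res_prev
                slope = np.where(np.abs(dm) > 1e-14, dr / np.where(dm == 0, 1, dm), 0.0)
                newton = -res / np.where(np.abs(slope) < 0.05, -1.0, slope)
                use = (slope < -0.05) & np.isfinite(newton)
                step = np.where(use, np.clip(newton, -8.0, 8.0), step)
            map_prev = map_
            res_prev = res
            map_ = map_ + step
            if (np.nanmax(err) < tol and np.nanmax(err_ff) < 10 * tol
                    and np.nanmax(err_tg) < 10 * tol):
                converged = np.ones(n, dtype=bool)
                break
        else:
            converged = (err < 1e-8) & (err_ff < 1e-7) & (err_tg < 1e-7)

    # renin cascade at the converged point
    b1_drive = (cur.b1_rsna_weight * sna_r / c["renal_sna_basal"]
                + (1.0 - cur.b1_rsna_weight) * ne / NE_N)
    # sanitize failed patients so the cascade never raises; they stay flagged
    md_s = np.where(np.isfinite(md), md, MD_N)
    b1_s = np.where(np.isfinite(b1_drive), b1_drive, 1.0)
    anp_s = np.where(np.isfinite(anp), anp, ANP_N)
    raas = renin_angiotensin_aldosterone(
        md_s, b1_s, anp_s,
        renin_gain=c["renin_secretion_gain"], aldo_gain=c["aldo_secretion_gain"],
        ace_gain=c["ace_gain"], md_sens=c["md_renin_sensitivity"],
        b1_sens=c["b1_renin_sensitivity"],
        anp_sens=c["anp_renin_sensitivity"],
        aldo_sens=c["angii_aldo_sensitivity"], curves=cur)

    ok = (converged
          & np.isfinite(map_) & (map_ > 20.0) & (map_ < 300.0)
          & np.isfinite(co) & (co > 500.0)
          & (ff > 1e-5) & (ff < 0.59)
          & (una >= 0.0) & (rap < msfp) & np.isfinite(una))

    return PhysState(
        map=map_, hr=hr, co=co, tpr=tpr, rap=rap, lap=lap, msfp=msfp,
        blood_volume=bv, plasma_volume=bv * (1 - hct), vein_volume=0.65 * bv,
        ecfv=ecfv, hct=hct, plasma_na=NA_CONC * ones, rifp=rifp,
        afferent=aff, baro_component=rsna_baro,
        atrial_activity=_em(rap, cur.anp_secretion),
        sna_cardiac=sna_c, sna_renal=sna_r, sna_peripheral=sna_p,
        sna_adrenal=sna_a, ne=ne, epi=epi, anp=anp,
        pra=cur.pra_scale * np.asarray(slow.pra, float) * ones,
        angii=angii_pool, aldo=aldo, renin_secretion=raas["renin_secretion"],
        gfr=gfr, sngfr=sngfr, ff=ff, rbf=rbf, rpf=rpf, kf=g_kf,
        p_c=p_c, p_bc=pbc, p_osm=pi,
        aa_resistance=r_aa, ea_resistance=r_ea, md_na=md, tgf=tgf,
        filtered_load=filtered, ptnar=pt, loopnar=loop, dtnar=dt_r,
        cdnar=cd_r, total_nar=pt + loop + dt_r + cd_r, na_excretion=una,
        e_md_renin=raas["e_md"], e_b1_renin=raas["e_b1"],
        e_angii_pt=e_angii_pt, e_sna_pt=e_sna_pt, e_anp_pt=e_anp_pt,
        e_ifp_pt=e_ifp_pt, e_tgf=tgf, e_visc_aa=e_visc,
        e_anp_aa=e_anp_aa, e_sna_aa=e_sna_aa, e_myo_aa=m_myo,
        converged=converged, ok=ok,
    )


def systemic_hemodynamics(state: PhysState) -> dict[str, np.ndarray]:
    """Convenience view of the systemic variables of a solved state."""
    return {k: getattr(state, k) for k in ("co", "map", "rap", "lap", "hr", "tpr")}


# --------------------------------------------------------------------------
# Time stepping
# --------------------------------------------------------------------------
def _slow_targets(eq: PhysState, coeffs, curves: Curves):
    """Relaxation targets of the slow states at a solved equilibrium."""
    c = coeffs
    f = np.clip(np.asarray(c["baro_adapt_frac"], float), 0.0, 1.0)
    set_target = (1.0 - f) * curves.adapt_ref + f * eq.map
    pra_target = eq.renin_secretion / RS_N
    aldo_target = (ALDO_N * c["aldo_secretion_gain"]
                   * _em(eq.angii / ANGII_N, curves.angii_aldo,
                         c["angii_aldo_sensitivity"]))
    rifp_target = (RIFP_N * np.maximum(eq.map / MAP_N, 0.1) ** curves.ifp_pressure_exp
                   * (eq.ecfv / ECFV_N) ** curves.ifp_volume_exp)
    return set_target, eq.map, pra_target, aldo_target, rifp_target


def advance(slow: SlowState, coeffs, dt_hours: float, bat_gain=0.0,
            clamps=None, curves: Curves = DEFAULT_CURVES,
            eq0: PhysState | None = None,
            warm: dict[str, np.ndarray] | None = None,
            solver_tol: float = 1e-9, solver_max_iter: int = 60):
    """Advance the slow states by one step (Heun / exact-exponential).

    Sodium mass integrates intake minus excretion with a two-stage
    (predictor-corrector) update; the relaxing states (setpoint, myogenic
    reference, PRA and aldosterone pools) use exponential updates toward
    targets averaged over the two stages.  Deterministic given state and
    coefficients; ``dt_hours`` must not exceed 24.

    Returns ``(new_slow, eq0)`` with ``eq0`` the equilibrium at the step
    start (reusable as an observation).
    """
    if not 0 < dt_hours <= 24.0:
        raise ValueError("dt must be in (0, 24] hours")
    c = _as_arrays(coeffs)
    if eq0 is None:
        eq0 = fast_equilibrium(slow, c, bat_gain, clamps, curves, warm=warm,
                               tol=solver_tol, max_iter=solver_max_iter)
    if not np.all(np.isfinite(eq0.map)):
        bad = ~np.isfinite(eq0.map)
        if np.all(bad):
            raise FloatingPointError("advance: non-finite state for all patients")
    dt_min = dt_hours * 60.0
    intake = c["salt_intake"] / 1440.0

    st1, pr1, pa1, al1, rf1 = _slow_targets(eq0, c, curves)
    d_na1 = intake - eq0.na_excretion

    # predictor
    k_set = 1.0 - np.exp(-dt_hours / curves.tau_setpoint_h)
    k_myo = 1.0 - np.exp(-dt_hours / curves.tau_myogenic_h)
    k_pra = 1.0 - np.exp(-dt_hours / curves.tau_pra_h)
    k_ald = 1.0 - np.exp(-dt_hours / curves.tau_aldo_h)
    k_rif = 1.0 - np.exp(-dt_hours / curves.tau_rifp_h)
    pred = SlowState(
        na=slow.na + dt_min * d_na1,
        setpoint=slow.setpoint + k_set * (st1 - slow.setpoint),
        pref=slow.pref + k_myo * (pr1 - slow.pref),
        pra=slow.pra + k_pra * (pa1 - slow.pra),
        aldo=slow.aldo + k_ald * (al1 - slow.aldo),
        rifp=slow.rifp + k_rif * (rf1 - slow.rifp),
    )
    warm = {"map": eq0.map, "ff": eq0.ff, "tgf": eq0.tgf}
    eq1 = fast_equilibrium(pred, c, bat_gain, clamps, curves, warm=warm,
                           tol=solver_tol, max_iter=solver_max_iter)
    st2, pr2, pa2, al2, rf2 = _slow_targets(eq1, c, curves)
    d_na2 = intake - eq1.na_excretion

    new = SlowState(
        na=np.maximum(slow.na + 0.5 * dt_min * (d_na1 + d_na2), 1.0),
        setpoint=slow.setpoint + k_set * (0.5 * (st1 + st2) - slow.setpoint),
        pref=slow.pref + k_myo * (0.5 * (pr1 + pr2) - slow.pref),
        pra=slow.pra + k_pra * (0.5 * (pa1 + pa2) - slow.pra),
        aldo=slow.aldo + k_ald * (0.5 * (al1 + al2) - slow.aldo),
        rifp=slow.rifp + k_rif * (0.5 * (rf1 + rf2) - slow.rifp),
    )
    return new, eq0


def run_for(slow: SlowState, coeffs, hours: float, bat_gain=0.0, clamps=None,
            curves: Curves = DEFAULT_CURVES, dt_hours: float = 1.0):
    """Integrate for a fixed duration; returns (slow, last equilibrium)."""
    c = _as_arrays(coeffs)
    eq = None
    warm = None
    steps = int(round(hours / dt_hours))
    for _ in range(steps):
        slow, eq = advance(slow, c, dt_hours, bat_gain, clamps, curves, warm=warm)
        warm = {"map": eq.map, "ff": eq.ff, "tgf": eq.tgf}
    return slow, eq


def run_to_steady_state(coeffs, max_days: int = 28, tol: float = 1e-6,
                        bat_gain=0.0, clamps=None,
                        curves: Curves = DEFAULT_CURVES,
                        slow: SlowState | None = None,
                        min_days: int = 7) -> SteadyStateResult:
    """Run until the slow states change by less than ``tol``/day (relative).

    Never raises on physiological divergence: patients that fail the fast
    solver or do not settle are flagged non-converged and carried along.
    """
    c = _as_arrays(coeffs)
    if slow is None:
        slow = SlowState.initial(c)
    rel = np.full(np.shape(slow.na), np.inf)
    day = 0
    warm = None
    for day in range(1, max_days + 1):
        prev = slow.copy()
        for _ in range(24):
            slow, _eq = advance(slow, c, 1.0, bat_gain, clamps, curves, warm=warm)
            warm = {"map": _eq.map, "ff": _eq.ff, "tgf": _eq.tgf}
        rel = np.zeros(np.shape(slow.na))
        for f in dataclasses.fields(SlowState):
            a, b = getattr(prev, f.name), getattr(slow, f.name)
            with np.errstate(all="ignore"):
                rel = np.maximum(rel, np.abs(b - a) / np.maximum(np.abs(a), 1e-9))
        if day >= min_days and np.nanmax(rel) < tol:
            break
    eq = fast_equilibrium(slow, c, bat_gain, clamps, curves)
    converged = (rel < tol) & eq.ok
    return SteadyStateResult(state=eq, slow=slow, converged=converged,
                             days=float(day), max_rel_daily_change=rel)


def arteriolar_resistances(state: PhysState) -> dict[str, np.ndarray]:
    """Afferent/efferent arteriolar resistances of a solved state."""
    return {"aa": state.aa_resistance, "ea": state.ea_resistance}


def segmental_sodium_reabsorption(state: PhysState) -> dict[str, np.ndarray]:
    """Segmental sodium handling of a solved state (mmol/min)."""
    return {"ptnar": state.ptnar, "loopnar": state.loopnar,
            "dtnar": state.dtnar, "cdnar": state.cdnar,
            "na_excretion": state.na_excretion}

def renal_function_curve(map_values, coeffs=None, curves: Curves = DEFAULT_CURVES):
    """Acute pressure-natriuresis curve: Na excretion vs perfusion pressure.

    Every neurohumoral input (SNA, ANG II, ANP, aldosterone, TGF) is held
    at its normal operating value and extracellular volume at normal, so
    the only pressure-dependent mechanisms are the physical ones: renal
    interstitial pressure on proximal reabsorption, pressure diuresis at
    the collecting duct, autoregulatory afferent tone, and the filtered
    load itself.  Returns excretion (mmol/min) per pressure.  Built from
    the same anchored constants and the scalar glomerular solver, it is an
    independent route to the engine's renal block (they agree at the
    normal operating point).
    """
    from .registry import registry_defaults

    c = {k: float(np.asarray(v).ravel()[0])
         for k, v in (coeffs or {}).items()} if coeffs else {}
    d = registry_defaults()
    d.update(c)
    out = []
    for m in np.atleast_1d(np.asarray(map_values, dtype=float)):
        rifp = RIFP_N * (m / MAP_N) ** curves.ifp_pressure_exp
        e_ifp = effect_multiplier(rifp, curves.ifp_pt, d["ifp_sensitivity"])
        r_aa = d["aa_resistance"] * max(m / MAP_N, 0.1) ** curves.autoreg_exp
        r_kid = r_aa + d["ea_resistance"] + d["renal_venous_resistance"]
        rbf = 2.0 * max(m - RAP_N, 1.0) / r_kid
        p_c = m - 0.5 * rbf * r_aa
        rpf = rbf * (1.0 - HCT_N)
        gl = glomerular_filtration(p_c, rpf, nephrons=d["renal_mass"],
                                   kf_gain=d["kf_gain"], curves=curves)
        filtered = gl["gfr"] * NA_CONC / 1000.0
        pt = (PTNAR_N * d["pt_fractional_gain"] ** curves.pt_obesity_exp
              * max(filtered / FL_N, 1e-9) ** curves.pt_load_exp * e_ifp)
        pt = min(pt, 0.98 * filtered)
        d1 = filtered - pt
        loop = min(min(LOOP_FRAC * d["loop_fraction"] * _D1_N
                       * max(d1 / _D1_N, 1e-9) ** curves.loop_load_exp,
                       curves.loop_tm_cap * LOOP_FRAC * d["loop_fraction"] * _D1_N),
                   0.97 * d1)
        md = d1 - loop
        dt_r = min(DT_FRAC * d["dt_fraction"], 0.95) * md
        cdload = md - dt_r
        e_rifp_cd = max(rifp / RIFP_N, 0.1) ** (-curves.rifp_cd_exp)
        e_load_cd = max(cdload / _CDLOAD_N, 1e-6) ** (-curves.cd_load_exp)
        cd = min(CD_FRAC * d["cd_fraction"] * e_rifp_cd * e_load_cd, 0.995) * cdload
        out.append(max(cdload - cd, 0.0))
    return np.asarray(out)
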
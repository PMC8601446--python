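"""Coefficient registry for the reduced cardiovascular-renal model.

Every physiological gain, basal rate, and sensitivity that the virtual
population varies lives here as a :class:`CoefficientRange`: a default value
(the "Normal" operating point), an admissible multiplier range relative to
that default, and units.  Most coefficients vary within 5% of default; a
small set of named exceptions with larger known physiological variability
(salt intake, renal mass, the three sympathetic channels, renin and
aldosterone secretion, intrinsic sinoatrial rate) carry wider ranges, and
two obesity modifiers (fat mass, fractional proximal sodium reabsorption)
are shifted upward when an obese population is requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


@dataclass(frozen=True)
class CoefficientRange:
    """One registered model coefficient.

    Parameters
    ----------
    name : str
        Unique registry key.
    default : float
        Value at the Normal operating point.
    low, high : float
        Admissible multiplier range relative to ``default``.
    units : str
        Physical units of ``default`` ("-" for dimensionless gains).
    description : str
        What the coefficient does in the model.
    """

    name: str
    default: float
    low: float = 0.95
    high: float = 1.05
    units: str = "-"
    description: str = ""

    def __post_init__(self) -> None:
        if not self.low <= self.high:
            raise ValueError(f"{self.name}: low {self.low} > high {self.high}")

    def sample_bounds(self) -> tuple[float, float]:
        """Admissible value range (default x multiplier range)."""
        return self.default * self.low, self.default * self.high


# Named exceptions with the wider physiological ranges; everything else is
# within 5% of default.
_EXCEPTION_RANGES: dict[str, tuple[float, float]] = {
    "salt_intake": (0.8, 1.2),
    "renal_mass": (0.8, 1.2),
    "cardiac_sna_basal": (1.0, 1.5),
    "peripheral_sna_basal": (1.0, 1.5),
    "renal_sna_basal": (1.0, 2.0),
    "aldo_secretion_gain": (0.5, 1.5),
    "renin_secretion_gain": (1.0, 2.0),
    "sa_rate": (0.75, 1.5),
}

# Obesity modifiers replace these coefficients' ranges when enabled.
OBESITY_RANGES: dict[str, tuple[float, float]] = {
    "fat_mass": (1.3, 1.5),
    "pt_fractional_gain": (1.1, 1.4),
}


def _c(name, default, units="-", description=""):
    lo, hi = _EXCEPTION_RANGES.get(name, (0.95, 1.05))
    return CoefficientRange(name, default, lo, hi, units, description)


def build_registry() -> list[CoefficientRange]:
    """Full coefficient registry at normal (non-obese) ranges.

    Returns the list of :class:`CoefficientRange` defining the uncalibrated
    virtual-population prior: uniform and independent per coefficient.
    """
    regs = [
        # --- intake / structural ---
        _c("salt_intake", 139.0, "mmol/day", "dietary sodium intake"),
        _c("renal_mass", 2.4, "million nephrons", "functional nephron count"),
        _c("fat_mass", 15.0, "kg", "adipose tissue mass"),
        _c("pt_fractional_gain", 1.0, "-",
           "fractional proximal tubular Na reabsorption gain"),
        # --- autonomic ---
        _c("cardiac_sna_basal", 1.5, "Hz", "basal SNA to the heart"),
        _c("peripheral_sna_basal", 1.5, "Hz", "basal SNA to the periphery"),
        _c("renal_sna_basal", 1.5, "Hz", "basal SNA to the kidney"),
        _c("adrenal_sna_basal", 1.5, "Hz", "basal SNA to the adrenal medulla"),
        _c("baro_gain", 1.0, "-", "carotid baroreceptor slope gain"),
        _c("baro_adapt_frac", 0.7, "-",
           "fraction of a sustained MAP change the afferent setpoint adopts"),
        _c("chemo_gain", 1.0, "-",
           "chemoreceptor drive to renal SNA per unit fat-mass excess"),
        _c("hr_sna_sensitivity", 1.0, "-", "chronotropic slope to cardiac SNA"),
        _c("inotropy_sensitivity", 1.0, "-", "inotropic slope to cardiac SNA"),
        _c("venous_tone_sensitivity", 1.0, "-",
           "unstressed-volume slope to peripheral SNA"),
        _c("sna_vasc_sensitivity", 1.0, "-",
           "systemic vasoconstrictor slope to peripheral SNA"),
        _c("sna_pt_sensitivity", 1.0, "-",
           "alpha1 slope of proximal Na reabsorption to renal SNA"),
        _c("sna_aa_sensitivity", 1.0, "-",
           "afferent arteriolar constrictor slope to renal SNA"),
        _c("b1_renin_sensitivity", 1.0, "-",
           "beta1 slope of renin secretion to renal SNA + catecholamines"),
        # --- hormones ---
        _c("ne_gain", 1.0, "-", "norepinephrine spillover gain"),
        _c("epi_gain", 1.0, "-", "epinephrine secretion gain"),
        _c("anp_secretion_gain", 1.0, "-", "ANP secretion gain at the atria"),
        _c("anp_aa_sensitivity", 1.0, "-", "ANP afferent dilator slope"),
        _c("anp_pt_sensitivity", 1.0, "-", "ANP proximal natriuretic slope"),
        _c("anp_cd_sensitivity", 1.0, "-",
           "ANP collecting-duct natriuretic slope"),
        _c("anp_renin_sensitivity", 1.0, "-", "ANP renin-suppression slope"),
        _c("anp_tgf_sensitivity", 1.0, "-", "ANP blunting of TGF slope"),
        _c("renin_secretion_gain", 1.0, "-", "basal renin secretion gain"),
        _c("md_renin_sensitivity", 1.0, "-",
           "macula densa slope of renin secretion"),
        _c("ace_gain", 1.0, "-", "PRA -> ANG II conversion gain"),
        _c("aldo_secretion_gain", 1.0, "-", "basal aldosterone secretion gain"),
        _c("angii_aldo_sensitivity", 1.0, "-", "ANG II slope of aldosterone"),
        _c("angii_ea_sensitivity", 1.0, "-",
           "ANG II efferent arteriolar constrictor slope"),
        _c("angii_pt_sensitivity", 1.0, "-",
           "ANG II proximal antinatriuretic slope"),
        _c("angii_vasc_sensitivity", 1.0, "-",
           "ANG II systemic vasoconstrictor slope"),
        _c("angii_tgf_sensitivity", 1.0, "-", "ANG II sensitization of TGF"),
        _c("aldo_dt_sensitivity", 1.0, "-", "aldosterone distal-tubule slope"),
        _c("aldo_cd_sensitivity", 1.0, "-", "aldosterone collecting-duct slope"),
        # --- heart / circulation ---
        _c("sa_rate", 72.0, "bpm", "intrinsic sinoatrial rate"),
        _c("sv_scale", 1.0, "-", "ventricular stroke-volume scale"),
        _c("starling_offset", 0.5, "mmHg", "Frank-Starling preload offset"),
        _c("starling_k", 1.5, "mmHg", "Frank-Starling half-saturation"),
        _c("unstressed_volume", 4000.0, "mL", "basal unstressed vascular volume"),
        _c("systemic_compliance", 242.857, "mL/mmHg", "systemic compliance"),
        _c("venous_return_resistance", 6.0 / 5110.0, "mmHg/mL/min",
           "resistance to venous return"),
        _c("blood_volume_gain", 1.0, "-", "blood-volume compliance scale"),
        _c("rbc_volume", 2565.0, "mL", "red cell volume (sets hematocrit)"),
        # --- organ conductances (normal flows at MAP-RAP = 91 mmHg) ---
        _c("muscle_flow", 1000.0, "mL/min", "skeletal muscle flow at normal"),
        _c("gi_flow", 1250.0, "mL/min", "splanchnic flow at normal"),
        _c("brain_flow", 700.0, "mL/min", "cerebral flow (autoregulated)"),
        _c("skin_flow", 300.0, "mL/min", "cutaneous flow at normal"),
        _c("bone_flow", 260.0, "mL/min", "bone + remainder flow at normal"),
        _c("other_flow", 200.0, "mL/min", "residual organ flow at normal"),
        _c("fat_flow_per_kg", 25.0, "mL/min/kg", "adipose flow per kg fat"),
        # --- kidney ---
        _c("aa_resistance", 0.063, "mmHg/mL/min",
           "basal pre-glomerular (afferent) resistance per kidney"),
        _c("ea_resistance", 0.082, "mmHg/mL/min",
           "basal efferent arteriolar resistance per kidney"),
        _c("renal_venous_resistance", 91.0 / 512.5 - 0.145, "mmHg/mL/min",
           "post-efferent renal resistance per kidney"),
        _c("kf_gain", 1.0, "-", "glomerular filtration coefficient scale"),
        _c("tgf_gain", 1.0, "-", "tubuloglomerular feedback slope gain"),
        _c("myogenic_gain", 1.0, "-", "afferent myogenic slope gain"),
        _c("ifp_sensitivity", 1.0, "-",
           "renal interstitial pressure slope of proximal reabsorption"),
        _c("loop_fraction", 1.0, "-", "loop of Henle fractional reabsorption gain"),
        _c("dt_fraction", 1.0, "-", "distal tubule fractional reabsorption gain"),
        _c("cd_fraction", 1.0, "-", "collecting duct fractional reabsorption gain"),
    ]
    names = [r.name for r in regs]
    if len(names) != len(set(names)):
        raise ValueError("duplicate coefficient names in registry")
    return regs


def apply_obesity_modifiers(
    ranges: list[CoefficientRange], enabled: bool = True
) -> list[CoefficientRange]:
    """Shift the obesity coefficients to their obese ranges.

    With ``enabled=False`` the registry is returned with the obesity
    coefficients at the generic within-5% range (the toggle contract).
    """
    out = []
    for r in ranges:
        if r.name in OBESITY_RANGES:
            lo, hi = OBESITY_RANGES[r.name] if enabled else (0.95, 1.05)
            out.append(replace(r, low=lo, high=hi))
        else:
            out.append(r)
    return out


def registry_defaults(registry: list[CoefficientRange] | None = None) -> dict[str, float]:
    """Map of coefficient name -> default value."""
    if registry is None:
        registry = build_registry()
    return {r.name: r.default for r in registry}


def registry_index(registry: list[CoefficientRange]) -> dict[str, CoefficientRange]:
    return {r.name: r for r in registry}
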
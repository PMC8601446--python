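# Methods

`baropop` simulates a chronic blood-pressure intervention — baroreflex
activation therapy (BAT), i.e. sustained electrical stimulation of the
carotid baroreceptor afferents — on a virtual population of obese
hypertensive patients, and quantifies which pathways mediate the
antihypertensive response by clamp (ablation) experiments. This note
documents the model, its assumptions, the numerical choices, and what the
synthetic data do and do not establish.

## The physiological model

The model is a reduced whole-body cardiovascular–renal system in the
Guyton tradition: the fast circulation is assumed to be in quasi-steady
state at every instant, and *chronic* mean arterial pressure (MAP) is set
by renal sodium balance. The kidney excretes sodium at a rate that
increases with perfusion pressure (pressure natriuresis) and is modulated
by neurohumoral inputs; extracellular fluid volume (ECFV) integrates
intake minus excretion until the two match. Consequently any intervention
changes chronic MAP only insofar as it shifts renal sodium handling — a
property the full-clamp experiment exposes directly.

State is split into

* **slow states**, integrated in time: extracellular sodium mass (plasma
  [Na+] is held at 136 mmol/L by ad-libitum water, so ECFV is slaved to
  sodium), the baroreceptor afferent setpoint, the myogenic pressure
  reference of the afferent arteriole, renal interstitial fluid pressure
  (RIFP, time constant 18 h), and first-order pools for plasma renin
  activity (PRA, 30 min) and aldosterone (3 h);
* **fast states**, solved algebraically at every step: MAP, cardiac output
  (intersection of a Frank–Starling cardiac function curve and a venous
  return line), right atrial pressure, heart rate, the four sympathetic
  channels (cardiac, renal, peripheral, adrenal), hormones slaved to the
  fast states (ANP from atrial pressure, catecholamines from sympathetic
  outflow, ANG II from the PRA pool), and the renal sub-state: an implicit
  single-nephron filtration equation
  `SNGFR = Kf (P_C − P_BC(SNGFR) − π(FF))`, tubuloglomerular feedback
  (TGF), and segmental sodium reabsorption (proximal tubule, loop, distal
  tubule, collecting duct).

Every neurohumoral determinant acts through a normalized saturating
(logistic) multiplier that equals exactly 1 at its normal operating input.
The default coefficient set is anchored analytically so that the "Normal"
operating point (MAP 92 mmHg, HR 72 bpm, CO ≈ 5.1 L/min, blood volume
5.7 L, ECFV 15.4 L, GFR 123 mL/min, RBF 1025 mL/min, proximal reabsorption
10 mmol/min, ANP 25 pMol/L, NE 234 pg/mL, renin secretion 80 units,
ANG II 11 pg/mL, aldosterone 272 pMol/L) is an exact steady state of the
equations, not the result of a fit.

### Pathways that matter for BAT

* **Baroreflex.** Carotid afferent activity is a logistic function of MAP
  around a setpoint that adapts toward the prevailing pressure with a
  3-day time constant and an incomplete adaptation fraction of 0.7
  (partial resetting). BAT multiplies the afferent by 1.4 (+40%) *after*
  adaptation, so the stimulation is chronically sustained. All four
  sympathetic channels fall monotonically with afferent input; the renal
  channel additionally carries a small chemoreceptor drive (raised in
  obesity) and a weak ANG II modulation.
* **Renal sympathetic nerve activity (RSNA)** stimulates proximal sodium
  reabsorption (α1, a steep saturating curve) and renin secretion (β1).
  The β1 drive mixes neural RSNA (30%) with circulating catecholamines
  (70%), normalized to the patient's own basal tone — this is why renin
  still falls when only the baroreflex component of RSNA is clamped.
  Circulating norepinephrine also carries a direct α1-like effect on
  proximal reabsorption (power law, exponent 0.6).
* **ANP** is secreted with atrial stretch (BAT slows the heart, atrial
  pressure rises, ANP rises ~70%). It inhibits collecting-duct
  reabsorption, dilates the afferent arteriole, blunts TGF, suppresses
  renin, and mildly inhibits proximal reabsorption.
* **Renin–angiotensin–aldosterone.** Renin secretion = basal gain ×
  macula-densa effect × β1 effect × ANP effect; PRA is proportional to
  secretion with a first-order pool; ANG II follows PRA through a
  saturating conversion (exponent 0.8); aldosterone follows ANG II.
  ANG II constricts the efferent arteriole, stimulates proximal
  reabsorption, sensitizes TGF and supports systemic tone.
* **Pressure natriuresis.** RIFP rises steeply with renal perfusion
  pressure (cubic) and weakly with ECFV; it inhibits proximal reabsorption
  through a saturating curve whose steep region lies in the hypertensive
  range. A weaker direct pressure-diuresis term acts at the collecting
  duct. An afferent autoregulatory tone proportional to (MAP/92)^1.3
  stabilizes GFR against pressure changes; the myogenic component of that
  tone resets within ~12 h.
* **Distal buffering.** Loop reabsorption follows delivered load with
  exponent 1.2 up to a transport maximum (2.5× normal); the
  collecting-duct fraction rises toward complete reabsorption as delivered
  load falls. Together these keep urinary excretion under distal control
  at low loads (forcing chronic balance through the pressure axis) while
  capping reabsorption for hyperfiltering patients.

### Clamp semantics

A clamp freezes the named quantity at the patient's own pre-BAT
steady-state value throughout BAT: plasma ANP, the baroreflex component of
renal SNA (chemoreceptor/ANG II modulation stays live), plasma ANG II,
norepinephrine, epinephrine. Arms share a single baseline computation, so
paired arms have bit-identical baselines and differ only through clamps.

## Numerics

The fast circulation is solved by a damped fixed-point iteration on
(MAP, filtration fraction, TGF signal) with a per-patient secant
(Newton-on-residual) acceleration for MAP; convergence tolerance 1e−10
relative (1e−9 inside time steps), iteration caps 400 (cold) / 60 (warm
within a step). Slow states advance with a two-stage (Heun)
predictor–corrector at 1-h substeps; relaxing states use exact exponential
updates toward stage-averaged targets. Everything is vectorized across
patients, so a 1,000-patient, 8-week simulation runs in minutes on one
CPU. Patients whose solution fails (non-convergence, non-physical values,
NaN) are flagged and excluded from downstream statistics — emulating the
attrition of a large-scale population run — and the completion fraction is
reported in the run manifest (roughly 85–95% for the obese population).
Identical coefficients and seeds give bit-identical trajectories.

## Virtual population and calibration

The uncalibrated population samples every registry coefficient (~60)
independently and uniformly within 5% of default, except the documented
wide ranges (salt intake 0.8–1.2×, renal mass 0.8–1.2×, cardiac and
peripheral SNA 1–1.5×, renal SNA 1–2×, aldosterone secretion 0.5–1.5×,
renin secretion 1–2×, sinoatrial rate 0.75–1.5×) and the obesity modifiers
(fat mass 1.3–1.5×, fractional proximal reabsorption 1.1–1.4×). At the
desk scale used throughout (n = 1000) the resulting hypertensive
population has baseline MAP ≈ 114 ± 7 mmHg, GFR ≈ 160 ± 19 mL/min and
PRA ≈ 1.4 ± 0.3 (model units, normal = 0.8).

Calibration selects, for each of six animal target points, ten virtual
patients lying within one SD in all six coordinates (MAP, GFR, PRA before
and after BAT); a uniform ±2.5% kernel is centred on each selected
coefficient set (clipped to the admissible ranges), and one draw per
kernel yields the 60-patient calibrated population. Selection among
qualifiers is a seeded uniform draw ("sampled"); a nearest-neighbour mode
(SD-normalized Euclidean distance, ties by patient id) is available behind
a flag. The box half-width defaults to one full SD; the stricter
half-SD box is available behind a flag.

## The synthetic cohort

The six-animal cohort emulates the experimental dogs through the
population statistics the calibrated virtual population is known to match:
MAP 115 ± 6 → 100 ± 5 mmHg, human-equivalent GFR 162 ± 17 → 150 ± 13
mL/min (canine values rescaled +67%), PRA 1.36 ± 0.44 → 1.05 ± 0.45 model
units. Baselines are drawn from truncated (±1.3 SD) normals with mild
cross-variable correlation (MAP–PRA 0.4, GFR–PRA 0.35) — a selected,
homogeneous experimental colony lies on the physiological manifold — and
each animal's BAT response is drawn from the documented percent-change
spreads (MAP −14 ± 3%, GFR −7 ± 4%, renin −25 ± 18%, truncated likewise,
MAP fall at least 2%). Post-BAT marginals then reproduce the documented
statistics, every animal is antihypertensive-responsive, and the strong
pre/post correlation of repeated measurements emerges by construction.
Because of the truncation the realized baseline SDs are ~84% of nominal
(the truncated-normal value); the generator property test asserts exactly
that.

What the synthetic cohort does **not** emulate: real measurement error,
the dogs' obesity induction time course, heart-rate or body-weight
endpoints, or any within-animal longitudinal structure beyond the single
pre/post pair. Passing calibration against it shows the pipeline recovers
populations consistent with summary statistics — not that the model would
match raw canine time series.

## Design choices where the design was open

* **Box width**: "within one standard deviation in each dimension" is
  implemented as half-width = 1 SD (full side 2 SD); the literal
  "side lengths equal to one SD" box is behind a flag.
* **Chemoreceptor input** is a small constant modifier proportional to
  excess fat mass (a few percent of renal SNA; its whole contribution to
  the BAT response is on the order of 1 mmHg).
* **Aldosterone** has no potassium input; only ANG II drives it.
* **PRA ↔ renin**: PRA is proportional to renin secretion at steady state
  (pool half-life 30 min); the proportionality constant (0.8 per unit
  normalized secretion) is a units convention chosen so the population's
  PRA distribution is centred on the documented statistics.
* **Salt intake** is the registry coefficient (uniform 0.8–1.2 × 139
  mmol/day), one draw per patient, constant throughout; the population
  statistic ≈ 139 ± 16 mmol/day.
* **Sub-steps**: slow states always advance at 1-h substeps (a 6-h
  explicit step is unstable near the tuned operating point); observations
  are taken at baseline end, +1 h and +4 weeks.

## Tuned constants and known limitations

The effect-curve shapes are only known graphically, so their slopes and
saturations were tuned once so that the calibrated population reproduces
the documented operating anchors (baseline 115/162/1.36, post-BAT
100/150/1.05; clamp-arm MAP falls ≈ 16/10.4/11.1/4.9 mmHg; ANP +72%;
afferent resistance −26%; proximal and collecting-duct reabsorption
changes and their clamp contrasts), then frozen; they are model structure,
not per-run fit parameters.

Known limitations, in the package's own numbers:

* Chronic cardiac output in the control arm recovers only partially
  (≈ −8% vs the documented −1 ± 2%): the inotropy/Starling balance that
  would fix it degrades the pressure/volume responses that are central to
  the trial. TPR depression, immediate CO fall and progressive volume
  expansion are reproduced.
* The baseline β1-adrenergic effect multiplier is ≈ 1.1 rather than the
  documented 1.43, a consequence of normalizing the β1 drive to each
  patient's basal renal tone (needed so the wide renal-SNA gain range does
  not double-count in renin); renin secretion levels and responses are
  reproduced.
* Several documented effect-multiplier rows are mutually inconsistent
  with a fully multiplicative tubule under the documented obesity gains;
  the model resolves this with saturating load/obesity exponents and
  reproduces the absolute reabsorption values and their changes instead.
* The full-scale 7,000-model run and the exact completion count are out
  of scope; the attrition *mechanism* (failed patients flagged and
  excluded, fraction reported) is implemented.
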
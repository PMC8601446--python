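"""Statistical battery and summary tables for trial outputs.

Reproduces the analysis pipeline of the in silico trial: Spearman rank
correlations between baseline variables and the BAT-induced blood-pressure
fall (with Fisher-z confidence intervals), paired t / Wilcoxon signed-rank
tests for pre/post contrasts, two-way repeated-measures ANOVA with Tukey
post-hoc comparisons across clamp arms, and the Normal/Baseline/BAT/%Change
summary tables.

Parametric versus nonparametric choice follows a Shapiro-Wilk normality
gate at alpha = 0.05.  No multiple-testing correction is applied to the
correlation table (raw p-values are reported).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .physiology import PhysState
from .trial import TrialOutput

#: Baseline variables screened against the BAT-induced MAP fall, grouped as
#: sympathetic, renal, hormonal, and systemic.
CORRELATION_ROSTER: tuple[str, ...] = (
    "sna_cardiac", "epi", "sna_peripheral", "e_b1_renin", "e_sna_pt", "ne",
    "sna_renal", "atrial_activity", "e_sna_aa", "afferent",
    "cdnar", "renal_mass", "e_md_renin", "loopnar", "dtnar", "gfr", "ptnar",
    "e_anp_pt", "anp", "e_anp_aa", "e_angii_pt", "renin_secretion", "angii",
    "aldo",
    "tpr", "rap", "plasma_volume", "blood_volume", "vein_volume", "hr",
    "map", "lap", "ecfv", "salt_intake",
)


@dataclass(frozen=True)
class CorrelationRow:
    """Spearman correlation of one baseline variable with the MAP fall."""

    variable: str
    r: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int

    def __post_init__(self):
        if not -1.0 <= self.r <= 1.0:
            raise ValueError("correlation out of range")


def spearman_with_ci(x, y, alpha: float = 0.05) -> tuple[float, float, float, float]:
    """Spearman r with a Fisher-z confidence interval and two-tailed p."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    r, p = sps.spearmanr(x, y)
    n = len(x)
    if abs(r) >= 1.0 or n <= 3:
        return float(r), float(r), float(r), float(p)
    z = np.arctanh(r)
    # Fieller-corrected standard error for rank correlations
    se = np.sqrt(1.06 / (n - 3))
    crit = sps.norm.ppf(1 - alpha / 2)
    return (float(r), float(np.tanh(z - crit * se)),
            float(np.tanh(z + crit * se)), float(p))


def exact_spearman_p(x, y) -> float:
    """Exact permutation p-value for the Spearman statistic (tiny n only)."""
    from itertools import permutations

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n > 8:
        raise ValueError("exact permutation test limited to n <= 8")
    r_obs, _ = sps.spearmanr(x, y)
    count = total = 0
    for perm in permutations(range(n)):
        r, _ = sps.spearmanr(x, y[list(perm)])
        total += 1
        if abs(r) >= abs(r_obs) - 1e-12:
            count += 1
    return count / total


def spearman_table(control: TrialOutput, coeffs: dict[str, np.ndarray] | None = None,
                   roster: tuple[str, ...] = CORRELATION_ROSTER) -> pd.DataFrame:
    """Correlations between baseline variables and the fall in MAP.

    The response is the (signed) change in MAP over 4 weeks of BAT in the
    control arm; baseline variables are read from the baseline state (or,
    for coefficients such as nephron count and salt intake, from the
    coefficient sets).
    """
    ok = control.ok
    dmap = control.delta("map")[ok]
    base: PhysState = control.states["baseline"]
    rows = []
    for name in roster:
        if hasattr(base, name):
            x = np.asarray(getattr(base, name), float)[ok]
        elif coeffs is not None and name in coeffs:
            x = np.asarray(coeffs[name], float)[ok]
        else:
            continue
        if np.std(x) == 0:
            continue
        r, lo, hi, p = spearman_with_ci(x, dmap)
        rows.append(CorrelationRow(name, r, lo, hi, p, int(ok.sum())))
    df = pd.DataFrame([r.__dict__ for r in rows])
    return df.sort_values("p_value", ignore_index=True)


def paired_tests(pre, post, alpha: float = 0.05) -> dict:
    """Paired t-test and Wilcoxon signed-rank test for a pre/post contrast.

    Also applies the Shapiro-Wilk normality gate to the paired differences
    and reports which test the gate recommends.
    """
    pre = np.asarray(pre, float)
    post = np.asarray(post, float)
    if pre.shape != post.shape:
        raise ValueError("pre/post must be paired (same shape)")
    diff = post - pre
    t_stat, t_p = sps.ttest_rel(post, pre)
    if np.allclose(diff, 0):
        w_stat, w_p = np.nan, 1.0
    else:
        w_stat, w_p = sps.wilcoxon(post, pre)
    if len(diff) >= 3 and np.ptp(diff) > 0:
        _, shapiro_p = sps.shapiro(diff)
    else:
        shapiro_p = np.nan
    normal = bool(shapiro_p > alpha) if np.isfinite(shapiro_p) else True
    return {
        "t": float(t_stat), "t_p": float(t_p),
        "wilcoxon": float(w_stat), "wilcoxon_p": float(w_p),
        "shapiro_p": float(shapiro_p) if np.isfinite(shapiro_p) else None,
        "recommended": "t" if normal else "wilcoxon",
        "p": float(t_p if normal else w_p),
        "mean_diff": float(diff.mean()),
    }


def welch_test(a, b) -> dict:
    """Unpaired two-sided t-test with Welch's correction."""
    t, p = sps.ttest_ind(np.asarray(a, float), np.asarray(b, float),
                         equal_var=False)
    u, up = sps.mannwhitneyu(a, b, alternative="two-sided")
    return {"t": float(t), "t_p": float(p),
            "mannwhitney": float(u), "mannwhitney_p": float(up)}


def rm_anova_tukey(arm_outputs: dict[str, TrialOutput], variable: str = "map",
                   times: tuple[str, ...] = ("baseline", "bat_1h", "bat_4wk"),
                   ) -> dict:
    """Two-way repeated-measures ANOVA (arm x time) + Tukey HSD at 4 weeks.

    Patients are the repeated-measures subjects (paired across arms and
    times).  Returns the ANOVA table and the pairwise Tukey comparison of
    arms on the 4-week value.
    """
    from statsmodels.stats.anova import AnovaRM
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    ok = np.ones_like(next(iter(arm_outputs.values())).ok)
    for out in arm_outputs.values():
        ok &= out.ok
    rows = []
    for arm, out in arm_outputs.items():
        for t in times:
            vals = np.asarray(getattr(out.states[t], variable), float)[ok]
            ids = out.ids[ok]
            rows.extend({"patient": int(i), "arm": arm, "time": t, "y": v}
                        for i, v in zip(ids, vals))
    df = pd.DataFrame(rows)
    anova = AnovaRM(df, depvar="y", subject="patient",
                    within=["arm", "time"]).fit()
    week4 = df[df.time == times[-1]]
    tukey = pairwise_tukeyhsd(week4["y"], week4["arm"])
    tukey_df = pd.DataFrame(tukey.summary().data[1:],
                            columns=tukey.summary().data[0])
    return {"anova": anova.anova_table, "tukey_week4": tukey_df, "data": df}


#: Variable -> printed name and scale for the cardiovascular summary table.
TABLE1_ROWS = [
    ("map", "MAP (mmHg)", 1.0),
    ("hr", "Heart rate (bpm)", 1.0),
    ("co", "Cardiac output (mL/min)", 1.0),
    ("blood_volume", "Blood volume (mL)", 1.0),
    ("ecfv", "ECF volume (L)", 1.0),
    ("tpr", "TPR (mmHg/mL/min)", 1.0),
    ("rap", "Right atrial pressure (mmHg)", 1.0),
    ("angii", "Angiotensin II (pg/mL)", 1.0),
    ("aldo", "Aldosterone (pMol/L)", 1.0),
    ("anp", "ANP (pMol/L)", 1.0),
    ("ne", "Norepinephrine (pg/mL)", 1.0),
    ("sna_peripheral", "Peripheral SNA (Hz)", 1.0),
    ("sna_cardiac", "Cardiac SNA (Hz)", 1.0),
    ("sna_renal", "Renal SNA (Hz)", 1.0),
]

TABLE2_ROWS = [
    ("gfr", "GFR (mL/min)", 1.0),
    ("rbf", "Renal blood flow (mL/min)", 1.0),
    ("total_nar", "Total NaR (mmol/min)", 1.0),
    ("renin_secretion", "Renin secretion (model units)", 1.0),
    ("e_md_renin", "Macula densa effect (xNormal)", 1.0),
    ("e_b1_renin", "Beta1-adrenergic effect (xNormal)", 1.0),
    ("ptnar", "PT NaR (mmol/min)", 1.0),
    ("e_angii_pt", "ANG II effect on PT NaR (xNormal)", 1.0),
    ("e_sna_pt", "SNA effect on PT NaR (xNormal)", 1.0),
    ("e_anp_pt", "ANP effect on PT NaR (xNormal)", 1.0),
    ("e_ifp_pt", "IFP effect on PT NaR (xNormal)", 1.0),
    ("aa_resistance", "AA resistance (mmHg/mL/min)", 1.0),
    ("e_tgf", "TGF effect (xNormal)", 1.0),
    ("e_visc_aa", "Viscosity effect on AA (xNormal)", 1.0),
    ("e_anp_aa", "ANP effect on AA (xNormal)", 1.0),
    ("e_sna_aa", "SNA effect on AA (xNormal)", 1.0),
    ("e_myo_aa", "Myogenic effect on AA (xNormal)", 1.0),
    ("loopnar", "Loop NaR (mmol/min)", 1.0),
    ("dtnar", "DT NaR (mmol/min)", 1.0),
    ("cdnar", "CD NaR (mmol/min)", 1.0),
]


def summary_table(control: TrialOutput, normal_state: PhysState,
                  rows=TABLE1_ROWS) -> pd.DataFrame:
    """Normal / Baseline / BAT / %Change table over the calibrated patients.

    The Normal column is the single default model; Baseline and BAT columns
    are population mean +/- SD; %Change is the population mean +/- SD of the
    per-patient percent change, with the paired-test p-value.
    """
    ok = control.ok
    out = []
    for var, label, scale in rows:
        normal = float(np.asarray(getattr(normal_state, var))[0]) * scale
        pre = np.asarray(getattr(control.states["baseline"], var), float)[ok] * scale
        post = np.asarray(getattr(control.states["bat_4wk"], var), float)[ok] * scale
        pct = 100.0 * (post - pre) / pre
        tests = paired_tests(pre, post)
        out.append({
            "variable": label,
            "normal": normal,
            "baseline_mean": pre.mean(), "baseline_sd": pre.std(ddof=1),
            "bat_mean": post.mean(), "bat_sd": post.std(ddof=1),
            "pct_change_mean": pct.mean(), "pct_change_sd": pct.std(ddof=1),
            "p_value": tests["p"],
        })
    return pd.DataFrame(out)


def summary_tables(control: TrialOutput, normal_state: PhysState
                   ) -> dict[str, pd.DataFrame]:
    """Both summary tables (cardiovascular/neurohormonal and renal)."""
    return {
        "cardiovascular": summary_table(control, normal_state, TABLE1_ROWS),
        "renal": summary_table(control, normal_state, TABLE2_ROWS),
    }
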
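"""Statistical operators against exhaustive / closed-form oracles."""

import numpy as np
import pytest

from baropop.stats import (exact_spearman_p, paired_tests, rm_anova_tukey,
                           spearman_with_ci, welch_test)


def test_spearman_perfect_monotone_pairs():
    x = np.arange(1.0, 7.0)
    r, lo, hi, p = spearman_with_ci(x, 2 * x + 1)
    assert r == 1.0 and p < 0.05
    r2, *_ = spearman_with_ci(x, -x ** 3)
    assert r2 == -1.0


def test_spearman_ci_contains_r():
    rng = np.random.default_rng(0)
    x = rng.normal(size=40)
    y = x + rng.normal(size=40)
    r, lo, hi, p = spearman_with_ci(x, y)
    assert lo < r < hi
    assert -1 <= lo and hi <= 1


def test_spearman_invariant_under_monotone_transforms():
    rng = np.random.default_rng(1)
    x = rng.normal(size=25)
    y = rng.normal(size=25)
    r0, *_ = spearman_with_ci(x, y)
    r1, *_ = spearman_with_ci(np.exp(x), y)
    r2, *_ = spearman_with_ci(x, y ** 3)
    assert r0 == pytest.approx(r1) == pytest.approx(r2)


def test_spearman_p_matches_exhaustive_permutation_null():
    """n=6: asymptotic p agrees with the exact 720-permutation null."""
    x = np.array([1.0, 2, 3, 4, 5, 6])
    y = np.array([2.0, 1, 4, 3, 6, 5])
    p_exact = exact_spearman_p(x, y)
    _, _, _, p_asym = spearman_with_ci(x, y)
    # the asymptotic p approximates the exact 720-permutation null
    assert abs(p_exact - p_asym) < 0.05
    # strongly monotone data is significant under the exact null too
    assert exact_spearman_p(x, x) == pytest.approx(2 / 720)


def test_paired_identical_gives_p_one():
    x = np.array([1.0, 2, 3, 4, 5])
    out = paired_tests(x, x.copy())
    assert np.isnan(out["t"]) or out["t_p"] > 0.99
    assert out["wilcoxon_p"] == 1.0
    assert out["mean_diff"] == 0.0


def test_paired_t_matches_hand_computation():
    """Textbook 5-pair example: t = dbar / (sd/sqrt(n))."""
    pre = np.array([120.0, 118, 125, 130, 122])
    post = np.array([114.0, 115, 119, 121, 120])
    d = post - pre
    t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(5))
    out = paired_tests(pre, post)
    assert out["t"] == pytest.approx(t_hand)
    assert out["p"] < 0.05
    with pytest.raises(ValueError):
        paired_tests(pre, post[:3])


def test_welch_detects_shift():
    rng = np.random.default_rng(2)
    a = rng.normal(0, 1, 30)
    b = rng.normal(2, 3, 30)
    out = welch_test(a, b)
    assert out["t_p"] < 0.01 and out["mannwhitney_p"] < 0.01


class _FakeArm:
    def __init__(self, values, ids=None):
        import types
        self.states = {t: types.SimpleNamespace(y=np.asarray(v, float))
                       for t, v in values.items()}
        n = len(next(iter(values.values())))
        self.ids = np.arange(n) if ids is None else ids
        self.ok = np.ones(n, dtype=bool)


def test_rm_anova_identical_arms_not_significant():
    rng = np.random.default_rng(3)
    base = rng.normal(100, 5, 12)
    arms = {
        "a": _FakeArm({"baseline": base + rng.normal(0, 0.5, 12),
                       "bat_1h": base - 3 + rng.normal(0, 0.5, 12),
                       "bat_4wk": base - 5 + rng.normal(0, 0.5, 12)}),
        "b": _FakeArm({"baseline": base + rng.normal(0, 0.5, 12),
                       "bat_1h": base - 3 + rng.normal(0, 0.5, 12),
                       "bat_4wk": base - 5 + rng.normal(0, 0.5, 12)}),
    }
    out = rm_anova_tukey(arms, variable="y")
    tbl = out["anova"]
    assert tbl.loc["arm", "Pr > F"] > 0.05
    assert tbl.loc["time", "Pr > F"] < 0.01
    assert not out["tukey_week4"]["reject"].any()


def test_rm_anova_f_matches_closed_form_when_time_collapsed():
    """Balanced toy, one time point: arm F equals hand-computed one-way
    repeated-measures F."""
    rng = np.random.default_rng(4)
    n = 10
    subj = rng.normal(0, 1, n)
    a = subj + rng.normal(0, 0.3, n)
    b = subj + 2.0 + rng.normal(0, 0.3, n)
    arms = {"a": _FakeArm({"baseline": a}), "b": _FakeArm({"baseline": b})}
    out = rm_anova_tukey(arms, variable="y", times=("baseline",))
    # closed-form one-way RM ANOVA (2 conditions) == paired t squared
    d = b - a
    t = d.mean() / (d.std(ddof=1) / np.sqrt(n))
    f = float(out["anova"].loc["arm", "F Value"])
    assert f == pytest.approx(t ** 2, rel=1e-6)
    assert out["tukey_week4"]["reject"].iloc[0]


def test_shapiro_gate_switches_to_wilcoxon():
    rng = np.random.default_rng(5)
    pre = rng.normal(0, 1, 40)
    post = pre + np.exp(rng.normal(0, 1.5, 40))  # heavily skewed differences
    out = paired_tests(pre, post)
    assert out["recommended"] == "wilcoxon"
    assert out["p"] == out["wilcoxon_p"]
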
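"""Two-factor ANOVA and paired contrasts against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from nirspeech import (
    AnalysisError,
    format_report,
    paired_contrast,
    two_way_anova,
)

HEMIS = ("left", "right")


def make_table(y, conditions, subjects=None):
    """Long table from y[subject, condition, hemisphere]."""
    n, a, b = y.shape
    subjects = subjects or [f"S{i:02d}" for i in range(1, n + 1)]
    rows = []
    for i, s in enumerate(subjects):
        for j, c in enumerate(conditions):
            for k, h in enumerate(HEMIS[:b]):
                rows.append(dict(subject=s, condition=c, hemisphere=h,
                                 value=y[i, j, k]))
    return pd.DataFrame(rows)


def brute_force_anova(y, strategy):
    """Direct-summation sums of squares, computed with explicit loops."""
    n, a, b = y.shape
    grand = y.mean()
    ss_a = ss_b = ss_ab = ss_s = ss_sa = ss_sb = ss_tot = 0.0
    mean_a = [y[:, j, :].mean() for j in range(a)]
    mean_b = [y[:, :, k].mean() for k in range(b)]
    mean_s = [y[i].mean() for i in range(n)]
    for j in range(a):
        ss_a += n * b * (mean_a[j] - grand) ** 2
    for k in range(b):
        ss_b += n * a * (mean_b[k] - grand) ** 2
    for j in range(a):
        for k in range(b):
            cell = y[:, j, k].mean()
            ss_ab += n * (cell - mean_a[j] - mean_b[k] + grand) ** 2
    for i in range(n):
        ss_s += a * b * (mean_s[i] - grand) ** 2
        for j in range(a):
            ss_sa += b * (y[i, j, :].mean() - mean_a[j] - mean_s[i] + grand) ** 2
        for k in range(b):
            ss_sb += a * (y[i, :, k].mean() - mean_b[k] - mean_s[i] + grand) ** 2
    for i in range(n):
        for j in range(a):
            for k in range(b):
                ss_tot += (y[i, j, k] - grand) ** 2
    out = {}
    if strategy == "pooled":
        ss_err = 0.0
        for i in range(n):
            for j in range(a):
                for k in range(b):
                    ss_err += (y[i, j, k] - y[:, j, k].mean()) ** 2
        df_err = a * b * (n - 1)
        out["A"] = (ss_a / (a - 1)) / (ss_err / df_err)
        out["B"] = (ss_b / (b - 1)) / (ss_err / df_err)
        out["AxB"] = (ss_ab / ((a - 1) * (b - 1))) / (ss_err / df_err)
    else:
        ss_sab = ss_tot - ss_a - ss_b - ss_ab - ss_s - ss_sa - ss_sb
        out["A"] = (ss_a / (a - 1)) / (ss_sa / ((a - 1) * (n - 1)))
        out["B"] = (ss_b / (b - 1)) / (ss_sb / ((b - 1) * (n - 1)))
        out["AxB"] = (ss_ab / ((a - 1) * (b - 1))) / \
            (ss_sab / ((a - 1) * (b - 1) * (n - 1)))
    return out


@pytest.mark.parametrize("shape", [(15, 2, 2), (15, 3, 2), (8, 3, 2)])
@pytest.mark.parametrize("strategy", ["subject_blocked", "pooled"])
def test_anova_matches_brute_force(shape, strategy, rng):
    for _ in range(10):
        y = rng.normal(size=shape)
        conditions = [f"c{j}" for j in range(shape[1])]
        res = two_way_anova(make_table(y, conditions), strategy=strategy)
        oracle = brute_force_anova(y, strategy)
        assert res.effect("condition").f == pytest.approx(oracle["A"], abs=1e-8)
        assert res.effect("hemisphere").f == pytest.approx(oracle["B"], abs=1e-8)
        assert res.effect("condition x hemisphere").f == pytest.approx(
            oracle["AxB"], abs=1e-8)


def test_subject_blocked_matches_statsmodels(rng):
    from statsmodels.stats.anova import AnovaRM
    y = rng.normal(size=(8, 3, 2))
    conditions = ["c0", "c1", "c2"]
    table = make_table(y, conditions)
    res = two_way_anova(table, strategy="subject_blocked")
    fit = AnovaRM(table, "value", "subject",
                  within=["condition", "hemisphere"]).fit()
    sm = fit.anova_table
    assert res.effect("condition").f == pytest.approx(
        sm.loc["condition", "F Value"], rel=1e-9)
    assert res.effect("hemisphere").f == pytest.approx(
        sm.loc["hemisphere", "F Value"], rel=1e-9)
    assert res.effect("condition x hemisphere").f == pytest.approx(
        sm.loc["condition:hemisphere", "F Value"], rel=1e-9)
    assert res.effect("condition").df2 == int(
        sm.loc["condition", "Den DF"])


def test_study_design_df_pattern(rng):
    """2 x 2 with 15 subjects under the subject-blocked strategy yields the
    F(1, 14) pattern; a 3-level factor yields error df 28, not 14."""
    y2 = rng.normal(size=(15, 2, 2))
    res2 = two_way_anova(make_table(y2, ["pseudoword", "word"]))
    assert (res2.effect("condition").df1, res2.effect("condition").df2) == (1, 14)
    y3 = rng.normal(size=(15, 3, 2))
    res3 = two_way_anova(make_table(y3, ["a", "b", "c"]))
    assert (res3.effect("condition").df1, res3.effect("condition").df2) == (2, 28)


def test_all_equal_observations_give_zero_f():
    y = np.full((6, 2, 2), 3.14)
    res = two_way_anova(make_table(y, ["a", "b"]))
    for e in res.effects.values():
        assert e.f == 0.0 and e.p == 1.0


def test_unbalanced_table_rejected(rng):
    table = make_table(rng.normal(size=(5, 2, 2)), ["a", "b"])
    broken = table.drop(index=3)
    with pytest.raises(AnalysisError, match="unbalanced"):
        two_way_anova(broken)
    with pytest.raises(AnalysisError, match="2 levels"):
        two_way_anova(table, levels_a=("a",))


def test_paired_contrast_equals_scipy_and_f_is_t_squared(rng):
    y = rng.normal(size=(12, 2, 2))
    table = make_table(y, ["pseudoword", "word"])
    res = paired_contrast(table, ("pseudoword", "word"), hemisphere="left")
    t_ref, p_ref = sps.ttest_rel(y[:, 0, 0], y[:, 1, 0])
    assert res.t == pytest.approx(t_ref, rel=1e-10)
    assert res.p == pytest.approx(p_ref, rel=1e-10)
    assert res.f == pytest.approx(res.t ** 2, rel=1e-12)
    assert res.df == 11


def test_degenerate_contrasts_flagged(rng):
    base = rng.normal(size=12)
    y = np.stack([np.stack([base, base], axis=1)] * 2, axis=2).transpose(0, 1, 2)
    # identical columns
    y_eq = np.stack([base, base], axis=1)[:, :, None].repeat(2, axis=2)
    table = make_table(y_eq, ["a", "b"])
    res = paired_contrast(table, ("a", "b"), hemisphere="left")
    assert res.degenerate and res.mean_difference == 0.0 and res.p == 1.0
    # uniform shift, zero variance of differences
    y_shift = y_eq.copy()
    y_shift[:, 0, :] += 1.0
    res2 = paired_contrast(make_table(y_shift, ["a", "b"]), ("a", "b"),
                           hemisphere="left")
    assert res2.degenerate and res2.p == 0.0


def test_contrast_power_matches_noncentral_t(rng):
    """Empirical rejection rate over 500 direct draws agrees with the
    closed-form noncentral-t power within 5 points."""
    n, delta, sd, alpha = 15, 0.9, 1.0, 0.05
    dof = n - 1
    tcrit = sps.t.ppf(1 - alpha / 2, dof)
    nc = delta / (sd / np.sqrt(n))
    analytic = sps.nct.sf(tcrit, dof, nc) + sps.nct.cdf(-tcrit, dof, nc)
    hits = 0
    reps = 500
    for _ in range(reps):
        diffs = rng.normal(delta, sd, size=n)
        y = np.zeros((n, 2, 2))
        y[:, 0, 0] = diffs
        res = paired_contrast(make_table(y, ["a", "b"]), ("a", "b"),
                              hemisphere="left")
        hits += res.p < alpha
    assert hits / reps == pytest.approx(analytic, abs=0.05)


def test_report_is_deterministic_and_verbatim(rng):
    y = rng.normal(size=(6, 2, 2))
    table = make_table(y, ["pseudoword", "word"])
    res = two_way_anova(table)
    con = paired_contrast(table, ("pseudoword", "word"), hemisphere="left")
    r1 = format_report({"speech": res}, {"pw_vs_w": con})
    r2 = format_report({"speech": res}, {"pw_vs_w": con})
    assert r1 == r2
    assert f"{res.effect('condition').f:.4g}" in r1
    assert f"F(1, {con.df}) = {con.f:.4g}" in r1
    with pytest.raises(AnalysisError):
        format_report({}, {})
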
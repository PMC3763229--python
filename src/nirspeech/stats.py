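"""Group-level contrasts: two-factor ANOVA on time-binned observations.

Observations are one scalar per (subject, condition, hemisphere) cell — a
binned summary of the subject's event-locked response — and the subject is
the replication unit.  Two error strategies are provided for the balanced
condition × hemisphere decomposition:

* ``"subject_blocked"`` (default): the subject is a blocking factor and each
  effect is tested against its own effect × subject interaction — the
  textbook within-subject (repeated-measures) ANOVA.  For a 2 × 2 design with
  15 subjects this yields F(1, 14) for every effect.
* ``"pooled"``: subjects are treated as independent replicates and all
  effects share the pooled residual error with df = ab(n−1).

For a factor with three levels the subject-blocked error df is 2(n−1), i.e.
28 at n = 15; reports quoting F(2, 14) under such a design are not
reproducible by any single textbook scheme, which is why both strategies are
exposed rather than silently reconciled.

No multiple-testing correction is applied; reports state the number of tests
run so readers can judge for themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import AnalysisError

ALPHA_DEFAULT = 0.05


@dataclass(frozen=True)
class EffectResult:
    name: str
    ss: float
    df1: int
    df2: int
    f: float
    p: float


@dataclass
class AnovaResult:
    """Decomposition for one condition × hemisphere table."""

    effects: dict[str, EffectResult]
    strategy: str
    alpha: float
    n_subjects: int
    levels_a: tuple[str, ...]
    levels_b: tuple[str, ...]
    cell_means: pd.DataFrame
    ss_total: float

    def effect(self, name: str) -> EffectResult:
        return self.effects[name]

    def significant(self, name: str) -> bool:
        return self.effects[name].p < self.alpha


def _f_and_p(ss_effect: float, df1: int, ss_error: float, df2: int
             ) -> tuple[float, float]:
    # All observations equal -> SS 0 everywhere; define F = 0 (nothing to test).
    if ss_effect <= 0.0:
        return 0.0, 1.0
    if ss_error <= 0.0:
        return float("inf"), 0.0
    f = (ss_effect / df1) / (ss_error / df2)
    return f, float(sps.f.sf(f, df1, df2))


def two_way_anova(table: pd.DataFrame, *,
                  value: str = "value",
                  factor_a: str = "condition",
                  factor_b: str = "hemisphere",
                  subject: str = "subject",
                  levels_a: tuple[str, ...] | None = None,
                  levels_b: tuple[str, ...] | None = None,
                  strategy: str = "subject_blocked",
                  alpha: float = ALPHA_DEFAULT) -> AnovaResult:
    """Balanced two-factor ANOVA with the subject as replication unit.

    ``table`` is long-format with one row per (subject, level_a, level_b).
    ``levels_a``/``levels_b`` restrict the factors to a subset (e.g. the two
    speech categories).  The table must be complete: every subject must
    contribute exactly one observation per cell.
    """
    if strategy not in ("subject_blocked", "pooled"):
        raise AnalysisError(f"unknown error strategy {strategy!r}")
    df = table
    if levels_a is not None:
        df = df[df[factor_a].isin(levels_a)]
    if levels_b is not None:
        df = df[df[factor_b].isin(levels_b)]
    levels_a = tuple(levels_a) if levels_a is not None \
        else tuple(sorted(df[factor_a].unique()))
    levels_b = tuple(levels_b) if levels_b is not None \
        else tuple(sorted(df[factor_b].unique()))
    subjects = tuple(sorted(df[subject].unique()))
    a, b, n = len(levels_a), len(levels_b), len(subjects)
    if a < 2 or b < 2:
        raise AnalysisError(
            f"both factors need at least 2 levels (got {a} x {b})"
        )
    pivot = df.pivot_table(index=subject, columns=[factor_a, factor_b],
                           values=value, aggfunc="count")
    missing = []
    for s in subjects:
        for la in levels_a:
            for lb in levels_b:
                cnt = pivot.loc[s].get((la, lb), np.nan) if s in pivot.index else np.nan
                if not cnt == 1:
                    missing.append((s, la, lb))
    if missing:
        raise AnalysisError(
            f"table is unbalanced; offending (subject, {factor_a}, {factor_b}) "
            f"cells: {missing[:10]}{'...' if len(missing) > 10 else ''}"
        )

    y = np.empty((n, a, b))
    lookup = {(r[subject], r[factor_a], r[factor_b]): r[value]
              for r in df.to_dict("records")}
    for i, s in enumerate(subjects):
        for j, la in enumerate(levels_a):
            for k, lb in enumerate(levels_b):
                y[i, j, k] = lookup[(s, la, lb)]

    grand = y.mean()
    mean_a = y.mean(axis=(0, 2))
    mean_b = y.mean(axis=(0, 1))
    mean_ab = y.mean(axis=0)
    mean_s = y.mean(axis=(1, 2))
    ss_total = float(((y - grand) ** 2).sum())
    ss_a = float(n * b * ((mean_a - grand) ** 2).sum())
    ss_b = float(n * a * ((mean_b - grand) ** 2).sum())
    ss_ab = float(n * ((mean_ab - mean_a[:, None] - mean_b[None, :] + grand) ** 2).sum())
    df_a, df_b, df_ab = a - 1, b - 1, (a - 1) * (b - 1)

    if strategy == "pooled":
        ss_err = float(((y - mean_ab[None]) ** 2).sum())
        df_err = a * b * (n - 1)
        parts = [("A", ss_a, df_a, ss_err, df_err),
                 ("B", ss_b, df_b, ss_err, df_err),
                 ("AxB", ss_ab, df_ab, ss_err, df_err)]
    else:
        mean_sa = y.mean(axis=2)  # (n, a)
        mean_sb = y.mean(axis=1)  # (n, b)
        ss_s = float(a * b * ((mean_s - grand) ** 2).sum())
        ss_sa = float(b * ((mean_sa - mean_a[None, :] - mean_s[:, None] + grand) ** 2).sum())
        ss_sb = float(a * ((mean_sb - mean_b[None, :] - mean_s[:, None] + grand) ** 2).sum())
        ss_sab = ss_total - ss_a - ss_b - ss_ab - ss_s - ss_sa - ss_sb
        ss_sab = max(ss_sab, 0.0)
        parts = [("A", ss_a, df_a, ss_sa, df_a * (n - 1)),
                 ("B", ss_b, df_b, ss_sb, df_b * (n - 1)),
                 ("AxB", ss_ab, df_ab, ss_sab, df_ab * (n - 1))]

    names = {"A": factor_a, "B": factor_b, "AxB": f"{factor_a} x {factor_b}"}
    effects = {}
    for key, ss_e, d1, ss_err, d2 in parts:
        f, p = _f_and_p(ss_e, d1, ss_err, d2)
        effects[names[key]] = EffectResult(names[key], ss_e, d1, d2, f, p)

    cell_means = pd.DataFrame(
        [(la, lb, mean_ab[j, k], n)
         for j, la in enumerate(levels_a) for k, lb in enumerate(levels_b)],
        columns=[factor_a, factor_b, "mean", "n_subjects"],
    )
    return AnovaResult(effects=effects, strategy=strategy, alpha=alpha,
                       n_subjects=n, levels_a=levels_a, levels_b=levels_b,
                       cell_means=cell_means, ss_total=ss_total)


@dataclass
class ContrastResult:
    """Within-subject paired contrast between two condition columns."""

    condition_pair: tuple[str, str]
    hemisphere: str | None
    mean_difference: float
    t: float
    f: float
    p: float
    df: int
    degenerate: bool


def paired_contrast(table: pd.DataFrame, condition_pair: tuple[str, str],
                    hemisphere: str | None = None, *,
                    value: str = "value",
                    subject: str = "subject") -> ContrastResult:
    """Paired t test on per-subject differences; reports F = t² with df (1, n−1).

    Every subject must contribute both conditions.  Zero-variance differences
    (identical or uniformly shifted columns) are flagged degenerate rather
    than yielding a spurious p-value.
    """
    df = table
    if hemisphere is not None:
        df = df[df["hemisphere"] == hemisphere]
    cond_a, cond_b = condition_pair
    wide = df[df["condition"].isin(condition_pair)].pivot_table(
        index=subject, columns="condition", values=value)
    if cond_a not in wide.columns or cond_b not in wide.columns \
            or wide[list(condition_pair)].isna().any().any():
        missing = [] if cond_a not in wide.columns or cond_b not in wide.columns \
            else list(wide.index[wide[list(condition_pair)].isna().any(axis=1)])
        raise AnalysisError(
            f"paired contrast {condition_pair} requires both conditions for "
            f"every subject; missing for subjects {missing}"
        )
    d = (wide[cond_a] - wide[cond_b]).to_numpy(dtype=float)
    n = d.size
    if n < 2:
        raise AnalysisError("paired contrast needs at least 2 subjects")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    dof = n - 1
    # treat rounding-level spread of the differences as zero variance
    if sd <= 1e-10 * max(1.0, float(np.max(np.abs(d)))):
        t = 0.0 if mean == 0.0 else float("inf")
        p = 1.0 if mean == 0.0 else 0.0
        return ContrastResult(condition_pair, hemisphere, mean, t, t * t, p,
                              dof, degenerate=True)
    t = mean / (sd / np.sqrt(n))
    p = float(2.0 * sps.t.sf(abs(t), dof))
    return ContrastResult(condition_pair, hemisphere, mean, t, t * t, p, dof,
                          degenerate=False)


def format_report(anovas: dict[str, AnovaResult],
                  contrasts: dict[str, ContrastResult] | None = None,
                  notes: dict[str, str] | None = None) -> str:
    """Human-readable analysis report with deterministic ordering.

    F values are printed in the conventional F(df1, df2) notation; every
    ANOVA's error strategy and the total number of tests are stated.
    """
    if not anovas and not contrasts:
        raise AnalysisError("nothing to report")
    lines = ["nirspeech group analysis report", "=" * 34, ""]
    n_tests = 0
    for label in sorted(anovas):
        res = anovas[label]
        lines.append(f"[{label}]  two-way ANOVA "
                     f"({' x '.join([str(len(res.levels_a)), str(len(res.levels_b))])}"
                     f", n={res.n_subjects}, error strategy={res.strategy}, "
                     f"alpha={res.alpha})")
        for name in res.effects:
            e = res.effects[name]
            star = " *" if e.p < res.alpha else ""
            lines.append(f"  {name}: F({e.df1}, {e.df2}) = {e.f:.4g}, "
                         f"p = {e.p:.4g}{star}")
            n_tests += 1
        lines.append("")
    for label in sorted(contrasts or {}):
        c = contrasts[label]
        where = f" at {c.hemisphere}" if c.hemisphere else ""
        tag = " [degenerate]" if c.degenerate else ""
        lines.append(f"[{label}]  paired contrast {c.condition_pair[0]} - "
                     f"{c.condition_pair[1]}{where}: mean diff = "
                     f"{c.mean_difference:.4g}, F(1, {c.df}) = {c.f:.4g}, "
                     f"p = {c.p:.4g}{tag}")
        n_tests += 1
    lines.append("")
    for key in sorted(notes or {}):
        lines.append(f"note[{key}]: {notes[key]}")
    lines.append(f"tests run (no multiplicity correction): {n_tests}")
    lines.append("")
    return "\n".join(lines)
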
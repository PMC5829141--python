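"""Group-level inference across brain regions and consciousness conditions.

Per-session scalar summaries (40-Hz MTP and PLF band means; T/C gating
ratios) are compared with the study's stated statistics: a one-way ANOVA
across regions followed by Tukey's HSD for all pairwise region contrasts,
and a two-sided paired t-test between the conscious and anesthetized
condition within each region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as _stats

#: Session-summary measures the group statistics operate on.
MEASURES = ("mtp40", "plf40", "tc_negative", "tc_positive")


@dataclass
class AnovaResult:
    measure: str
    F: float
    df_between: int
    df_within: int
    p_value: float
    tukey: pd.DataFrame                 # columns group1, group2, meandiff, p_adj
    excluded: list[str] = field(default_factory=list)


@dataclass
class PairedResult:
    region: str
    measure: str
    t: float
    df: int
    p_value: float
    n_pairs: int
    mean_diff: float


def region_anova(summaries: pd.DataFrame, measure: str,
                 group_col: str = "region") -> AnovaResult:
    """One-way ANOVA across regions plus Tukey HSD pairwise contrasts.

    Regions with fewer than two finite sessions are excluded with a warning.
    Tukey-adjusted p-values come from the studentized-range distribution on
    the classic homoskedastic MS_within.
    """
    df = summaries[[group_col, measure]].dropna()
    groups, excluded = {}, []
    for name, sub in df.groupby(group_col, sort=False):
        vals = sub[measure].to_numpy(float)
        if len(vals) < 2:
            excluded.append(str(name))
        else:
            groups[str(name)] = vals
    if excluded:
        warnings.warn(f"{measure}: excluded groups with < 2 sessions: {excluded}",
                      stacklevel=2)
    if len(groups) < 2:
        raise ValueError(f"{measure}: need >= 2 groups with >= 2 sessions")
    names = list(groups)
    values = list(groups.values())
    grand = np.concatenate(values).mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in values)
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in values)
    df_b = len(values) - 1
    df_w = sum(len(v) for v in values) - len(values)
    if ss_between == 0.0:
        F, p = 0.0, 1.0
    else:
        F, p = (float(x) for x in _stats.f_oneway(*values))
    ms_within = ss_within / df_w if df_w > 0 else 0.0
    rows = []
    for a, b in combinations(names, 2):
        va, vb = groups[a], groups[b]
        diff = vb.mean() - va.mean()
        se = np.sqrt(ms_within / 2.0 * (1.0 / len(va) + 1.0 / len(vb)))
        if se == 0.0:
            p_adj = 1.0 if diff == 0.0 else 0.0
        else:
            q = abs(diff) / se
            p_adj = float(_stats.studentized_range.sf(q, len(names), df_w))
        rows.append({"group1": a, "group2": b, "meandiff": diff, "p_adj": p_adj})
    return AnovaResult(measure=measure, F=F, df_between=df_b, df_within=df_w,
                       p_value=p, tukey=pd.DataFrame(rows), excluded=excluded)


def paired_condition_test(summaries: pd.DataFrame, region: str, measure: str,
                          conditions: tuple[str, str] = ("conscious", "anesthetized"),
                          ) -> PairedResult:
    """Two-sided paired t-test on within-session condition differences.

    Sessions are matched on ``session_id``; unmatched sessions are dropped
    with a warning naming how many.
    """
    sub = summaries[summaries["region"] == region]
    wide = sub.pivot_table(index="session_id", columns="condition",
                           values=measure, aggfunc="first")
    missing_cols = [c for c in conditions if c not in wide.columns]
    if missing_cols:
        raise ValueError(f"{region}/{measure}: no sessions in condition(s) {missing_cols}")
    paired = wide[list(conditions)].dropna()
    dropped = len(wide) - len(paired)
    if dropped:
        warnings.warn(f"{region}/{measure}: dropped {dropped} unmatched sessions",
                      stacklevel=2)
    if len(paired) < 2:
        raise ValueError(f"{region}/{measure}: need >= 2 paired sessions")
    a = paired[conditions[0]].to_numpy(float)
    b = paired[conditions[1]].to_numpy(float)
    diffs = a - b
    n = len(diffs)
    if np.all(diffs == 0.0):
        t, p = 0.0, 1.0
    else:
        res = _stats.ttest_rel(a, b)
        t, p = float(res.statistic), float(res.pvalue)
    return PairedResult(region=region, measure=measure, t=t, df=n - 1,
                        p_value=p, n_pairs=n, mean_diff=float(diffs.mean()))


@dataclass
class GroupStatsReport:
    """All group-level results for one cohort."""

    anova: dict[str, AnovaResult]               # measure -> (conscious cohort)
    paired: dict[tuple[str, str], PairedResult]  # (region, measure) -> result
    alpha: float = 0.05

    def anova_frame(self) -> pd.DataFrame:
        rows = [{"measure": m, "F": r.F, "df_between": r.df_between,
                 "df_within": r.df_within, "p_value": r.p_value}
                for m, r in self.anova.items()]
        return pd.DataFrame(rows)

    def tukey_frame(self) -> pd.DataFrame:
        frames = []
        for m, r in self.anova.items():
            f = r.tukey.copy()
            f.insert(0, "measure", m)
            frames.append(f)
        return pd.concat(frames, ignore_index=True)

    def paired_frame(self) -> pd.DataFrame:
        rows = [{"region": r.region, "measure": r.measure, "t": r.t, "df": r.df,
                 "p_value": r.p_value, "n_pairs": r.n_pairs,
                 "mean_diff": r.mean_diff}
                for r in self.paired.values()]
        return pd.DataFrame(rows)

    def to_text(self) -> str:
        lines = ["Group statistics", "================", "",
                 "One-way ANOVA across regions (conscious sessions):"]
        for m, r in self.anova.items():
            lines.append(f"  {m:12s} F({r.df_between},{r.df_within}) = {r.F:8.3f}"
                         f"   p = {r.p_value:.3g}")
        lines.append("")
        lines.append(f"Paired t-tests, conscious vs anesthetized (alpha = {self.alpha}):")
        for (region, m), r in self.paired.items():
            flag = "*" if r.p_value < self.alpha else " "
            lines.append(f"  {region:4s} {m:12s} t({r.df}) = {r.t:8.3f}   "
                         f"p = {r.p_value:.3g} {flag}  mean diff = {r.mean_diff:.4g}")
        return "\n".join(lines) + "\n"


def group_stats(summaries: pd.DataFrame, measures=MEASURES,
                alpha: float = 0.05) -> GroupStatsReport:
    """ANOVA + Tukey on the conscious cohort, paired tests per region."""
    conscious = summaries[summaries["condition"] == "conscious"]
    anova = {}
    for m in measures:
        try:
            anova[m] = region_anova(conscious, m)
        except ValueError as exc:
            warnings.warn(f"ANOVA skipped: {exc}", stacklevel=2)
    paired = {}
    for region in summaries["region"].unique():
        for m in measures:
            try:
                paired[(region, m)] = paired_condition_test(summaries, region, m)
            except ValueError:
                continue
    return GroupStatsReport(anova=anova, paired=paired, alpha=alpha)
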
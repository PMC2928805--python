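"""Group summaries and hypothesis tests for phenotype tables.

Implements the analyses used throughout the assay figures: mean ± s.e.m. per
group, the unpaired two-tailed t-test (Welch by default, pooled on request),
one-way ANOVA, and Dunnett's many-to-one multiple comparison against a control
group.  Dunnett's familywise-adjusted p-values are computed by seeded Monte
Carlo from the joint null distribution of the correlated t statistics (shared
pooled variance, shared control mean), so the procedure is exactly
reproducible under a fixed seed and its calibration is directly testable.

Tables are long-format: one row per observation with columns
``group``, ``id``, ``value`` (``id`` optional).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError

TableLike = Union[pd.DataFrame, dict]


def as_group_table(table: TableLike) -> pd.DataFrame:
    """Normalize input to a long-format DataFrame with group/value columns."""
    if isinstance(table, dict):
        rows = [(g, i, float(v)) for g, vals in table.items()
                for i, v in enumerate(np.asarray(vals, dtype=float))]
        df = pd.DataFrame(rows, columns=["group", "id", "value"])
    else:
        df = table.copy()
    if "group" not in df or "value" not in df:
        raise ValidationError("table: needs 'group' and 'value' columns")
    return df


def significance_marker(p: float) -> str:
    """Conventional significance stars at 0.05 / 0.01 / 0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def group_summary(table: TableLike) -> pd.DataFrame:
    """Per-group n, mean and s.e.m. (sample sd with n-1 denominator / sqrt(n)).

    With n = 1 the s.e.m. is undefined and reported as missing.
    """
    df = as_group_table(table)
    out = df.groupby("group", sort=False)["value"].agg(
        n="count", mean="mean", sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)))
    return out.reset_index()


@dataclass
class ComparisonResult:
    test: str
    alpha: float
    comparisons: pd.DataFrame   # group_a, group_b, statistic, df, p, p_adjusted, marker
    flags: List[str] = field(default_factory=list)


def t_test_unpaired(group_a: Sequence[float], group_b: Sequence[float],
                    two_tailed: bool = True,
                    equal_var: bool = False) -> ComparisonResult:
    """Unpaired t-test; Welch (unequal variance) by default.

    With zero variance in both groups and equal means, t is undefined; the
    result reports t = 0, p = 1 with a flag.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("group: each group needs at least 2 observations")
    flags: List[str] = []
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            flags.append("zero variance in both groups; t undefined, p = 1 reported")
            t_stat, p, dof = 0.0, 1.0, float(a.size + b.size - 2)
        else:
            flags.append("zero variance, unequal means; p = 0 reported")
            t_stat, p, dof = np.inf, 0.0, float(a.size + b.size - 2)
    else:
        res = sps.ttest_ind(a, b, equal_var=equal_var,
                            alternative="two-sided" if two_tailed else "greater")
        t_stat, p, dof = float(res.statistic), float(res.pvalue), float(res.df)
    df = pd.DataFrame([{
        "group_a": "A", "group_b": "B", "statistic": t_stat, "df": dof,
        "p": p, "p_adjusted": p, "marker": significance_marker(p)}])
    name = ("unpaired two-tailed" if two_tailed else "unpaired one-tailed") + \
        (" pooled t-test" if equal_var else " Welch t-test")
    return ComparisonResult(test=name, alpha=0.05, comparisons=df, flags=flags)


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


def one_way_anova(table: TableLike) -> AnovaResult:
    """Standard one-way between/within variance decomposition."""
    df = as_group_table(table)
    groups = [g["value"].to_numpy(dtype=float) for _, g in df.groupby("group", sort=False)]
    k = len(groups)
    if k < 2:
        raise ValidationError("table: need at least 2 groups for ANOVA")
    n_total = sum(len(g) for g in groups)
    df_within = n_total - k
    if df_within <= 0:
        raise ValidationError("table: no within-group degrees of freedom")
    grand = np.concatenate(groups).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_between = k - 1
    if ssw == 0:
        F = 0.0 if ssb == 0 else np.inf
    else:
        F = (ssb / df_between) / (ssw / df_within)
    p = float(sps.f.sf(F, df_between, df_within)) if np.isfinite(F) else 0.0
    return AnovaResult(F=float(F), df_between=df_between, df_within=df_within, p=p)


def dunnett(table: TableLike, control_group, alpha: float = 0.05,
            n_draws: int = 100_000,
            rng: Optional[Union[int, np.random.Generator]] = None) -> ComparisonResult:
    """Dunnett's many-to-one comparisons against ``control_group``.

    Each treatment statistic is ``t_i = (mean_i - mean_0) / sqrt(s2 (1/n_i + 1/n_0))``
    with the variance pooled over all groups (df = N - k).  The familywise
    adjusted p is the Monte-Carlo tail probability of the maximum absolute
    statistic under the joint null (shared control mean and shared pooled
    variance induce the correlation).  Adjusted p-values are floored at the
    parametric raw p so adjusted >= raw holds exactly.
    """
    df = as_group_table(table)
    if control_group not in set(df["group"]):
        raise ValidationError("control_group: not present in the table")
    ctrl = df.loc[df["group"] == control_group, "value"].to_numpy(dtype=float)
    if ctrl.size < 2:
        raise ValidationError("control_group: needs at least 2 observations")
    treat_names = [g for g in df["group"].unique() if g != control_group]
    if not treat_names:
        raise ValidationError("table: need at least one treatment group")
    treats = [df.loc[df["group"] == g, "value"].to_numpy(dtype=float)
              for g in treat_names]

    groups = [ctrl] + treats
    ns = np.array([len(g) for g in groups])
    N, k = int(ns.sum()), len(groups)
    nu = N - k
    if nu <= 0:
        raise ValidationError("table: no residual degrees of freedom")
    s2 = sum(((g - g.mean()) ** 2).sum() for g in groups) / nu
    if s2 == 0:
        raise ValidationError("table: zero pooled variance, statistics undefined")
    se = np.sqrt(s2 * (1.0 / ns[1:] + 1.0 / ns[0]))
    t_obs = np.array([(g.mean() - ctrl.mean()) for g in treats]) / se

    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    z = gen.standard_normal((n_draws, k))
    w = gen.chisquare(nu, size=n_draws)
    sd_scale = np.sqrt(w / nu)
    diffs = z[:, 1:] / np.sqrt(ns[1:]) - z[:, [0]] / np.sqrt(ns[0])
    t_null = diffs / (sd_scale[:, None] * np.sqrt(1.0 / ns[1:] + 1.0 / ns[0]))
    max_abs = np.abs(t_null).max(axis=1)

    raw = 2.0 * sps.t.sf(np.abs(t_obs), nu)
    adj = (1.0 + (max_abs[:, None] >= np.abs(t_obs)[None, :]).sum(axis=0)) \
        / (n_draws + 1.0)
    adj = np.maximum(adj, raw)

    rows = [{"group_a": g, "group_b": control_group, "statistic": float(t),
             "df": nu, "p": float(pr), "p_adjusted": float(pa),
             "marker": significance_marker(pa)}
            for g, t, pr, pa in zip(treat_names, t_obs, raw, adj)]
    return ComparisonResult(test="Dunnett (Monte Carlo)", alpha=alpha,
                            comparisons=pd.DataFrame(rows))
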
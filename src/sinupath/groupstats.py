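"""Univariate group comparisons: one-way ANOVA, Tukey HSD with a compact
letter display, and a pairwise-correlation screen for covariate selection.

These drive the location-by-location comparisons of movement indices,
morphometrics and enzyme activities across the four sampled populations, and
the resident/disperser two-group contrasts.  P-values come from scipy's F and
studentized-range distributions; the sums of squares, Tukey q statistics and
letter display are computed here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateVarianceError, InsufficientReplicationError

__all__ = [
    "AnovaResult",
    "GroupComparisonResult",
    "one_way_anova",
    "tukey_hsd",
    "compact_letter_display",
    "screen_collinear",
    "compare_variables",
]


@dataclass(frozen=True)
class AnovaResult:
    variable: str
    F: float
    df_between: int
    df_within: int
    p_value: float
    ss_between: float
    ss_within: float
    ms_within: float
    group_means: dict
    group_ns: dict


@dataclass(frozen=True)
class GroupComparisonResult:
    """ANOVA plus Tukey table and letters for one variable/grouping."""

    anova: AnovaResult
    tukey_table: pd.DataFrame  # group1, group2, diff, se, q, p_adj
    letters: dict  # group -> letter string
    alpha: float


def _split_groups(values, groups):
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    ok = np.isfinite(values)
    values, groups = values[ok], groups[ok]
    labels = sorted(pd.unique(groups).tolist())
    split = {g: values[groups == g] for g in labels}
    return split, labels


def one_way_anova(values, groups, variable: str = "value") -> AnovaResult:
    """Classical one-way fixed-effects ANOVA.

    Decomposes SS_total = SS_between + SS_within; F = MS_between / MS_within
    with (k - 1, n - k) degrees of freedom.  Requires >= 2 groups, each with
    >= 2 observations, and positive pooled within-group variance.
    """
    split, labels = _split_groups(values, groups)
    if len(labels) < 2:
        raise InsufficientReplicationError("need at least 2 groups")
    for g, v in split.items():
        if len(v) < 2:
            raise InsufficientReplicationError(f"group {g!r} has < 2 observations")
    n = sum(len(v) for v in split.values())
    grand = np.concatenate(list(split.values())).mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in split.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in split.values())
    df_b, df_w = len(labels) - 1, n - len(labels)
    if ss_within <= 0:
        raise DegenerateVarianceError(f"{variable}: zero within-group variance")
    F = (ss_between / df_b) / (ss_within / df_w)
    return AnovaResult(
        variable=variable,
        F=float(F),
        df_between=df_b,
        df_within=df_w,
        p_value=float(stats.f.sf(F, df_b, df_w)),
        ss_between=float(ss_between),
        ss_within=float(ss_within),
        ms_within=float(ss_within / df_w),
        group_means={g: float(v.mean()) for g, v in split.items()},
        group_ns={g: int(len(v)) for g, v in split.items()},
    )


def tukey_hsd(values, groups, alpha: float = 0.05,
              variable: str = "value") -> GroupComparisonResult:
    """Tukey (Kramer) honestly-significant-difference pairwise comparisons.

    For each pair, q = |mean_i - mean_j| / sqrt(MS_within * (1/n_i + 1/n_j) / 2)
    with the adjusted p from the studentized range distribution with
    (k, df_within) parameters; groups then receive compact display letters
    where sharing a letter means the pair is not significantly different at
    ``alpha``.
    """
    anova = one_way_anova(values, groups, variable)
    labels = sorted(anova.group_means)
    k, df_w = len(labels), anova.df_within
    rows = []
    sig_pairs = set()
    for i, gi in enumerate(labels):
        for gj in labels[i + 1:]:
            diff = anova.group_means[gi] - anova.group_means[gj]
            se = np.sqrt(
                anova.ms_within
                * (1.0 / anova.group_ns[gi] + 1.0 / anova.group_ns[gj]) / 2.0
            )
            q = abs(diff) / se
            p_adj = float(stats.studentized_range.sf(q, k, df_w))
            p_adj = min(p_adj, 1.0)
            rows.append({"group1": gi, "group2": gj, "diff": diff,
                         "se": se, "q": q, "p_adj": p_adj})
            if p_adj < alpha:
                sig_pairs.add((gi, gj))
    letters = compact_letter_display(labels, sig_pairs)
    return GroupComparisonResult(
        anova=anova,
        tukey_table=pd.DataFrame(rows),
        letters=letters,
        alpha=alpha,
    )


def compact_letter_display(labels, sig_pairs) -> dict:
    """Insert-and-absorb compact letter display.

    Each letter names a maximal set of mutually non-significant groups;
    groups share a letter exactly when they are not significantly different.
    Deterministic given the sorted label order.
    """
    sig = {frozenset(p) for p in sig_pairs}

    def compatible(group, letter_set):
        return all(frozenset((group, other)) not in sig for other in letter_set)

    letter_sets: list[set] = []
    for g in labels:
        placed = False
        for s in letter_sets:
            if compatible(g, s):
                s.add(g)
                placed = True
        if not placed:
            # insert a new letter; seed it with every earlier compatible group
            new = {g}
            for h in labels:
                if h != g and compatible(h, new):
                    new.add(h)
            letter_sets.append(new)
    # absorb: drop letter sets wholly contained in another
    letter_sets = [
        s for i, s in enumerate(letter_sets)
        if not any(i != j and s < t for j, t in enumerate(letter_sets))
    ]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in labels}
    for letter, s in zip(alphabet, letter_sets):
        for g in sorted(s):
            out[g] += letter
    return out


def screen_collinear(data: pd.DataFrame, candidates, threshold: float = 0.7):
    """Iteratively drop collinear covariates until no pair exceeds ``threshold``.

    Pairwise Pearson correlations are computed on complete cases; at each
    step the variable with the largest mean absolute correlation among the
    offending pairs is removed (ties broken by variable name).  Constant
    variables are excluded up front with a warning entry in the returned log.

    Returns (retained variable names, log of removals).
    """
    retained = list(candidates)
    log = []
    sub = data[retained].dropna()
    if len(sub) < 3:
        raise InsufficientReplicationError("need >= 3 complete records")
    for v in list(retained):
        if sub[v].nunique() <= 1:
            retained.remove(v)
            log.append({"variable": v, "action": "excluded_constant"})
    while True:
        corr = data[retained].dropna().corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        offenders = corr[corr > threshold]
        if offenders.notna().sum().sum() == 0:
            break
        # mean |r| over the pairs that exceed the threshold, per variable
        scores = offenders.mean(axis=1, skipna=True).fillna(0.0)
        worst = scores[scores > 0]
        drop = sorted(worst.index[worst == worst.max()])[0]
        retained.remove(drop)
        log.append({"variable": drop, "action": "dropped_collinear",
                    "mean_abs_r": float(worst.max())})
        if len(retained) < 2:
            break
    return retained, log


def compare_variables(data: pd.DataFrame, variables, grouping: str,
                      alpha: float = 0.05) -> tuple[pd.DataFrame, dict]:
    """Run ANOVA + Tukey for each variable against one grouping column.

    Missing values are dropped listwise per variable (assay sample sizes
    differ across variables).  Returns a long-format report and a dict of the
    full :class:`GroupComparisonResult` objects keyed by variable.
    """
    rows, results = [], {}
    for var in variables:
        sub = data[[var, grouping]].dropna()
        res = tukey_hsd(sub[var], sub[grouping], alpha=alpha, variable=var)
        results[var] = res
        a = res.anova
        rows.append({
            "variable": var,
            "grouping": grouping,
            "n": sum(a.group_ns.values()),
            "F": a.F,
            "df1": a.df_between,
            "df2": a.df_within,
            "p": a.p_value,
            "letters": ";".join(f"{g}={res.letters[g]}" for g in sorted(res.letters)),
        })
    return pd.DataFrame(rows), results
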
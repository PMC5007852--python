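"""Group statistics: control normalization, one-way ANOVA with
Bonferroni post hoc comparisons, ANOVA reconstruction from printed
summary statistics, and Spearman correlation.

Measurements are normalized per (region × parameter) stratum so that
the control-group mean is exactly 100 %, then each parameter is tested
independently with a one-way ANOVA followed by classical Bonferroni
pairwise t tests using the pooled mean squared error (adjusted
p = min(1, m·p) over the m pairwise comparisons).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class PairwiseResult:
    """One Bonferroni pairwise comparison from the pooled-MSE t test."""

    pair: tuple[str, str]
    t: float
    p_raw: float
    p_adj: float


@dataclass
class ANOVAResult:
    """One-way ANOVA summary: F(df_between, df_within), p, pooled MSE."""

    F: float
    df_between: int
    df_within: int
    p: float
    mse: float
    group_labels: tuple[str, ...]
    group_means: tuple[float, ...]
    group_ns: tuple[int, ...]
    posthoc: list[PairwiseResult] = field(default_factory=list)


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman rank correlation; ``undefined`` flags constant input."""

    rho: float
    p: float
    undefined: bool = False


def normalize_to_control(
    table: pd.DataFrame,
    control_label: str,
    *,
    value_col: str = "value",
    group_col: str = "condition",
    strata: Sequence[str] = ("region", "parameter"),
) -> pd.DataFrame:
    """Express values as percent of the control-group mean per stratum.

    Within every stratum the control mean is defined as 100 %, so each
    value maps to ``value / mean(control stratum) × 100``.  Strata with
    an absent or zero-mean control group are excluded and listed in
    ``result.attrs["flagged_strata"]``.
    """
    strata = list(strata)
    out = []
    flagged = []
    for key, sub in table.groupby(strata, sort=True):
        ctrl = sub.loc[sub[group_col] == control_label, value_col]
        if len(ctrl) == 0 or ctrl.mean() == 0 or not np.isfinite(ctrl.mean()):
            flagged.append(key)
            continue
        sub = sub.copy()
        sub[value_col] = sub[value_col] / ctrl.mean() * 100.0
        out.append(sub)
    result = (
        pd.concat(out, ignore_index=True)
        if out
        else table.iloc[0:0].copy()
    )
    result.attrs["flagged_strata"] = flagged
    return result


def _validate_groups(groups: Sequence[np.ndarray]) -> list[np.ndarray]:
    gs = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    for g in gs:
        if g.size < 2:
            raise ValueError("each group needs at least two values")
    return gs


def one_way_anova(groups: Sequence[np.ndarray]) -> ANOVAResult:
    """Textbook between/within sum-of-squares one-way ANOVA.

    Raises ``ValueError`` when both the between- and within-group sums
    of squares vanish (all observations identical — F undefined).
    """
    gs = _validate_groups(groups)
    k = len(gs)
    ns = np.array([g.size for g in gs])
    N = int(ns.sum())
    means = np.array([g.mean() for g in gs])
    grand = float(np.concatenate(gs).mean())
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in gs))
    df_b = k - 1
    df_w = N - k
    if ss_within == 0.0 and ss_between == 0.0:
        raise ValueError("degenerate data: zero variance everywhere")
    mse = ss_within / df_w
    if mse == 0.0:
        F = math.inf
        p = 0.0
    else:
        F = (ss_between / df_b) / mse
        p = float(sps.f.sf(F, df_b, df_w))
    return ANOVAResult(
        F=float(F),
        df_between=df_b,
        df_within=df_w,
        p=p,
        mse=mse,
        group_labels=tuple(str(i) for i in range(k)),
        group_means=tuple(means),
        group_ns=tuple(int(n) for n in ns),
    )


def bonferroni_posthoc(
    groups: Sequence[np.ndarray],
    anova: ANOVAResult,
    labels: Optional[Sequence[str]] = None,
) -> list[PairwiseResult]:
    """All pairwise pooled-MSE t tests with Bonferroni adjustment.

    t = (m_i − m_j) / sqrt(MSE·(1/n_i + 1/n_j)) on ``df_within`` degrees
    of freedom; adjusted p = min(1, m·p) with m = k(k−1)/2.
    """
    gs = _validate_groups(groups)
    k = len(gs)
    labels = list(labels) if labels is not None else [str(i) for i in range(k)]
    if len(labels) != k:
        raise ValueError("labels must match the number of groups")
    m = k * (k - 1) // 2
    results = []
    for i, j in itertools.combinations(range(k), 2):
        gi, gj = gs[i], gs[j]
        se = math.sqrt(anova.mse * (1.0 / gi.size + 1.0 / gj.size))
        if se == 0.0:
            t = math.inf if gi.mean() != gj.mean() else 0.0
        else:
            t = (gi.mean() - gj.mean()) / se
        p_raw = float(2.0 * sps.t.sf(abs(t), anova.df_within))
        results.append(
            PairwiseResult(
                pair=(labels[i], labels[j]),
                t=float(t),
                p_raw=p_raw,
                p_adj=min(1.0, m * p_raw),
            )
        )
    anova.posthoc = results
    anova.group_labels = tuple(labels)
    return results


def anova_from_summary(
    means: Sequence[float],
    sems: Sequence[float],
    ns: Sequence[int],
) -> ANOVAResult:
    """One-way ANOVA reconstructed from printed mean ± SEM and n.

    Group variance is recovered as ``n·sem²``; the pooled MSE and the
    between-group sum of squares then give F without the raw data.  For
    balanced raw data this reproduces :func:`one_way_anova` exactly.
    """
    means = np.asarray(means, dtype=float)
    sems = np.asarray(sems, dtype=float)
    ns = np.asarray(ns, dtype=int)
    k = means.size
    if k < 2:
        raise ValueError("need at least two groups")
    if not (sems.size == k and ns.size == k):
        raise ValueError("means, sems and ns must have equal length")
    if np.any(ns < 2):
        raise ValueError("each group needs n ≥ 2")
    if np.any(sems <= 0):
        raise ValueError("sems must be positive")
    variances = ns * sems ** 2
    N = int(ns.sum())
    df_b = k - 1
    df_w = N - k
    grand = float(np.sum(ns * means) / N)
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(np.sum((ns - 1) * variances))
    mse = ss_within / df_w
    if mse == 0.0:
        F = 0.0 if ss_between == 0.0 else math.inf
        p = 1.0 if ss_between == 0.0 else 0.0
    else:
        F = (ss_between / df_b) / mse
        p = float(sps.f.sf(F, df_b, df_w))
    return ANOVAResult(
        F=float(F),
        df_between=df_b,
        df_within=df_w,
        p=p,
        mse=mse,
        group_labels=tuple(str(i) for i in range(k)),
        group_means=tuple(means),
        group_ns=tuple(int(n) for n in ns),
    )


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation with average ranks for ties.

    p-value uses the t approximation.  Constant input makes the
    correlation undefined: the result carries NaNs and the
    ``undefined`` flag instead of raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least three observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(float("nan"), float("nan"), undefined=True)
    rho, p = sps.spearmanr(x, y)
    return CorrelationResult(float(rho), float(p), undefined=False)


def anova_table(
    table: pd.DataFrame,
    *,
    value_col: str = "value",
    group_col: str = "condition",
    strata: Sequence[str] = ("region", "parameter"),
    min_n: int = 2,
) -> pd.DataFrame:
    """Per-stratum ANOVA + Bonferroni post hoc over a long-format table.

    Returns one row per stratum with F, dfs, p, and one column triple
    (t, p_raw, p_adj) per group pair.  Strata lacking ≥ 2 groups with
    ≥ ``min_n`` values are skipped.
    """
    strata = list(strata)
    rows = []
    for key, sub in table.groupby(strata, sort=True):
        groups = []
        labels = []
        for glabel, gsub in sub.groupby(group_col, sort=True):
            vals = gsub[value_col].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            if vals.size >= min_n:
                groups.append(vals)
                labels.append(str(glabel))
        if len(groups) < 2:
            continue
        res = one_way_anova(groups)
        pw = bonferroni_posthoc(groups, res, labels)
        row = dict(zip(strata, key if isinstance(key, tuple) else (key,)))
        row.update(
            F=res.F, df_between=res.df_between, df_within=res.df_within,
            p=res.p, mse=res.mse,
        )
        for r in pw:
            tag = f"{r.pair[0]}_vs_{r.pair[1]}"
            row[f"t_{tag}"] = r.t
            row[f"p_raw_{tag}"] = r.p_raw
            row[f"p_adj_{tag}"] = r.p_adj
        rows.append(row)
    return pd.DataFrame(rows)
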
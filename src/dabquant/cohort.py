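"""Two-group cohort comparison of H-scores by TNM staging criteria.

Samples are partitioned by a grouping rule — the headline dichotomy is
Breslow thickness, thin = {T1, T2} (at or below 2.0 mm) versus thick =
{T3, T4} (above 2.0 mm) — then compared by group mean and SEM, fold
change, and a two-tailed unpaired t-test with significance at p <= alpha.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .scoring import SampleRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GroupingRule:
    """Maps a sample to at most one group label (None = unassigned).

    ``labels`` fixes the group order; the first label is the reference
    group for fold-change reporting.
    """

    name: str
    labels: tuple[str, str]
    assign: Callable[[SampleRecord], str | None]


def rule_from_stage_map(name: str, groups: dict[str, Sequence[str]]) -> GroupingRule:
    """Build a grouping rule from a {label: [T stages]} mapping.

    Example: ``{"thin": ["T1", "T2"], "thick": ["T3", "T4"]}``.
    """
    if len(groups) != 2:
        raise ValueError(f"a comparison needs exactly two groups, got {len(groups)}")
    stage_to_label: dict[str, str] = {}
    for label, stages in groups.items():
        for s in stages:
            if s in stage_to_label:
                raise ValueError(f"stage {s!r} mapped to more than one group")
            stage_to_label[s] = label

    def assign(record: SampleRecord) -> str | None:
        return stage_to_label.get(record.t_stage)

    return GroupingRule(name=name, labels=tuple(groups.keys()), assign=assign)


#: Breslow-thickness dichotomy: T1+T2 (<= 2.0 mm) vs T3+T4 (> 2.0 mm).
THICKNESS_RULE = rule_from_stage_map(
    "thickness", {"thin": ["T1", "T2"], "thick": ["T3", "T4"]}
)


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    mean_h: float
    sem_h: float


@dataclass(frozen=True)
class GroupComparison:
    """Two-group comparison: summaries, fold change, t-test, significance."""

    rule_name: str
    group_a: GroupSummary
    group_b: GroupSummary
    fold_change: float
    direction: str
    t_statistic: float
    df: float
    p_value: float
    alpha: float
    significant: bool
    variant: str = "student"


def assign_groups(
    records: Sequence[SampleRecord], rule: GroupingRule
) -> dict[str, list[SampleRecord]]:
    """Partition records by the rule; unassigned records are logged and dropped.

    Raises ``ValueError`` if any group ends up with fewer than 2 samples,
    since such a group cannot enter a t-test.
    """
    if len(records) == 0:
        raise ValueError("no records to group")
    partition: dict[str, list[SampleRecord]] = {lab: [] for lab in rule.labels}
    unassigned = 0
    for rec in records:
        label = rule.assign(rec)
        if label is None:
            unassigned += 1
            continue
        if label not in partition:
            raise ValueError(f"rule produced unknown label {label!r}")
        partition[label].append(rec)
    if unassigned:
        logger.info(
            "grouping rule %r left %d record(s) unassigned", rule.name, unassigned
        )
    for label, group in partition.items():
        if len(group) < 2:
            raise ValueError(
                f"group {label!r} has n={len(group)} < 2; comparison refused"
            )
    return partition


def mean_sem(values: Sequence[float]) -> tuple[float, float]:
    """Arithmetic mean and standard error (sample sd / sqrt(n)); needs n >= 2."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError(f"mean_sem needs at least 2 values, got {arr.size}")
    return float(arr.mean()), float(arr.std(ddof=1) / math.sqrt(arr.size))


def unpaired_t_test(
    a: Sequence[float], b: Sequence[float], variant: str = "student"
) -> tuple[float, float, float]:
    """Two-tailed unpaired t-test; returns (t, df, p).

    ``student`` pools the variances (df = n_a + n_b - 2); ``welch`` uses
    the Satterthwaite degrees of freedom.  Degenerate zero-variance inputs
    follow a documented convention: equal constant groups give p = 1,
    unequal means with zero pooled variance give p = 0, both with a warning.
    """
    xa = np.asarray(a, dtype=float)
    xb = np.asarray(b, dtype=float)
    if xa.size < 2 or xb.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")

    na, nb = xa.size, xb.size
    ma, mb = xa.mean(), xb.mean()
    va, vb = xa.var(ddof=1), xb.var(ddof=1)

    if va == 0.0 and vb == 0.0:
        df = float(na + nb - 2)
        if ma == mb:
            warnings.warn("both groups constant and equal; returning t=0, p=1")
            return 0.0, df, 1.0
        warnings.warn(
            "zero variance in both groups with unequal means; returning p=0"
        )
        return math.copysign(math.inf, ma - mb), df, 0.0

    if variant == "student":
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se = math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        df = float(na + nb - 2)
    else:
        se = math.sqrt(va / na + vb / nb)
        df = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
    t = float((ma - mb) / se)
    p = float(2.0 * stats.t.sf(abs(t), df))
    return t, float(df), p


def fold_change(mean_a: float, mean_b: float) -> float:
    """Ratio of the reference group mean to the comparison group mean.

    With the thin group as reference, a ratio above 1 reads as an
    "x-fold decrease" in the thick group.  Both means must be positive.
    """
    if mean_a <= 0 or mean_b <= 0:
        raise ValueError(
            f"fold change undefined for nonpositive means ({mean_a}, {mean_b})"
        )
    return mean_a / mean_b


def compare_groups(
    records: Sequence[SampleRecord],
    rule: GroupingRule = THICKNESS_RULE,
    alpha: float = 0.05,
    variant: str = "student",
) -> GroupComparison:
    """Full two-group comparison of H-scores under a grouping rule.

    Composes group assignment, per-group mean/SEM, fold change with the
    first-listed group as reference, and the two-tailed unpaired t-test;
    ``significant`` uses p <= alpha.
    """
    partition = assign_groups(records, rule)
    label_a, label_b = rule.labels
    ha = [r.h_score for r in partition[label_a]]
    hb = [r.h_score for r in partition[label_b]]
    mean_a, sem_a = mean_sem(ha)
    mean_b, sem_b = mean_sem(hb)
    fc = fold_change(mean_a, mean_b)
    if mean_a == mean_b:
        direction = "no change"
    elif mean_a > mean_b:
        direction = f"decrease in {label_b}"
    else:
        direction = f"increase in {label_b}"
    t, df, p = unpaired_t_test(ha, hb, variant=variant)
    return GroupComparison(
        rule_name=rule.name,
        group_a=GroupSummary(label=label_a, n=len(ha), mean_h=mean_a, sem_h=sem_a),
        group_b=GroupSummary(label=label_b, n=len(hb), mean_h=mean_b, sem_h=sem_b),
        fold_change=fc,
        direction=direction,
        t_statistic=t,
        df=df,
        p_value=p,
        alpha=alpha,
        significant=p <= alpha,
        variant=variant,
    )


_REPORT_COLUMNS = [
    "rule",
    "group_a",
    "n_a",
    "mean_h_a",
    "sem_h_a",
    "group_b",
    "n_b",
    "mean_h_b",
    "sem_h_b",
    "fold_change",
    "direction",
    "variant",
    "t_statistic",
    "df",
    "p_value",
    "alpha",
    "significant",
    "p_bonferroni",
]


def cohort_report(
    comparisons: Sequence[GroupComparison], out_dir: str | Path
) -> tuple[Path, Path]:
    """Write a comparison CSV and a mean-with-SEM bar chart.

    When several comparisons are reported together, a Bonferroni-adjusted
    p-value column is emitted alongside the unadjusted one for
    transparency; single planned comparisons carry no adjustment penalty.
    Returns (csv_path, chart_path).
    """
    import pandas as pd

    if len(comparisons) == 0:
        raise ValueError("nothing to report")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    k = len(comparisons)
    rows = []
    for c in comparisons:
        rows.append(
            {
                "rule": c.rule_name,
                "group_a": c.group_a.label,
                "n_a": c.group_a.n,
                "mean_h_a": c.group_a.mean_h,
                "sem_h_a": c.group_a.sem_h,
                "group_b": c.group_b.label,
                "n_b": c.group_b.n,
                "mean_h_b": c.group_b.mean_h,
                "sem_h_b": c.group_b.sem_h,
                "fold_change": c.fold_change,
                "direction": c.direction,
                "variant": c.variant,
                "t_statistic": c.t_statistic,
                "df": c.df,
                "p_value": c.p_value,
                "alpha": c.alpha,
                "significant": c.significant,
                "p_bonferroni": min(1.0, c.p_value * k),
            }
        )
    csv_path = out / "comparisons.csv"
    pd.DataFrame(rows, columns=_REPORT_COLUMNS).to_csv(csv_path, index=False)

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(
        1, k, figsize=(3.2 * k, 3.6), squeeze=False, constrained_layout=True
    )
    for ax, c in zip(axes[0], comparisons):
        labels = [c.group_a.label, c.group_b.label]
        means = [c.group_a.mean_h, c.group_b.mean_h]
        sems = [c.group_a.sem_h, c.group_b.sem_h]
        ax.bar(labels, means, yerr=sems, capsize=4, color=["#4472c4", "#c45244"])
        ax.set_ylabel("mean H-score")
        ax.set_title(f"{c.rule_name} (p = {c.p_value:.3g})")
        ax.set_ylim(bottom=0)
    chart_path = out / "mean_h_scores.png"
    fig.savefig(chart_path, dpi=150)
    plt.close(fig)
    return csv_path, chart_path
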
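"""Group statistics: one-way ANOVA, Tukey-Kramer pairwise tests, curve
areas, and the module-level significance report.

Each metric (graph metrics, critical couplings, synchrony-curve areas,
lesioned efficiencies) is compared across architecture modules with a
one-way ANOVA using module assignment as the categorical factor, followed
by Tukey-Kramer multiple-comparison correction (studentized range, valid
for unequal group sizes).  Modules are then grouped into *pairing classes*:
the transitive closure of pairs that do not significantly differ at alpha,
reproducing the "same color = indistinguishable" summary tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd


@dataclass(frozen=True)
class GroupComparison:
    metric_name: str
    groups: tuple
    F: float
    p: float
    pairwise: dict = field(repr=False)  # frozenset({a, b}) -> adjusted p
    pairing_classes: tuple = ()
    alpha: float = 0.05

    def pair_p(self, a, b) -> float:
        return self.pairwise[frozenset((a, b))]


def one_way_anova(samples: dict):
    """Between/within mean-square F statistic and p-value.

    ``samples`` maps group label -> list of values; every group needs at
    least two values.
    """
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    arrays = []
    for label, vals in samples.items():
        v = np.asarray(vals, dtype=float)
        if v.size < 2:
            raise ValueError(f"group {label!r} has fewer than 2 values")
        arrays.append(v)
    F, p = sps.f_oneway(*arrays)
    if np.isnan(F):  # all values identical in every group
        F, p = 0.0, 1.0
    return float(F), float(p)


def _pairing_classes(groups, pairwise, alpha):
    """Transitive closure of non-significant pairs (union-find)."""
    parent = {g: g for g in groups}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in combinations(groups, 2):
        if pairwise[frozenset((a, b))] >= alpha:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
    classes = {}
    for g in groups:
        classes.setdefault(find(g), []).append(g)
    return tuple(tuple(sorted(c)) for c in sorted(classes.values()))


def tukey_kramer(samples: dict, alpha: float = 0.05):
    """Tukey-Kramer pairwise adjusted p-values and pairing classes.

    Returns ``(pairwise, pairing_classes)`` where ``pairwise`` maps
    ``frozenset({a, b})`` to the adjusted p-value.
    """
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    values, labels = [], []
    for label, vals in samples.items():
        v = np.asarray(vals, dtype=float)
        if v.size < 2:
            raise ValueError(f"group {label!r} has fewer than 2 values")
        values.append(v)
        labels.extend([str(label)] * v.size)
    data = np.concatenate(values)
    if np.allclose(data.std(), 0):
        # identical constant groups: nothing to distinguish
        pairwise = {
            frozenset((a, b)): 1.0 for a, b in combinations(samples, 2)
        }
    else:
        res = pairwise_tukeyhsd(data, labels, alpha=alpha)
        names = [str(g) for g in res.groupsunique]
        pairwise = {}
        for (i, j), p in zip(combinations(range(len(names)), 2),
                             res.pvalues):
            key_names = frozenset((names[i], names[j]))
            # map back to original (possibly non-string) labels
            orig = frozenset(g for g in samples if str(g) in key_names)
            pairwise[orig] = float(p)
    groups = tuple(samples)
    return pairwise, _pairing_classes(groups, pairwise, alpha)


def compare_groups(
    samples: dict, metric_name: str = "", alpha: float = 0.05
) -> GroupComparison:
    """ANOVA + Tukey-Kramer + pairing classes in one record."""
    F, p = one_way_anova(samples)
    pairwise, classes = tukey_kramer(samples, alpha=alpha)
    return GroupComparison(
        metric_name=metric_name,
        groups=tuple(samples),
        F=F,
        p=p,
        pairwise=pairwise,
        pairing_classes=classes,
        alpha=alpha,
    )


def curve_auc(x, y) -> float:
    """Trapezoidal area under y(x); x must be strictly ascending."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or x.size != y.size:
        raise ValueError("need >= 2 matching (x, y) points")
    if np.any(np.diff(x) <= 0):
        raise ValueError("x must be strictly ascending")
    return float(np.trapezoid(y, x))


def normality_screen(values) -> float:
    """R^2 of sorted values against normal quantiles (logged, not
    enforced — a quantile-quantile linearity summary)."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size < 3 or v.std() == 0:
        return float("nan")
    q = sps.norm.ppf((np.arange(1, v.size + 1) - 0.5) / v.size)
    r = np.corrcoef(q, v)[0, 1]
    return float(r**2)


def _group_label(row) -> str:
    return f"{row['sex'][:1].upper()}{int(row['module']) + 1}"


def module_report(
    partition_df: pd.DataFrame,
    metrics_df: pd.DataFrame = None,
    sweep_summary_df: pd.DataFrame = None,
    lesion_metrics_df: pd.DataFrame = None,
    alpha: float = 0.05,
):
    """Per-metric group comparisons across sex-module groups.

    ``partition_df`` needs columns subject_id, sex, module; the other
    tables are keyed by subject_id (lesion metrics additionally by level).
    Returns ``{metric_name: GroupComparison}``; single-group inputs yield
    no pairwise tests but a valid (empty-pairwise) record.
    """
    part = partition_df.copy()
    part["group"] = part.apply(_group_label, axis=1)
    key = part.set_index("subject_id")["group"]

    def split(df, col):
        missing = sorted(set(df["subject_id"]) - set(key.index))
        if missing:
            raise ValueError(f"subjects missing from partition: {missing}")
        g = df.assign(group=df["subject_id"].map(key))
        return {
            label: sub[col].to_numpy() for label, sub in g.groupby("group")
        }

    report = {}

    def add(name, samples):
        if len(samples) < 2:
            report[name] = GroupComparison(
                name, tuple(samples), 0.0, 1.0, {},
                tuple((g,) for g in samples), alpha,
            )
        else:
            cmp_ = compare_groups(samples, metric_name=name, alpha=alpha)
            report[name] = cmp_

    if metrics_df is not None:
        for col in ("GE", "MSPL", "mean_BC", "mean_CC"):
            if col in metrics_df:
                add(col, split(metrics_df, col))
    if sweep_summary_df is not None:
        for col in ("Kcrit_syn", "Kcrit_mts", "auc_synchrony"):
            if col in sweep_summary_df:
                add(col, split(sweep_summary_df, col))
    if lesion_metrics_df is not None:
        for level, sub in lesion_metrics_df.groupby("level"):
            add(f"GE_level_{level:g}", split(sub, "GE"))
    return report


def report_table(report: dict) -> pd.DataFrame:
    """Flat summary of a module_report result."""
    rows = []
    for name, cmp_ in report.items():
        rows.append(
            {
                "metric": name,
                "F": cmp_.F,
                "p": cmp_.p,
                "pairing_classes": " | ".join(
                    "+".join(c) for c in cmp_.pairing_classes
                ),
            }
        )
    return pd.DataFrame(rows)
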
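"""Group comparison and composition reporting.

One-tailed Welch t-tests with the star annotation used throughout the
figures (* p<0.1, ** p<0.01, *** p<0.001, strict inequalities),
time-course / cluster composition tables, and marker-based high/low
cluster composition (e.g. CD51/CD61/CD106 triple-negative fractions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from emplex.errors import ValidationError
from emplex.io import CountMatrix

__all__ = [
    "GroupComparison",
    "one_tailed_ttest",
    "stars_for_p",
    "fraction_table",
    "marker_composition",
    "trajectory_comparisons",
]

_STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.1, "*"))


def stars_for_p(p: float) -> str:
    """Map a p-value to its star annotation (strict thresholds: a p equal
    to a threshold takes the weaker label)."""
    for cut, label in _STAR_THRESHOLDS:
        if p < cut:
            return label
    return "ns"


@dataclass(frozen=True)
class GroupComparison:
    statistic: float
    pvalue: float
    direction: str  # which group is hypothesized larger
    stars: str


def one_tailed_ttest(a, b, alternative: str = "b_greater") -> GroupComparison:
    """Welch two-sample t-test with a one-sided alternative.

    ``alternative="b_greater"`` tests H1: mean(b) > mean(a);
    ``"a_greater"`` the reverse. Stars follow the strict thresholds
    0.1 / 0.01 / 0.001.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("both samples need >= 2 observations")
    if alternative not in {"b_greater", "a_greater"}:
        raise ValidationError("alternative must be 'b_greater' or 'a_greater'")
    side = "less" if alternative == "b_greater" else "greater"
    res = sps.ttest_ind(a, b, equal_var=False, alternative=side)
    return GroupComparison(
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        direction=alternative,
        stars=stars_for_p(float(res.pvalue)),
    )


def fraction_table(labels, grouping) -> pd.DataFrame:
    """Fraction of each category within each group (rows sum to 1).

    ``labels`` are the per-cell categories (e.g. E/I1/I2/M state calls),
    ``grouping`` the per-cell groups (e.g. time points). Empty groups
    are dropped with a warning.
    """
    labels = np.asarray(labels)
    grouping = np.asarray(grouping)
    if labels.shape[0] != grouping.shape[0]:
        raise ValidationError("labels and grouping must align")
    cats = sorted(set(labels.tolist()))
    rows = {}
    for g in sorted(set(grouping.tolist())):
        mask = grouping == g
        n = int(mask.sum())
        if n == 0:
            warnings.warn(f"group {g!r} is empty; dropping its row")
            continue
        rows[g] = {c: float((labels[mask] == c).sum()) / n for c in cats}
    return pd.DataFrame.from_dict(rows, orient="index")[cats]


def marker_composition(
    raw: CountMatrix,
    labels,
    markers: list[str],
    thresholds: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-cluster composition over high/low marker combinations.

    Each cell is called high on a marker when its raw count exceeds the
    marker's threshold (default 0, i.e. any expression); cells are
    binned by the ``2^m`` high/low combination, labelled like
    ``CD51+CD61-CD106-`` with ``TN`` (all low) and ``TP`` (all high)
    aliases. Rows (clusters) sum to 1.
    """
    labels = np.asarray(labels)
    gene_index = {g: i for i, g in enumerate(raw.gene_names)}
    missing = [m for m in markers if m not in gene_index]
    if missing:
        raise ValidationError(f"marker genes absent from matrix: {missing}")
    thresholds = thresholds or {}
    high = np.stack(
        [
            raw.values[gene_index[m], :] > thresholds.get(m, 0)
            for m in markers
        ]
    )  # marker x cell

    def bin_name(pattern: tuple[bool, ...]) -> str:
        if not any(pattern):
            return "TN"
        if all(pattern):
            return "TP"
        return "".join(
            f"{m}{'+' if h else '-'}" for m, h in zip(markers, pattern)
        )

    cell_bins = np.array(
        [bin_name(tuple(high[:, c])) for c in range(raw.n_cells)]
    )
    return fraction_table(cell_bins, labels)


def trajectory_comparisons(
    values,
    labels,
    cluster_order: list,
    mode: str = "consecutive",
    alternative: str = "b_greater",
) -> pd.DataFrame:
    """One-tailed t-tests along a trajectory.

    Compares per-cell ``values`` (e.g. EMT circuit energy) between
    clusters, either for consecutive pairs along ``cluster_order`` or
    for all pairs; the default alternative tests whether the later
    cluster is larger, matching the reported energy increases.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if mode == "consecutive":
        pairs = [
            (cluster_order[i], cluster_order[i + 1])
            for i in range(len(cluster_order) - 1)
        ]
    elif mode == "all":
        pairs = [
            (cluster_order[i], cluster_order[j])
            for i in range(len(cluster_order))
            for j in range(i + 1, len(cluster_order))
        ]
    else:
        raise ValidationError("mode must be 'consecutive' or 'all'")
    rows = []
    for a, b in pairs:
        cmp = one_tailed_ttest(
            values[labels == a], values[labels == b], alternative=alternative
        )
        rows.append(
            {
                "earlier": a,
                "later": b,
                "statistic": cmp.statistic,
                "pvalue": cmp.pvalue,
                "stars": cmp.stars,
            }
        )
    return pd.DataFrame(rows)
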
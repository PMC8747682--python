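"""Mutation-expression association.

Joins per-gene mutation classes with expression values and compares
groups with the two-sided Wilcoxon-Mann-Whitney test (expression is not
assumed normal; the statistic is invariant under any strictly increasing
transform).  Two-way: mutated vs non-mutated.  Three-way: pairwise
comparisons among mutated-with-Sn, mutated-without-Sn and non-mutated
genes, Holm-adjusted across the three tests.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .effects import MUTATED_NO_SN, MUTATED_SN, NON_MUTATED


@dataclasses.dataclass
class GroupComparison:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    statistic: float  # Mann-Whitney U for group a
    p_value: float
    effect_size: float  # rank-biserial, positive when a > b
    direction: str  # "a>b" | "a<b" | "a=b"
    p_adjusted: float | None = None


def gene_means(expression: pd.DataFrame) -> pd.Series:
    """Per-gene mean across samples (columns gene_id, sample, value)."""
    if (expression["value"] < 0).any():
        raise ValueError("expression values must be non-negative")
    if expression.duplicated(subset=["gene_id", "sample"]).any():
        raise ValueError("(gene, sample) pairs must be unique")
    return expression.groupby("gene_id")["value"].mean()


def _compare(name_a: str, name_b: str, a: np.ndarray, b: np.ndarray) -> GroupComparison:
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    u = float(res.statistic)
    r = 2.0 * u / (len(a) * len(b)) - 1.0  # rank-biserial
    med_a, med_b = float(np.median(a)), float(np.median(b))
    direction = "a>b" if med_a > med_b else ("a<b" if med_a < med_b else "a=b")
    return GroupComparison(
        group_a=name_a, group_b=name_b, n_a=len(a), n_b=len(b),
        median_a=med_a, median_b=med_b, statistic=u,
        p_value=float(res.pvalue), effect_size=r, direction=direction,
    )


def compare_groups(
    expression: pd.DataFrame,
    gene_classes: pd.DataFrame,
    grouping: str = "two-way",
) -> list[GroupComparison]:
    """Compare expression between mutation classes.

    *gene_classes* is the per-gene summary (columns gene_id,
    gene_class).  Genes lacking expression data are dropped with a
    logged count; an empty group makes its comparison a warning-level
    skip, not an error.
    """
    means = gene_means(expression)
    classes = gene_classes.set_index("gene_id")["gene_class"]
    joined = pd.DataFrame({"value": means}).join(classes, how="inner")
    dropped = len(classes) - len(joined)
    if dropped:
        warnings.warn(f"{dropped} genes lack expression data and were dropped")

    def values(*names: str) -> np.ndarray:
        return joined.loc[joined["gene_class"].isin(names), "value"].to_numpy()

    if grouping == "two-way":
        pairs = [("mutated", "non-mutated", values(MUTATED_SN, MUTATED_NO_SN), values(NON_MUTATED))]
    elif grouping == "three-way":
        pairs = [
            (MUTATED_SN, MUTATED_NO_SN, values(MUTATED_SN), values(MUTATED_NO_SN)),
            (MUTATED_SN, NON_MUTATED, values(MUTATED_SN), values(NON_MUTATED)),
            (MUTATED_NO_SN, NON_MUTATED, values(MUTATED_NO_SN), values(NON_MUTATED)),
        ]
    else:
        raise ValueError(f"unknown grouping {grouping!r}")

    comparisons = []
    for name_a, name_b, a, b in pairs:
        if len(a) == 0 or len(b) == 0:
            warnings.warn(
                f"comparison {name_a} vs {name_b} skipped: empty group "
                f"(n_a={len(a)}, n_b={len(b)})"
            )
            continue
        comparisons.append(_compare(name_a, name_b, a, b))
    if len(comparisons) > 1:
        _, adjusted, _, _ = multipletests(
            [c.p_value for c in comparisons], method="holm"
        )
        for c, p in zip(comparisons, adjusted):
            c.p_adjusted = float(p)
    elif comparisons:
        comparisons[0].p_adjusted = comparisons[0].p_value
    return comparisons


def comparisons_frame(comparisons: list[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(c) for c in comparisons])


def expression_track(
    expression: pd.DataFrame,
    gene_positions: pd.DataFrame,
    chromosome_lengths: dict[str, int],
    window_bp: int,
) -> dict[str, np.ndarray]:
    """Per-window mean expression over genes whose midpoint is in the window.

    *gene_positions* needs columns gene_id, chrom, start, end.  Windows
    without genes are NaN (absent), never zero.
    """
    means = gene_means(expression)
    midpoints = gene_positions.assign(
        mid=(gene_positions["start"] + gene_positions["end"]) // 2
    ).set_index("gene_id")
    out = {}
    for chrom, length in chromosome_lengths.items():
        n_windows = max(1, -(-length // window_bp))
        sums = np.zeros(n_windows)
        counts = np.zeros(n_windows)
        sub = midpoints[midpoints["chrom"] == chrom]
        for gene_id, row in sub.iterrows():
            if gene_id not in means.index:
                continue
            w = int((row["mid"] - 1) // window_bp)
            sums[w] += means[gene_id]
            counts[w] += 1
        with np.errstate(invalid="ignore"):
            out[chrom] = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return out
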
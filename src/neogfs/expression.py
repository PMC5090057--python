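"""Developmental expression contrast around full cortical maturation.

Human cortical thickness peaks at about 13 years of age; the contrast splits
cortical samples into a "before" window (age <= 13 years, prenatal ages
negative) and an "after" window, averages each gene across the samples of each
window after per-sample total-expression normalization, and compares the
paired per-gene window means with a Wilcoxon signed-rank test (one-tailed
"greater" = higher expression before maturation by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

from .data_io import ExpressionDataset

MATURATION_AGE_YEARS = 13.0
EXACT_WILCOXON_MAX_N = 25


@dataclass(frozen=True)
class WindowSummary:
    """Per-gene mean normalized expression in each developmental window."""

    gene_id: str
    mean_before: float
    mean_after: float
    n_samples_before: int
    n_samples_after: int


def normalize_samples(data: ExpressionDataset) -> ExpressionDataset:
    """Divide each sample's column by its total expression (columns sum to 1)."""
    totals = data.values.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total expression: {list(zero.index)[:5]}")
    return ExpressionDataset(data.values / totals, data.meta.copy())


def window_means(data: ExpressionDataset,
                 cutoff_years: float = MATURATION_AGE_YEARS,
                 gene_subset: Iterable[str] | None = None,
                 cell_means: bool = False) -> list[WindowSummary]:
    """Per-gene mean expression before (age <= cutoff) and after the cutoff.

    ``cell_means=True`` first averages within each (age, region) cell and then
    across cells, weighting developmental stages equally instead of samples.
    """
    ages = data.meta["age_years"].to_numpy(dtype=float)
    before = ages <= cutoff_years
    if not before.any() or before.all():
        raise ValueError("both developmental windows must contain samples")
    values = data.values
    if gene_subset is not None:
        wanted = [g for g in values.index if g in set(gene_subset)]
        if not wanted:
            raise ValueError("gene subset matches no genes in the matrix")
        values = values.loc[wanted]
    if cell_means:
        cells = values.T.groupby(
            [data.meta["age_years"].to_numpy(), data.meta["region"].to_numpy()]
        ).mean().T
        cell_before = np.array([age <= cutoff_years for age, _ in cells.columns])
        mb = cells.loc[:, cell_before].mean(axis=1)
        ma = cells.loc[:, ~cell_before].mean(axis=1)
    else:
        mb = values.loc[:, before].mean(axis=1)
        ma = values.loc[:, ~before].mean(axis=1)
    nb, na = int(before.sum()), int((~before).sum())
    return [
        WindowSummary(g, float(mb[g]), float(ma[g]), nb, na)
        for g in values.index
    ]


def paired_wilcoxon(summaries: Sequence[WindowSummary],
                    alternative: Literal["greater", "two_sided"] = "greater",
                    ) -> tuple[float, float]:
    """Wilcoxon signed-rank test of the per-gene (before - after) differences.

    Zero differences are dropped; the exact null distribution is used up to
    25 non-zero pairs and the normal approximation with continuity correction
    above that. ``greater`` tests for higher expression before maturation.
    """
    if alternative not in ("greater", "two_sided"):
        raise ValueError("alternative must be 'greater' or 'two_sided'")
    diffs = np.array([s.mean_before - s.mean_after for s in summaries])
    diffs = diffs[diffs != 0]
    if len(diffs) == 0:
        raise ValueError("all before/after differences are zero")
    if len(diffs) < 6:
        raise ValueError("need at least 6 genes with a non-zero difference")
    method = "exact" if len(diffs) <= EXACT_WILCOXON_MAX_N else "approx"
    res = stats.wilcoxon(
        diffs,
        alternative=alternative.replace("_", "-"),
        method=method,
        correction=(method == "approx"),
    )
    return float(res.statistic), float(res.pvalue)
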
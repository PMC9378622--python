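"""Cell-type specificity statistics for GPCR expression screening.

Given a gene × sample expression matrix with biological replicate groups
(e.g. retinal cell types in triplicate), the analysis

1. averages replicates into a gene × cell-group *mean data* matrix,
2. splits the cell groups into a selected combination (*sc*, e.g. microglia)
   and a disjoint non-selected combination (*n-sc*),
3. scores each gene with the specificity ratio
   ``sr = min(sc row) / max(n-sc row)`` — ``sr > 1`` holds exactly when the
   gene's lowest selected-group mean still exceeds its highest
   non-selected-group mean (exclusive enrichment),
4. attaches a Wilcoxon rank-sum p-value per gene (exact permutation null for
   small group sizes, tie-corrected normal approximation otherwise), and
5. normalises each gene row to its maximum for heatmap display.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, ValidationError

#: Combined sample size up to which the exact permutation p-value is used.
EXACT_N_MAX = 12


def compute_mean_data(
    expr: pd.DataFrame, grouping: dict[str, str]
) -> pd.DataFrame:
    """Average replicate columns into one column per biological group.

    ``expr`` is genes × samples; ``grouping`` maps every sample (column) to
    its group name.  Group column order follows first appearance in ``expr``.
    """
    unmapped = [c for c in expr.columns if c not in grouping]
    if unmapped:
        raise ConfigError(f"samples without group assignment: {unmapped}")
    if expr.isna().any().any():
        raise ValidationError("expression matrix contains missing values")
    if (expr.values < 0).any():
        raise ValidationError("expression values must be non-negative")
    order: list[str] = []
    for c in expr.columns:
        g = grouping[c]
        if g not in order:
            order.append(g)
    mean = expr.T.groupby([grouping[c] for c in expr.columns]).mean().T
    return mean[order]


def specificity_ratio(sc_row, nsc_row) -> float:
    """min(sc) / max(n-sc); infinite (flagged undefined) when max(n-sc) = 0."""
    sc = np.asarray(sc_row, dtype=float)
    nsc = np.asarray(nsc_row, dtype=float)
    if sc.size == 0 or nsc.size == 0:
        raise ValidationError("sc and n-sc rows must be non-empty")
    hi = nsc.max()
    lo = sc.min()
    if hi == 0.0:
        return math.inf if lo > 0 else math.nan
    return float(lo / hi)


def _midranks(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, method="average")


def rank_sum_p(sc_row, nsc_row, alternative: str = "two-sided") -> float:
    """Wilcoxon rank-sum p-value for one gene's sc vs n-sc values.

    Exact enumeration of all rank assignments for combined n ≤ 12 (group
    sizes here are triplicate-scale); tie-corrected normal approximation
    above.  ``alternative`` is ``two-sided`` or ``greater`` (sc enriched).
    Deterministic; all-tied input gives p = 1.
    """
    if alternative not in ("two-sided", "greater"):
        raise ConfigError(f"alternative must be 'two-sided' or 'greater'")
    x = np.asarray(sc_row, dtype=float)
    y = np.asarray(nsc_row, dtype=float)
    n1, n2 = x.size, y.size
    n = n1 + n2
    if n < 2 or n1 == 0 or n2 == 0:
        raise ValidationError("rank-sum test needs both rows non-empty")

    if n <= EXACT_N_MAX:
        ranks = _midranks(np.concatenate([x, y]))
        w_obs = ranks[:n1].sum()
        mu = n1 * (n + 1) / 2.0
        total = 0
        hits = 0
        for combo in itertools.combinations(range(n), n1):
            w = ranks[list(combo)].sum()
            total += 1
            if alternative == "greater":
                hits += w >= w_obs - 1e-12
            else:
                hits += abs(w - mu) >= abs(w_obs - mu) - 1e-12
        return hits / total

    res = stats.mannwhitneyu(x, y, alternative=alternative, method="asymptotic")
    return float(res.pvalue)


def heatmap_normalize(mean_data: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Divide each gene row by its maximum; all-zero rows stay zero, flagged."""
    values = mean_data.to_numpy(dtype=float)
    row_max = values.max(axis=1)
    zero_rows = row_max == 0
    safe = np.where(zero_rows, 1.0, row_max)
    normalized = pd.DataFrame(
        values / safe[:, None], index=mean_data.index, columns=mean_data.columns
    )
    flags = pd.Series(zero_rows, index=mean_data.index, name="all_zero")
    return normalized, flags


@dataclass
class SpecificityResult:
    """Per-gene sr, p and row-normalised expression for a chosen sc/n-sc."""

    table: pd.DataFrame  # columns: sr, p + one normalised column per group
    sc: list[str]
    nsc: list[str]


def specificity_table(
    mean_data: pd.DataFrame,
    sc: list[str],
    nsc: list[str],
    alternative: str = "two-sided",
) -> SpecificityResult:
    """Score every gene against a selected / non-selected group split."""
    if not sc or not nsc:
        raise ConfigError("sc and n-sc must both name at least one group")
    overlap = set(sc) & set(nsc)
    if overlap:
        raise ConfigError(f"sc and n-sc overlap: {sorted(overlap)}")
    for g in [*sc, *nsc]:
        if g not in mean_data.columns:
            raise ConfigError(f"group {g!r} not in mean data columns")

    sc_m = mean_data[sc].to_numpy(dtype=float)
    nsc_m = mean_data[nsc].to_numpy(dtype=float)
    sr = [specificity_ratio(a, b) for a, b in zip(sc_m, nsc_m)]
    p = [rank_sum_p(a, b, alternative) for a, b in zip(sc_m, nsc_m)]
    normalized, _flags = heatmap_normalize(mean_data)
    out = pd.DataFrame({"sr": sr, "p": p}, index=mean_data.index)
    out = pd.concat([out, normalized], axis=1)
    return SpecificityResult(table=out, sc=list(sc), nsc=list(nsc))
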
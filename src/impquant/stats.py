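"""Index reliability (Cronbach alpha) and one-way group comparisons.

Alpha is computed on the 0/50/100 scored item values (scoring precedes all
analysis), listwise-deleting rows with any missing item:

    alpha = k/(k-1) * (1 - sum(var_i) / var(total))

with sample variances (n−1). Alpha is at most 1 but can be negative; it is
undefined when the row totals have zero variance.

The one-way comparison is the standard between/within sum-of-squares
decomposition with F and p from the F distribution (scipy). Post hoc
procedures and variance-homogeneity gates are deliberately not provided; the
result carries per-group n/mean/SD so external tools can run them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ReliabilityResult",
    "GroupComparison",
    "ReliabilityError",
    "GroupingError",
    "cronbach_alpha",
    "oneway_anova",
]


class ReliabilityError(ValueError):
    """Alpha undefined (too few items/respondents or zero total variance)."""


class GroupingError(ValueError):
    """Comparison impossible (fewer than two groups, or too few observations)."""


@dataclass(frozen=True)
class ReliabilityResult:
    index_name: str
    n_items: int
    n_respondents: int
    alpha: float


@dataclass(frozen=True)
class GroupComparison:
    measure: str
    grouping: str
    groups: pd.DataFrame  # per-group n / mean / sd
    f_statistic: float
    p_value: float


def cronbach_alpha(items: pd.DataFrame, name: str = "") -> ReliabilityResult:
    """Cronbach alpha of an index from its respondent × item score matrix.

    Rows with any missing item are dropped (listwise deletion). Requires at
    least two items and two complete respondents.
    """
    complete = items.dropna()
    k = complete.shape[1]
    n = complete.shape[0]
    if k < 2:
        raise ReliabilityError(f"alpha needs >= 2 items, got {k}")
    if n < 2:
        raise ReliabilityError(f"alpha needs >= 2 complete respondents, got {n}")
    values = complete.to_numpy(dtype=float)
    item_var = values.var(axis=0, ddof=1)
    total_var = values.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ReliabilityError("alpha undefined: row totals have zero variance")
    alpha = k / (k - 1) * (1 - item_var.sum() / total_var)
    return ReliabilityResult(name or "index", k, n, float(alpha))


def oneway_anova(
    values: Sequence[float],
    groups: Sequence,
    measure: str = "",
    grouping: str = "",
) -> GroupComparison:
    """One-way ANOVA of ``values`` across ``groups`` (missing values dropped)."""
    df = pd.DataFrame({"value": values, "group": groups}).dropna()
    arrays = [g["value"].to_numpy(dtype=float) for _, g in df.groupby("group", sort=True)]
    if len(arrays) < 2:
        raise GroupingError(f"one-way comparison needs >= 2 groups, got {len(arrays)}")
    if any(len(a) < 1 for a in arrays) or sum(len(a) for a in arrays) < len(arrays) + 1:
        raise GroupingError("too few observations for a one-way comparison")
    summary = (
        df.groupby("group", sort=True)["value"]
        .agg(n="count", mean="mean", sd=lambda v: v.std(ddof=1))
        .reset_index()
    )
    f, p = sps.f_oneway(*arrays)
    # identical group means give an exactly zero between-group sum of squares
    if np.isnan(f) and all(len(a) > 0 for a in arrays):
        f, p = 0.0, 1.0
    return GroupComparison(measure or "value", grouping or "group", summary, float(f), float(p))
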
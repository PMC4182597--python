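"""Threshold sensitivity of the risk re-categorization.

The choice of how many net arrows shift a taxon one risk category is a
judgment call; this module sweeps the transition threshold (published sweep:
7, 6, 5, 4, 3 arrows, most to least conservative) and tabulates the
resulting category distributions against the current (no-climate-change)
baseline.

The published sensitivity table contains a handful of internally
inconsistent cells — its columns do not all reconcile with a recomputation
from the published per-taxon arrow data (e.g. the 4-arrow column prints 15
Critical taxa where the row data yield 14).  Recomputation from the taxon
table is this package's ground truth; :func:`reconcile_with_published`
reports every divergent cell rather than silently patching either side.
Only the baseline column and the 7-arrow column reconcile exactly and are
treated as hard reference values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .assessment import (
    CategoryDistribution,
    assess_all,
    category_distribution,
)
from .errors import ParameterError
from .species_table import RiskCategory, SpeciesProfile

__all__ = [
    "SensitivityTable",
    "sweep",
    "high_risk_count",
    "DEFAULT_THRESHOLDS",
    "PUBLISHED_SENSITIVITY",
    "reconcile_with_published",
]

#: Published sweep order: most conservative (7 arrows) to most liberal (3).
DEFAULT_THRESHOLDS: tuple[int, ...] = (7, 6, 5, 4, 3)

#: The sensitivity table as printed in the source publication, keyed by
#: column ("current" baseline or the integer threshold), each column a tuple
#: of counts over ordinals 1..6.  Reference data for reconciliation only.
PUBLISHED_SENSITIVITY: dict[str | int, tuple[int, ...]] = {
    "current": (0, 7, 16, 23, 6, 0),
    7: (0, 6, 12, 14, 17, 3),
    6: (0, 3, 12, 13, 18, 6),
    5: (0, 2, 11, 13, 17, 9),
    4: (0, 2, 7, 13, 15, 15),
    3: (0, 1, 4, 11, 14, 22),
}


@dataclass(frozen=True)
class SensitivityTable:
    """Category distributions across a threshold sweep, plus the baseline."""

    thresholds: tuple[int, ...]
    distributions: Mapping[int, CategoryDistribution]
    baseline: CategoryDistribution

    def to_frame(self) -> pd.DataFrame:
        """Rows = category labels, columns = Current + one per threshold."""
        data = {"Current": [self.baseline.counts[c] for c in RiskCategory]}
        for t in self.thresholds:
            data[f"{t} arrows"] = [self.distributions[t].counts[c] for c in RiskCategory]
        return pd.DataFrame(data, index=[c.label for c in RiskCategory])


def sweep(
    profiles: Sequence[SpeciesProfile],
    thresholds: Sequence[int] = DEFAULT_THRESHOLDS,
) -> SensitivityTable:
    """Recompute the full assessment at each threshold and tally categories."""
    thresholds = tuple(int(t) for t in thresholds)
    if not thresholds:
        raise ParameterError("threshold sweep requires at least one threshold")
    if any(t < 1 for t in thresholds):
        raise ParameterError(f"thresholds must be positive integers: {thresholds}")
    baseline = category_distribution(p.current_category for p in profiles)
    distributions = {
        t: category_distribution(r.revised_category for r in assess_all(profiles, t))
        for t in thresholds
    }
    return SensitivityTable(thresholds=thresholds, distributions=distributions, baseline=baseline)


def high_risk_count(
    distribution: CategoryDistribution, floor_ordinal: RiskCategory | int
) -> int:
    """Taxa at or above ``floor_ordinal`` (e.g. 5 = Highly Imperiled + Critical)."""
    floor = int(floor_ordinal)
    if not 1 <= floor <= 6:
        raise ParameterError(f"floor ordinal must be in [1, 6], got {floor_ordinal!r}")
    return distribution.at_or_above(floor)


@dataclass(frozen=True)
class CellDivergence:
    """One sensitivity-table cell where recomputation differs from print."""

    column: str | int
    category: RiskCategory
    published: int
    recomputed: int


def reconcile_with_published(table: SensitivityTable) -> list[CellDivergence]:
    """Compare a recomputed sensitivity table against the printed one.

    Returns every cell where they differ (empty list = full agreement).
    Thresholds absent from the printed table are skipped.
    """
    divergences: list[CellDivergence] = []
    columns: list[tuple[str | int, CategoryDistribution]] = [("current", table.baseline)]
    columns += [(t, table.distributions[t]) for t in table.thresholds]
    for key, dist in columns:
        published = PUBLISHED_SENSITIVITY.get(key)
        if published is None:
            continue
        for cat, printed in zip(RiskCategory, published):
            ours = dist.counts[cat]
            if ours != printed:
                divergences.append(
                    CellDivergence(column=key, category=cat, published=printed, recomputed=ours)
                )
    return divergences
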
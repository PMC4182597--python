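"""Aggregation of factor levels into risk-category revisions.

The framework's decision rule: a taxon's six signed arrow counts are summed
into a *net* arrow count (one up-arrow and one down-arrow cancel), and every
``threshold`` net arrows in the same direction shift the taxon one ordinal
risk category (default threshold 4, i.e. extreme risk on two of the six
factors).  Formally::

    delta  = sign(net) * floor(|net| / threshold)
    revised = clamp(current + delta, 1, 6)

The floor rule is the unique simple extension of the published single-step
criterion that is consistent with every row of the published table,
including 8-11-arrow taxa rising exactly two levels.  Arrows — not the
PIF-style scores — drive transitions; total scores are reported but never
thresholded.  Category 6 (Critical) is an absorbing cap, and downward
revision is permitted (down-arrows indicate decreased risk) although no
taxon in the published data triggers it.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import ParameterError, ValidationError
from .factor_model import FactorKind, level_from_score
from .species_table import RiskCategory, SpeciesProfile

__all__ = [
    "AssessmentResult",
    "CategoryDistribution",
    "net_arrows",
    "total_score",
    "revise_category",
    "assess_all",
    "delta_histogram",
    "factor_response_summary",
    "FactorResponse",
    "category_distribution",
    "concordance_r2",
    "DEFAULT_THRESHOLD",
    "MAX_NET_ARROWS",
]

DEFAULT_THRESHOLD = 4
#: six factors, at most two arrows each
MAX_NET_ARROWS = 2 * len(FactorKind)


@dataclass(frozen=True)
class AssessmentResult:
    """Outcome of the transition rule for one taxon at one threshold.

    ``delta`` is the *realized* category change (revised − current), which
    can be smaller in magnitude than the raw rule step when the revision is
    clamped at the scale ends (e.g. a Highly Imperiled taxon with 8 net
    arrows rises one level, to Critical, not two).
    """

    common_name: str
    population_tag: str | None
    current_category: RiskCategory
    net_arrows: int
    total_score: int
    threshold: int
    revised_category: RiskCategory
    delta: int

    @property
    def display_name(self) -> str:
        if self.population_tag:
            return f"{self.common_name} ({self.population_tag})"
        return self.common_name


@dataclass(frozen=True)
class CategoryDistribution:
    """Taxon counts over the six-level ordinal scale."""

    counts: Mapping[RiskCategory, int]

    def __post_init__(self) -> None:
        full = {cat: int(self.counts.get(cat, 0)) for cat in RiskCategory}
        if any(v < 0 for v in full.values()):
            raise ValidationError("category counts must be non-negative")
        object.__setattr__(self, "counts", full)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def at_or_above(self, floor: RiskCategory | int) -> int:
        """Count of taxa at or above ``floor`` on the ordinal scale."""
        floor = RiskCategory(int(floor))
        return sum(v for cat, v in self.counts.items() if cat >= floor)

    def as_dict(self) -> dict[int, int]:
        return {int(cat): v for cat, v in self.counts.items()}


def net_arrows(profile: SpeciesProfile) -> int:
    """Algebraic sum of the six signed arrow counts."""
    return sum(profile.levels[kind].arrows for kind in FactorKind)


def total_score(
    profile_or_scores: SpeciesProfile | Sequence[int],
    kinds: Sequence[FactorKind] | None = None,
) -> int:
    """Algebraic sum of the six PIF-style scores.

    Accepts either a profile or an explicit sequence of six scores (one per
    factor, in canonical order unless ``kinds`` is given); explicit scores
    are validated against each factor's menu.
    """
    if isinstance(profile_or_scores, SpeciesProfile):
        return sum(profile_or_scores.levels[k].score for k in FactorKind)
    scores = list(profile_or_scores)
    kinds = list(kinds) if kinds is not None else list(FactorKind)
    if len(scores) != len(FactorKind) or sorted(kinds, key=lambda k: k.value) != sorted(
        FactorKind, key=lambda k: k.value
    ):
        raise ValidationError("exactly one score per factor is required")
    return sum(level_from_score(k, s).score for k, s in zip(kinds, scores))


def revise_category(
    current: RiskCategory | int, net: int, threshold: int = DEFAULT_THRESHOLD
) -> RiskCategory:
    """Apply the category-transition rule and clamp to the ordinal scale."""
    if not isinstance(threshold, (int, np.integer)) or threshold < 1:
        raise ParameterError(f"threshold must be a positive integer, got {threshold!r}")
    current = RiskCategory(int(current))
    step = int(np.sign(net)) * (abs(int(net)) // int(threshold))
    revised = min(max(int(current) + step, RiskCategory.NOT_AT_RISK), RiskCategory.CRITICAL)
    return RiskCategory(revised)


def assess_all(
    profiles: Sequence[SpeciesProfile], threshold: int = DEFAULT_THRESHOLD
) -> list[AssessmentResult]:
    """Run the transition rule over a cohort, preserving input order."""
    results = []
    for p in profiles:
        net = net_arrows(p)
        revised = revise_category(p.current_category, net, threshold)
        results.append(
            AssessmentResult(
                common_name=p.common_name,
                population_tag=p.population_tag,
                current_category=p.current_category,
                net_arrows=net,
                total_score=total_score(p),
                threshold=int(threshold),
                revised_category=revised,
                delta=int(revised) - int(p.current_category),
            )
        )
    return results


def delta_histogram(results: Iterable[AssessmentResult]) -> dict[int, int]:
    """Counts of realized category changes (negative deltas included)."""
    return dict(sorted(Counter(r.delta for r in results).items()))


@dataclass(frozen=True)
class FactorResponse:
    """Per-factor cohort response: how many taxa this factor pushed upward."""

    increased: int  # arrows > 0
    maximal: int  # arrows == +2
    none_or_positive: int  # arrows <= 0 (no added risk, or risk decreased)

    @property
    def total(self) -> int:
        return self.increased + self.none_or_positive


def factor_response_summary(
    profiles: Sequence[SpeciesProfile],
) -> dict[FactorKind, FactorResponse]:
    """Per-factor counts of increased / maximal / non-increased responses."""
    out = {}
    for kind in FactorKind:
        arrows = [p.levels[kind].arrows for p in profiles]
        out[kind] = FactorResponse(
            increased=sum(a > 0 for a in arrows),
            maximal=sum(a == 2 for a in arrows),
            none_or_positive=sum(a <= 0 for a in arrows),
        )
    return out


def category_distribution(
    categories: Iterable[RiskCategory | int],
) -> CategoryDistribution:
    """Tally categories over the full 1-6 ordinal scale."""
    counter = Counter(RiskCategory(int(c)) for c in categories)
    return CategoryDistribution(counts=dict(counter))


def concordance_r2(x: Sequence[float], y: Sequence[float]) -> float:
    """Squared Pearson correlation between two paired score vectors.

    Used to compare the framework's net-arrow assessments with the external
    State of the Birds vulnerability scores.  Requires length >= 3 and
    nonzero variance in both vectors.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ParameterError("x and y must be equal-length 1-D vectors")
    if xa.size < 3:
        raise ParameterError("need at least 3 paired observations")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ParameterError("correlation undefined: a vector has zero variance")
    r = stats.pearsonr(xa, ya).statistic
    return float(r * r)
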
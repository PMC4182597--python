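"""The six climate-risk factors and their legal (score, arrow) levels.

Each shorebird taxon is assessed on six factors: expected change in breeding,
wintering and migration habitat, dependence on ecological synchronicities
(e.g. arctic invertebrate emergence, horseshoe-crab egg laying), one-way
migration distance, and degree of habitat specialization.  Every factor takes
one of a small menu of levels; a level carries both a PIF-style score
(-5..+5, 5 = greatest added risk) and a signed arrow count (-2..+2, up =
increased extinction risk).  Habitat factors admit negative levels because
climate change can create habitat as well as destroy it; synchronicity and
specialization cannot decrease risk; migration distance is a 1-5 rank used
directly as its score.

The menus below are the single source of truth for what constitutes a valid
assessment; everything downstream (table I/O, aggregation, simulation)
validates against them.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable

from .errors import GlyphParseError, ValidationError

__all__ = [
    "FactorKind",
    "FactorLevel",
    "legal_levels",
    "legal_scores",
    "legal_arrow_counts",
    "score_to_arrows",
    "level_from_score",
    "level_from_arrows",
    "parse_arrow_glyph",
    "format_arrow_glyph",
    "validate_confidence",
    "CONFIDENCE_MIN",
    "CONFIDENCE_MAX",
]


class FactorKind(Enum):
    """The six risk factors, in their canonical (published) order."""

    BREEDING_HABITAT = "breeding"
    WINTERING_HABITAT = "wintering"
    MIGRATION_HABITAT = "migration"
    ECOLOGICAL_SYNCHRONICITY = "synchronicity"
    MIGRATION_DISTANCE = "distance"
    HABITAT_SPECIALIZATION = "specialization"

    @property
    def column(self) -> str:
        """Column name used in CSV/JSON interchange."""
        return self.value


# Legal (score, arrows) pairs per factor.  The three habitat factors share a
# five-level menu spanning major loss (+5, two up-arrows) to major gain
# (-5, two down-arrows).  Synchronicity is high/moderate/low.  Migration
# distance uses the distance rank itself as the score (ranks 5..1 map to
# arrows 2,1,1,0,0).  Specialization has four levels, two of which carry the
# maximal two-arrow response.
_HABITAT_MENU: tuple[tuple[int, int], ...] = ((5, 2), (3, 1), (0, 0), (-3, -1), (-5, -2))

_LEGAL_PAIRS: dict[FactorKind, tuple[tuple[int, int], ...]] = {
    FactorKind.BREEDING_HABITAT: _HABITAT_MENU,
    FactorKind.WINTERING_HABITAT: _HABITAT_MENU,
    FactorKind.MIGRATION_HABITAT: _HABITAT_MENU,
    FactorKind.ECOLOGICAL_SYNCHRONICITY: ((5, 2), (3, 1), (0, 0)),
    FactorKind.MIGRATION_DISTANCE: ((5, 2), (4, 1), (3, 1), (2, 0), (1, 0)),
    FactorKind.HABITAT_SPECIALIZATION: ((5, 2), (4, 2), (3, 1), (0, 0)),
}


@dataclass(frozen=True)
class FactorLevel:
    """One legal (score, arrows) level of one factor.

    Instances validate on construction: the pair must appear in the factor's
    menu, so an in-memory ``FactorLevel`` is legal by construction.
    """

    kind: FactorKind
    score: int
    arrows: int

    def __post_init__(self) -> None:
        if not isinstance(self.kind, FactorKind):
            raise ValidationError(f"unknown factor kind: {self.kind!r}")
        if (self.score, self.arrows) not in _LEGAL_PAIRS[self.kind]:
            raise ValidationError(
                f"(score={self.score}, arrows={self.arrows}) is not a legal "
                f"level for factor {self.kind.name}"
            )


def legal_levels(kind: FactorKind) -> frozenset[FactorLevel]:
    """Return the exact set of legal levels for ``kind``."""
    if not isinstance(kind, FactorKind):
        raise ValidationError(f"unknown factor kind: {kind!r}")
    return frozenset(FactorLevel(kind, s, a) for s, a in _LEGAL_PAIRS[kind])


def legal_scores(kind: FactorKind) -> tuple[int, ...]:
    if not isinstance(kind, FactorKind):
        raise ValidationError(f"unknown factor kind: {kind!r}")
    return tuple(s for s, _ in _LEGAL_PAIRS[kind])


def legal_arrow_counts(kind: FactorKind) -> tuple[int, ...]:
    if not isinstance(kind, FactorKind):
        raise ValidationError(f"unknown factor kind: {kind!r}")
    return tuple(sorted({a for _, a in _LEGAL_PAIRS[kind]}))


def score_to_arrows(kind: FactorKind, score: int) -> int:
    """Arrow count paired with ``score`` for ``kind`` (unique per menu)."""
    return level_from_score(kind, score).arrows


def level_from_score(kind: FactorKind, score: int) -> FactorLevel:
    """The level of ``kind`` holding ``score``; scores are unique per factor."""
    if not isinstance(kind, FactorKind):
        raise ValidationError(f"unknown factor kind: {kind!r}")
    for s, a in _LEGAL_PAIRS[kind]:
        if s == score:
            return FactorLevel(kind, s, a)
    raise ValidationError(f"score {score} is not legal for factor {kind.name}")


def level_from_arrows(kind: FactorKind, arrows: int) -> FactorLevel:
    """Canonical level of ``kind`` with the given arrow count.

    Arrow counts do not always determine the score (migration distance maps
    both ranks 4 and 3 to one up-arrow; specialization maps scores 5 and 4 to
    two up-arrows).  The canonical choice is the *highest* score carrying that
    arrow count.  Only arrows enter category-transition arithmetic, so the
    convention never changes an assessment outcome.
    """
    if not isinstance(kind, FactorKind):
        raise ValidationError(f"unknown factor kind: {kind!r}")
    candidates = [s for s, a in _LEGAL_PAIRS[kind] if a == arrows]
    if not candidates:
        raise ValidationError(
            f"arrow count {arrows:+d} is not legal for factor {kind.name}"
        )
    return level_from_score(kind, max(candidates))


# Arrow-glyph dialects.  The published table prints unicode arrow runs; CSV
# interchange also accepts signed integers and an ascii letter shorthand.
_GLYPH_TOKENS: dict[str, int] = {
    "↑↑": 2, "↑": 1, "↓": -1, "↓↓": -2,
    "uu": 2, "u": 1, "d": -1, "dd": -2,
    "UU": 2, "U": 1, "D": -1, "DD": -2,
    "+2": 2, "+1": 1, "-1": -1, "-2": -2,
    "2": 2, "1": 1, "0": 0, "o": 0, "O": 0,
}

_CANONICAL_UNICODE = {2: "↑↑", 1: "↑", 0: "0", -1: "↓", -2: "↓↓"}
_CANONICAL_ASCII = {2: "+2", 1: "+1", 0: "0", -1: "-1", -2: "-2"}


def parse_arrow_glyph(text: str) -> int:
    """Parse one arrow cell in any accepted dialect to a signed arrow count.

    Accepted: unicode arrow runs (``↑↑ ↑ 0 ↓ ↓↓``), letter shorthand
    (``uu u 0 d dd``), and signed integers ``+2..-2`` (bare ``2``/``1``
    included).  Anything else — including integers outside ``[-2, 2]`` —
    raises :class:`GlyphParseError`.
    """
    token = str(text).strip()
    try:
        return _GLYPH_TOKENS[token]
    except KeyError:
        raise GlyphParseError(f"unrecognized arrow glyph: {text!r}") from None


def format_arrow_glyph(arrows: int, dialect: str = "unicode") -> str:
    """Render a signed arrow count in the ``unicode`` or ``ascii`` dialect."""
    table = {"unicode": _CANONICAL_UNICODE, "ascii": _CANONICAL_ASCII}.get(dialect)
    if table is None:
        raise ValidationError(f"unknown glyph dialect: {dialect!r}")
    if arrows not in table:
        raise ValidationError(f"arrow count out of range: {arrows!r}")
    return table[arrows]


CONFIDENCE_MIN = 1
CONFIDENCE_MAX = 5


def validate_confidence(value: int) -> int:
    """Check a per-factor confidence score (1 = low ... 5 = high).

    Confidences are carried through I/O and reports but never enter any
    computation; the framework defines no arithmetic over them.
    """
    v = int(value)
    if not CONFIDENCE_MIN <= v <= CONFIDENCE_MAX:
        raise ValidationError(f"confidence score must be in [1, 5], got {value!r}")
    return v


def iter_kinds() -> Iterable[FactorKind]:
    """The six factors in canonical order."""
    return tuple(FactorKind)
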
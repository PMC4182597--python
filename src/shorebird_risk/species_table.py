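"""Species profiles, risk categories, and table I/O.

A :class:`SpeciesProfile` is one row of the assessment dataset: a taxon
(species, or a distinct population of a species assessed separately), its
current ordinal risk category under the U.S. Shorebird Conservation Plan
(USSCP), and its six factor levels, plus optional per-factor confidence
scores and an optional external State of the Birds vulnerability score
(0-5) used for concordance checks.

The packaged dataset covers the 52 North American shorebird taxa
(49 species; Willet, Piping Plover and Snowy Plover each split into two
populations).  Scientific-name spellings are copied as printed in the source
table — including "Charadrius vociferous" for Killdeer, a known misspelling
of *vociferus* — so the bundled data round-trips exactly; the misspelling is
deliberate and must not be "fixed" in the data file.

CSV/JSON schema (column order is fixed)::

    common_name, scientific_name, population_tag, current_category,
    breeding, wintering, migration, synchronicity, distance, specialization,
    [conf_breeding ... conf_specialization], external_score

Factor cells are arrow glyphs by default (any accepted dialect); with
``cells="scores"`` they are integer PIF-style scores instead.  Arrow cells
lose the score distinction for the two ambiguous menus (see
:func:`~shorebird_risk.factor_model.level_from_arrows`), so score cells are
the lossless interchange form; arrow cells are lossless for data that uses
canonical scores, which includes the packaged table.  Unrecognized columns
are ignored on read.
"""

from __future__ import annotations

import csv
import hashlib
import io
import json
from dataclasses import dataclass, field, replace
from enum import IntEnum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import IntegrityError, SchemaError, ValidationError
from .factor_model import (
    FactorKind,
    FactorLevel,
    format_arrow_glyph,
    level_from_arrows,
    level_from_score,
    parse_arrow_glyph,
    validate_confidence,
)

__all__ = [
    "RiskCategory",
    "SpeciesProfile",
    "load_packaged_table",
    "load_packaged_reference",
    "read_profiles",
    "write_profiles",
    "profiles_to_frame",
    "PACKAGED_TABLE_RESOURCE",
]

PACKAGED_TABLE_RESOURCE = "usscp_climate_table.csv"
_PACKAGED_SHA256 = "89b2be3bd3f2f64731c4e80e898099a45f98cbfda8d2da2d2a627331de30cdf4"
_PACKAGED_ROWS = 52


class RiskCategory(IntEnum):
    """USSCP ordinal risk scale, extended with the Critical level.

    Categories 1-5 are the published USSCP scale; 6 (Critical) exists only
    as a *revised* category, created because some taxa already at Highly
    Imperiled accumulate enough climate-driven risk to move up a level.
    """

    NOT_AT_RISK = 1
    LOW_CONCERN = 2
    MODERATE_CONCERN = 3
    HIGH_CONCERN = 4
    HIGHLY_IMPERILED = 5
    CRITICAL = 6

    @property
    def label(self) -> str:
        return _CATEGORY_LABELS[self]


_CATEGORY_LABELS = {
    RiskCategory.NOT_AT_RISK: "Not at risk",
    RiskCategory.LOW_CONCERN: "Low concern",
    RiskCategory.MODERATE_CONCERN: "Moderate concern",
    RiskCategory.HIGH_CONCERN: "High concern",
    RiskCategory.HIGHLY_IMPERILED: "Highly imperiled",
    RiskCategory.CRITICAL: "Critical",
}

_FACTOR_COLUMNS = tuple(k.column for k in FactorKind)
_CONF_COLUMNS = tuple(f"conf_{k.column}" for k in FactorKind)
_IDENTITY_COLUMNS = ("common_name", "scientific_name", "population_tag")


@dataclass(frozen=True)
class SpeciesProfile:
    """One assessed taxon: identity, current category, and six factor levels."""

    common_name: str
    scientific_name: str | None
    population_tag: str | None
    current_category: RiskCategory
    levels: Mapping[FactorKind, FactorLevel]
    confidences: Mapping[FactorKind, int] | None = None
    external_score: int | None = None
    notes: str | None = None

    def __post_init__(self) -> None:
        if not self.common_name:
            raise ValidationError("common_name must be non-empty")
        try:
            cat = RiskCategory(int(self.current_category))
        except ValueError:
            raise ValidationError(
                f"{self.common_name}: current_category out of range: "
                f"{self.current_category!r}"
            ) from None
        if cat is RiskCategory.CRITICAL:
            raise ValidationError(
                f"{self.display_name}: current_category must be 1-5 "
                "(Critical exists only as a revised category)"
            )
        object.__setattr__(self, "current_category", cat)
        lv = dict(self.levels)
        missing = [k.name for k in FactorKind if k not in lv]
        if missing or len(lv) != len(FactorKind):
            raise ValidationError(
                f"{self.display_name}: profile must carry exactly the six "
                f"factor levels (missing: {missing})"
            )
        for kind, level in lv.items():
            if not isinstance(level, FactorLevel) or level.kind is not kind:
                raise ValidationError(
                    f"{self.display_name}: level stored under {kind.name} "
                    f"does not belong to that factor"
                )
        object.__setattr__(self, "levels", lv)
        if self.confidences is not None:
            conf = {k: validate_confidence(v) for k, v in self.confidences.items()}
            unknown = [k for k in conf if not isinstance(k, FactorKind)]
            if unknown:
                raise ValidationError(f"unknown factor in confidences: {unknown}")
            object.__setattr__(self, "confidences", conf)
        if self.external_score is not None:
            ext = int(self.external_score)
            if not 0 <= ext <= 5:
                raise ValidationError(
                    f"{self.display_name}: external_score must be in [0, 5], "
                    f"got {self.external_score!r}"
                )
            object.__setattr__(self, "external_score", ext)

    @property
    def key(self) -> tuple[str, str | None]:
        """Identity key; population splits share a name but not a tag."""
        return (self.common_name, self.population_tag)

    @property
    def display_name(self) -> str:
        if self.population_tag:
            return f"{self.common_name} ({self.population_tag})"
        return self.common_name

    def with_level(self, level: FactorLevel, note: str | None = None) -> "SpeciesProfile":
        """Return a copy with one factor level replaced (and a note appended)."""
        levels = dict(self.levels)
        levels[level.kind] = level
        notes = self.notes
        if note:
            notes = f"{notes}; {note}" if notes else note
        return replace(self, levels=levels, notes=notes)


# ---------------------------------------------------------------------------
# parsing helpers

def _parse_level(kind: FactorKind, cell: str, cells: str, where: str) -> FactorLevel:
    text = str(cell).strip()
    if text == "":
        raise SchemaError(f"{where}: empty {kind.column} cell")
    try:
        if cells == "arrows":
            return level_from_arrows(kind, parse_arrow_glyph(text))
        return level_from_score(kind, int(text))
    except (ValidationError, ValueError) as exc:
        raise ValidationError(f"{where}, factor {kind.column}: {exc}") from None


def _profile_from_record(record: Mapping[str, object], cells: str, where: str) -> SpeciesProfile:
    for col in ("common_name", "current_category", *_FACTOR_COLUMNS):
        if col not in record or record[col] is None or str(record[col]).strip() == "":
            if col in _FACTOR_COLUMNS and col in record:
                raise ValidationError(f"{where}: empty cell for factor {col}")
            raise SchemaError(f"{where}: missing required column {col!r}")

    def opt(colname: str) -> str | None:
        v = record.get(colname)
        if v is None:
            return None
        s = str(v).strip()
        return s or None

    levels = {
        kind: _parse_level(kind, str(record[kind.column]), cells, where)
        for kind in FactorKind
    }
    confidences = None
    conf = {
        kind: int(str(record[c]).strip())
        for kind, c in zip(FactorKind, _CONF_COLUMNS)
        if opt(c) is not None
    }
    if conf:
        if len(conf) != len(FactorKind):
            raise SchemaError(f"{where}: confidences must be given for all six factors or none")
        confidences = conf
    ext = opt("external_score")
    try:
        current = int(str(record["current_category"]).strip())
    except ValueError:
        raise ValidationError(f"{where}: current_category must be an integer") from None
    try:
        return SpeciesProfile(
            common_name=str(record["common_name"]).strip(),
            scientific_name=opt("scientific_name"),
            population_tag=opt("population_tag"),
            current_category=RiskCategory(current) if 1 <= current <= 6 else current,
            levels=levels,
            confidences=confidences,
            external_score=int(ext) if ext is not None else None,
        )
    except ValueError as exc:
        raise ValidationError(f"{where}: {exc}") from None


def _read_profiles_text(text: str, fmt: str, cells: str, source: str) -> list[SpeciesProfile]:
    if cells not in ("arrows", "scores"):
        raise SchemaError(f"unknown cell mode: {cells!r}")
    profiles: list[SpeciesProfile] = []
    if fmt == "csv":
        reader = csv.DictReader(io.StringIO(text))
        if reader.fieldnames is None:
            raise SchemaError(f"{source}: empty file")
        for col in ("common_name", "current_category", *_FACTOR_COLUMNS):
            if col not in reader.fieldnames:
                raise SchemaError(f"{source}: missing required column {col!r}")
        for i, row in enumerate(reader, start=2):
            profiles.append(_profile_from_record(row, cells, f"{source} row {i}"))
    elif fmt == "json":
        try:
            records = json.loads(text)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"{source}: invalid JSON: {exc}") from None
        if not isinstance(records, list):
            raise SchemaError(f"{source}: expected a JSON array of row objects")
        for i, rec in enumerate(records, start=1):
            if not isinstance(rec, dict):
                raise SchemaError(f"{source} record {i}: expected an object")
            profiles.append(_profile_from_record(rec, cells, f"{source} record {i}"))
    else:
        raise SchemaError(f"unknown format: {fmt!r}")
    return profiles


def read_profiles(
    path: str | Path,
    fmt: str | None = None,
    cells: str = "arrows",
    encoding: str = "utf-8",
) -> list[SpeciesProfile]:
    """Read species profiles from a CSV or JSON table.

    ``fmt`` defaults from the file suffix.  ``cells`` selects whether factor
    cells hold arrow glyphs (default, any dialect) or integer scores.  Every
    level is validated against the factor menus; errors cite the offending
    row and factor.
    """
    path = Path(path)
    if fmt is None:
        fmt = "json" if path.suffix.lower() == ".json" else "csv"
    try:
        text = path.read_text(encoding=encoding)
    except OSError as exc:
        raise OSError(f"cannot read {path}: {exc}") from exc
    return _read_profiles_text(text, fmt, cells, path.name)


def _profile_record(
    profile: SpeciesProfile, cells: str, glyphs: str, with_conf: bool
) -> dict[str, object]:
    rec: dict[str, object] = {
        "common_name": profile.common_name,
        "scientific_name": profile.scientific_name or "",
        "population_tag": profile.population_tag or "",
        "current_category": int(profile.current_category),
    }
    for kind in FactorKind:
        level = profile.levels[kind]
        if cells == "arrows":
            rec[kind.column] = format_arrow_glyph(level.arrows, glyphs)
        else:
            rec[kind.column] = level.score
    if with_conf:
        for kind, col in zip(FactorKind, _CONF_COLUMNS):
            conf = (profile.confidences or {}).get(kind)
            rec[col] = "" if conf is None else conf
    rec["external_score"] = "" if profile.external_score is None else profile.external_score
    return rec


def write_profiles(
    profiles: Sequence[SpeciesProfile],
    path: str | Path,
    fmt: str | None = None,
    cells: str = "arrows",
    glyphs: str = "unicode",
) -> Path:
    """Write profiles to CSV or JSON with a fixed, deterministic column order.

    Two writes of the same data produce byte-identical files.  ``glyphs``
    selects the arrow dialect (ignored when ``cells="scores"``).
    """
    if cells not in ("arrows", "scores"):
        raise SchemaError(f"unknown cell mode: {cells!r}")
    if glyphs not in ("unicode", "ascii"):
        raise ValidationError(f"unknown glyph dialect: {glyphs!r}")
    path = Path(path)
    if fmt is None:
        fmt = "json" if path.suffix.lower() == ".json" else "csv"
    with_conf = any(p.confidences for p in profiles)
    columns = list(_IDENTITY_COLUMNS) + ["current_category"] + list(_FACTOR_COLUMNS)
    if with_conf:
        columns += list(_CONF_COLUMNS)
    columns.append("external_score")
    records = [_profile_record(p, cells, glyphs, with_conf) for p in profiles]
    if fmt == "csv":
        buf = io.StringIO()
        writer = csv.DictWriter(buf, fieldnames=columns, lineterminator="\n")
        writer.writeheader()
        writer.writerows(records)
        payload = buf.getvalue()
    elif fmt == "json":
        payload = json.dumps(records, indent=2, ensure_ascii=False) + "\n"
    else:
        raise SchemaError(f"unknown format: {fmt!r}")
    try:
        path.write_text(payload, encoding="utf-8")
    except OSError as exc:
        raise OSError(f"cannot write {path}: {exc}") from exc
    return path


# ---------------------------------------------------------------------------
# packaged dataset

def _packaged_text() -> str:
    data = resources.files("shorebird_risk.data").joinpath(PACKAGED_TABLE_RESOURCE)
    try:
        raw = data.read_bytes()
    except (FileNotFoundError, OSError) as exc:
        raise IntegrityError(f"packaged table missing: {exc}") from exc
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _PACKAGED_SHA256:
        raise IntegrityError(
            f"packaged table failed its integrity check "
            f"(sha256 {digest} != {_PACKAGED_SHA256})"
        )
    return raw.decode("utf-8")


def load_packaged_table() -> list[SpeciesProfile]:
    """Load the bundled 52-taxon assessment table.

    Rows are verbatim from the published assessment: per-factor arrow
    responses, State of the Birds score, and current USSCP category.  The
    bundle is integrity-checked (sha256 + row count) before parsing.
    """
    profiles = _read_profiles_text(_packaged_text(), "csv", "arrows", PACKAGED_TABLE_RESOURCE)
    if len(profiles) != _PACKAGED_ROWS:
        raise IntegrityError(
            f"packaged table has {len(profiles)} rows, expected {_PACKAGED_ROWS}"
        )
    return profiles


def load_packaged_reference() -> pd.DataFrame:
    """The packaged table as a DataFrame, including the *published* net-arrow
    sums and revised categories as printed in the source.

    These printed columns serve as the reproduction oracle for the
    assessment engine; they are reference data, not inputs to it.
    """
    frame = pd.read_csv(io.StringIO(_packaged_text()), keep_default_na=False)
    if len(frame) != _PACKAGED_ROWS:
        raise IntegrityError("packaged table row count mismatch")
    return frame


def profiles_to_frame(profiles: Iterable[SpeciesProfile]) -> pd.DataFrame:
    """Tabular (score + arrow) view of profiles for analysis and export."""
    rows = []
    for p in profiles:
        row: dict[str, object] = {
            "common_name": p.common_name,
            "scientific_name": p.scientific_name,
            "population_tag": p.population_tag,
            "current_category": int(p.current_category),
        }
        for kind in FactorKind:
            row[f"{kind.column}_arrows"] = p.levels[kind].arrows
            row[f"{kind.column}_score"] = p.levels[kind].score
        row["external_score"] = p.external_score
        rows.append(row)
    return pd.DataFrame(rows)
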
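"""Seeded synthetic cohorts and range polygons.

Two generators make every pipeline stage testable without any download:

* :func:`generate_profiles` draws valid random species profiles.  Default
  level probabilities are the empirical level frequencies of the packaged
  52-taxon table, so a default synthetic cohort statistically resembles the
  study population (categorical factor levels, ordinal current categories,
  and — optionally — an external vulnerability score loosely linearly
  coupled to net arrows).  What it does *not* emulate: correlations between
  factors within a taxon (real coastal specialists share habitat responses)
  or phylogenetic structure; each factor is drawn independently.

* :func:`generate_range_pair` builds a pair of approximately circular
  breeding/wintering range polygons around requested centroids with a known
  centroid separation, standing in for real range maps in the
  migration-distance stage.

All randomness flows from a single integer seed through one
``numpy.random.default_rng`` stream per call, so outputs are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .errors import ParameterError
from .factor_model import FactorKind, FactorLevel, legal_levels
from .geometry import EARTH_RADIUS_KM, GeoPoint, RangePolygon
from .species_table import RiskCategory, SpeciesProfile, load_packaged_table

__all__ = [
    "ExternalScoreModel",
    "ProfileGeneratorConfig",
    "empirical_level_probabilities",
    "empirical_category_probabilities",
    "generate_profiles",
    "generate_range_pair",
]

_PROB_TOL = 1e-9


@dataclass(frozen=True)
class ExternalScoreModel:
    """Linear link from net arrows to a 0-5 external vulnerability score.

    ``score = round(intercept + slope * net + N(0, noise_sd))`` clipped to
    [0, 5].  With ``noise_sd`` near 0 the external score is a deterministic
    function of net arrows (high concordance r²); large ``noise_sd`` decouples
    them.
    """

    slope: float = 5.0 / 12.0
    intercept: float = 0.0
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ParameterError(f"noise_sd must be >= 0, got {self.noise_sd}")


def empirical_level_probabilities() -> dict[FactorKind, dict[FactorLevel, float]]:
    """Per-factor level frequencies observed in the packaged table."""
    profiles = load_packaged_table()
    out: dict[FactorKind, dict[FactorLevel, float]] = {}
    n = len(profiles)
    for kind in FactorKind:
        counts: dict[FactorLevel, int] = {
            lv: 0 for lv in sorted(legal_levels(kind), key=lambda lv: lv.score)
        }
        for p in profiles:
            counts[p.levels[kind]] += 1
        out[kind] = {lv: c / n for lv, c in counts.items()}
    return out


def empirical_category_probabilities() -> dict[int, float]:
    """Current-category frequencies observed in the packaged table."""
    profiles = load_packaged_table()
    n = len(profiles)
    return {
        c: sum(int(p.current_category) == c for p in profiles) / n for c in range(1, 6)
    }


def _check_distribution(probs: Mapping, what: str) -> None:
    values = list(probs.values())
    if any(v < 0 for v in values):
        raise ParameterError(f"{what}: probabilities must be non-negative")
    if abs(sum(values) - 1.0) > _PROB_TOL:
        raise ParameterError(f"{what}: probabilities must sum to 1 (got {sum(values)!r})")


@dataclass(frozen=True)
class ProfileGeneratorConfig:
    """Configuration for the synthetic-cohort generator.

    Defaults reproduce the statistical structure of the study population
    (empirical packaged-table frequencies, no external score).
    """

    n: int = 52
    seed: int = 0
    level_probabilities: Mapping[FactorKind, Mapping[FactorLevel, float]] | None = None
    current_category_probabilities: Mapping[int, float] | None = None
    external_score_model: ExternalScoreModel | None = None

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ParameterError(f"n must be non-negative, got {self.n}")
        if self.level_probabilities is not None:
            for kind, probs in self.level_probabilities.items():
                if not isinstance(kind, FactorKind):
                    raise ParameterError(f"unknown factor kind: {kind!r}")
                legal = legal_levels(kind)
                for lv in probs:
                    if lv not in legal:
                        raise ParameterError(
                            f"{kind.name}: probability assigned to illegal level {lv}"
                        )
                _check_distribution(probs, f"level probabilities for {kind.name}")
        if self.current_category_probabilities is not None:
            for c in self.current_category_probabilities:
                if not 1 <= int(c) <= 5:
                    raise ParameterError(f"current category out of range: {c!r}")
            _check_distribution(
                self.current_category_probabilities, "current-category probabilities"
            )


def generate_profiles(config: ProfileGeneratorConfig) -> list[SpeciesProfile]:
    """Draw ``config.n`` valid random species profiles, deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    level_probs = (
        dict(config.level_probabilities)
        if config.level_probabilities is not None
        else empirical_level_probabilities()
    )
    cat_probs = (
        dict(config.current_category_probabilities)
        if config.current_category_probabilities is not None
        else empirical_category_probabilities()
    )
    for kind in FactorKind:
        if kind not in level_probs:
            raise ParameterError(f"missing level probabilities for {kind.name}")

    # fixed, sorted support per factor so draws are reproducible across runs
    supports = {
        kind: tuple(sorted(level_probs[kind].keys(), key=lambda lv: lv.score))
        for kind in FactorKind
    }
    cats = tuple(sorted(cat_probs.keys()))
    cat_weights = np.array([cat_probs[c] for c in cats], dtype=float)

    profiles: list[SpeciesProfile] = []
    width = max(3, len(str(max(config.n, 1))))
    for i in range(config.n):
        levels = {}
        for kind in FactorKind:
            support = supports[kind]
            weights = np.array([level_probs[kind][lv] for lv in support], dtype=float)
            idx = rng.choice(len(support), p=weights)
            levels[kind] = support[idx]
        current = int(cats[rng.choice(len(cats), p=cat_weights)])
        external = None
        if config.external_score_model is not None:
            m = config.external_score_model
            net = sum(lv.arrows for lv in levels.values())
            raw = m.intercept + m.slope * net + rng.normal(0.0, m.noise_sd)
            external = int(np.clip(round(raw), 0, 5))
        profiles.append(
            SpeciesProfile(
                common_name=f"Synthetic taxon {i + 1:0{width}d}",
                scientific_name=None,
                population_tag=None,
                current_category=RiskCategory(current),
                levels=levels,
                external_score=external,
                notes="synthetic",
            )
        )
    return profiles


def generate_range_pair(
    seed: int,
    centroid_a: GeoPoint,
    centroid_b: GeoPoint,
    radius_km: float = 500.0,
    vertex_count: int = 24,
    jitter: float = 0.08,
) -> tuple[RangePolygon, RangePolygon]:
    """Two approximately circular range polygons at known centers.

    Each polygon's vertices sit at a geodesic distance ``radius_km`` from its
    center (with a small seeded radial jitter so edges are irregular, as real
    range maps are), at evenly spaced bearings.  The construction is
    rotationally symmetric up to jitter, so each polygon's spherical centroid
    recovers its requested center closely, and the centroid-to-centroid
    distance is known by construction.
    """
    if vertex_count < 8:
        raise ParameterError(f"vertex_count must be >= 8, got {vertex_count}")
    if not 0 <= jitter < 0.5:
        raise ParameterError(f"jitter must be in [0, 0.5), got {jitter}")
    max_radius = EARTH_RADIUS_KM * math.pi / 4  # stay well inside a hemisphere
    if not 0 < radius_km <= max_radius:
        raise ParameterError(
            f"radius_km must be in (0, {max_radius:.0f}] km, got {radius_km!r}"
        )
    rng = np.random.default_rng(seed)

    def circle(center: GeoPoint) -> RangePolygon:
        c = center.unit_vector()
        # orthonormal tangent basis at the center (east, north)
        helper = np.array([0.0, 0.0, 1.0])
        if abs(np.dot(helper, c)) > 0.99:
            helper = np.array([1.0, 0.0, 0.0])
        east = np.cross(helper, c)
        east /= np.linalg.norm(east)
        north = np.cross(c, east)
        vertices = []
        for theta in np.linspace(0.0, 2.0 * math.pi, vertex_count, endpoint=False):
            delta = (radius_km / EARTH_RADIUS_KM) * (
                1.0 + jitter * rng.uniform(-1.0, 1.0)
            )
            v = (
                math.cos(delta) * c
                + math.sin(delta) * (math.cos(theta) * east + math.sin(theta) * north)
            )
            vertices.append(GeoPoint.from_unit_vector(v))
        return RangePolygon(tuple(vertices))

    return circle(centroid_a), circle(centroid_b)
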
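"""Domain record types shared by all analysis stages.

Lengths are stored in centimetres and weights in grams throughout.  Input
tables that carry millimetre lengths must be converted on ingest; the CSV
schemas in :mod:`fishtroph.io` make the unit explicit in the column name
(``total_length_cm``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "ValidationError",
    "FishRecord",
    "GutSample",
    "IsotopeSample",
    "CommunityCount",
    "DistanceMatrix",
    "STATUS_VALUES",
    "ISOTOPE_GROUPS",
]

STATUS_VALUES = ("purebred", "introgressed")
ISOTOPE_GROUPS = ("consumer", "baseline_bmi", "producer")


class ValidationError(ValueError):
    """A record violated one of its invariants."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


@dataclass(frozen=True)
class FishRecord:
    """One captured fish.

    ``age`` (completed years, from scale reading) and ``pass_number``
    (electrofishing removal pass, 1-based) may be missing (``None``).
    """

    fish_id: str
    population_id: str
    status: str
    total_length: float  # cm
    weight: float | None = None  # g
    age: int | None = None  # years
    pass_number: int | None = None

    def __post_init__(self) -> None:
        _require(self.status in STATUS_VALUES,
                 f"status must be one of {STATUS_VALUES}, got {self.status!r}")
        _require(self.total_length > 0, "total_length must be > 0")
        if self.weight is not None:
            _require(self.weight > 0, "weight must be > 0 when present")
        if self.age is not None:
            _require(self.age >= 0, "age must be >= 0 when present")
        if self.pass_number is not None:
            _require(self.pass_number >= 1, "pass_number must be >= 1")


@dataclass(frozen=True)
class GutSample:
    """Relative-fullness diet record for one fish.

    ``fullness`` is the visually estimated gut fullness in percent of gut
    volume; ``items`` apportions it among food categories so that the item
    percentages sum to the fullness.  An empty gut has fullness 0 and no
    items.
    """

    fish_id: str
    population_id: str
    total_length: float  # cm
    fullness: float  # percent, 0..100
    items: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _require(self.total_length > 0, "total_length must be > 0")
        _require(0.0 <= self.fullness <= 100.0,
                 "fullness must be in [0, 100]")
        for cat, v in self.items.items():
            _require(v >= 0, f"item percentage for {cat!r} must be >= 0")
        total = float(sum(self.items.values()))
        _require(abs(total - self.fullness) <= 1e-9,
                 f"item percentages sum to {total}, fullness is {self.fullness}")
        if self.fullness == 0:
            _require(not self.items, "empty gut must have no items")

    @property
    def is_empty(self) -> bool:
        return self.fullness == 0.0


@dataclass(frozen=True)
class IsotopeSample:
    """One bulk stable-isotope measurement (per-mil vs. international
    standards): delta-13C tracks the carbon (energy) source, delta-15N the
    trophic level.  ``group`` separates consumers (fish), pooled
    benthic-macroinvertebrate baselines and primary producers."""

    sample_id: str
    group: str
    taxon: str
    population_id: str
    d13C: float
    d15N: float
    c_to_n: float | None = None

    def __post_init__(self) -> None:
        _require(self.group in ISOTOPE_GROUPS,
                 f"group must be one of {ISOTOPE_GROUPS}, got {self.group!r}")
        _require(math.isfinite(self.d13C) and math.isfinite(self.d15N),
                 "isotope ratios must be finite")
        if self.c_to_n is not None:
            _require(self.c_to_n > 0, "c_to_n must be > 0 when present")


@dataclass(frozen=True)
class CommunityCount:
    """Count of one taxon at one site, with the sampled area in m^2."""

    site_id: str
    taxon: str
    count: int
    area: float  # m^2

    def __post_init__(self) -> None:
        _require(self.count >= 0, "count must be >= 0")
        _require(int(self.count) == self.count, "count must be an integer")
        _require(self.area > 0, "area must be > 0")


@dataclass(frozen=True)
class DistanceMatrix:
    """Labelled symmetric dissimilarity matrix with a zero diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        _require(v.shape == (n, n), "matrix shape must match labels")
        _require(np.allclose(v, v.T, atol=1e-12), "matrix must be symmetric")
        _require(np.allclose(np.diag(v), 0.0, atol=1e-12),
                 "diagonal must be zero")
        _require(bool(np.all(v >= -1e-12)), "distances must be non-negative")
        object.__setattr__(self, "values", v)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy ``squareform`` order."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]
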
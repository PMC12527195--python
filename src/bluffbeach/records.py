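"""Domain record types for bluff-beach field surveys.

Each dataclass models one raw survey record (a quadrat, a transect, a trap,
...) and validates its own invariants on construction.  Site-level metrics are
computed from lists of these records by :mod:`bluffbeach.metrics`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

TREATMENTS = ("ProtectHigh", "ProtectLow", "RestoreHigh", "RestoreLow")
REGIONS = ("PennCove", "DabobBay", "AgatePass", "VashonIsland", "HarstineIsland")
SEASONS = ("spring", "summer")
VEG_STATUS = ("native", "introduced", "cryptic")


class RecordError(ValueError):
    """A survey record violates one of its invariants."""


def _check_pct(value: float, name: str) -> None:
    if not 0.0 <= value <= 100.0:
        raise RecordError(f"{name} must be in [0, 100], got {value!r}")


def _check_nonneg(value: float, name: str) -> None:
    if value < 0:
        raise RecordError(f"{name} must be non-negative, got {value!r}")


@dataclass(frozen=True)
class SiteDescriptor:
    """Identity and management classification of one surveyed bluff site.

    ``treatment`` crosses armoring status (Protect = natural bluff, Restore =
    armored) with the ranked potential benefit to sediment supply (High/Low).
    ``facing`` is the shore-normal compass direction in degrees true, used to
    assign the design wind scenario.
    """

    site_id: str
    treatment: str
    region: str
    facing: float

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise RecordError(
                f"unknown treatment {self.treatment!r}; expected one of {TREATMENTS}"
            )
        if self.region not in REGIONS:
            raise RecordError(
                f"unknown region {self.region!r}; expected one of {REGIONS}"
            )
        if not 0.0 <= self.facing < 360.0:
            raise RecordError(f"facing must be in [0, 360), got {self.facing!r}")


@dataclass(frozen=True)
class WrackQuadrat:
    """One 0.1 m^2 wrack quadrat: percent covers and wrack line dimensions."""

    site_id: str
    percent_cover_total: float
    percent_algae: float
    percent_eelgrass: float
    percent_terrestrial: float
    wrack_width: float  # m
    wrack_depth: float  # cm

    def __post_init__(self) -> None:
        for name in (
            "percent_cover_total",
            "percent_algae",
            "percent_eelgrass",
            "percent_terrestrial",
        ):
            _check_pct(getattr(self, name), name)
        parts = self.percent_algae + self.percent_eelgrass + self.percent_terrestrial
        if parts > self.percent_cover_total + 1e-9:
            raise RecordError(
                "component covers exceed total cover "
                f"({parts:.3f} > {self.percent_cover_total:.3f})"
            )
        _check_nonneg(self.wrack_width, "wrack_width")
        _check_nonneg(self.wrack_depth, "wrack_depth")


@dataclass(frozen=True)
class LogLineSample:
    """One random point on the log line: log counts and line width."""

    site_id: str
    log_count: int
    buried_count: int
    log_line_width: float  # m
    fallen_trees_site_total: int

    def __post_init__(self) -> None:
        for name in ("log_count", "buried_count", "fallen_trees_site_total"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise RecordError(f"{name} must be a non-negative integer, got {v!r}")
        if self.buried_count > self.log_count:
            raise RecordError(
                f"buried_count ({self.buried_count}) exceeds log_count ({self.log_count})"
            )
        _check_nonneg(self.log_line_width, "log_line_width")


@dataclass(frozen=True)
class SnorkelTransect:
    """One snorkel transect with fish counts and salmon feeding observations.

    Counts are raw tallies; densities are derived from ``transect_length`` and
    horizontal Secchi ``visibility`` (sampled area = length x visibility).
    """

    site_id: str
    season: str
    transect_length: float  # m
    visibility: float  # m
    count_total_fish: int
    count_juv_salmon: int
    count_forage_fish: int
    count_other: int
    feeding_observed: int
    salmon_observation_events: int

    def __post_init__(self) -> None:
        if self.season not in SEASONS:
            raise RecordError(f"season must be one of {SEASONS}, got {self.season!r}")
        if self.transect_length <= 0:
            raise RecordError("transect_length must be > 0")
        if self.visibility <= 0:
            raise RecordError("visibility must be > 0")
        for name in (
            "count_total_fish",
            "count_juv_salmon",
            "count_forage_fish",
            "count_other",
            "feeding_observed",
            "salmon_observation_events",
        ):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise RecordError(f"{name} must be a non-negative integer, got {v!r}")
        if self.feeding_observed > self.salmon_observation_events:
            raise RecordError(
                "feeding_observed exceeds salmon_observation_events "
                f"({self.feeding_observed} > {self.salmon_observation_events})"
            )


@dataclass(frozen=True)
class FalloutTrapSample:
    """One supratidal fallout trap (default 40 x 25 cm bin, 2 h deployment)."""

    site_id: str
    counts_by_taxon: Mapping[str, int]
    trap_area: float = 0.10  # m^2
    deploy_hours: float = 2.0

    def __post_init__(self) -> None:
        if self.trap_area <= 0:
            raise RecordError("trap_area must be > 0")
        for taxon, count in self.counts_by_taxon.items():
            if int(count) != count or count < 0:
                raise RecordError(
                    f"count for taxon {taxon!r} must be a non-negative integer"
                )


@dataclass(frozen=True)
class MllwQuadrat:
    """One 0.25 m^2 quadrat of surface biota at MLLW."""

    site_id: str
    cover_by_taxon: Mapping[str, float]
    eelgrass_percent: float
    quadrat_area: float = 0.25
    taxa_present: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.quadrat_area <= 0:
            raise RecordError("quadrat_area must be > 0")
        _check_pct(self.eelgrass_percent, "eelgrass_percent")
        for taxon, cover in self.cover_by_taxon.items():
            _check_pct(cover, f"cover for {taxon!r}")
        if not self.taxa_present:
            object.__setattr__(
                self,
                "taxa_present",
                frozenset(t for t, c in self.cover_by_taxon.items() if c > 0),
            )


@dataclass(frozen=True)
class VegetationTransect:
    """One backshore vegetation transect: overhang intervals, supratidal
    cover, dunegrass patches, and the species list within 5 m of the
    backshore."""

    site_id: str
    transect_length: float
    overhang_intervals: Sequence[tuple]
    supratidal_percent: float
    dunegrass_patch_widths: Sequence[float]
    species_list: Sequence[tuple]  # (name, status)

    def __post_init__(self) -> None:
        if self.transect_length <= 0:
            raise RecordError("transect_length must be > 0")
        for start, end in self.overhang_intervals:
            if start > end:
                raise RecordError(f"interval start {start} > end {end}")
            if start < 0 or end > self.transect_length:
                raise RecordError(
                    f"interval ({start}, {end}) outside transect "
                    f"[0, {self.transect_length}]"
                )
        _check_pct(self.supratidal_percent, "supratidal_percent")
        for w in self.dunegrass_patch_widths:
            _check_nonneg(w, "dunegrass patch width")
        for name, status in self.species_list:
            if status not in VEG_STATUS:
                raise RecordError(
                    f"species {name!r} has unknown status {status!r}; "
                    f"expected one of {VEG_STATUS}"
                )
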
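"""Geomorphic metrics from cross-shore elevation profiles and tidal datums.

The vertical frame is whichever datum the profile elevations use; the
:class:`TidalDatums` must be supplied in the same frame.  Relative
encroachment E = MHHW - toe elevation: positive E means the bluff or armor toe
sits below MHHW, intruding into the intertidal zone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np


class ProfileError(ValueError):
    """An elevation profile cannot support the requested computation."""


@dataclass(frozen=True)
class TidalDatums:
    """MHHW / MSL / MLLW elevations (m) in the profile's vertical datum."""

    mhhw: float
    msl: float
    mllw: float

    def __post_init__(self) -> None:
        if not (self.mhhw > self.msl > self.mllw):
            raise ProfileError(
                f"datums must satisfy mhhw > msl > mllw, got "
                f"({self.mhhw}, {self.msl}, {self.mllw})"
            )


@dataclass(frozen=True)
class ElevationProfile:
    """Cross-shore profile, seaward-increasing distance, with the bluff or
    armor toe marked by index."""

    distances: Sequence[float]  # m
    elevations: Sequence[float]  # m
    toe_index: int = 0

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        e = np.asarray(self.elevations, dtype=float)
        if d.size < 2 or d.size != e.size:
            raise ProfileError("profile needs >= 2 (distance, elevation) points")
        if not np.all(np.diff(d) > 0):
            raise ProfileError("profile distances must be strictly increasing")
        if not 0 <= self.toe_index < d.size:
            raise ProfileError(f"toe_index {self.toe_index} out of range")
        object.__setattr__(self, "distances", d)
        object.__setattr__(self, "elevations", e)

    @property
    def toe_elevation(self) -> float:
        return float(self.elevations[self.toe_index])

    @property
    def toe_distance(self) -> float:
        return float(self.distances[self.toe_index])


@dataclass(frozen=True)
class GeomorphMetrics:
    relative_encroachment: float  # m, signed
    slope_toe_msl: float  # m/m, reported as positive magnitude
    width_toe_mllw: float  # m
    bluff_height: float  # m, pass-through input
    bluff_exposure: float  # m^2, pass-through input

    def __post_init__(self) -> None:
        if self.bluff_height < 0 or self.bluff_exposure < 0:
            raise ProfileError("bluff height and exposure must be >= 0")


def relative_encroachment(toe_elevation: float, datums: TidalDatums) -> float:
    """E = MHHW - toe elevation (m); positive = toe below MHHW."""
    return datums.mhhw - toe_elevation


def _first_crossing_distance(profile: ElevationProfile, level: float) -> float:
    """Cross-shore distance of the first seaward descent through ``level``.

    Scans segments seaward of the toe and linearly interpolates within the
    first bracketing segment.  If the toe itself is at or below the level the
    crossing is at the toe (zero horizontal run).
    """
    d = profile.distances
    e = profile.elevations
    i0 = profile.toe_index
    if e[i0] <= level:
        return float(d[i0])
    for i in range(i0, d.size - 1):
        if e[i] > level >= e[i + 1]:
            frac = (e[i] - level) / (e[i] - e[i + 1])
            return float(d[i] + frac * (d[i + 1] - d[i]))
    raise ProfileError(f"profile does not cross elevation {level} seaward of the toe")


def slope_toe_msl(profile: ElevationProfile, datums: TidalDatums) -> float:
    """Beach slope (m/m) from the toe down to the MSL crossing, as a
    positive magnitude."""
    if profile.toe_elevation <= datums.msl:
        raise ProfileError("profile does not cross MSL (toe at or below MSL)")
    try:
        x = _first_crossing_distance(profile, datums.msl)
    except ProfileError:
        raise ProfileError("profile does not cross MSL") from None
    run = x - profile.toe_distance
    if run <= 0:
        raise ProfileError("zero horizontal run from toe to MSL")
    return (profile.toe_elevation - datums.msl) / run


def width_toe_mllw(profile: ElevationProfile, datums: TidalDatums) -> float:
    """Horizontal beach width (m) from the toe to the first MLLW crossing."""
    if profile.toe_elevation < datums.mllw:
        raise ProfileError("toe is below MLLW; width undefined")
    x = _first_crossing_distance(profile, datums.mllw)
    return x - profile.toe_distance


def geomorph_metrics(
    profile: ElevationProfile,
    datums: TidalDatums,
    bluff_height: float,
    bluff_exposure: float,
) -> GeomorphMetrics:
    """Bundle all profile-derived metrics plus the imagery-derived
    pass-through values for one site."""
    return GeomorphMetrics(
        relative_encroachment=relative_encroachment(profile.toe_elevation, datums),
        slope_toe_msl=slope_toe_msl(profile, datums),
        width_toe_mllw=width_toe_mllw(profile, datums),
        bluff_height=bluff_height,
        bluff_exposure=bluff_exposure,
    )
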
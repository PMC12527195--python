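"""Folk & Ward grain-size statistics on the phi scale (Gradistat logarithmic
method).

A distribution is percent-by-class over a descending ladder of sieve
diameters (mm).  phi = -log2(diameter in mm), so the ladder is ascending in
phi.  The cumulative percent-coarser curve is linear in phi within each
class; percentiles are read off that curve, and the Folk & Ward graphic
statistics follow:

    mean   = (phi16 + phi50 + phi84) / 3
    sigma_I = (phi84 - phi16)/4 + (phi95 - phi5)/6.6
    Sk_I   = (phi16 + phi84 - 2 phi50)/(2 (phi84 - phi16))
             + (phi5 + phi95 - 2 phi50)/(2 (phi95 - phi5))
    K_G    = (phi95 - phi5) / (2.44 (phi75 - phi25))

The geometric ("normalized", unitless) sorting is sigma_G = 2^sigma_I >= 1,
with 1 = perfectly sorted.  Percent sand uses the Wentworth limits
0.0625-2 mm, with classes straddling a limit contributing pro-rata by their
phi-linear fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

SAND_MIN_MM = 0.0625
SAND_MAX_MM = 2.0
PCT_SUM_TOL = 0.5


class GrainSizeError(ValueError):
    pass


def phi_from_mm(diameter_mm) -> np.ndarray:
    return -np.log2(diameter_mm)


def mm_from_phi(phi) -> np.ndarray:
    return 2.0 ** (-np.asarray(phi, dtype=float))


@dataclass(frozen=True)
class GrainSizeDistribution:
    """Percent of surface area per sieve class.

    ``class_bounds`` are strictly decreasing diameters (mm).  With n+1 bounds
    there are n closed classes.  If ``percent_by_class`` has n+2 entries the
    first/last classes are open-ended and are closed one phi unit beyond the
    extreme bounds (Gradistat convention).
    """

    class_bounds: Sequence[float]  # mm, descending
    percent_by_class: Sequence[float]
    elevation_station: str = "MHHW"  # or "MLLW"
    layer: str = "surface"  # or "subsurface"

    def __post_init__(self) -> None:
        b = np.asarray(self.class_bounds, dtype=float)
        p = np.asarray(self.percent_by_class, dtype=float)
        if b.size < 2 or not np.all(np.diff(b) < 0) or np.any(b <= 0):
            raise GrainSizeError("class_bounds must be positive and strictly decreasing")
        if p.size == b.size + 1:
            # open-ended extreme classes: close one phi unit beyond each end
            b = np.concatenate(([b[0] * 2.0], b, [b[-1] / 2.0]))
        elif p.size != b.size - 1:
            raise GrainSizeError(
                f"{p.size} class percents do not match {b.size} bounds "
                "(expected n_bounds - 1 or n_bounds + 1)"
            )
        if np.any(p < 0):
            raise GrainSizeError("class percents must be >= 0")
        if abs(p.sum() - 100.0) > PCT_SUM_TOL:
            raise GrainSizeError(
                f"class percents sum to {p.sum():.2f}, outside 100 +/- {PCT_SUM_TOL}"
            )
        if self.elevation_station not in ("MHHW", "MLLW"):
            raise GrainSizeError("elevation_station must be 'MHHW' or 'MLLW'")
        if self.layer not in ("surface", "subsurface"):
            raise GrainSizeError("layer must be 'surface' or 'subsurface'")
        object.__setattr__(self, "class_bounds", b)
        object.__setattr__(self, "percent_by_class", p)

    @property
    def phi_bounds(self) -> np.ndarray:
        """Class boundaries on the phi scale, ascending."""
        return phi_from_mm(np.asarray(self.class_bounds, dtype=float))

    @property
    def cumulative_percent(self) -> np.ndarray:
        """Percent coarser than each boundary (0 at the coarsest bound)."""
        p = np.asarray(self.percent_by_class, dtype=float)
        cum = np.concatenate(([0.0], np.cumsum(p)))
        # renormalize the small rounding slack so the curve ends at 100
        return cum * (100.0 / cum[-1])


@dataclass(frozen=True)
class GrainSizeStats:
    d50: float  # mm
    mean_phi: float
    sorting_phi: float  # sigma_I
    sorting_geometric: float  # sigma_G = 2^sigma_I
    skewness: float
    kurtosis: float
    percent_sand: float
    station: str = "MHHW"
    layer: str = "surface"


def percentile_phi(dist: GrainSizeDistribution, p: float) -> float:
    """phi value at cumulative percent-coarser ``p`` by linear interpolation
    on the phi-scale cumulative curve."""
    if not 0.0 < p < 100.0:
        raise GrainSizeError(f"percentile must be in (0, 100), got {p!r}")
    cum = dist.cumulative_percent
    phis = dist.phi_bounds
    j = int(np.searchsorted(cum, p, side="left"))
    if cum[j] == p:
        return float(phis[j])
    lo, hi = j - 1, j
    frac = (p - cum[lo]) / (cum[hi] - cum[lo])
    return float(phis[lo] + frac * (phis[hi] - phis[lo]))


def folk_ward(dist: GrainSizeDistribution) -> GrainSizeStats:
    """Folk & Ward graphic statistics plus D50 and percent sand."""
    q = {p: percentile_phi(dist, p) for p in (5, 16, 25, 50, 75, 84, 95)}
    spread_inner = q[84] - q[16]
    spread_outer = q[95] - q[5]
    sigma_i = spread_inner / 4.0 + spread_outer / 6.6
    if spread_inner <= 0 or spread_outer <= 0:
        warnings.warn("degenerate grain-size distribution: zero spread", stacklevel=2)
        sigma_i = 0.0
        skew = 0.0
        kurt = 0.0
    else:
        skew = (q[16] + q[84] - 2 * q[50]) / (2 * spread_inner) + (
            q[5] + q[95] - 2 * q[50]
        ) / (2 * spread_outer)
        iqr = q[75] - q[25]
        kurt = spread_outer / (2.44 * iqr) if iqr > 0 else float("inf")
    return GrainSizeStats(
        d50=float(mm_from_phi(q[50])),
        mean_phi=(q[16] + q[50] + q[84]) / 3.0,
        sorting_phi=sigma_i,
        sorting_geometric=2.0**sigma_i,
        skewness=skew,
        kurtosis=kurt,
        percent_sand=percent_sand(dist),
        station=dist.elevation_station,
        layer=dist.layer,
    )


def percent_sand(dist: GrainSizeDistribution) -> float:
    """Summed percent within the Wentworth sand window 0.0625-2 mm, with
    straddling classes counted pro-rata by phi-linear fraction."""
    phi_lo = float(phi_from_mm(SAND_MAX_MM))  # -1
    phi_hi = float(phi_from_mm(SAND_MIN_MM))  # +4
    phis = dist.phi_bounds
    pct = np.asarray(dist.percent_by_class, dtype=float)
    pct = pct * (100.0 / pct.sum())
    a = phis[:-1]
    b = phis[1:]
    overlap = np.clip(np.minimum(b, phi_hi) - np.maximum(a, phi_lo), 0.0, None)
    frac = np.where(b > a, overlap / (b - a), 0.0)
    return float(np.sum(pct * frac))
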
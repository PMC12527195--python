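"""Deep-water fetch-limited wave hindcast (simplified SMB-type method).

Each site is assigned a design wind scenario from its shore-normal facing:
a 6 h event at 20 km/h for S/SW-facing shores (the dominant storm sector in
the Puget Sound main basin), 15 km/h for N/NE-facing shores, and 10 km/h
where strong winds are infrequent.  Significant wave height and period then
follow the Shore Protection Manual (1984) deep-water simplified relations
with the wind-stress factor U_A = 0.71 U^1.23 (U in m/s):

    Hs = 1.6e-3 (g F / U_A^2)^(1/2) U_A^2 / g      (fetch-limited)
    T  = 0.2857 (g F / U_A^2)^(1/3) U_A / g
    t_req = 68.8 (g F / U_A^2)^(2/3) U_A / g       (minimum duration)

If the stated duration is shorter than t_req the event is duration-limited
and the duration-equivalent fetch is used instead; growth is capped at the
fully developed limits Hs = 0.2433 U_A^2/g, T = 8.134 U_A/g.
"""

from __future__ import annotations

from dataclasses import dataclass

G = 9.81  # m/s^2

# Design wind sectors, degrees true.  The northerly sector wraps through 0.
SSW_SECTOR = (169.0, 214.0)
NNE_SECTOR = (349.0, 34.0)


class WaveInputError(ValueError):
    pass


@dataclass(frozen=True)
class WindScenario:
    speed_kmh: float
    duration_h: float
    basis: str  # "S/SW", "N/NE", or "infrequent"

    @property
    def speed_ms(self) -> float:
        return self.speed_kmh / 3.6


@dataclass(frozen=True)
class FetchSpec:
    fetch_distance: float  # m, along the dominant wind direction
    fetch_bearing: float = 0.0  # degrees true
    shoreline_angle: float = 90.0  # degrees between fetch vector and shoreline

    def __post_init__(self) -> None:
        if self.fetch_distance <= 0:
            raise WaveInputError("fetch_distance must be > 0")
        for name in ("fetch_bearing", "shoreline_angle"):
            v = getattr(self, name)
            if not 0.0 <= v < 360.0:
                raise WaveInputError(f"{name} must be in [0, 360), got {v!r}")


@dataclass(frozen=True)
class WaveEstimate:
    hs: float  # m, significant wave height
    period: float  # s
    regime: str  # fetch_limited | duration_limited | fully_developed


def assign_wind(facing: float) -> WindScenario:
    """Design wind scenario for a site from its facing (degrees true)."""
    if not 0.0 <= facing < 360.0:
        raise WaveInputError(f"facing must be in [0, 360), got {facing!r}")
    if SSW_SECTOR[0] <= facing <= SSW_SECTOR[1]:
        return WindScenario(20.0, 6.0, "S/SW")
    if facing >= NNE_SECTOR[0] or facing <= NNE_SECTOR[1]:
        return WindScenario(15.0, 6.0, "N/NE")
    return WindScenario(10.0, 6.0, "infrequent")


def wind_stress_factor(speed_ms: float) -> float:
    """U_A = 0.71 U^1.23 with U in m/s."""
    return 0.71 * speed_ms**1.23


def smb_wave(scenario: WindScenario, fetch: FetchSpec) -> WaveEstimate:
    """Significant wave height and period for a wind scenario over a fetch."""
    if scenario.speed_kmh < 0:
        raise WaveInputError("wind speed must be >= 0")
    if scenario.speed_kmh == 0:
        return WaveEstimate(0.0, 0.0, "fetch_limited")
    ua = wind_stress_factor(scenario.speed_ms)
    x = G * fetch.fetch_distance / ua**2  # dimensionless fetch
    t_req_s = 68.8 * x ** (2.0 / 3.0) * ua / G
    duration_s = scenario.duration_h * 3600.0
    regime = "fetch_limited"
    if duration_s < t_req_s:
        # duration-equivalent fetch: invert the minimum-duration relation
        x = (G * duration_s / (68.8 * ua)) ** 1.5
        regime = "duration_limited"
    hs = 1.6e-3 * x**0.5 * ua**2 / G
    period = 0.2857 * x ** (1.0 / 3.0) * ua / G
    hs_cap = 0.2433 * ua**2 / G
    t_cap = 8.134 * ua / G
    if hs >= hs_cap:
        hs, period, regime = hs_cap, t_cap, "fully_developed"
    return WaveEstimate(hs, period, regime)


def required_duration_h(scenario: WindScenario, fetch: FetchSpec) -> float:
    """Minimum event duration (h) for the fetch-limited estimate to hold."""
    ua = wind_stress_factor(scenario.speed_ms)
    x = G * fetch.fetch_distance / ua**2
    return 68.8 * x ** (2.0 / 3.0) * ua / G / 3600.0


def fetch_for_height(scenario: WindScenario, hs_target: float) -> float:
    """Fetch (m) at which the fetch-limited Hs equals ``hs_target``.

    Used by the synthetic-data generator to place sites so the hindcast
    reproduces a configured wave height.  Raises if the target exceeds what
    the scenario can raise within its stated duration (duration-limited) or
    the fully developed cap.
    """
    if hs_target <= 0:
        raise WaveInputError("hs_target must be > 0")
    ua = wind_stress_factor(scenario.speed_ms)
    if hs_target >= 0.2433 * ua**2 / G:
        raise WaveInputError(
            f"target Hs {hs_target} m exceeds the fully developed cap for "
            f"{scenario.speed_kmh} km/h"
        )
    x = (hs_target * G / (1.6e-3 * ua**2)) ** 2
    fetch_m = x * ua**2 / G
    t_req = 68.8 * x ** (2.0 / 3.0) * ua / G / 3600.0
    if t_req > scenario.duration_h:
        raise WaveInputError(
            f"target Hs {hs_target} m needs {t_req:.1f} h of wind at "
            f"{scenario.speed_kmh} km/h; the scenario provides "
            f"{scenario.duration_h} h"
        )
    return fetch_m
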
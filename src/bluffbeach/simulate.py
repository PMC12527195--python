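"""Synthetic survey campaign generator.

Emulates the study design: 4 treatments x 5 regions x 1 site, with the
configured treatment-mean structure for all 30 metrics (packaged defaults),
mean-zero region random effects shared by the sites of a region, and
replicate-level noise matched to each data type: logit-normal for bounded
percentages, negative-binomial (NB2, var = mu(1 + theta mu); theta = 0 gives
Poisson) for counts, and weighted taxon selection + multinomial allocation
for assemblage composition.  Every draw flows from a single integer seed.

Replicate counts default to the field protocol (10 wrack quadrats, 5 log
points, 4 snorkel transects x 2 seasons, 7 fallout traps, 10 MLLW quadrats,
1 vegetation transect) and are scalable in config, which is how
law-of-large-numbers recovery of the configured means is exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm
from scipy.optimize import brentq

from .dataset import SurveyDataset
from .geomorph import TidalDatums
from .grainsize import GrainSizeDistribution, mm_from_phi
from .records import REGIONS, TREATMENTS
from .waves import WindScenario, assign_wind, fetch_for_height


class SimulationError(ValueError):
    pass


TREATMENT_CODES = {
    "ProtectHigh": "PH",
    "ProtectLow": "PL",
    "RestoreHigh": "RH",
    "RestoreLow": "RL",
}

#: Metrics simulated on the logit scale (bounded percentages).
PERCENT_METRICS = frozenset(
    {
        "% Wrack Cover",
        "% Terrestrial Wrack",
        "% Overhanging Vegetation",
        "% Supratidal Vegetation",
        "% Eelgrass",
        "Juv. Salmon Feeding Observations (%)",
        "% Sand MHHW",
        "% Sand MLLW",
    }
)
#: Metrics with additive region effects (signed, in metres).
ADDITIVE_METRICS = frozenset({"Relative Encroachment (m)"})

FALLOUT_TAXA = (
    "acari",
    "collembola",
    "diptera",
    "hemiptera",
    "hymenoptera",
    "coleoptera",
    "araneae",
    "amphipoda",
)
#: Arthropod groups that do not fly (mites, springtails, spiders, beach hoppers).
NON_FLYING_TAXA = frozenset({"acari", "collembola", "araneae", "amphipoda"})

# Per-treatment fallout composition.  Protect sites are insect-dominated
# (salmon prey: flies, true bugs, wasps/bees/ants); Restore Low is dominated
# by non-flying mites and springtails.
FALLOUT_PROFILES = {
    "ProtectHigh": (0.12, 0.05, 0.30, 0.16, 0.20, 0.09, 0.05, 0.03),
    "ProtectLow": (0.12, 0.05, 0.30, 0.16, 0.20, 0.09, 0.05, 0.03),
    "RestoreHigh": (0.25, 0.15, 0.25, 0.12, 0.10, 0.05, 0.05, 0.03),
    "RestoreLow": (0.60, 0.28, 0.05, 0.03, 0.02, 0.005, 0.01, 0.005),
}

MLLW_TAXA = (
    "eelgrass",
    "ulva",
    "fucus",
    "barnacle",
    "littorina",
    "hermit_crab",
    "shore_crab",
    "oyster",
    "mussel",
    "sand_dollar",
)
MLLW_PROFILES = {
    "ProtectHigh": (0.08, 0.18, 0.14, 0.18, 0.14, 0.10, 0.08, 0.04, 0.04, 0.02),
    "ProtectLow": (0.08, 0.18, 0.14, 0.18, 0.14, 0.10, 0.08, 0.04, 0.04, 0.02),
    "RestoreHigh": (0.06, 0.22, 0.10, 0.22, 0.12, 0.10, 0.08, 0.04, 0.04, 0.02),
    "RestoreLow": (0.30, 0.22, 0.06, 0.14, 0.10, 0.06, 0.05, 0.03, 0.02, 0.02),
}

NATIVE_SPECIES_POOL = tuple(
    f"native_sp_{i:02d}" for i in range(1, 26)
)
INTRODUCED_SPECIES = ("himalayan_blackberry", "english_ivy", "scotch_broom")

#: Salmon observation events per snorkel transect, by treatment (derived from
#: the observed event totals over 5 sites x 8 transects).
EVENTS_PER_TRANSECT = {
    "ProtectHigh": 0.4,
    "ProtectLow": 0.175,
    "RestoreHigh": 0.25,
    "RestoreLow": 0.3,
}


def _default_replicates() -> dict:
    return {
        "wrack": 10,
        "log_points": 5,
        "snorkel": 4,  # transects per season; two seasons are always simulated
        "fallout": 7,
        "mllw": 10,
        "veg": 1,
    }


def default_treatment_means() -> pd.DataFrame:
    from .io import load_table1

    return load_table1()


@dataclass
class SimulationConfig:
    """Knobs for the synthetic campaign.

    ``treatment_means`` is a metrics x treatments table (packaged survey
    averages by default).  ``region_sd`` scales the shared region random
    effect: lognormal sigma for positive metrics, logit shift for
    percentages, metres for relative encroachment.  ``within_cv`` /
    ``logit_sd`` control replicate-level noise of continuous / percentage
    draws, and ``dispersion`` is the NB2 theta for counts.  Setting all four
    to zero removes every noise source except counting (Poisson) noise.
    """

    treatment_means: pd.DataFrame | None = None
    region_sd: float = 0.15
    within_cv: float = 0.35
    logit_sd: float = 0.6
    dispersion: float = 0.7
    replicates: dict = field(default_factory=_default_replicates)
    datums: TidalDatums = field(default_factory=lambda: TidalDatums(3.0, 1.5, 0.0))
    fallout_profiles: dict = field(default_factory=lambda: dict(FALLOUT_PROFILES))
    mllw_profiles: dict = field(default_factory=lambda: dict(MLLW_PROFILES))
    events_per_transect: dict = field(default_factory=lambda: dict(EVENTS_PER_TRANSECT))
    transect_length_m: float = 75.0
    visibility_m: float = 2.0
    trap_area_m2: float = 0.10
    quadrat_area_m2: float = 0.25
    veg_transect_length_m: float = 50.0
    ladder_phi_step: float = 0.25
    ladder_phi_range: tuple = (-9.0, 5.0)
    profile_noise_m: float = 0.0

    def __post_init__(self) -> None:
        if self.treatment_means is None:
            self.treatment_means = default_treatment_means()
        for name, profiles in (("fallout", self.fallout_profiles), ("mllw", self.mllw_profiles)):
            for treat, p in profiles.items():
                if abs(sum(p) - 1.0) > 1e-6 or min(p) < 0:
                    raise SimulationError(
                        f"{name} composition for {treat} is not a probability vector"
                    )
        for v in (self.region_sd, self.within_cv, self.logit_sd, self.dispersion):
            if v < 0:
                raise SimulationError("noise scales must be >= 0")

    def mean(self, treatment: str, metric: str) -> float:
        return float(self.treatment_means.loc[metric, treatment])


# ---------------------------------------------------------------------------
# elementary noise draws
# ---------------------------------------------------------------------------

def _lognormal_mean(rng, mean: float, cv: float, size) -> np.ndarray:
    """Lognormal draws parameterized by mean and CV (mean-preserving)."""
    if mean <= 0:
        return np.zeros(size)
    if cv <= 0:
        return np.full(size, mean)
    s2 = np.log1p(cv**2)
    return rng.lognormal(np.log(mean) - s2 / 2.0, np.sqrt(s2), size)

def _logit_normal(rng, pct: float, sd: float, size) -> np.ndarray:
    """Percent draws on the logit scale around a median of ``pct``."""
    if pct <= 0:
        return np.zeros(size)
    if pct >= 100:
        return np.full(size, 100.0)
    if sd <= 0:
        return np.full(size, pct)
    return expit(rng.normal(logit(pct / 100.0), sd, size)) * 100.0

def _nb(rng, mean, theta: float, size) -> np.ndarray:
    """NB2 counts with var = mean (1 + theta mean); theta = 0 is Poisson.
    ``mean`` may be a scalar or an array broadcastable to ``size``."""
    shape = (size,) if np.isscalar(size) else tuple(size)
    mu = np.broadcast_to(np.asarray(mean, dtype=float), shape)
    out = np.zeros(shape, dtype=np.int64)
    pos = mu > 0
    if not pos.any():
        return out
    if theta <= 0:
        out[pos] = rng.poisson(mu[pos])
    else:
        n = 1.0 / theta
        out[pos] = rng.negative_binomial(n, n / (n + mu[pos]))
    return out

def _stoch_round(rng, mean: float, size) -> np.ndarray:
    """Integer draws whose expectation is exactly ``mean`` (floor + Bernoulli)."""
    if mean <= 0:
        return np.zeros(size, dtype=np.int64)
    base = int(np.floor(mean))
    return base + (rng.random(size) < (mean - base)).astype(np.int64)


# ---------------------------------------------------------------------------
# site expectations (treatment mean + region effect)
# ---------------------------------------------------------------------------

def site_expectations(cfg: SimulationConfig, rng) -> pd.DataFrame:
    """One row per site with its expected value for every metric.

    Region effects are drawn once per (region, metric) and shared by the
    region's four sites: lognormal multipliers for positive metrics, logit
    shifts for percentages, additive (m) for encroachment.
    """
    metrics = list(cfg.treatment_means.index)
    z = rng.normal(0.0, 1.0, size=(len(REGIONS), len(metrics)))
    rows = []
    for ri, region in enumerate(REGIONS):
        for treatment in TREATMENTS:
            sid = f"{region}_{TREATMENT_CODES[treatment]}"
            row = {"site_id": sid, "treatment": treatment, "region": region}
            for mi, m in enumerate(metrics):
                base = cfg.mean(treatment, m)
                eff = z[ri, mi] * cfg.region_sd
                if m in ADDITIVE_METRICS:
                    val = base + eff
                elif m in PERCENT_METRICS:
                    if base <= 0 or base >= 100 or cfg.region_sd == 0:
                        val = base
                    else:
                        val = float(expit(logit(base / 100.0) + eff) * 100.0)
                else:
                    val = base * float(np.exp(eff)) if cfg.region_sd > 0 else base
                row[m] = val
            rows.append(row)
    return pd.DataFrame(rows).set_index("site_id")


# ---------------------------------------------------------------------------
# per-stream generators
# ---------------------------------------------------------------------------

def _gen_wrack(cfg, rng, exp_row) -> pd.DataFrame:
    n = cfg.replicates["wrack"]
    cover = _logit_normal(rng, exp_row["% Wrack Cover"], cfg.logit_sd, n)
    mu_cov = exp_row["% Wrack Cover"]
    terr_frac_mu = (exp_row["% Terrestrial Wrack"] / mu_cov * 100.0) if mu_cov > 0 else 0.0
    terr_frac = _logit_normal(rng, min(terr_frac_mu, 100.0), cfg.logit_sd, n) / 100.0
    terr = cover * terr_frac
    rem = cover - terr
    return pd.DataFrame(
        {
            "quadrat": np.arange(1, n + 1),
            "pct_cover_total": cover,
            "pct_algae": 0.7 * rem,
            "pct_eelgrass": 0.2 * rem,
            "pct_terrestrial": terr,
            "wrack_width_m": _lognormal_mean(rng, exp_row["Wrack Width (m)"], cfg.within_cv, n),
            "wrack_depth_cm": _lognormal_mean(rng, exp_row["Wrack Depth (cm)"], cfg.within_cv, n),
        }
    )


def _gen_logs(cfg, rng, exp_row) -> pd.DataFrame:
    n = cfg.replicates["log_points"]
    mu_log = exp_row["Log Count"]
    log_count = _nb(rng, mu_log, cfg.dispersion, n)
    p_buried = min(exp_row["Count Partially Buried Logs"] / mu_log, 1.0) if mu_log > 0 else 0.0
    return pd.DataFrame(
        {
            "point": np.arange(1, n + 1),
            "log_count": log_count,
            "buried_count": rng.binomial(log_count, p_buried),
            "log_line_width_m": _lognormal_mean(
                rng, exp_row["Width of Log Line (m)"], cfg.within_cv, n
            ),
            # repeated-census observation noise: drawn per survey pass
            "fallen_trees": _nb(rng, exp_row["Fallen Tree Count"], cfg.dispersion, n),
        }
    )


def _gen_snorkel(cfg, rng, exp_row, treatment) -> pd.DataFrame:
    n = cfg.replicates["snorkel"]
    frames = []
    for season in ("spring", "summer"):
        vis = _lognormal_mean(rng, cfg.visibility_m, cfg.within_cv * 0.3, n)
        area = cfg.transect_length_m * vis
        counts = {}
        for col, metric in (
            ("count_total_fish", "Total Fish Density (100m-2)"),
            ("count_juv_salmon", "Juvenile Salmon Density (100m-2)"),
            ("count_forage_fish", "Forage Fish Density (100m-2)"),
        ):
            mu = exp_row[metric] * area / 100.0
            counts[col] = _nb(rng, mu, cfg.dispersion, n)
        events = rng.poisson(cfg.events_per_transect[treatment], n)
        feeding = rng.binomial(
            events, exp_row["Juv. Salmon Feeding Observations (%)"] / 100.0
        )
        frames.append(
            pd.DataFrame(
                {
                    "season": season,
                    "transect": np.arange(1, n + 1),
                    "transect_length_m": cfg.transect_length_m,
                    "visibility_m": vis,
                    **counts,
                    "count_other": _nb(rng, 1.5, cfg.dispersion, n),
                    "feeding_observed": feeding,
                    "salmon_observation_events": events,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _choose_taxa(rng, probs: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Boolean (n_samples, n_taxa) mask choosing r[i] taxa per sample,
    weighted by ``probs`` (Gumbel top-k sampling without replacement)."""
    n, k = r.size, probs.size
    with np.errstate(divide="ignore"):
        keys = np.log(probs)[None, :] + rng.gumbel(size=(n, k))
    rank = np.argsort(np.argsort(-keys, axis=1), axis=1)
    return rank < r[:, None]


def _gen_fallout(cfg, rng, exp_row, treatment):
    n = cfg.replicates["fallout"]
    probs = np.asarray(cfg.fallout_profiles[treatment], dtype=float)
    mu_rich = exp_row["Fallout Trap Taxa Richness"]
    mu_total = exp_row["Fallout Trap Density (m-2)"] * cfg.trap_area_m2
    r = np.clip(_stoch_round(rng, mu_rich, n), 0, len(FALLOUT_TAXA))
    chosen = _choose_taxa(rng, probs, r)
    extra_mu = max(mu_total - mu_rich, 0.0)
    extra = _nb(rng, extra_mu, cfg.dispersion, n)
    pvals = np.where(chosen, probs[None, :], 0.0)
    rowsum = pvals.sum(axis=1, keepdims=True)
    pvals = np.where(rowsum > 0, pvals / np.where(rowsum > 0, rowsum, 1.0), 1.0 / len(FALLOUT_TAXA))
    alloc = rng.multinomial(np.where(r > 0, extra, 0), pvals)
    counts = chosen.astype(np.int64) + alloc
    traps = pd.DataFrame(
        {
            "trap": np.arange(1, n + 1),
            "trap_area_m2": cfg.trap_area_m2,
            "deploy_hours": 2.0,
        }
    )
    ti, xi = np.nonzero(counts)
    long = pd.DataFrame(
        {
            "trap": ti + 1,
            "taxon": np.asarray(FALLOUT_TAXA, dtype=object)[xi],
            "count": counts[ti, xi],
        }
    )
    return traps, long


def _gen_mllw(cfg, rng, exp_row, treatment):
    n = cfg.replicates["mllw"]
    probs = np.asarray(cfg.mllw_profiles[treatment], dtype=float)
    eel = _logit_normal(rng, exp_row["% Eelgrass"], cfg.logit_sd, n)
    r = np.clip(_stoch_round(rng, exp_row["Biota Taxa Richness"], n), 1, len(MLLW_TAXA))
    chosen = _choose_taxa(rng, probs, r)
    covers = np.where(
        chosen, np.clip(_lognormal_mean(rng, 12.0, max(cfg.within_cv, 0.05), (n, len(MLLW_TAXA))), 0.5, 100.0), 0.0
    )
    eel_col = MLLW_TAXA.index("eelgrass")
    covers[:, eel_col] = np.where(chosen[:, eel_col], np.maximum(eel, 0.5), 0.0)
    quads = pd.DataFrame(
        {
            "quadrat": np.arange(1, n + 1),
            "quadrat_area_m2": cfg.quadrat_area_m2,
            "eelgrass_percent": eel,
        }
    )
    qi, xi = np.nonzero(covers)
    long = pd.DataFrame(
        {
            "quadrat": qi + 1,
            "taxon": np.asarray(MLLW_TAXA, dtype=object)[xi],
            "percent_cover": covers[qi, xi],
        }
    )
    return quads, long


def _gen_vegetation(cfg, rng, exp_row):
    n = cfg.replicates["veg"]
    L = cfg.veg_transect_length_m
    veg_rows, ov_rows, dg_rows, sp_rows = [], [], [], []
    for t in range(1, n + 1):
        ov_len = _logit_normal(rng, exp_row["% Overhanging Vegetation"], cfg.logit_sd, 1)[0] / 100.0 * L
        veg_rows.append(
            {
                "transect": t,
                "transect_length_m": L,
                "supratidal_percent": _logit_normal(
                    rng, exp_row["% Supratidal Vegetation"], cfg.logit_sd, 1
                )[0],
            }
        )
        if ov_len > 0:
            ov_rows.append({"transect": t, "start_m": 0.0, "end_m": 0.6 * ov_len})
            if ov_len * 0.4 > 1e-12:
                ov_rows.append({"transect": t, "start_m": L - 0.4 * ov_len, "end_m": L})
        mu_dg = exp_row["Dunegrass Patch Width (m)"]
        if mu_dg > 0:
            for w in _lognormal_mean(rng, mu_dg, cfg.within_cv, 3):
                dg_rows.append({"transect": t, "patch_width_m": w})
        r = int(np.clip(_stoch_round(rng, exp_row["Native Vegetation Taxa Richness"], 1)[0], 0, len(NATIVE_SPECIES_POOL)))
        for sp in rng.choice(NATIVE_SPECIES_POOL, size=r, replace=False):
            sp_rows.append({"transect": t, "species": sp, "status": "native"})
        for sp in INTRODUCED_SPECIES:
            sp_rows.append({"transect": t, "species": sp, "status": "introduced"})
    return (
        pd.DataFrame(veg_rows),
        pd.DataFrame(ov_rows, columns=["transect", "start_m", "end_m"]),
        pd.DataFrame(dg_rows, columns=["transect", "patch_width_m"]),
        pd.DataFrame(sp_rows, columns=["transect", "species", "status"]),
    )


# ---------------------------------------------------------------------------
# physical streams
# ---------------------------------------------------------------------------

def build_profile_points(
    encroachment: float, slope: float, width: float, datums: TidalDatums,
) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-linear cross-shore profile realizing the target
    encroachment, toe-MSL slope, and toe-MLLW width."""
    toe = datums.mhhw - encroachment
    if toe <= datums.mllw:
        raise SimulationError(
            f"infeasible geometry: toe elevation {toe:.2f} m is at or below MLLW"
        )
    if slope <= 0 or width <= 0:
        raise SimulationError("slope and width must be > 0")
    if toe <= datums.msl:
        raise SimulationError("toe at or below MSL; upper-beach slope undefined")
    x_msl = (toe - datums.msl) / slope
    if x_msl >= width:
        raise SimulationError(
            f"infeasible geometry: MSL crossing at {x_msl:.1f} m is beyond the "
            f"{width:.1f} m MLLW width"
        )
    xs = np.array([0.0, x_msl, width, width + 5.0])
    es = np.array([toe, datums.msl, datums.mllw, datums.mllw - 0.5])
    return xs, es


def simulate_profiles(cfg: SimulationConfig, seed: int | None = None,
                      expectations: pd.DataFrame | None = None) -> pd.DataFrame:
    """Elevation profiles (long format) for every site.

    Optional seeded noise perturbs interior elevations by
    ``cfg.profile_noise_m``; the toe point is never perturbed.
    """
    rng = np.random.default_rng(seed)
    if expectations is None:
        expectations = site_expectations(cfg, rng)
    rows = []
    for sid, exp_row in expectations.iterrows():
        xs, es = build_profile_points(
            exp_row["Relative Encroachment (m)"],
            exp_row["Beach Slope (m/m) Toe-MSL"],
            exp_row["Beach Width (m) Toe-MLLW"],
            cfg.datums,
        )
        if cfg.profile_noise_m > 0:
            es = es + np.concatenate(([0.0], rng.normal(0, cfg.profile_noise_m, es.size - 1)))
        for x, e in zip(xs, es):
            rows.append({"site_id": sid, "distance_m": x, "elevation_m": e})
    return pd.DataFrame(rows)


_Z84 = float(norm.ppf(0.84))
_Z95 = float(norm.ppf(0.95))
#: sigma_I of a unit-sd normal phi distribution under the Folk & Ward formula.
_FW_FACTOR = _Z84 / 2.0 + _Z95 / 3.3

SAND_PHI = (-1.0, 4.0)  # 2 mm .. 0.0625 mm


def simulate_grainsize(
    percent_sand: float,
    sorting_geometric: float,
    ladder_phi: np.ndarray | None = None,
    station: str = "MHHW",
    layer: str = "surface",
) -> GrainSizeDistribution:
    """Grain-size distribution tuned so the Folk & Ward statistics recover
    the target geometric sorting and percent sand.

    The distribution is a normal on the phi scale: its sd is set from the
    sorting target via the Folk & Ward percentile formula, and its mean is
    solved (coarse branch) so the mass inside the Wentworth sand window
    matches the sand target.  Discretized onto the class ladder.
    """
    if sorting_geometric <= 1.0:
        raise SimulationError("sorting target must be > 1 (sigma_G = 1 is zero spread)")
    if not 0.0 < percent_sand < 100.0:
        raise SimulationError("percent sand target must be in (0, 100)")
    s = float(np.log2(sorting_geometric)) / _FW_FACTOR
    if ladder_phi is None:
        # dyadic refinement keeps the Wentworth sand bounds (integer phi) on
        # the grid while resolving well-sorted (small-spread) targets
        step = 0.25
        while step > s / 3.0:
            step /= 2.0
        ladder_phi = np.arange(-9.0, 5.0 + 1e-9, step)
    ladder_phi = np.asarray(ladder_phi, dtype=float)
    q = percent_sand / 100.0

    def sand_mass(mu: float) -> float:
        return norm.cdf((SAND_PHI[1] - mu) / s) - norm.cdf((SAND_PHI[0] - mu) / s)

    mu_center = (SAND_PHI[0] + SAND_PHI[1]) / 2.0
    if sand_mass(mu_center) < q:
        raise SimulationError(
            f"targets unattainable: sigma_G={sorting_geometric} caps sand at "
            f"{sand_mass(mu_center) * 100:.1f}% < {percent_sand}%"
        )
    mu = brentq(lambda m: sand_mass(m) - q, ladder_phi[0], mu_center)
    cdf = norm.cdf((ladder_phi - mu) / s)
    pct = np.diff(cdf)
    pct[0] += cdf[0]
    pct[-1] += 1.0 - cdf[-1]
    pct = pct / pct.sum() * 100.0
    bounds_mm = mm_from_phi(ladder_phi)
    return GrainSizeDistribution(bounds_mm, pct, elevation_station=station, layer=layer)


def _gen_grainsize_frame(cfg, expectations: pd.DataFrame) -> pd.DataFrame:
    ladder = np.arange(
        cfg.ladder_phi_range[0], cfg.ladder_phi_range[1] + 1e-9, cfg.ladder_phi_step
    )
    bounds_mm = mm_from_phi(ladder)
    cols = [
        f"pct_{hi:g}_{lo:g}mm" for hi, lo in zip(bounds_mm[:-1], bounds_mm[1:])
    ]
    rows = []
    for sid, exp_row in expectations.iterrows():
        for station in ("MHHW", "MLLW"):
            dist = simulate_grainsize(
                float(np.clip(exp_row[f"% Sand {station}"], 1.0, 99.0)),
                max(float(exp_row[f"Normalized Sorting {station}"]), 1.05),
                ladder,
                station=station,
            )
            for layer in ("surface", "subsurface"):
                row = {"site_id": sid, "station": station, "layer": layer}
                row.update(dict(zip(cols, dist.percent_by_class)))
                rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full campaign
# ---------------------------------------------------------------------------

def simulate_sites(cfg: SimulationConfig | None = None, seed: int = 0) -> SurveyDataset:
    """Generate the complete record set for the 20-site campaign."""
    cfg = cfg if cfg is not None else SimulationConfig()
    rng = np.random.default_rng(seed)
    exp = site_expectations(cfg, rng)

    site_rows = []
    frames: dict[str, list[pd.DataFrame]] = {
        k: []
        for k in (
            "wrack",
            "logs",
            "snorkel",
            "fallout_traps",
            "fallout_counts",
            "mllw_quadrats",
            "mllw_covers",
            "vegetation",
            "overhang_intervals",
            "dunegrass_patches",
            "veg_species",
        )
    }
    wind_rows = []
    for sid, exp_row in exp.iterrows():
        treatment = exp_row["treatment"]
        facing = float(rng.uniform(171.0, 212.0))
        scenario = assign_wind(facing)
        # a 6 h 20 km/h event cannot raise more than ~0.61 m; clamp jittered
        # region targets below that so fetch inversion stays feasible
        hs_target = float(min(exp_row["Wave Height (m)"], 0.60))
        fetch_m = fetch_for_height(scenario, hs_target)
        site_rows.append(
            {
                "site_id": sid,
                "treatment": treatment,
                "region": exp_row["region"],
                "facing_degrees": facing,
                "bluff_height_m": float(exp_row["Bluff Height (m)"]),
                "bluff_exposure_m2": float(exp_row["Bluff Exposure (m2)"]),
                "toe_index": 0,
            }
        )
        wind_rows.append(
            {
                "site_id": sid,
                "fetch_m": fetch_m,
                "shoreline_angle_deg": float(rng.uniform(60.0, 85.0)),
            }
        )
        adders = {
            "wrack": _gen_wrack(cfg, rng, exp_row),
            "logs": _gen_logs(cfg, rng, exp_row),
            "snorkel": _gen_snorkel(cfg, rng, exp_row, treatment),
        }
        traps, fallout_long = _gen_fallout(cfg, rng, exp_row, treatment)
        quads, mllw_long = _gen_mllw(cfg, rng, exp_row, treatment)
        veg, ov, dg, sp = _gen_vegetation(cfg, rng, exp_row)
        adders.update(
            fallout_traps=traps,
            fallout_counts=fallout_long,
            mllw_quadrats=quads,
            mllw_covers=mllw_long,
            vegetation=veg,
            overhang_intervals=ov,
            dunegrass_patches=dg,
            veg_species=sp,
        )
        for key, frame in adders.items():
            frame = frame.copy()
            frame.insert(0, "site_id", sid)
            frames[key].append(frame)

    profiles = simulate_profiles(cfg, seed=int(rng.integers(2**31)), expectations=exp)
    grain = _gen_grainsize_frame(cfg, exp)

    def cat(key):
        parts = [p for p in frames[key] if len(p)] or frames[key][:1]
        return pd.concat(parts, ignore_index=True)

    return SurveyDataset(
        sites=pd.DataFrame(site_rows),
        wind_fetch=pd.DataFrame(wind_rows),
        wrack=cat("wrack"),
        logs=cat("logs"),
        snorkel=cat("snorkel"),
        fallout_traps=cat("fallout_traps"),
        fallout_counts=cat("fallout_counts"),
        mllw_quadrats=cat("mllw_quadrats"),
        mllw_covers=cat("mllw_covers"),
        vegetation=cat("vegetation"),
        overhang_intervals=cat("overhang_intervals"),
        dunegrass_patches=cat("dunegrass_patches"),
        veg_species=cat("veg_species"),
        profiles=profiles,
        grainsize=grain,
    )


def noise_free_config(replicates: dict | None = None) -> SimulationConfig:
    """Config with every noise scale at zero (counts become Poisson), used
    for law-of-large-numbers recovery of the configured treatment means."""
    cfg = SimulationConfig(
        region_sd=0.0, within_cv=0.0, logit_sd=0.0, dispersion=0.0
    )
    if replicates:
        cfg.replicates.update(replicates)
    return cfg
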
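"""Aggregation of raw survey records into the 30 site-level metrics.

Site-level metric values are unweighted means over within-site replicates
(quadrats, transects, traps, survey points); the two snorkel seasons are
pooled into one site value.  Missing data stay missing (NaN), never zero.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import geomorph as gm
from . import grainsize as gs
from . import waves as wv
from .dataset import SurveyDataset
from .records import (
    TREATMENTS,
    FalloutTrapSample,
    RecordError,
    SnorkelTransect,
    VegetationTransect,
    WrackQuadrat,
)

#: The 30 site metrics, in scale-bar order.
METRIC_NAMES = (
    "% Wrack Cover",
    "% Terrestrial Wrack",
    "Wrack Depth (cm)",
    "Wrack Width (m)",
    "Log Count",
    "Width of Log Line (m)",
    "Count Partially Buried Logs",
    "Fallen Tree Count",
    "Total Fish Density (100m-2)",
    "Juvenile Salmon Density (100m-2)",
    "Forage Fish Density (100m-2)",
    "Juv. Salmon Feeding Observations (%)",
    "% Overhanging Vegetation",
    "% Supratidal Vegetation",
    "Dunegrass Patch Width (m)",
    "Native Vegetation Taxa Richness",
    "Fallout Trap Taxa Richness",
    "Fallout Trap Density (m-2)",
    "Biota Taxa Richness",
    "% Eelgrass",
    "Beach Slope (m/m) Toe-MSL",
    "Beach Width (m) Toe-MLLW",
    "Bluff Height (m)",
    "Bluff Exposure (m2)",
    "Relative Encroachment (m)",
    "Wave Height (m)",
    "% Sand MHHW",
    "% Sand MLLW",
    "Normalized Sorting MHHW",
    "Normalized Sorting MLLW",
)


class AggregationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# record-level operations
# ---------------------------------------------------------------------------

def aggregate_wrack(quadrats: Sequence[WrackQuadrat]):
    """Mean wrack metrics over a site's quadrats.

    Returns (% total cover, % terrestrial, depth cm, width m).
    """
    if not quadrats:
        raise AggregationError("no quadrats for site")
    return (
        float(np.mean([q.percent_cover_total for q in quadrats])),
        float(np.mean([q.percent_terrestrial for q in quadrats])),
        float(np.mean([q.wrack_depth for q in quadrats])),
        float(np.mean([q.wrack_width for q in quadrats])),
    )


def fish_density(count: int, transect_length: float, visibility: float) -> float:
    """Convert a transect count to a density per 100 m^2.

    The sampled area is transect length x horizontal Secchi visibility.
    """
    if transect_length <= 0 or visibility <= 0:
        raise AggregationError("transect_length and visibility must be > 0")
    if count < 0:
        raise AggregationError("count must be >= 0")
    return count / (transect_length * visibility) * 100.0


def fallout_density(sample: FalloutTrapSample):
    """(individuals per m^2, taxa richness) for one fallout trap."""
    total = sum(sample.counts_by_taxon.values())
    richness = sum(1 for c in sample.counts_by_taxon.values() if c > 0)
    return total / sample.trap_area, richness


def overhang_percent(t: VegetationTransect) -> float:
    """Percent of the transect overlain by overhanging vegetation (union of
    intervals; overlaps are not double-counted)."""
    if not t.overhang_intervals:
        return 0.0
    ivals = sorted((float(a), float(b)) for a, b in t.overhang_intervals)
    total = 0.0
    cur_a, cur_b = ivals[0]
    for a, b in ivals[1:]:
        if a > cur_b:
            total += cur_b - cur_a
            cur_a, cur_b = a, b
        else:
            cur_b = max(cur_b, b)
    total += cur_b - cur_a
    return total / t.transect_length * 100.0


def feeding_contingency(
    transects: Iterable[SnorkelTransect],
    treatment_of: Mapping[str, str],
) -> pd.DataFrame:
    """2 x 4 contingency table of salmon feeding vs not-feeding observations
    by treatment, from snorkel transects."""
    feeding = dict.fromkeys(TREATMENTS, 0)
    not_feeding = dict.fromkeys(TREATMENTS, 0)
    seen = set()
    for t in transects:
        try:
            treat = treatment_of[t.site_id]
        except KeyError:
            raise AggregationError(f"site {t.site_id!r} has no treatment") from None
        if treat not in TREATMENTS:
            raise RecordError(f"unknown treatment label {treat!r}")
        feeding[treat] += t.feeding_observed
        not_feeding[treat] += t.salmon_observation_events - t.feeding_observed
        seen.add(treat)
    missing = [t for t in TREATMENTS if t not in seen]
    if missing:
        raise AggregationError(f"no snorkel records for treatment(s): {missing}")
    return pd.DataFrame(
        [[feeding[t] for t in TREATMENTS], [not_feeding[t] for t in TREATMENTS]],
        index=["feeding", "not_feeding"],
        columns=list(TREATMENTS),
    )


def build_site_metric_table(site_metrics: Mapping[str, Mapping[str, float]]) -> pd.DataFrame:
    """Assemble per-site metric dicts into the canonical sites x 30 table.

    Every row carries the full, fixed metric column set; metrics a site did
    not supply are explicit NaN.  Duplicate site ids are rejected.
    """
    ids = list(site_metrics)
    if len(ids) != len(set(ids)):
        raise AggregationError("duplicate site ids")
    rows = {}
    for sid, metrics in site_metrics.items():
        unknown = set(metrics) - set(METRIC_NAMES)
        if unknown:
            raise AggregationError(f"unknown metric names for {sid!r}: {sorted(unknown)}")
        rows[sid] = {name: metrics.get(name, np.nan) for name in METRIC_NAMES}
    table = pd.DataFrame.from_dict(rows, orient="index", dtype=float)
    table = table[list(METRIC_NAMES)]
    table.index.name = "site_id"
    return table


# ---------------------------------------------------------------------------
# dataset-level aggregation (vectorized over all sites)
# ---------------------------------------------------------------------------

def parse_grainsize_columns(columns) -> tuple[list[str], np.ndarray]:
    """Extract ``pct_<hi>_<lo>mm`` columns and the descending mm ladder."""
    pct_cols = [c for c in columns if c.startswith("pct_")]
    if not pct_cols:
        raise AggregationError("no pct_<hi>_<lo>mm grain-size columns found")
    bounds = []
    for c in pct_cols:
        hi, lo = c[4:].removesuffix("mm").split("_")
        bounds.append((float(hi), float(lo)))
    ladder = [bounds[0][0]] + [b[1] for b in bounds]
    arr = np.asarray(ladder, dtype=float)
    for (hi, lo), top, bot in zip(bounds, arr[:-1], arr[1:]):
        if hi != top:
            raise AggregationError("grain-size class columns are not contiguous")
    return pct_cols, arr


def _grainsize_metrics(grainsize: pd.DataFrame) -> pd.DataFrame:
    pct_cols, ladder = parse_grainsize_columns(grainsize.columns)
    out = {}
    surface = grainsize[grainsize["layer"] == "surface"]
    for (sid, station), grp in surface.groupby(["site_id", "station"], sort=False):
        pct = grp[pct_cols].mean(axis=0).to_numpy(dtype=float)
        dist = gs.GrainSizeDistribution(ladder, pct, elevation_station=station)
        stats = gs.folk_ward(dist)
        rec = out.setdefault(sid, {})
        rec[f"% Sand {station}"] = stats.percent_sand
        rec[f"Normalized Sorting {station}"] = stats.sorting_geometric
    return pd.DataFrame.from_dict(out, orient="index")


def _geomorph_metrics(ds: SurveyDataset, datums: gm.TidalDatums) -> pd.DataFrame:
    toe_index = ds.sites.set_index("site_id")["toe_index"]
    out = {}
    for sid, grp in ds.profiles.groupby("site_id", sort=False):
        profile = gm.ElevationProfile(
            grp["distance_m"].to_numpy(),
            grp["elevation_m"].to_numpy(),
            toe_index=int(toe_index[sid]),
        )
        out[sid] = {
            "Relative Encroachment (m)": gm.relative_encroachment(
                profile.toe_elevation, datums
            ),
            "Beach Slope (m/m) Toe-MSL": gm.slope_toe_msl(profile, datums),
            "Beach Width (m) Toe-MLLW": gm.width_toe_mllw(profile, datums),
        }
    return pd.DataFrame.from_dict(out, orient="index")


def _wave_metrics(ds: SurveyDataset) -> pd.Series:
    sites = ds.sites.set_index("site_id")
    wf = ds.wind_fetch.set_index("site_id")
    out = {}
    for sid in sites.index:
        scenario = wv.assign_wind(float(sites.loc[sid, "facing_degrees"]))
        fetch = wv.FetchSpec(
            float(wf.loc[sid, "fetch_m"]),
            shoreline_angle=float(wf.loc[sid, "shoreline_angle_deg"]),
        )
        out[sid] = wv.smb_wave(scenario, fetch).hs
    return pd.Series(out, name="Wave Height (m)")


def compute_site_metrics(ds: SurveyDataset, datums: gm.TidalDatums) -> pd.DataFrame:
    """Aggregate a full survey dataset into the sites x 30 metric table."""
    agg = {}

    w = ds.wrack.groupby("site_id", sort=False).mean(numeric_only=True)
    agg["% Wrack Cover"] = w["pct_cover_total"]
    agg["% Terrestrial Wrack"] = w["pct_terrestrial"]
    agg["Wrack Depth (cm)"] = w["wrack_depth_cm"]
    agg["Wrack Width (m)"] = w["wrack_width_m"]

    lg = ds.logs.groupby("site_id", sort=False).mean(numeric_only=True)
    agg["Log Count"] = lg["log_count"]
    agg["Width of Log Line (m)"] = lg["log_line_width_m"]
    agg["Count Partially Buried Logs"] = lg["buried_count"]
    agg["Fallen Tree Count"] = lg["fallen_trees"]

    sn = ds.snorkel.copy()
    area = sn["transect_length_m"] * sn["visibility_m"]
    for col, name in (
        ("count_total_fish", "Total Fish Density (100m-2)"),
        ("count_juv_salmon", "Juvenile Salmon Density (100m-2)"),
        ("count_forage_fish", "Forage Fish Density (100m-2)"),
    ):
        sn[name] = sn[col] / area * 100.0
        agg[name] = sn.groupby("site_id", sort=False)[name].mean()
    ev = sn.groupby("site_id", sort=False)[
        ["feeding_observed", "salmon_observation_events"]
    ].sum()
    agg["Juv. Salmon Feeding Observations (%)"] = np.where(
        ev["salmon_observation_events"] > 0,
        ev["feeding_observed"] / ev["salmon_observation_events"] * 100.0,
        np.nan,
    )
    agg["Juv. Salmon Feeding Observations (%)"] = pd.Series(
        agg["Juv. Salmon Feeding Observations (%)"], index=ev.index
    )

    # vegetation: overhang union per transect, then site mean
    veg = ds.vegetation.set_index(["site_id", "transect"])
    ov_union = (
        ds.overhang_intervals.assign(
            length=lambda d: d["end_m"].clip(lower=0) - d["start_m"]
        )
        .groupby(["site_id", "transect"], sort=False)
        .apply(_union_length, include_groups=False)
        if len(ds.overhang_intervals)
        else pd.Series(dtype=float)
    )
    ov_pct = (ov_union.reindex(veg.index, fill_value=0.0) / veg["transect_length_m"]) * 100.0
    agg["% Overhanging Vegetation"] = ov_pct.groupby("site_id", sort=False).mean()
    agg["% Supratidal Vegetation"] = veg["supratidal_percent"].groupby(
        "site_id", sort=False
    ).mean()
    dg = (
        ds.dunegrass_patches.groupby(["site_id", "transect"], sort=False)[
            "patch_width_m"
        ].mean()
        if len(ds.dunegrass_patches)
        else pd.Series(dtype=float)
    )
    agg["Dunegrass Patch Width (m)"] = (
        dg.reindex(veg.index, fill_value=0.0).groupby("site_id", sort=False).mean()
    )
    native = ds.veg_species[ds.veg_species["status"] == "native"]
    nat = native.groupby(["site_id", "transect"], sort=False)["species"].nunique()
    agg["Native Vegetation Taxa Richness"] = (
        nat.reindex(veg.index, fill_value=0).groupby("site_id", sort=False).mean()
    )

    # fallout traps: per-trap density and richness, then site mean
    traps = ds.fallout_traps.set_index(["site_id", "trap"])
    counts = ds.fallout_counts[ds.fallout_counts["count"] > 0]
    per_trap = counts.groupby(["site_id", "trap"], sort=False)["count"].agg(
        total="sum", richness="count"
    )
    per_trap = per_trap.reindex(traps.index, fill_value=0)
    density = per_trap["total"] / traps["trap_area_m2"]
    agg["Fallout Trap Density (m-2)"] = density.groupby("site_id", sort=False).mean()
    agg["Fallout Trap Taxa Richness"] = per_trap["richness"].groupby(
        "site_id", sort=False
    ).mean()

    # MLLW biota
    quads = ds.mllw_quadrats.set_index(["site_id", "quadrat"])
    cov = ds.mllw_covers[ds.mllw_covers["percent_cover"] > 0]
    rich = cov.groupby(["site_id", "quadrat"], sort=False)["taxon"].nunique()
    agg["Biota Taxa Richness"] = (
        rich.reindex(quads.index, fill_value=0).groupby("site_id", sort=False).mean()
    )
    agg["% Eelgrass"] = quads["eelgrass_percent"].groupby("site_id", sort=False).mean()

    # physical metrics
    sites = ds.sites.set_index("site_id")
    agg["Bluff Height (m)"] = sites["bluff_height_m"]
    agg["Bluff Exposure (m2)"] = sites["bluff_exposure_m2"]
    geo = _geomorph_metrics(ds, datums)
    for c in geo.columns:
        agg[c] = geo[c]
    agg["Wave Height (m)"] = _wave_metrics(ds)
    grain = _grainsize_metrics(ds.grainsize)
    for c in grain.columns:
        agg[c] = grain[c]

    table = pd.DataFrame(agg)
    table = table.reindex(index=sites.index, columns=list(METRIC_NAMES))
    table.index.name = "site_id"
    return table


def _union_length(grp: pd.DataFrame) -> float:
    ivals = sorted(zip(grp["start_m"], grp["end_m"]))
    total, cur_a, cur_b = 0.0, *ivals[0]
    for a, b in ivals[1:]:
        if a > cur_b:
            total += cur_b - cur_a
            cur_a, cur_b = a, b
        else:
            cur_b = max(cur_b, b)
    return total + (cur_b - cur_a)
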
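"""Tabular container for a full survey campaign.

A :class:`SurveyDataset` bundles one DataFrame per record stream, in the same
shape as the on-disk CSVs written by :mod:`bluffbeach.io` and produced by
:mod:`bluffbeach.simulate`.  Column conventions:

- ``sites``: site_id, treatment, region, facing_degrees, bluff_height_m,
  bluff_exposure_m2, toe_index
- ``wind_fetch``: site_id, fetch_m, shoreline_angle_deg
- ``wrack``: site_id, quadrat, pct_cover_total, pct_algae, pct_eelgrass,
  pct_terrestrial, wrack_width_m, wrack_depth_cm
- ``logs``: site_id, point, log_count, buried_count, log_line_width_m,
  fallen_trees
- ``snorkel``: site_id, season, transect, transect_length_m, visibility_m,
  count_total_fish, count_juv_salmon, count_forage_fish, count_other,
  feeding_observed, salmon_observation_events
- ``fallout_traps``: site_id, trap, trap_area_m2, deploy_hours
- ``fallout_counts``: site_id, trap, taxon, count
- ``mllw_quadrats``: site_id, quadrat, quadrat_area_m2, eelgrass_percent
- ``mllw_covers``: site_id, quadrat, taxon, percent_cover
- ``vegetation``: site_id, transect, transect_length_m, supratidal_percent
- ``overhang_intervals``: site_id, transect, start_m, end_m
- ``dunegrass_patches``: site_id, transect, patch_width_m
- ``veg_species``: site_id, transect, species, status
- ``profiles``: site_id, distance_m, elevation_m (seaward-increasing per site)
- ``grainsize``: site_id, station, layer, then one ``pct_<hi>_<lo>mm`` column
  per sieve class (bounds in mm, descending)
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import pandas as pd

FRAME_NAMES = (
    "sites",
    "wind_fetch",
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
    "profiles",
    "grainsize",
)


@dataclass
class SurveyDataset:
    sites: pd.DataFrame
    wind_fetch: pd.DataFrame
    wrack: pd.DataFrame
    logs: pd.DataFrame
    snorkel: pd.DataFrame
    fallout_traps: pd.DataFrame
    fallout_counts: pd.DataFrame
    mllw_quadrats: pd.DataFrame
    mllw_covers: pd.DataFrame
    vegetation: pd.DataFrame
    overhang_intervals: pd.DataFrame
    dunegrass_patches: pd.DataFrame
    veg_species: pd.DataFrame
    profiles: pd.DataFrame
    grainsize: pd.DataFrame

    def frames(self):
        """Iterate over (name, DataFrame) pairs in canonical order."""
        for f in fields(self):
            yield f.name, getattr(self, f.name)

    @property
    def site_ids(self):
        return list(self.sites["site_id"])

    def treatment_of(self) -> pd.Series:
        return self.sites.set_index("site_id")["treatment"]

    def region_of(self) -> pd.Series:
        return self.sites.set_index("site_id")["region"]
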
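"""CSV readers/writers, packaged fixtures, schema validation, run reports."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dataset import FRAME_NAMES, SurveyDataset
from .metrics import METRIC_NAMES, parse_grainsize_columns
from .records import REGIONS, SEASONS, TREATMENTS, VEG_STATUS
from .scorecard import MetricDefinition


class InputError(ValueError):
    pass


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------

def load_table1() -> pd.DataFrame:
    """The packaged treatment-mean table (30 metrics x 4 treatments)."""
    with resources.files("bluffbeach.data").joinpath(
        "table1_treatment_means.csv"
    ).open() as fh:
        df = pd.read_csv(fh).set_index("metric")
    assert list(df.index) == list(METRIC_NAMES)
    return df


def load_metric_definitions(path: str | Path | None = None) -> list[MetricDefinition]:
    """Metric orientations: packaged defaults, or a user YAML override."""
    if path is None:
        src = resources.files("bluffbeach.data").joinpath("metric_definitions.yaml")
        text = src.read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    return [
        MetricDefinition(
            name=m["name"],
            orientation=m.get("orientation", "higher_is_better"),
            units=m.get("units", ""),
            rationale=m.get("rationale", ""),
        )
        for m in raw["metrics"]
    ]


def load_simulation_config(path: str | Path | None = None):
    """Build a :class:`~bluffbeach.simulate.SimulationConfig` from a YAML
    file.  Recognized keys: region_sd, within_cv, logit_sd, dispersion,
    replicates (mapping), datums (mhhw/msl/mllw), profile_noise_m,
    treatment_means_csv (path to a metric,<treatments> table),
    metric_definitions (path, returned alongside).  Any omitted key keeps
    its default.
    """
    from .geomorph import TidalDatums
    from .simulate import SimulationConfig

    if path is None:
        return SimulationConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    for key in ("region_sd", "within_cv", "logit_sd", "dispersion", "profile_noise_m"):
        if key in raw:
            kwargs[key] = float(raw[key])
    if "datums" in raw:
        d = raw["datums"]
        kwargs["datums"] = TidalDatums(float(d["mhhw"]), float(d["msl"]), float(d["mllw"]))
    if "treatment_means_csv" in raw:
        kwargs["treatment_means"] = pd.read_csv(raw["treatment_means_csv"]).set_index("metric")
    cfg = SimulationConfig(**kwargs)
    if "replicates" in raw:
        cfg.replicates.update({k: int(v) for k, v in raw["replicates"].items()})
    return cfg


# ---------------------------------------------------------------------------
# dataset round-trip
# ---------------------------------------------------------------------------

def write_dataset(ds: SurveyDataset, out_dir: str | Path, seed: int | None = None,
                  config_echo: dict | None = None) -> "RunReport":
    """Write every record stream to ``<out_dir>/<name>.csv`` plus a manifest
    (digests, row counts, seed) as ``manifest.json``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=seed, config_echo=config_echo or {})
    for name, frame in ds.frames():
        path = out / f"{name}.csv"
        frame.to_csv(path, index=False)
        report.add_output(path, n_records=len(frame))
    report.write(out / "manifest.json")
    return report


def read_dataset(in_dir: str | Path) -> SurveyDataset:
    """Read a dataset directory written by :func:`write_dataset` (or
    hand-assembled CSVs with the same schemas)."""
    d = Path(in_dir)
    frames = {}
    for name in FRAME_NAMES:
        path = d / f"{name}.csv"
        if not path.exists():
            raise InputError(f"missing mandatory input file: {path.name}")
        frames[name] = pd.read_csv(path)
    return SurveyDataset(**frames)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def _check_range(df, frame, col, lo, hi, out):
    bad = df.index[(df[col] < lo) | (df[col] > hi) | df[col].isna()]
    for i in bad:
        out.append(f"{frame}.csv row {i + 2}: {col}={df.loc[i, col]!r} outside [{lo}, {hi}]")


def _check_nonneg_int(df, frame, col, out):
    v = df[col]
    bad = df.index[(v < 0) | (v != np.floor(v)) | v.isna()]
    for i in bad:
        out.append(f"{frame}.csv row {i + 2}: {col}={df.loc[i, col]!r} is not a non-negative integer")


def validate_dataset(ds: SurveyDataset) -> list[str]:
    """Schema checks for every stream; returns human-readable violations
    (empty list = valid).  Row numbers refer to the CSV files (header = 1)."""
    v: list[str] = []
    sites = ds.sites
    if sites["site_id"].duplicated().any():
        dups = sorted(sites.loc[sites["site_id"].duplicated(), "site_id"])
        v.append(f"sites.csv: duplicated site_id(s): {dups}")
    known = set(sites["site_id"])
    for i in sites.index:
        if sites.loc[i, "treatment"] not in TREATMENTS:
            v.append(f"sites.csv row {i + 2}: unknown treatment {sites.loc[i, 'treatment']!r}")
        if sites.loc[i, "region"] not in REGIONS:
            v.append(f"sites.csv row {i + 2}: unknown region {sites.loc[i, 'region']!r}")
    _check_range(sites, "sites", "facing_degrees", 0, 360, v)
    _check_range(sites, "sites", "bluff_height_m", 0, np.inf, v)
    _check_range(sites, "sites", "bluff_exposure_m2", 0, np.inf, v)

    for name, frame in ds.frames():
        if name == "sites":
            continue
        stray = set(frame["site_id"]) - known
        if stray:
            v.append(f"{name}.csv: site_id(s) not in the registry: {sorted(stray)[:5]}")

    for col in ("pct_cover_total", "pct_algae", "pct_eelgrass", "pct_terrestrial"):
        _check_range(ds.wrack, "wrack", col, 0, 100, v)
    _check_range(ds.wrack, "wrack", "wrack_width_m", 0, np.inf, v)
    _check_range(ds.wrack, "wrack", "wrack_depth_cm", 0, np.inf, v)

    for col in ("log_count", "buried_count", "fallen_trees"):
        _check_nonneg_int(ds.logs, "logs", col, v)
    bad = ds.logs.index[ds.logs["buried_count"] > ds.logs["log_count"]]
    for i in bad:
        v.append(f"logs.csv row {i + 2}: buried_count exceeds log_count")

    sn = ds.snorkel
    for i in sn.index[~sn["season"].isin(SEASONS)]:
        v.append(f"snorkel.csv row {i + 2}: unknown season {sn.loc[i, 'season']!r}")
    for col in ("transect_length_m", "visibility_m"):
        bad = sn.index[sn[col] <= 0]
        for i in bad:
            v.append(f"snorkel.csv row {i + 2}: {col} must be > 0")
    for col in (
        "count_total_fish",
        "count_juv_salmon",
        "count_forage_fish",
        "count_other",
        "feeding_observed",
        "salmon_observation_events",
    ):
        _check_nonneg_int(sn, "snorkel", col, v)
    for i in sn.index[sn["feeding_observed"] > sn["salmon_observation_events"]]:
        v.append(f"snorkel.csv row {i + 2}: feeding_observed exceeds observation events")

    _check_range(ds.fallout_traps, "fallout_traps", "trap_area_m2", 1e-9, np.inf, v)
    _check_nonneg_int(ds.fallout_counts, "fallout_counts", "count", v)
    _check_range(ds.mllw_quadrats, "mllw_quadrats", "eelgrass_percent", 0, 100, v)
    _check_range(ds.mllw_covers, "mllw_covers", "percent_cover", 0, 100, v)
    _check_range(ds.vegetation, "vegetation", "supratidal_percent", 0, 100, v)
    _check_range(ds.dunegrass_patches, "dunegrass_patches", "patch_width_m", 0, np.inf, v)
    for i in ds.veg_species.index[~ds.veg_species["status"].isin(VEG_STATUS)]:
        v.append(f"veg_species.csv row {i + 2}: unknown status {ds.veg_species.loc[i, 'status']!r}")

    ov = ds.overhang_intervals.merge(
        ds.vegetation[["site_id", "transect", "transect_length_m"]],
        on=["site_id", "transect"],
        how="left",
    )
    for i in ov.index[(ov["start_m"] > ov["end_m"]) | (ov["start_m"] < 0)
                      | (ov["end_m"] > ov["transect_length_m"])]:
        v.append(f"overhang_intervals.csv row {i + 2}: interval outside its transect")

    for sid, grp in ds.profiles.groupby("site_id", sort=False):
        if not np.all(np.diff(grp["distance_m"].to_numpy()) > 0):
            v.append(f"profiles.csv: distances not strictly increasing for {sid}")

    try:
        pct_cols, _ = parse_grainsize_columns(ds.grainsize.columns)
        sums = ds.grainsize[pct_cols].sum(axis=1)
        for i in ds.grainsize.index[(sums - 100).abs() > 0.5]:
            v.append(f"grainsize.csv row {i + 2}: class percents sum to {sums[i]:.2f}")
        if (ds.grainsize[pct_cols] < 0).any().any():
            v.append("grainsize.csv: negative class percent")
    except ValueError as exc:
        v.append(f"grainsize.csv: {exc}")
    return v


def validate_inputs(in_dir: str | Path) -> list[str]:
    """Validate a dataset directory; missing mandatory files are reported as
    violations (the CLI treats any violation as a nonzero exit)."""
    d = Path(in_dir)
    if not d.is_dir():
        raise InputError(f"input directory does not exist: {d}")
    missing = [f"{name}.csv" for name in FRAME_NAMES if not (d / f"{name}.csv").exists()]
    if missing:
        return [f"missing mandatory input file: {m}" for m in missing]
    return validate_dataset(read_dataset(d))


# ---------------------------------------------------------------------------
# run report
# ---------------------------------------------------------------------------

def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunReport:
    """Provenance sidecar: seed, config echo, per-output record counts,
    warnings, and content digests (stable for identical inputs)."""

    seed: int | None = None
    config_echo: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    def add_output(self, path: Path, n_records: int | None = None) -> None:
        self.outputs.append(
            {
                "path": str(path),
                "name": Path(path).name,
                "sha256": _digest(Path(path)),
                "n_records": n_records,
            }
        )

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "config": self.config_echo,
            "outputs": self.outputs,
            "warnings": self.warnings,
        }

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, default=str) + "\n")
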
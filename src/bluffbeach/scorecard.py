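"""The beach-function "scale bar": orient, min-max scale, and average the 30
site metrics into one 0-1 score per management treatment.

Steps: (1) average each metric over a treatment's sites; (2) scale the four
treatment means of each metric to [0, 1] by that metric's min and max,
flipping metrics where a lower raw value indicates greater beach function;
(3) average the scaled values across metrics.  The standard error is taken
across the scaled metric values (n = number of metrics), one error bar per
treatment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .metrics import METRIC_NAMES
from .records import TREATMENTS

ORIENTATIONS = ("higher_is_better", "lower_is_better")


class ScorecardError(ValueError):
    pass


@dataclass(frozen=True)
class MetricDefinition:
    name: str
    orientation: str = "higher_is_better"
    units: str = ""
    rationale: str = ""

    def __post_init__(self) -> None:
        if self.orientation not in ORIENTATIONS:
            raise ScorecardError(
                f"orientation must be one of {ORIENTATIONS}, got {self.orientation!r}"
            )


def default_metric_definitions() -> list[MetricDefinition]:
    """The packaged orientation set: every metric reads higher-is-better
    except relative encroachment (a toe below MHHW degrades the upper
    beach).  Override per metric via config where a different inversion set
    is wanted."""
    from .io import load_metric_definitions

    return load_metric_definitions()


def treatment_means(
    table: pd.DataFrame,
    treatments: Mapping[str, str] | pd.Series | None = None,
) -> pd.DataFrame:
    """Average a sites x metrics table into a 4 x metrics treatment table.

    ``treatments`` maps site_id -> treatment.  If the table is already
    indexed by the four treatment labels it passes through unchanged.
    Missing values are excluded pairwise from the means.
    """
    if treatments is None:
        if set(table.index) == set(TREATMENTS):
            return table.reindex(list(TREATMENTS))
        raise ScorecardError(
            "table is not indexed by treatments; pass a site->treatment mapping"
        )
    t = pd.Series(dict(treatments) if not isinstance(treatments, pd.Series) else treatments)
    labels = t.reindex(table.index)
    if labels.isna().any():
        missing = list(table.index[labels.isna()])
        raise ScorecardError(f"sites without treatment label: {missing}")
    out = table.groupby(labels).mean()
    absent = [tr for tr in TREATMENTS if tr not in out.index]
    if absent:
        raise ScorecardError(f"treatment(s) with zero sites: {absent}")
    return out.reindex(list(TREATMENTS))


def minmax_scale(values: Sequence[float], orientation: str = "higher_is_better") -> np.ndarray:
    """Scale the treatment means of one metric to [0, 1].

    s = (x - min)/(max - min); flipped for lower-is-better metrics.  If all
    values tie the metric is neutral: every treatment gets 0.5 (keeping the
    metric in the denominator rather than dropping it).
    """
    if orientation not in ORIENTATIONS:
        raise ScorecardError(f"unknown orientation {orientation!r}")
    x = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ScorecardError(f"non-finite metric values: {values!r}")
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.full(x.shape, 0.5)
    s = (x - lo) / (hi - lo)
    if orientation == "lower_is_better":
        s = 1.0 - s
    return s


def scaled_metric_table(
    means: pd.DataFrame, definitions: Iterable[MetricDefinition]
) -> pd.DataFrame:
    """Min-max scale every metric column of a treatment-mean table."""
    defs = {d.name: d for d in definitions}
    missing = [c for c in means.columns if c not in defs]
    if missing:
        raise ScorecardError(f"metrics without a definition: {missing}")
    scaled = {
        c: minmax_scale(means[c].to_numpy(), defs[c].orientation) for c in means.columns
    }
    return pd.DataFrame(scaled, index=means.index)


def scale_bar(
    table: pd.DataFrame,
    definitions: Iterable[MetricDefinition] | None = None,
    treatments: Mapping[str, str] | pd.Series | None = None,
) -> pd.DataFrame:
    """Per-treatment beach-function score with its standard error.

    ``table`` is either a sites x metrics table (pass ``treatments``) or an
    already-averaged treatments x metrics table.  Returns a DataFrame indexed
    by treatment with columns score, se, n_metrics.
    """
    definitions = list(definitions) if definitions is not None else default_metric_definitions()
    if table.shape[1] < 2:
        raise ScorecardError("scale bar needs at least 2 metrics")
    means = treatment_means(table, treatments)
    scaled = scaled_metric_table(means, definitions)
    n = scaled.shape[1]
    score = scaled.mean(axis=1)
    se = scaled.std(axis=1, ddof=1) / np.sqrt(n)
    return pd.DataFrame({"score": score, "se": se, "n_metrics": n})


def full_metric_definitions_check(definitions: Iterable[MetricDefinition]) -> None:
    """Require a unique definition for each of the 30 canonical metrics."""
    names = [d.name for d in definitions]
    if len(names) != len(set(names)):
        raise ScorecardError("duplicate metric definitions")
    missing = set(METRIC_NAMES) - set(names)
    if missing:
        raise ScorecardError(f"missing metric definitions: {sorted(missing)}")
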
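"""Min-max scaling and the per-treatment beach-function scale bar."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bluffbeach.metrics import METRIC_NAMES
from bluffbeach.records import TREATMENTS
from bluffbeach.scorecard import (
    MetricDefinition,
    ScorecardError,
    default_metric_definitions,
    full_metric_definitions_check,
    minmax_scale,
    scale_bar,
    scaled_metric_table,
    treatment_means,
)


class TestMinmaxScale:
    def test_wrack_cover_row(self):
        s = minmax_scale([43.2, 41.7, 13.7, 24.0])
        assert s == pytest.approx([1.0, 0.9492, 0.0, 0.3492], abs=5e-4)

    def test_all_equal_goes_neutral(self):
        assert minmax_scale([7.0] * 4).tolist() == [0.5] * 4

    def test_encroachment_row_inverted(self):
        s = minmax_scale([-0.51, -0.12, 0.27, 0.41], "lower_is_better")
        assert s == pytest.approx([1.0, 0.5761, 0.1522, 0.0], abs=5e-4)

    def test_non_finite_rejected(self):
        with pytest.raises(ScorecardError):
            minmax_scale([1.0, np.nan, 2.0, 3.0])

    @given(
        a=st.floats(0.01, 100.0),
        b=st.floats(-50.0, 50.0),
    )
    @settings(max_examples=30, deadline=None)
    def test_affine_invariance(self, a, b):
        x = np.array([3.0, 1.0, 4.0, 1.5])
        assert minmax_scale(a * x + b) == pytest.approx(minmax_scale(x), abs=1e-9)

    def test_orientation_flip_identity(self, rng):
        x = rng.uniform(0, 10, 4)
        s_hi = minmax_scale(x, "higher_is_better")
        s_lo = minmax_scale(x, "lower_is_better")
        assert s_lo == pytest.approx(1.0 - s_hi)

    def test_extremes_attained_absent_ties(self, rng):
        for _ in range(20):
            x = rng.uniform(0, 10, 4)
            if len(np.unique(x)) < 4:
                continue
            s = minmax_scale(x)
            assert np.sum(s == 1.0) == 1 and np.sum(s == 0.0) == 1


class TestTreatmentMeans:
    def test_identical_sites_reproduce_common_values(self):
        table = pd.DataFrame(
            {"m1": [2.0] * 8, "m2": [5.0] * 8},
            index=[f"s{i}" for i in range(8)],
        )
        treatments = {f"s{i}": TREATMENTS[i % 4] for i in range(8)}
        means = treatment_means(table, treatments)
        assert (means["m1"] == 2.0).all() and (means["m2"] == 5.0).all()

    def test_pre_averaged_table_passes_through(self, table1):
        means = treatment_means(table1.T)
        pd.testing.assert_frame_equal(means, table1.T.reindex(list(TREATMENTS)))

    def test_missing_values_excluded_pairwise(self):
        table = pd.DataFrame(
            {"m1": [1.0, np.nan, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0]},
            index=[f"s{i}" for i in range(8)],
        )
        treatments = {f"s{i}": TREATMENTS[i // 2] for i in range(8)}
        means = treatment_means(table, treatments)
        assert means.loc["ProtectHigh", "m1"] == 1.0  # NaN partner excluded

    def test_empty_treatment_rejected(self):
        table = pd.DataFrame({"m1": [1.0]}, index=["s0"])
        with pytest.raises(ScorecardError, match="zero sites"):
            treatment_means(table, {"s0": "ProtectHigh"})


class TestScaleBar:
    def test_single_metric_identity(self, table1):
        sub = table1.T[["% Wrack Cover", "Wrack Depth (cm)"]]
        bar = scale_bar(sub, [MetricDefinition(c) for c in sub.columns])
        scaled = scaled_metric_table(sub, [MetricDefinition(c) for c in sub.columns])
        assert bar["score"].to_numpy() == pytest.approx(scaled.mean(axis=1).to_numpy())

    def test_protect_scores_twice_restore_on_survey_means(self, table1):
        bar = scale_bar(table1.T)
        s = bar["score"]
        protect = (s["ProtectHigh"] + s["ProtectLow"]) / 2
        restore = (s["RestoreHigh"] + s["RestoreLow"]) / 2
        assert protect / restore >= 2.0
        assert 2.0 <= s["ProtectHigh"] / s["RestoreHigh"] <= 3.0

    def test_frozen_regression_scores(self, table1):
        # values independently derived with a spreadsheet-style recomputation
        bar = scale_bar(table1.T)
        assert bar["score"].to_numpy() == pytest.approx(
            [0.6410, 0.6315, 0.2755, 0.2460], abs=5e-4
        )
        assert bar["se"].to_numpy() == pytest.approx(
            [0.0686, 0.0764, 0.0600, 0.0677], abs=5e-4
        )
        assert (bar["n_metrics"] == 30).all()

    def test_ratio_robust_to_slope_orientation(self, table1):
        defs = [
            MetricDefinition(
                name,
                "lower_is_better"
                if name in ("Relative Encroachment (m)", "Beach Slope (m/m) Toe-MSL")
                else "higher_is_better",
            )
            for name in METRIC_NAMES
        ]
        s = scale_bar(table1.T, defs)["score"]
        assert (s["ProtectHigh"] + s["ProtectLow"]) / (
            s["RestoreHigh"] + s["RestoreLow"]
        ) >= 2.0

    def test_missing_definition_rejected(self, table1):
        defs = default_metric_definitions()[:-1]
        with pytest.raises(ScorecardError, match="without a definition"):
            scale_bar(table1.T, defs)

    def test_reversing_one_metric_leaves_others_untouched(self, table1):
        base = scaled_metric_table(table1.T, default_metric_definitions())
        flipped_defs = [
            MetricDefinition(
                d.name,
                "lower_is_better" if d.name == "% Wrack Cover" else d.orientation,
            )
            for d in default_metric_definitions()
        ]
        flipped = scaled_metric_table(table1.T, flipped_defs)
        assert flipped["% Wrack Cover"].to_numpy() == pytest.approx(
            1.0 - base["% Wrack Cover"].to_numpy()
        )
        others = [c for c in base.columns if c != "% Wrack Cover"]
        pd.testing.assert_frame_equal(base[others], flipped[others])


def test_packaged_definitions_cover_all_metrics():
    defs = default_metric_definitions()
    full_metric_definitions_check(defs)
    inverted = [d.name for d in defs if d.orientation == "lower_is_better"]
    assert inverted == ["Relative Encroachment (m)"]
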
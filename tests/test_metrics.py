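"""Record-level aggregation into site metrics."""

import numpy as np
import pandas as pd
import pytest

from bluffbeach.metrics import (
    METRIC_NAMES,
    AggregationError,
    aggregate_wrack,
    build_site_metric_table,
    compute_site_metrics,
    fallout_density,
    feeding_contingency,
    fish_density,
    overhang_percent,
)
from bluffbeach.records import (
    FalloutTrapSample,
    RecordError,
    SnorkelTransect,
    VegetationTransect,
    WrackQuadrat,
)


def _quadrat(total, terr, depth, width):
    return WrackQuadrat("s1", total, 0.0, 0.0, terr, width, depth)


class TestWrackAggregation:
    def test_all_zero_quadrats_give_zero_metrics(self):
        qs = [_quadrat(0, 0, 0, 0) for _ in range(10)]
        assert aggregate_wrack(qs) == (0, 0, 0, 0)

    def test_hand_computed_means(self):
        qs = [_quadrat(40, 10, 2, 4), _quadrat(20, 0, 1, 2)]
        assert aggregate_wrack(qs) == (30, 5, 1.5, 3)

    def test_empty_input_raises(self):
        with pytest.raises(AggregationError, match="no quadrats"):
            aggregate_wrack([])

    def test_order_invariance(self, rng):
        vals = rng.uniform(0, 10, size=(8, 4))
        vals[:, 1] = vals[:, 0] * rng.uniform(0, 1, 8)  # terrestrial <= total
        qs = [_quadrat(*v) for v in vals]
        shuffled = [qs[i] for i in rng.permutation(len(qs))]
        assert aggregate_wrack(qs) == pytest.approx(aggregate_wrack(shuffled))


class TestFishDensity:
    @pytest.mark.parametrize(
        "count,length,vis,expected",
        [(0, 75, 2, 0.0), (10, 50, 2, 10.0), (13, 50, 1, 26.0)],
    )
    def test_examples(self, count, length, vis, expected):
        assert fish_density(count, length, vis) == pytest.approx(expected)

    def test_linearity_in_count_and_inverse_area(self):
        base = fish_density(5, 60, 2)
        assert fish_density(10, 60, 2) == pytest.approx(2 * base)
        assert fish_density(5, 120, 2) == pytest.approx(base / 2)
        assert fish_density(5, 60, 4) == pytest.approx(base / 2)

    @pytest.mark.parametrize("length,vis", [(0, 2), (50, 0), (-1, 2)])
    def test_nonpositive_geometry_rejected(self, length, vis):
        with pytest.raises(AggregationError):
            fish_density(1, length, vis)


class TestFalloutDensity:
    def test_empty_trap(self):
        d, r = fallout_density(FalloutTrapSample("s1", {}))
        assert (d, r) == (0, 0)

    def test_density_scales_by_area(self):
        d, _ = fallout_density(FalloutTrapSample("s1", {"acari": 10}, trap_area=0.10))
        assert d == pytest.approx(100.0)

    def test_richness_counts_nonzero_taxa(self):
        sample = FalloutTrapSample("s1", {"a": 5, "b": 4, "c": 1, "d": 0})
        assert fallout_density(sample)[1] == 3

    def test_zero_area_rejected(self):
        with pytest.raises(RecordError):
            FalloutTrapSample("s1", {}, trap_area=0.0)


class TestOverhangPercent:
    def _transect(self, intervals, length=50.0):
        return VegetationTransect("s1", length, intervals, 0.0, [], [])

    def test_no_intervals(self):
        assert overhang_percent(self._transect([])) == 0.0

    def test_overlapping_intervals_union(self):
        assert overhang_percent(self._transect([(0, 10), (5, 20)])) == pytest.approx(40.0)

    def test_full_span(self):
        assert overhang_percent(self._transect([(0, 50)])) == pytest.approx(100.0)

    def test_union_never_exceeds_100(self, rng):
        starts = rng.uniform(0, 50, 20)
        ends = np.minimum(starts + rng.uniform(0, 30, 20), 50.0)
        pct = overhang_percent(self._transect(list(zip(starts, ends))))
        assert 0.0 <= pct <= 100.0

    def test_interval_outside_transect_rejected(self):
        with pytest.raises(RecordError):
            self._transect([(40, 60)])


def _snorkel(site, feeding, events):
    return SnorkelTransect(site, "spring", 75, 2, 0, 0, 0, 0, feeding, events)


class TestFeedingContingency:
    TREATMENT_OF = {"a": "ProtectHigh", "b": "ProtectLow", "c": "RestoreHigh", "d": "RestoreLow"}

    def test_printed_counts_fixture(self):
        transects = [
            _snorkel("a", 1, 16),
            _snorkel("b", 0, 7),
            _snorkel("c", 4, 10),
            _snorkel("d", 6, 12),
        ]
        table = feeding_contingency(transects, self.TREATMENT_OF)
        assert table.values.tolist() == [[1, 0, 4, 6], [15, 7, 6, 6]]

    def test_no_feeding_anywhere(self):
        transects = [_snorkel(s, 0, 3) for s in "abcd"]
        table = feeding_contingency(transects, self.TREATMENT_OF)
        assert (table.loc["feeding"] == 0).all()

    def test_missing_treatment_raises(self):
        transects = [_snorkel(s, 0, 3) for s in "abc"]
        with pytest.raises(AggregationError, match="RestoreLow"):
            feeding_contingency(transects, self.TREATMENT_OF)


class TestSiteMetricTable:
    def test_complete_table_shape(self):
        metrics = {f"s{i}": {m: 1.0 for m in METRIC_NAMES} for i in range(20)}
        table = build_site_metric_table(metrics)
        assert table.shape == (20, 30)
        assert not table.isna().any().any()

    def test_missing_metric_is_nan_not_zero(self):
        partial = {m: 1.0 for m in METRIC_NAMES if m != "% Eelgrass"}
        table = build_site_metric_table({"s1": partial})
        assert np.isnan(table.loc["s1", "% Eelgrass"])

    def test_treatment_mean_table_fits_same_schema(self, table1):
        rows = {t: table1[t].to_dict() for t in table1.columns}
        table = build_site_metric_table(rows)
        assert list(table.columns) == list(METRIC_NAMES)
        assert table.shape == (4, 30)

    def test_unknown_metric_rejected(self):
        with pytest.raises(AggregationError, match="unknown metric"):
            build_site_metric_table({"s1": {"Not A Metric": 1.0}})


class TestDatasetAggregation:
    def test_full_campaign_covers_all_metrics(self, default_campaign):
        cfg, ds = default_campaign
        table = compute_site_metrics(ds, cfg.datums)
        assert table.shape == (20, 30)
        # feeding % may be missing where no salmon was observed; all other
        # columns must be complete
        other = [c for c in table.columns if c != "Juv. Salmon Feeding Observations (%)"]
        assert not table[other].isna().any().any()

    def test_rebuild_is_deterministic(self, default_campaign):
        cfg, ds = default_campaign
        a = compute_site_metrics(ds, cfg.datums)
        b = compute_site_metrics(ds, cfg.datums)
        pd.testing.assert_frame_equal(a, b, check_exact=True)

    def test_matches_record_level_wrack_aggregation(self, default_campaign):
        cfg, ds = default_campaign
        table = compute_site_metrics(ds, cfg.datums)
        sid = ds.site_ids[0]
        sub = ds.wrack[ds.wrack["site_id"] == sid]
        quadrats = [
            WrackQuadrat(
                sid,
                r.pct_cover_total,
                r.pct_algae,
                r.pct_eelgrass,
                r.pct_terrestrial,
                r.wrack_width_m,
                r.wrack_depth_cm,
            )
            for r in sub.itertuples()
        ]
        cover, terr, depth, width = aggregate_wrack(quadrats)
        assert table.loc[sid, "% Wrack Cover"] == pytest.approx(cover)
        assert table.loc[sid, "% Terrestrial Wrack"] == pytest.approx(terr)
        assert table.loc[sid, "Wrack Depth (cm)"] == pytest.approx(depth)
        assert table.loc[sid, "Wrack Width (m)"] == pytest.approx(width)
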
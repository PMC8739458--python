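"""Dashboard view computations against brute-force recomputation."""

import statistics
from datetime import datetime, timedelta, timezone

import numpy as np
import pytest

from lcmsqc import datastore, synth
from lcmsqc.cutoff_calibration import empirical_border
from lcmsqc.qc_engine import CompoundCutoffs, FlagStatus, RuleSet, check_std_a
from lcmsqc.records import (
    BatchRecord,
    ParsedBatch,
    ResultFilter,
    ResultRecord,
    SampleType,
)
from lcmsqc.views import (
    Grouping,
    ViewParameter,
    absolute_rt_view,
    average_trend_view,
    batch_view,
    histogram_view,
    std_a_signal_view,
    summarize,
)

from conftest import load_all

UTC = timezone.utc


def make_batch(name, values, *, month=1, instrument="LCMS-1", compound="Morphine",
               rt=None, day=1):
    """A hand-built batch whose patient rows carry the given
    is_peak_area values (and optionally fixed RTs)."""
    t0 = datetime(2021, month, day, 8, 0, tzinfo=UTC)
    results = [
        ResultRecord(
            xml_file_name=name,
            sample_type=SampleType.PATIENT,
            sample_id=f"P{k:03d}",
            compound=compound,
            injection_time=t0 + timedelta(minutes=3 * k),
            is_peak_area=v,
            rt=rt if rt is not None else 2.0,
            is_rt=2.0,
            peak_area=1000.0,
            instrument_id=instrument,
            result_key=k,
        )
        for k, v in enumerate(values)
    ]
    batch = BatchRecord(
        xml_file_name=name, timestamp=t0, instrument_id=instrument,
        sample_count=len(values),
    )
    return ParsedBatch(batch=batch, calibrations=[], results=results)


class TestSummarize:
    def test_small_vector(self):
        s = summarize([1.0, 2.0, 3.0])
        assert (s.mean, s.median, s.min, s.max) == (2.0, 2.0, 1.0, 3.0)
        assert s.n == 3 and s.n_null == 0

    def test_constant_vector(self):
        s = summarize([4.0] * 10)
        assert s.sd == 0.0
        assert set(s.quantiles.values()) == {4.0}

    def test_nulls_counted_and_excluded(self):
        s = summarize([None, 1.0, None, 3.0], cutoff=2.0)
        assert s.n == 2 and s.n_null == 2
        assert s.pct_below_cutoff == 50.0

    def test_all_null_raises(self):
        with pytest.raises(ValueError):
            summarize([None, None])

    def test_random_vector_matches_independent_recomputation(self):
        rng = np.random.default_rng(12)
        values = rng.lognormal(11, 0.4, size=500).tolist()
        s = summarize(values, cutoff=50_000.0, window=(20_000.0, 150_000.0))
        assert s.mean == pytest.approx(statistics.fmean(values))
        assert s.median == pytest.approx(statistics.median(values))
        assert s.sd == pytest.approx(statistics.stdev(values))
        assert s.min == min(values) and s.max == max(values)
        assert s.pct_below_cutoff == pytest.approx(
            100 * sum(1 for v in values if v < 50_000) / len(values)
        )
        assert s.pct_outside_window == pytest.approx(
            100 * sum(1 for v in values if v < 20_000 or v > 150_000) / len(values)
        )
        # monotone quantile ordering
        assert s.min <= s.quantiles[0.25] <= s.median <= s.quantiles[0.75] <= s.max


class TestHistogramView:
    def test_uniform_plant_fills_bins_evenly(self, store):
        values = [float(v) for v in np.arange(0.0, 10.0, 0.1)]  # 100 values on [0, 9.9]
        datastore.load_batch(make_batch("u.xml", values), store)
        view = histogram_view(store, ResultFilter(), ViewParameter.IS_PEAK_AREA,
                              n_bins=10)
        assert [count for _l, _r, count in view.bins] == [10] * 10
        assert sum(c for _l, _r, c in view.bins) == view.summary.n == 100

    def test_border_overlay_equals_empirical_border_on_same_selection(self, loaded_small):
        store, batches, _ = loaded_small
        flt = ResultFilter.build(sample_types=["calibrator"])
        view = histogram_view(store, flt, ViewParameter.IS_PEAK_AREA)
        values = [
            r.is_peak_area
            for b in batches for r in b.results
            if r.sample_type is SampleType.CALIBRATOR and r.is_peak_area is not None
        ]
        assert view.overlays["border"] == empirical_border(values, 0.02)

    def test_cutoff_overlay_resolves_for_single_compound_selection(self, loaded_small):
        store, _, _ = loaded_small
        compound = synth.default_compound_panel(1)[0].name
        rs = RuleSet.from_cutoffs("rs", [
            CompoundCutoffs(compound=compound, is_peak_area_min=20_000.0)
        ])
        flt = ResultFilter.build(compounds=[compound], instruments=["LCMS-1"])
        view = histogram_view(store, flt, ViewParameter.IS_PEAK_AREA, ruleset=rs)
        assert view.overlays["cutoff"] == 20_000.0
        assert view.summary.pct_below_cutoff is not None

    def test_bimodal_mixture_shows_two_histogram_modes(self, store):
        config = synth.GeneratorConfig(
            seed=21, n_batches=10, patients_per_batch=40, missing_field_rate=0.0,
            compounds=synth.default_compound_panel(1),
            is_area_log_sigma=0.15, bimodal_fraction=0.4, bimodal_log_mu_shift=-1.5,
            instruments=(synth.InstrumentSpec("LCMS-1", 1.0),),
        )
        batches, _ = synth.generate_batches(config)
        load_all(batches, store)
        view = histogram_view(store, ResultFilter(), ViewParameter.IS_PEAK_AREA,
                              n_bins=40)
        counts = [c for _l, _r, c in view.bins]
        edges = [l for l, _r, _c in view.bins]
        split = np.searchsorted(edges, np.exp(11.0 - 0.75))  # between the modes
        left_peak, right_peak = max(counts[:split]), max(counts[split:])
        valley = min(counts[max(split - 3, 0):split + 3])
        assert left_peak > 3 * valley and right_peak > 3 * valley


class TestTrendViews:
    def test_two_months_with_planted_means(self, store):
        datastore.load_batch(make_batch("jan.xml", [100_000.0] * 20, month=1), store)
        datastore.load_batch(make_batch("feb.xml", [120_000.0] * 20, month=2), store)
        view = average_trend_view(store, ResultFilter(), ViewParameter.IS_PEAK_AREA,
                                  Grouping.BY_MONTH)
        assert [(label, s.mean) for label, s in view.points] == [
            ("2021-01", 100_000.0), ("2021-02", 120_000.0),
        ]

    def test_group_rows_partition_the_selection(self, loaded_small):
        store, batches, _ = loaded_small
        view = average_trend_view(store, ResultFilter(), ViewParameter.IS_PEAK_AREA,
                                  Grouping.BY_BATCH)
        total = sum(s.n for _label, s in view.points)
        non_null = sum(
            1 for b in batches for r in b.results if r.is_peak_area is not None
        )
        assert total == non_null
        assert len(view.points) == len(batches)

    def test_single_batch_is_one_group(self, store):
        datastore.load_batch(make_batch("only.xml", [1.0, 2.0, 3.0]), store)
        view = average_trend_view(store, ResultFilter(), ViewParameter.IS_PEAK_AREA,
                                  Grouping.BY_BATCH)
        assert len(view.points) == 1 and view.points[0][1].n == 3


class TestBatchView:
    def test_ten_injections_in_order(self, store):
        values = [float(v) for v in range(10)]
        datastore.load_batch(make_batch("b.xml", values), store)
        view, overlays = batch_view(store, "b.xml", ViewParameter.IS_PEAK_AREA)
        assert [label for label, _s in view.points] == [f"P{k:03d}" for k in range(10)]
        assert [s.mean for _l, s in view.points] == values

    def test_order_is_injection_time_not_storage_order(self, store):
        batch = make_batch("s.xml", [float(v) for v in range(6)])
        batch.results = list(reversed(batch.results))  # shuffle storage order
        datastore.load_batch(batch, store)
        view, _ = batch_view(store, "s.xml", ViewParameter.IS_PEAK_AREA)
        assert [label for label, _s in view.points] == [f"P{k:03d}" for k in range(6)]

    def test_overlay_passes_through_ruleset_threshold(self, store):
        datastore.load_batch(make_batch("o.xml", [1.0] * 4), store)
        rs = RuleSet.from_cutoffs("rs", [
            CompoundCutoffs(compound="Morphine", is_peak_area_min=123.0)
        ])
        _view, overlays = batch_view(store, "o.xml", ViewParameter.IS_PEAK_AREA,
                                     ruleset=rs)
        assert overlays == {"cutoff": 123.0}

    def test_unknown_batch_raises(self, store):
        with pytest.raises(ValueError, match="ghost"):
            batch_view(store, "ghost.xml", ViewParameter.IS_PEAK_AREA)


class TestStdASignalView:
    @pytest.fixture
    def planted(self, store):
        config = synth.plant_failures(
            synth.GeneratorConfig(
                seed=33, n_batches=10, patients_per_batch=2, missing_field_rate=0.0,
                compounds=synth.default_compound_panel(3),
            ),
            [synth.PlantStdABelow(n_batches=3, cutoff=4_000.0)],
        )
        batches, truth = synth.generate_batches(config)
        load_all(batches, store)
        rs = RuleSet.from_cutoffs("rs", [
            CompoundCutoffs(compound=c.name, std_a_peak_area_min=4_000.0)
            for c in config.compounds
        ])
        return store, batches, truth, rs

    def test_exactly_three_batches_any_fail(self, planted):
        store, batches, truth, rs = planted
        view = std_a_signal_view(store, ResultFilter(), rs)
        assert sorted(view.color_code.values()).count("any-fail") == 3
        planted_batches = set(
            truth.loc[truth["planted"] == "std_a_below", "xml_file_name"]
        )
        assert {b for b, s in view.color_code.items() if s == "any-fail"} == planted_batches

    def test_points_agree_with_rule_engine_check(self, planted):
        store, batches, truth, rs = planted
        view = std_a_signal_view(store, ResultFilter(), rs)
        by_point = {(b, c): (m, s) for b, c, m, s in view.points}
        stored = datastore.query_results(
            ResultFilter.build(sample_types=["calibrator"]), store
        )
        from collections import defaultdict
        groups = defaultdict(list)
        for r in stored:
            groups[(r.xml_file_name, r.compound)].append(r)
        assert set(by_point) == set(groups)
        for key, group in groups.items():
            flag = check_std_a(group, rs.resolve(key[1], group[0].instrument_id))
            assert by_point[key] == (flag.measured, flag.status)

    def test_no_calibrators_raises(self, store):
        datastore.load_batch(make_batch("p.xml", [1.0]), store)
        rs = RuleSet.from_cutoffs("rs", [CompoundCutoffs(compound="Morphine")])
        with pytest.raises(ValueError, match="calibrator"):
            std_a_signal_view(store, ResultFilter(), rs)


class TestAbsoluteRTView:
    def test_identical_rts_give_zero_deviations(self, store):
        for m, name in [(1, "a.xml"), (1, "b.xml")]:
            datastore.load_batch(make_batch(name, [1.0] * 5, month=m, rt=2.5), store)
        view = absolute_rt_view(store, ResultFilter())
        assert all(d == 0.0 for _b, _c, d in view.deviations)

    def test_shifted_batch_deviation_matches_brute_force(self, store):
        datastore.load_batch(make_batch("a.xml", [1.0] * 5, rt=2.50, day=1), store)
        datastore.load_batch(make_batch("b.xml", [1.0] * 5, rt=2.55, day=2), store)
        view = absolute_rt_view(store, ResultFilter())
        # equal-weight monthly mean over 10 rows
        month_mean = (5 * 2.50 + 5 * 2.55) / 10
        expected = {"a.xml": 2.50 - month_mean, "b.xml": 2.55 - month_mean}
        got = {b: d for b, _c, d in view.deviations}
        assert got == pytest.approx(expected)

    def test_deviations_are_internally_consistent(self, loaded_small):
        store, _, _ = loaded_small
        view = absolute_rt_view(store, ResultFilter())
        monthly = {(m, c): v for m, c, v in view.monthly_average}
        per_batch = {(b, c): v for b, c, v in view.per_batch_rt}
        # recompute every deviation from the returned fields
        for b, c, d in view.deviations:
            months = [m for (m, cc) in monthly if cc == c]
            assert any(
                d == pytest.approx(per_batch[(b, c)] - monthly[(m, c)], abs=1e-12)
                for m in months
            )
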
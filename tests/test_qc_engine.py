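"""Rule semantics: boundaries, null handling, oracle equivalence."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lcmsqc import synth
from lcmsqc.qc_engine import (
    CompoundCutoffs,
    FlagStatus,
    Rule,
    RuleResolutionError,
    RuleSet,
    adjust_is_cutoff_for_lot,
    check_ion_ratio,
    check_is_peak_area,
    check_rrt,
    check_sn,
    check_std_a,
    compute_ion_ratio,
    compute_rrt,
    evaluate_corpus,
    ruleset_from_yaml,
    ruleset_to_yaml,
)
from lcmsqc.records import ResultRecord, SampleType

from oracles import brute_force_flags, random_results, report_as_map


def row(**kw):
    defaults = dict(
        xml_file_name="b.xml", sample_type=SampleType.PATIENT,
        sample_id="Pat-1", compound="Morphine", instrument_id="LCMS-1",
        result_key=0,
    )
    defaults.update(kw)
    return ResultRecord(**defaults)


CUT = CompoundCutoffs(
    compound="Morphine", rrt_window=(0.984, 1.024), is_peak_area_min=20_000,
    std_a_peak_area_min=5_000, sn_min=10.0, ion_ratio_tolerance=0.2,
    expected_ion_ratio=0.5,
)


class TestComputations:
    def test_coeluting_pair_has_unit_rrt(self):
        assert compute_rrt(2.40, 2.40) == 1.0

    def test_rrt_is_plain_ratio(self):
        assert compute_rrt(2.50, 2.00) == 1.25

    @given(st.floats(0.1, 10.0), st.floats(0.1, 10.0))
    def test_rrt_times_is_rt_recovers_rt(self, rt, is_rt):
        assert compute_rrt(rt, is_rt) * is_rt == pytest.approx(rt, rel=1e-12)

    @pytest.mark.parametrize("rt, is_rt", [(None, 2.0), (2.0, None), (2.0, 0.0), (2.0, -1.0)])
    def test_rrt_not_evaluable_inputs(self, rt, is_rt):
        assert compute_rrt(rt, is_rt) is None

    def test_ion_ratio_trivials(self):
        assert compute_ion_ratio(5.0, 5.0) == 1.0
        assert compute_ion_ratio(0.0, 7.0) == 0.0
        assert compute_ion_ratio(1.0, 0.0) is None
        assert compute_ion_ratio(None, 5.0) is None

    @given(st.floats(0.0, 1e6), st.floats(1e-3, 1e6))
    def test_ion_ratio_times_quantifier_recovers_confirmer(self, conf, quant):
        assert compute_ion_ratio(conf, quant) * quant == pytest.approx(conf, rel=1e-9, abs=1e-9)


class TestRRTRule:
    @pytest.mark.parametrize("rrt, expected", [
        (1.000, FlagStatus.PASS),
        (0.984, FlagStatus.PASS),   # inclusive lower bound
        (1.024, FlagStatus.PASS),   # inclusive upper bound
        (0.9839, FlagStatus.FAIL),
        (1.0241, FlagStatus.FAIL),
    ])
    def test_window_boundaries(self, rrt, expected):
        r = row(rt=2.0 * rrt, is_rt=2.0)
        assert check_rrt(r, CUT).status is expected

    def test_null_rt_is_not_evaluable(self):
        assert check_rrt(row(rt=None, is_rt=2.0), CUT).status is FlagStatus.NOT_EVALUABLE

    def test_disabled_window_passes_through(self):
        cut = dataclasses.replace(CUT, rrt_window=None)
        flag = check_rrt(row(rt=5.0, is_rt=2.0), cut)
        assert flag.status is FlagStatus.PASS and flag.threshold_repr == "disabled"

    def test_thousand_random_rrts_match_brute_force(self):
        rng = np.random.default_rng(5)
        low, high = CUT.rrt_window
        for _ in range(1000):
            rrt = float(rng.uniform(0.95, 1.05))
            r = row(rt=2.0 * rrt, is_rt=2.0)
            expect = FlagStatus.PASS if low <= rrt <= high else FlagStatus.FAIL
            assert check_rrt(r, CUT).status is expect


class TestMinimumRules:
    @pytest.mark.parametrize("check, field, minimum", [
        (check_is_peak_area, "is_peak_area", 20_000.0),
        (check_sn, "sn", 10.0),
    ])
    def test_pass_at_equality_fail_strictly_below(self, check, field, minimum):
        assert check(row(**{field: minimum}), CUT).status is FlagStatus.PASS
        assert check(row(**{field: minimum * 0.999}), CUT).status is FlagStatus.FAIL
        assert check(row(**{field: 0.0}), CUT).status is FlagStatus.FAIL
        assert check(row(**{field: None}), CUT).status is FlagStatus.NOT_EVALUABLE

    def test_null_threshold_is_disabled_pass_through(self):
        cut = dataclasses.replace(CUT, sn_min=None)
        flag = check_sn(row(sn=0.001), cut)
        assert flag.status is FlagStatus.PASS and flag.threshold_repr == "disabled"


class TestIonRatioRule:
    def test_measured_equals_expected_passes(self):
        r = row(confirming_ion_area=500.0, peak_area=1000.0)
        assert check_ion_ratio(r, CUT, [r]).status is FlagStatus.PASS

    def test_relative_deviation_just_over_tolerance_fails(self):
        # |0.61/0.50 - 1| = 0.22 > 0.2
        r = row(confirming_ion_area=610.0, peak_area=1000.0)
        assert check_ion_ratio(r, CUT, [r]).status is FlagStatus.FAIL

    def test_expected_derived_from_batch_calibrators(self):
        cut = dataclasses.replace(CUT, expected_ion_ratio=None)
        cals = [
            row(sample_type=SampleType.CALIBRATOR, sample_id=f"Std-{lvl}",
                confirming_ion_area=300.0, peak_area=1000.0, result_key=k)
            for k, lvl in enumerate("ABC", start=10)
        ]
        patient = row(confirming_ion_area=300.0, peak_area=1000.0)
        assert check_ion_ratio(patient, cut, cals + [patient]).status is FlagStatus.PASS

    def test_no_calibrators_and_no_expected_is_not_evaluable(self):
        cut = dataclasses.replace(CUT, expected_ion_ratio=None)
        patient = row(confirming_ion_area=300.0, peak_area=1000.0)
        assert check_ion_ratio(patient, cut, [patient]).status is FlagStatus.NOT_EVALUABLE


class TestStdARule:
    def cal_rows(self, areas):
        return [
            row(sample_type=SampleType.CALIBRATOR, sample_id=f"Std-{lvl}",
                peak_area=area, concentration=conc, result_key=k)
            for k, (lvl, conc, area) in enumerate(
                zip("ABC", (1.0, 5.0, 10.0), areas)
            )
        ]

    def test_boundary_pass_and_attachment_to_std_a_row(self):
        flag = check_std_a(self.cal_rows([5_000.0, 9e5, 9e5]), CUT)
        assert flag.status is FlagStatus.PASS
        assert flag.result_key == 0  # the Std-A row

    def test_below_cutoff_fails_even_if_other_levels_are_high(self):
        assert check_std_a(self.cal_rows([4_999.0, 9e5, 9e5]), CUT).status is FlagStatus.FAIL

    def test_null_std_a_area_is_not_evaluable(self):
        assert check_std_a(self.cal_rows([None, 9e5, 9e5]), CUT).status is FlagStatus.NOT_EVALUABLE

    def test_no_calibrators_is_not_evaluable(self):
        assert check_std_a([row()], CUT).status is FlagStatus.NOT_EVALUABLE

    def test_planted_sub_cutoff_std_a_in_3_of_10_batches(self):
        config = synth.plant_failures(
            synth.GeneratorConfig(
                seed=9, n_batches=10, patients_per_batch=2, missing_field_rate=0.0,
                compounds=synth.default_compound_panel(3),
            ),
            [synth.PlantStdABelow(n_batches=3, cutoff=4_000.0)],
        )
        batches, truth = synth.generate_batches(config)
        cut = CompoundCutoffs(compound=config.compounds[0].name,
                              std_a_peak_area_min=4_000.0)
        fails = 0
        for parsed in batches:
            group = [r for r in parsed.results if r.compound == cut.compound]
            if check_std_a(group, cut).status is FlagStatus.FAIL:
                fails += 1
        assert fails == 3
        assert (truth["planted"] == "std_a_below").sum() == 3


class TestLotAdjustment:
    @pytest.mark.parametrize("reference, lot, cutoff, expected", [
        (100_000, 100_000, 20_000, 20_000),   # identical lots
        (100_000, 110_000, 20_000, 20_000),   # bias exactly 10%: inclusive, unchanged
        (100_000, 90_000, 20_000, 20_000),
        (100_000, 130_000, 20_000, 26_000),   # 30% hot lot rescales the cutoff
        (100_000, 80_000, 20_000, 16_000),
    ])
    def test_rescaling(self, reference, lot, cutoff, expected):
        assert adjust_is_cutoff_for_lot(reference, lot, cutoff) == pytest.approx(expected)

    @pytest.mark.parametrize("reference", [0.0, -5.0])
    def test_non_positive_reference_raises(self, reference):
        with pytest.raises(ValueError):
            adjust_is_cutoff_for_lot(reference, 1.0, 1.0)


def make_ruleset(compounds, rng=None, name="rs"):
    rng = rng or np.random.default_rng(0)
    cutoffs = []
    for compound in compounds:
        cutoffs.append(
            CompoundCutoffs(
                compound=compound,
                rrt_window=(float(rng.uniform(0.96, 0.99)), float(rng.uniform(1.01, 1.04))),
                is_peak_area_min=float(rng.uniform(10_000, 80_000)),
                std_a_peak_area_min=float(rng.uniform(5_000, 60_000)),
                sn_min=float(rng.uniform(5, 60)),
                ion_ratio_tolerance=float(rng.uniform(0.1, 0.3)),
                expected_ion_ratio=None if rng.random() < 0.5 else float(rng.uniform(0.3, 0.8)),
            )
        )
    return RuleSet.from_cutoffs(name, cutoffs)


class TestEvaluateCorpus:
    def test_random_corpus_matches_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        compounds = [c.name for c in synth.default_compound_panel(6)]
        results = random_results(rng, 2_000, compounds,
                                 boundary_values=(20_000.0, 10.0))
        ruleset = make_ruleset(compounds, rng)
        report = evaluate_corpus(results, ruleset)
        assert report_as_map(report) == brute_force_flags(results, ruleset)

    def test_all_null_numeric_fields_never_fail(self):
        results = [
            row(result_key=k, sample_id=f"P{k}", rt=None, sn=None,
                peak_area=None, confirming_ion_area=None, is_peak_area=None,
                is_rt=None)
            for k in range(20)
        ]
        report = evaluate_corpus(results, RuleSet.from_cutoffs("rs", [CUT]))
        assert report.n_fail == 0
        assert all(f.status is FlagStatus.NOT_EVALUABLE for f in report.flags)

    def test_totals_conserve_flag_counts(self):
        rng = np.random.default_rng(23)
        compounds = [c.name for c in synth.default_compound_panel(4)]
        results = random_results(rng, 500, compounds)
        report = evaluate_corpus(results, make_ruleset(compounds, rng))
        totals = report.totals
        assert sum(sum(v) for v in totals.values()) == len(report.flags)
        for rule, (n_pass, n_fail, n_ne) in totals.items():
            statuses = [f.status for f in report.flags if f.rule is rule]
            assert n_pass == statuses.count(FlagStatus.PASS)
            assert n_fail == statuses.count(FlagStatus.FAIL)
            assert n_ne == statuses.count(FlagStatus.NOT_EVALUABLE)

    def test_raising_minima_never_decreases_fails(self):
        rng = np.random.default_rng(31)
        compounds = [c.name for c in synth.default_compound_panel(4)]
        results = random_results(rng, 800, compounds)
        base = make_ruleset(compounds, np.random.default_rng(1))
        raised = RuleSet.from_cutoffs(
            "raised",
            [
                dataclasses.replace(
                    c,
                    is_peak_area_min=c.is_peak_area_min * 1.5,
                    sn_min=c.sn_min * 1.5,
                    std_a_peak_area_min=c.std_a_peak_area_min * 1.5,
                )
                for c in base.entries.values()
            ],
        )
        assert evaluate_corpus(results, raised).n_fail >= evaluate_corpus(results, base).n_fail

    def test_widening_rrt_window_never_increases_fails(self):
        rng = np.random.default_rng(37)
        compounds = [c.name for c in synth.default_compound_panel(4)]
        results = random_results(rng, 800, compounds)
        base = make_ruleset(compounds, np.random.default_rng(1))
        widened = RuleSet.from_cutoffs(
            "wide",
            [
                dataclasses.replace(
                    c, rrt_window=(c.rrt_window[0] - 0.02, c.rrt_window[1] + 0.02)
                )
                for c in base.entries.values()
            ],
        )
        def rrt_fails(report):
            return sum(
                1 for f in report.flags
                if f.rule is Rule.RRT and f.status is FlagStatus.FAIL
            )
        assert rrt_fails(evaluate_corpus(results, widened)) <= rrt_fails(
            evaluate_corpus(results, base)
        )

    def test_unresolvable_compound_lists_missing_entries(self):
        results = [row(compound="Ghost")]
        with pytest.raises(RuleResolutionError, match="Ghost"):
            evaluate_corpus(results, RuleSet.from_cutoffs("rs", [CUT]))

    def test_instrument_specific_entry_beats_wildcard(self):
        specific = dataclasses.replace(CUT, instrument_id="LCMS-1", sn_min=100.0)
        rs = RuleSet.from_cutoffs("rs", [CUT, specific])
        assert rs.resolve("Morphine", "LCMS-1").sn_min == 100.0
        assert rs.resolve("Morphine", "LCMS-9").sn_min == 10.0


def test_ruleset_yaml_roundtrip(tmp_path):
    rs = make_ruleset(["Morphine", "Codeine"], np.random.default_rng(3))
    path = ruleset_to_yaml(rs, tmp_path / "rules.yaml")
    back = ruleset_from_yaml(path)
    assert back.name == rs.name and back.entries == rs.entries
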
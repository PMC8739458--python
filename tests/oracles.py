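"""Independent brute-force re-implementations of the QC rule semantics.

Deliberately written as plain loops with no imports from
``lcmsqc.qc_engine``'s evaluation path, so that oracle-equivalence
tests compare two genuinely separate routes to the same flags.
"""

from collections import defaultdict

import numpy as np

from lcmsqc.records import ResultRecord, SampleType


def random_results(rng, n, compounds, instruments=("LCMS-1", "LCMS-2"),
                   null_rate=0.1, boundary_rate=0.1, boundary_values=()):
    """Randomized result rows, salted with nulls and boundary-equal values."""
    rows = []
    n_batches = max(1, n // 200)
    for i in range(n):
        batch = f"rand_{i % n_batches:04d}.xml"

        def num(scale, allow_null=True):
            if allow_null and rng.random() < null_rate:
                return None
            if boundary_values and rng.random() < boundary_rate:
                return float(rng.choice(boundary_values))
            return float(scale * rng.lognormal(0.0, 0.5))

        stype = [SampleType.PATIENT, SampleType.QC, SampleType.CALIBRATOR][
            int(rng.integers(3))
        ]
        rt_base = 2.0 + float(rng.integers(4))
        rows.append(
            ResultRecord(
                xml_file_name=batch,
                sample_type=stype,
                sample_id=f"S{i}",
                compound=str(rng.choice(compounds)),
                instrument_id=str(rng.choice(instruments)),
                peak_area=num(50_000),
                confirming_ion_area=num(25_000),
                rt=None if rng.random() < null_rate else rt_base * float(rng.normal(1.0, 0.02)),
                sn=num(50),
                is_peak_area=num(60_000),
                is_rt=None if rng.random() < null_rate else rt_base,
                is_sn=num(200),
                concentration=num(30),
                result_key=i,
            )
        )
    return rows


def _first_calibrator_bf(group):
    """Lowest-level calibrator by Std-X letter, else lowest concentration."""
    cals = [r for r in group if r.sample_type is SampleType.CALIBRATOR]
    if not cals:
        return None
    lettered = []
    for r in cals:
        sid = r.sample_id.strip()
        letter = sid[-1].upper() if len(sid) >= 2 and sid[-2] in "-_ " and sid[-1].isalpha() else None
        lettered.append((letter, r))
    if all(letter is not None for letter, _r in lettered):
        return sorted(lettered, key=lambda t: (t[0], t[1].sample_id))[0][1]
    return sorted(
        cals,
        key=lambda r: (r.concentration is None,
                       r.concentration if r.concentration is not None else 0.0,
                       r.sample_id),
    )[0]


def brute_force_flags(results, ruleset):
    """Re-derive every flag with plain loops; returns
    {(result_key, rule_name): status_name} plus std_a keyed flags."""
    flags = {}
    groups = defaultdict(list)
    for r in results:
        groups[(r.xml_file_name, r.compound)].append(r)
    for (_f, _c), group in groups.items():
        cut = ruleset.resolve(group[0].compound, group[0].instrument_id)

        cal_ratios = []
        for r in group:
            if r.sample_type is SampleType.CALIBRATOR:
                if (r.confirming_ion_area is not None and r.peak_area is not None
                        and r.peak_area > 0):
                    cal_ratios.append(r.confirming_ion_area / r.peak_area)
        expected_ratio = (
            cut.expected_ion_ratio
            if cut.expected_ion_ratio is not None
            else (sum(cal_ratios) / len(cal_ratios) if cal_ratios else None)
        )

        for r in group:
            if r.sample_type not in (SampleType.PATIENT, SampleType.QC):
                continue
            # rrt
            if cut.rrt_window is None:
                flags[(r.result_key, "rrt")] = "pass"
            elif r.rt is None or r.is_rt is None or r.is_rt <= 0 or r.rt <= 0:
                flags[(r.result_key, "rrt")] = "not_evaluable"
            else:
                rrt = r.rt / r.is_rt
                ok = cut.rrt_window[0] <= rrt <= cut.rrt_window[1]
                flags[(r.result_key, "rrt")] = "pass" if ok else "fail"
            # is peak area
            if cut.is_peak_area_min is None:
                flags[(r.result_key, "is_peak_area")] = "pass"
            elif r.is_peak_area is None:
                flags[(r.result_key, "is_peak_area")] = "not_evaluable"
            else:
                ok = r.is_peak_area >= cut.is_peak_area_min
                flags[(r.result_key, "is_peak_area")] = "pass" if ok else "fail"
            # s/n
            if cut.sn_min is None:
                flags[(r.result_key, "sn")] = "pass"
            elif r.sn is None:
                flags[(r.result_key, "sn")] = "not_evaluable"
            else:
                flags[(r.result_key, "sn")] = "pass" if r.sn >= cut.sn_min else "fail"
            # ion ratio
            if cut.ion_ratio_tolerance is None:
                flags[(r.result_key, "ion_ratio")] = "pass"
            else:
                measurable = (
                    r.confirming_ion_area is not None
                    and r.peak_area is not None
                    and r.peak_area > 0
                )
                if not measurable or expected_ratio is None or expected_ratio <= 0:
                    flags[(r.result_key, "ion_ratio")] = "not_evaluable"
                else:
                    measured = r.confirming_ion_area / r.peak_area
                    ok = abs(measured / expected_ratio - 1.0) <= cut.ion_ratio_tolerance
                    flags[(r.result_key, "ion_ratio")] = "pass" if ok else "fail"

        if any(r.sample_type is SampleType.CALIBRATOR for r in group):
            std_a = _first_calibrator_bf(group)
            key = (None if std_a is None else std_a.result_key, "std_a")
            if cut.std_a_peak_area_min is None:
                flags[key] = "pass"
            elif std_a is None or std_a.peak_area is None:
                flags[key] = "not_evaluable"
            else:
                ok = std_a.peak_area >= cut.std_a_peak_area_min
                flags[key] = "pass" if ok else "fail"
    return flags


def report_as_map(report):
    return {(f.result_key, f.rule.value): f.status.value for f in report.flags}
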
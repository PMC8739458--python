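"""Per-sample QC rule evaluation for targeted quantification batches.

Five rules gate each analytical result:

``rrt``
    Relative retention time — analyte RT divided by its internal
    standard's RT — must fall inside a per-compound window.  Analyte
    and isotope-labelled internal standard co-elute, so the expected
    value is ~1.0.
``is_peak_area``
    The internal-standard peak area must reach a minimum; a depressed
    IS signal indicates injection failure or matrix ion suppression.
``std_a``
    The first (lowest-level) calibrator's analyte peak area must reach
    a minimum — a batch-level sensitivity gate, evaluated once per
    compound per batch.
``sn``
    Chromatographic signal-to-noise minimum on the analyte peak.
``ion_ratio``
    Confirming-ion area over quantifying-ion area must sit within a
    relative tolerance band around an expected ratio (configured, or
    derived from the batch's calibrators) — the identity check.

Boundary semantics, fixed and tested: every minimum passes at equality
and the RRT window is inclusive at both bounds.  A rule whose threshold
is null is *disabled* and passes through (``threshold_repr ==
"disabled"``), which permits partial rule sets during migration.  A
null measurement is never a failure: it yields ``not_evaluable``.
"""

from __future__ import annotations

import enum
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import yaml

from .records import ParsedBatch, ResultRecord, SampleType, first_calibrator

__all__ = [
    "Rule",
    "FlagStatus",
    "CompoundCutoffs",
    "RuleSet",
    "Flag",
    "FlagReport",
    "WILDCARD_INSTRUMENT",
    "RuleResolutionError",
    "compute_rrt",
    "compute_ion_ratio",
    "check_rrt",
    "check_is_peak_area",
    "check_sn",
    "check_ion_ratio",
    "check_std_a",
    "adjust_is_cutoff_for_lot",
    "evaluate_batch",
    "evaluate_corpus",
    "ruleset_from_yaml",
    "ruleset_to_yaml",
]

WILDCARD_INSTRUMENT = "*"

#: Default relative tolerance on the ion ratio when a rule set enables
#: the check without naming one (±20%, standard confirmation practice).
DEFAULT_ION_RATIO_TOLERANCE = 0.20

#: Accepted relative bias between internal-standard lots before the IS
#: peak-area cutoff is rescaled.
IS_LOT_BIAS_TOLERANCE = 0.10


class Rule(str, enum.Enum):
    RRT = "rrt"
    IS_PEAK_AREA = "is_peak_area"
    STD_A = "std_a"
    SN = "sn"
    ION_RATIO = "ion_ratio"

    def __str__(self) -> str:
        return self.value


class FlagStatus(str, enum.Enum):
    PASS = "pass"
    FAIL = "fail"
    NOT_EVALUABLE = "not_evaluable"

    def __str__(self) -> str:
        return self.value


class RuleResolutionError(KeyError):
    """A compound in the data has no rule entry (specific or wildcard)."""


@dataclass(frozen=True)
class CompoundCutoffs:
    """QC thresholds for one compound on one instrument (or wildcard).

    Null thresholds disable the corresponding rule.
    ``expected_ion_ratio = None`` with a non-null tolerance means the
    expected ratio is derived from the batch's calibrators.
    """

    compound: str
    instrument_id: str = WILDCARD_INSTRUMENT
    rrt_window: Optional[tuple[float, float]] = None
    is_peak_area_min: Optional[float] = None
    std_a_peak_area_min: Optional[float] = None
    sn_min: Optional[float] = None
    ion_ratio_tolerance: Optional[float] = None
    expected_ion_ratio: Optional[float] = None
    lloq: Optional[float] = None

    def __post_init__(self) -> None:
        if self.rrt_window is not None:
            low, high = self.rrt_window
            if not (0 < low < high):
                raise ValueError(f"invalid RRT window {self.rrt_window}")
        if self.ion_ratio_tolerance is not None and not (
            0 < self.ion_ratio_tolerance < 1
        ):
            raise ValueError(
                f"ion_ratio_tolerance must lie in (0, 1), got {self.ion_ratio_tolerance}"
            )


@dataclass
class RuleSet:
    """Named, versioned map (compound, instrument) -> cutoffs.

    Lookup is total over its compounds: an instrument-specific entry
    beats the wildcard entry; a compound with neither raises.
    """

    name: str
    entries: dict[tuple[str, str], CompoundCutoffs]
    version: str = "1"

    @staticmethod
    def from_cutoffs(name: str, cutoffs: Iterable[CompoundCutoffs], version: str = "1") -> "RuleSet":
        entries = {}
        for c in cutoffs:
            key = (c.compound, c.instrument_id)
            if key in entries:
                raise ValueError(f"duplicate rule entry for {key}")
            entries[key] = c
        return RuleSet(name=name, entries=entries, version=version)

    def resolve(self, compound: str, instrument_id: str) -> CompoundCutoffs:
        hit = self.entries.get((compound, instrument_id))
        if hit is None:
            hit = self.entries.get((compound, WILDCARD_INSTRUMENT))
        if hit is None:
            raise RuleResolutionError(
                f"no rule entry for compound {compound!r} on instrument "
                f"{instrument_id!r} (and no wildcard) in rule set {self.name!r}"
            )
        return hit

    def compounds(self) -> set[str]:
        return {c for (c, _i) in self.entries}


@dataclass(frozen=True)
class Flag:
    result_key: Optional[int]
    rule: Rule
    status: FlagStatus
    measured: Optional[float]
    threshold_repr: str


@dataclass
class FlagReport:
    ruleset_name: str
    flags: list[Flag] = field(default_factory=list)

    @property
    def totals(self) -> dict[Rule, tuple[int, int, int]]:
        """Per rule: (n_pass, n_fail, n_not_evaluable); exact tallies."""
        counts: dict[Rule, list[int]] = defaultdict(lambda: [0, 0, 0])
        index = {FlagStatus.PASS: 0, FlagStatus.FAIL: 1, FlagStatus.NOT_EVALUABLE: 2}
        for f in self.flags:
            counts[f.rule][index[f.status]] += 1
        return {rule: tuple(c) for rule, c in counts.items()}

    @property
    def n_fail(self) -> int:
        return sum(1 for f in self.flags if f.status is FlagStatus.FAIL)


def compute_rrt(rt: Optional[float], is_rt: Optional[float]) -> Optional[float]:
    """Relative retention time rt / is_rt; None when not evaluable."""
    if rt is None or is_rt is None or is_rt <= 0 or rt <= 0:
        return None
    return rt / is_rt


def compute_ion_ratio(
    confirming_area: Optional[float], quantifying_area: Optional[float]
) -> Optional[float]:
    """Confirming-ion / quantifying-ion area ratio; None when not evaluable."""
    if confirming_area is None or quantifying_area is None or quantifying_area <= 0:
        return None
    return confirming_area / quantifying_area


def _disabled(result: ResultRecord, rule: Rule, measured: Optional[float]) -> Flag:
    return Flag(result.result_key, rule, FlagStatus.PASS, measured, "disabled")


def _minimum_check(
    result: ResultRecord, rule: Rule, measured: Optional[float], minimum: Optional[float]
) -> Flag:
    if minimum is None:
        return _disabled(result, rule, measured)
    if measured is None:
        return Flag(result.result_key, rule, FlagStatus.NOT_EVALUABLE, None, f">= {minimum}")
    status = FlagStatus.PASS if measured >= minimum else FlagStatus.FAIL
    return Flag(result.result_key, rule, status, measured, f">= {minimum}")


def check_rrt(result: ResultRecord, cutoffs: CompoundCutoffs) -> Flag:
    """Inclusive-window RRT check; not_evaluable when rt or is_rt is null."""
    rrt = compute_rrt(result.rt, result.is_rt)
    if cutoffs.rrt_window is None:
        return _disabled(result, Rule.RRT, rrt)
    low, high = cutoffs.rrt_window
    repr_ = f"[{low}, {high}]"
    if rrt is None:
        return Flag(result.result_key, Rule.RRT, FlagStatus.NOT_EVALUABLE, None, repr_)
    status = FlagStatus.PASS if low <= rrt <= high else FlagStatus.FAIL
    return Flag(result.result_key, Rule.RRT, status, rrt, repr_)


def check_is_peak_area(result: ResultRecord, cutoffs: CompoundCutoffs) -> Flag:
    return _minimum_check(
        result, Rule.IS_PEAK_AREA, result.is_peak_area, cutoffs.is_peak_area_min
    )


def check_sn(result: ResultRecord, cutoffs: CompoundCutoffs) -> Flag:
    return _minimum_check(result, Rule.SN, result.sn, cutoffs.sn_min)


def _expected_ion_ratio(
    cutoffs: CompoundCutoffs, batch_results: Sequence[ResultRecord]
) -> Optional[float]:
    if cutoffs.expected_ion_ratio is not None:
        return cutoffs.expected_ion_ratio
    ratios = [
        compute_ion_ratio(r.confirming_ion_area, r.peak_area)
        for r in batch_results
        if r.sample_type is SampleType.CALIBRATOR
    ]
    ratios = [x for x in ratios if x is not None]
    if not ratios:
        return None
    return sum(ratios) / len(ratios)


def check_ion_ratio(
    result: ResultRecord,
    cutoffs: CompoundCutoffs,
    batch_results: Sequence[ResultRecord],
) -> Flag:
    """Relative-deviation ion-ratio check.

    Expected ratio: the configured value if set, otherwise the mean
    ratio over the batch's calibrator rows with usable areas.  Fails
    when |measured / expected - 1| exceeds the tolerance.
    """
    if cutoffs.ion_ratio_tolerance is None:
        return _disabled(
            result, Rule.ION_RATIO,
            compute_ion_ratio(result.confirming_ion_area, result.peak_area),
        )
    tol = cutoffs.ion_ratio_tolerance
    measured = compute_ion_ratio(result.confirming_ion_area, result.peak_area)
    expected = _expected_ion_ratio(cutoffs, batch_results)
    if measured is None or expected is None or expected <= 0:
        repr_ = f"within ±{tol:.0%} of {'?' if expected is None else expected}"
        return Flag(result.result_key, Rule.ION_RATIO, FlagStatus.NOT_EVALUABLE, measured, repr_)
    repr_ = f"within ±{tol:.0%} of {expected:.4g}"
    status = (
        FlagStatus.PASS if abs(measured / expected - 1.0) <= tol else FlagStatus.FAIL
    )
    return Flag(result.result_key, Rule.ION_RATIO, status, measured, repr_)


def check_std_a(
    batch_results: Sequence[ResultRecord], cutoffs: CompoundCutoffs
) -> Flag:
    """Batch-level first-calibrator signal gate for one compound.

    ``batch_results`` must be one batch × one compound.  The flag is
    attached to the Std-A row's result key.
    """
    std_a = first_calibrator(batch_results)
    if cutoffs.std_a_peak_area_min is None:
        return Flag(
            None if std_a is None else std_a.result_key,
            Rule.STD_A, FlagStatus.PASS,
            None if std_a is None else std_a.peak_area, "disabled",
        )
    minimum = cutoffs.std_a_peak_area_min
    if std_a is None or std_a.peak_area is None:
        return Flag(
            None if std_a is None else std_a.result_key,
            Rule.STD_A, FlagStatus.NOT_EVALUABLE, None, f">= {minimum}",
        )
    status = FlagStatus.PASS if std_a.peak_area >= minimum else FlagStatus.FAIL
    return Flag(std_a.result_key, Rule.STD_A, status, std_a.peak_area, f">= {minimum}")


def adjust_is_cutoff_for_lot(
    reference_mean: float, current_lot_mean: float, cutoff: float
) -> float:
    """Rescale an IS peak-area cutoff for a new internal-standard lot.

    Internal-standard solutions are prepared in-lab and lots vary
    slightly; a relative bias of up to 10% (inclusive) between the
    current lot's mean peak area and the reference lot's is accepted
    without change.  Beyond that, the cutoff is rescaled by the lot
    ratio so the flag rate is preserved rather than silently shifting
    the sensitivity of the check.
    """
    if reference_mean <= 0 or current_lot_mean <= 0 or cutoff <= 0:
        raise ValueError("reference_mean, current_lot_mean and cutoff must be positive")
    ratio = current_lot_mean / reference_mean
    # inclusive 10% boundary; tiny epsilon absorbs float division error
    if abs(ratio - 1.0) <= IS_LOT_BIAS_TOLERANCE * (1.0 + 1e-9):
        return cutoff
    return cutoff * ratio


#: Rules applied to each individual patient / QC row.
PER_RESULT_RULES = (Rule.RRT, Rule.IS_PEAK_AREA, Rule.SN, Rule.ION_RATIO)
#: Sample types whose rows are individually evaluated.
EVALUATED_SAMPLE_TYPES = frozenset({SampleType.PATIENT, SampleType.QC})


def evaluate_corpus(
    results: Sequence[ResultRecord],
    ruleset: RuleSet,
    ruleset_name: Optional[str] = None,
) -> FlagReport:
    """Evaluate all five rules over results spanning one or more batches.

    Patient and QC rows receive the four per-result rules; the Std-A
    rule runs once per (batch, compound).  Rows are grouped by
    ``xml_file_name`` so calibrator-derived context (expected ion
    ratio, Std-A row) never leaks across batches.
    """
    missing = sorted(
        {
            (r.compound, r.instrument_id)
            for r in results
            if (r.compound, r.instrument_id) not in ruleset.entries
            and (r.compound, WILDCARD_INSTRUMENT) not in ruleset.entries
        }
    )
    if missing:
        raise RuleResolutionError(
            f"rule set {ruleset.name!r} is missing entries for: {missing}"
        )

    by_group: dict[tuple[str, str], list[ResultRecord]] = defaultdict(list)
    for r in results:
        by_group[(r.xml_file_name, r.compound)].append(r)

    report = FlagReport(ruleset_name=ruleset_name or ruleset.name)
    for (_file, _compound), group in by_group.items():
        cutoffs = ruleset.resolve(group[0].compound, group[0].instrument_id)
        for r in group:
            if r.sample_type not in EVALUATED_SAMPLE_TYPES:
                continue
            report.flags.append(check_rrt(r, cutoffs))
            report.flags.append(check_is_peak_area(r, cutoffs))
            report.flags.append(check_sn(r, cutoffs))
            report.flags.append(check_ion_ratio(r, cutoffs, group))
        if any(r.sample_type is SampleType.CALIBRATOR for r in group):
            report.flags.append(check_std_a(group, cutoffs))
    return report


def evaluate_batch(parsed: ParsedBatch, ruleset: RuleSet) -> FlagReport:
    """Apply the full rule set to one parsed batch."""
    return evaluate_corpus(parsed.results, ruleset)


# ---------------------------------------------------------------------------
# Rule-set serialization (YAML)

def _cutoffs_to_dict(c: CompoundCutoffs) -> dict:
    d: dict = {"compound": c.compound, "instrument": c.instrument_id}
    if c.rrt_window is not None:
        d["rrt_window"] = [c.rrt_window[0], c.rrt_window[1]]
    for attr in (
        "is_peak_area_min", "std_a_peak_area_min", "sn_min",
        "ion_ratio_tolerance", "expected_ion_ratio", "lloq",
    ):
        value = getattr(c, attr)
        if value is not None:
            d[attr] = value
    return d


def ruleset_to_yaml(ruleset: RuleSet, path: Union[str, Path]) -> Path:
    payload = {
        "name": ruleset.name,
        "version": ruleset.version,
        "cutoffs": [
            _cutoffs_to_dict(c)
            for _key, c in sorted(ruleset.entries.items())
        ],
    }
    path = Path(path)
    path.write_text(yaml.safe_dump(payload, sort_keys=False), encoding="utf-8")
    return path


def ruleset_from_yaml(path: Union[str, Path]) -> RuleSet:
    payload = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    cutoffs = []
    for entry in payload.get("cutoffs", []):
        window = entry.get("rrt_window")
        cutoffs.append(
            CompoundCutoffs(
                compound=entry["compound"],
                instrument_id=entry.get("instrument", WILDCARD_INSTRUMENT),
                rrt_window=None if window is None else (float(window[0]), float(window[1])),
                is_peak_area_min=entry.get("is_peak_area_min"),
                std_a_peak_area_min=entry.get("std_a_peak_area_min"),
                sn_min=entry.get("sn_min"),
                ion_ratio_tolerance=entry.get("ion_ratio_tolerance"),
                expected_ion_ratio=entry.get("expected_ion_ratio"),
                lloq=entry.get("lloq"),
            )
        )
    return RuleSet.from_cutoffs(
        name=payload.get("name", Path(path).stem),
        cutoffs=cutoffs,
        version=str(payload.get("version", "1")),
    )
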
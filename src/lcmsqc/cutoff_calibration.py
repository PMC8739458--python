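"""Empirical re-derivation of QC cutoffs and rule-set comparison.

The calibration workflow mirrors how a laboratory reviews thresholds
set during assay validation against accumulated production data:

1. pull the historical distribution of a parameter (internal-standard
   peak area, analyte peak area, S/N, or RRT) per compound and per
   instrument — instruments differ systematically in ion optics and
   detector gain, so borders are always derived per group;
2. compute the empirical border excluding the bottom ``level`` fraction
   of the data (default 2%);
3. quantify how an existing cutoff performs (fraction of historical
   values it would flag), optionally in two passes: calibrators + QC
   material only, then including patient specimens where matrix
   effects (ion suppression) widen the left tail;
4. compare a revised rule set against the incumbent by double-running
   the flag engine on identical observations and counting flag
   transitions.

Conventions: the quantile estimator is linear interpolation between
order statistics (the common "type 7" definition) and ``fraction_below``
counts strictly-below values, mirroring the flag engine's
pass-at-equality boundary so predicted fail rates match realized flags
exactly.
"""

from __future__ import annotations

import enum
import warnings as _warnings
from collections import defaultdict
from dataclasses import dataclass, field
from datetime import datetime
from typing import Iterable, Optional, Sequence

import numpy as np

from .datastore import Store, query_results
from .qc_engine import (
    FlagStatus,
    Rule,
    RuleSet,
    evaluate_corpus,
)
from .records import ResultFilter, ResultRecord, SampleType

__all__ = [
    "Parameter",
    "CutoffEstimate",
    "RulesetComparison",
    "empirical_border",
    "fraction_below",
    "fraction_outside_window",
    "derive_cutoffs",
    "compare_rulesets",
    "DEFAULT_MIN_GROUP_SIZE",
]

DEFAULT_MIN_GROUP_SIZE = 50


class Parameter(str, enum.Enum):
    """Monitored parameters with historical distributions."""

    IS_PEAK_AREA = "is_peak_area"
    PEAK_AREA = "peak_area"
    SN = "sn"
    RRT = "rrt"

    def __str__(self) -> str:
        return self.value


def parameter_value(record: ResultRecord, parameter: "Parameter") -> Optional[float]:
    """Extract one parameter value from a result row (None if missing)."""
    from .qc_engine import compute_rrt

    if parameter is Parameter.RRT:
        return compute_rrt(record.rt, record.is_rt)
    return getattr(record, parameter.value)


def _clean(values: Iterable[Optional[float]]) -> np.ndarray:
    arr = np.asarray([v for v in values if v is not None], dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("no usable (non-null, finite) values")
    return arr


def empirical_border(values: Iterable[Optional[float]], level: float = 0.02) -> float:
    """Empirical quantile at ``level`` — the border under which the
    bottom ``level`` fraction of the historical data is excluded.

    Nulls are removed first; the estimator is linear interpolation
    between order statistics (quantile "type 7"), so with distinct
    values the count strictly below the border is within one of
    ``level * n``.
    """
    if not (0.0 < level < 1.0):
        raise ValueError(f"level must lie in (0, 1), got {level}")
    return float(np.quantile(_clean(values), level, method="linear"))


def fraction_below(values: Iterable[Optional[float]], cutoff: float) -> float:
    """Fraction of non-null values strictly below ``cutoff``.

    Strict inequality matches the flag engine's pass-at-equality
    convention, so this predicts the realized fail rate of a
    minimum-type rule exactly.
    """
    arr = _clean(values)
    return float(np.count_nonzero(arr < cutoff) / arr.size)


def fraction_outside_window(
    values: Iterable[Optional[float]], window: tuple[float, float]
) -> float:
    """Fraction of non-null values outside an inclusive window."""
    low, high = window
    if not low < high:
        raise ValueError(f"window low must be < high, got {window}")
    arr = _clean(values)
    outside = np.count_nonzero((arr < low) | (arr > high))
    return float(outside / arr.size)


@dataclass(frozen=True)
class CutoffEstimate:
    """An empirically derived border for one parameter × compound ×
    instrument over a date range."""

    compound: str
    instrument_id: str
    parameter: Parameter
    level: float
    border: float
    n: int
    date_range: Optional[tuple[datetime, datetime]] = None
    sample_types: Optional[frozenset[SampleType]] = None


def derive_cutoffs(
    store: Store,
    flt: ResultFilter,
    parameter: Parameter,
    level: float = 0.02,
    min_group_size: int = DEFAULT_MIN_GROUP_SIZE,
) -> list[CutoffEstimate]:
    """One percentile border per (compound, instrument) group in the
    filtered selection.

    Whether calibrators + QC only or patients as well contribute is
    governed by ``flt.sample_types`` — one code path, two review
    configurations.  Groups with fewer than ``min_group_size`` usable
    values are skipped with a warning rather than yielding an unstable
    border.
    """
    records = query_results(flt, store)
    if not records:
        raise ValueError("filter selects no results")
    groups: dict[tuple[str, str], list[float]] = defaultdict(list)
    for r in records:
        value = parameter_value(r, parameter)
        if value is not None:
            groups[(r.compound, r.instrument_id)].append(value)
    estimates = []
    for (compound, instrument), values in sorted(groups.items()):
        if len(values) < min_group_size:
            _warnings.warn(
                f"group ({compound}, {instrument}) has only {len(values)} usable "
                f"values (< {min_group_size}); skipped",
                stacklevel=2,
            )
            continue
        estimates.append(
            CutoffEstimate(
                compound=compound,
                instrument_id=instrument,
                parameter=parameter,
                level=level,
                border=empirical_border(values, level),
                n=len(values),
                date_range=flt.date_range,
                sample_types=flt.sample_types,
            )
        )
    return estimates


@dataclass
class RulesetComparison:
    """Flag-transition summary between two rule sets on one selection.

    An observation is one (result, rule) pair that both rule sets
    evaluate (rule enabled in both, status not ``not_evaluable`` under
    either).  A *new* flag fails under the new set but passed under the
    old; a *removed* flag is the converse — a presumed false positive
    eliminated by the revision.
    """

    old_name: str
    new_name: str
    n_observations: int
    n_new_flags: int
    n_removed_flags: int
    per_rule_breakdown: dict[Rule, tuple[int, int]] = field(default_factory=dict)
    n_skipped_unshared: int = 0

    @property
    def pct_increase(self) -> float:
        return 100.0 * self.n_new_flags / self.n_observations

    @property
    def pct_decrease(self) -> float:
        return 100.0 * self.n_removed_flags / self.n_observations

    @property
    def n_unchanged(self) -> int:
        return self.n_observations - self.n_new_flags - self.n_removed_flags


def compare_rulesets(
    store: Store,
    flt: ResultFilter,
    old: RuleSet,
    new: RuleSet,
) -> RulesetComparison:
    """Double-run the flag engine and count flag transitions.

    Both rule sets are evaluated on the identical stored selection.
    Observations are restricted to (result, rule) pairs evaluable
    under both: a rule disabled (null threshold) in either set, or not
    evaluable on a row because of a null measurement, is excluded and
    counted under ``n_skipped_unshared``.
    """
    records = query_results(flt, store)
    if not records:
        raise ValueError("filter selects no results")
    old_report = evaluate_corpus(records, old)
    new_report = evaluate_corpus(records, new)

    def flag_map(report):
        return {(f.result_key, f.rule): f for f in report.flags}

    old_flags = flag_map(old_report)
    new_flags = flag_map(new_report)
    assert set(old_flags) == set(new_flags), "rule engine emitted unequal flag keys"

    n_obs = n_new = n_removed = n_skipped = 0
    breakdown: dict[Rule, list[int]] = defaultdict(lambda: [0, 0])
    for key, of in old_flags.items():
        nf = new_flags[key]
        shared = (
            of.threshold_repr != "disabled"
            and nf.threshold_repr != "disabled"
            and of.status is not FlagStatus.NOT_EVALUABLE
            and nf.status is not FlagStatus.NOT_EVALUABLE
        )
        if not shared:
            n_skipped += 1
            continue
        n_obs += 1
        if nf.status is FlagStatus.FAIL and of.status is FlagStatus.PASS:
            n_new += 1
            breakdown[key[1]][0] += 1
        elif nf.status is FlagStatus.PASS and of.status is FlagStatus.FAIL:
            n_removed += 1
            breakdown[key[1]][1] += 1
    return RulesetComparison(
        old_name=old.name,
        new_name=new.name,
        n_observations=n_obs,
        n_new_flags=n_new,
        n_removed_flags=n_removed,
        per_rule_breakdown={rule: tuple(v) for rule, v in breakdown.items()},
        n_skipped_unshared=n_skipped,
    )
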
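"""Data behind the five instrument-monitoring dashboard views.

Each view is computed as plain data (bins, points, summary tables) so a
rendering layer — an interactive web dashboard, a notebook plot, a CSV
export — stays a thin, stateless adapter.  The views layer adds no
arithmetic of its own beyond grouping: every summary number equals an
independent recomputation on the same filtered rows, and overlays
(cutoff lines, percentile borders, pass/fail markers) are produced by
the rule engine and calibration modules, never re-derived here.

Views:

* **histogram** — historical distribution of one parameter over a
  selection, with the active rule-set cutoff and the bottom-2% border
  overlaid for comparison;
* **plotted average** — per-month (or per-batch) summary statistics,
  the trend view for drifts;
* **plotted batch** — one batch in injection order, the within-run view;
* **plotted Std-A signal** — the first calibrator's analyte signal per
  batch × compound with pass/fail coloring, the batch-to-batch
  sensitivity monitor;
* **absolute RT vs monthly average** — per-batch mean retention time
  against its month's average, the chromatography-health view.
"""

from __future__ import annotations

import enum
from collections import defaultdict
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .cutoff_calibration import (
    empirical_border,
    fraction_below,
    fraction_outside_window,
)
from .datastore import Store, query_results
from .qc_engine import FlagStatus, Rule, RuleSet, check_std_a, compute_rrt
from .records import ResultFilter, ResultRecord, SampleType, to_utc

__all__ = [
    "ViewParameter",
    "SummaryStats",
    "HistogramView",
    "TrendView",
    "StdASignalView",
    "AbsoluteRTView",
    "Grouping",
    "summarize",
    "histogram_view",
    "average_trend_view",
    "batch_view",
    "std_a_signal_view",
    "absolute_rt_view",
]


class ViewParameter(str, enum.Enum):
    IS_PEAK_AREA = "is_peak_area"
    PEAK_AREA = "peak_area"
    SN = "sn"
    RRT = "rrt"
    CONCENTRATION = "concentration"
    CONFIRMING_ION_AREA = "confirming_ion_area"

    def __str__(self) -> str:
        return self.value


class Grouping(str, enum.Enum):
    BY_MONTH = "by_month"
    BY_BATCH = "by_batch"
    BY_INJECTION_ORDER = "by_injection_order"

    def __str__(self) -> str:
        return self.value


def view_value(record: ResultRecord, parameter: ViewParameter) -> Optional[float]:
    if parameter is ViewParameter.RRT:
        return compute_rrt(record.rt, record.is_rt)
    return getattr(record, parameter.value)


@dataclass(frozen=True)
class SummaryStats:
    n: int
    n_null: int
    mean: float
    median: float
    sd: float
    min: float
    max: float
    quantiles: dict[float, float]
    pct_below_cutoff: Optional[float] = None
    pct_outside_window: Optional[float] = None


#: Quantile levels every summary table reports.
SUMMARY_QUANTILES = (0.02, 0.25, 0.75)


def summarize(
    values: Sequence[Optional[float]],
    cutoff: Optional[float] = None,
    window: Optional[tuple[float, float]] = None,
) -> SummaryStats:
    """Statistical summary table for one selection.

    Nulls are counted and excluded from the statistics.  The standard
    deviation is the sample (ddof=1) estimate, 0.0 for a single value.
    ``pct_below_cutoff`` / ``pct_outside_window`` delegate to the
    calibration module so the table agrees exactly with derived borders
    and flag rates.
    """
    clean = [v for v in values if v is not None]
    n_null = len(values) - len(clean)
    if not clean:
        raise ValueError("no non-null values to summarize")
    arr = np.asarray(clean, dtype=float)
    return SummaryStats(
        n=arr.size,
        n_null=n_null,
        mean=float(arr.mean()),
        median=float(np.median(arr)),
        sd=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        min=float(arr.min()),
        max=float(arr.max()),
        quantiles={q: float(np.quantile(arr, q)) for q in SUMMARY_QUANTILES},
        pct_below_cutoff=None if cutoff is None else 100.0 * fraction_below(clean, cutoff),
        pct_outside_window=(
            None if window is None else 100.0 * fraction_outside_window(clean, window)
        ),
    )


@dataclass
class HistogramView:
    filter: ResultFilter
    parameter: ViewParameter
    bins: list[tuple[float, float, int]]
    overlays: dict[str, float]
    summary: SummaryStats


def _ruleset_cutoff(
    ruleset: Optional[RuleSet],
    parameter: ViewParameter,
    records: Sequence[ResultRecord],
) -> tuple[Optional[float], Optional[tuple[float, float]]]:
    """Resolve the rule-set overlay when the selection pins one
    compound/instrument pair; ambiguous selections get no overlay."""
    if ruleset is None:
        return None, None
    pairs = {(r.compound, r.instrument_id) for r in records}
    if len(pairs) != 1:
        return None, None
    compound, instrument = next(iter(pairs))
    cutoffs = ruleset.resolve(compound, instrument)
    if parameter is ViewParameter.IS_PEAK_AREA:
        return cutoffs.is_peak_area_min, None
    if parameter is ViewParameter.PEAK_AREA:
        return cutoffs.std_a_peak_area_min, None
    if parameter is ViewParameter.SN:
        return cutoffs.sn_min, None
    if parameter is ViewParameter.RRT:
        return None, cutoffs.rrt_window
    return None, None


def histogram_view(
    store: Store,
    flt: ResultFilter,
    parameter: ViewParameter,
    ruleset: Optional[RuleSet] = None,
    n_bins: int = 50,
    border_level: float = 0.02,
) -> HistogramView:
    """Equal-width histogram spanning [min, max] with cutoff + border
    overlays.

    Bins are half-open [left, right) except the last, which includes
    the maximum (the standard closed-last-bin convention), so bin
    counts always sum to the non-null n.
    """
    records = query_results(flt, store)
    values = [view_value(r, parameter) for r in records]
    clean = [v for v in values if v is not None]
    if not clean:
        raise ValueError("selection contains no non-null values for the parameter")
    cutoff, window = _ruleset_cutoff(ruleset, parameter, records)
    counts, edges = np.histogram(np.asarray(clean, dtype=float), bins=n_bins)
    overlays = {"border": empirical_border(clean, border_level)}
    if cutoff is not None:
        overlays["cutoff"] = cutoff
    if window is not None:
        overlays["window_low"], overlays["window_high"] = window
    return HistogramView(
        filter=flt,
        parameter=parameter,
        bins=[
            (float(edges[i]), float(edges[i + 1]), int(counts[i]))
            for i in range(len(counts))
        ],
        overlays=overlays,
        summary=summarize(values, cutoff=cutoff, window=window),
    )


@dataclass
class TrendView:
    filter: Optional[ResultFilter]
    parameter: ViewParameter
    grouping: Grouping
    points: list[tuple[str, SummaryStats]]


def _month_label(record: ResultRecord) -> str:
    t = to_utc(record.injection_time)
    return f"{t.year:04d}-{t.month:02d}"


def average_trend_view(
    store: Store,
    flt: ResultFilter,
    parameter: ViewParameter,
    grouping: Grouping = Grouping.BY_MONTH,
) -> TrendView:
    """Per-month (UTC calendar months) or per-batch summary trend.

    Each selected row lands in exactly one group; groups are ordered
    chronologically (for by_batch: by first injection time).
    """
    records = query_results(flt, store)
    if not records:
        raise ValueError("filter selects no results")
    groups: dict[str, list[Optional[float]]] = defaultdict(list)
    order_key: dict[str, str] = {}
    for r in records:
        if grouping is Grouping.BY_MONTH:
            if r.injection_time is None:
                continue
            label = _month_label(r)
            key = label
        elif grouping is Grouping.BY_BATCH:
            label = r.xml_file_name
            t = r.injection_time
            key = min(order_key.get(label, "~"), to_utc(t).isoformat() if t else "~")
        else:
            raise ValueError("use batch_view for by_injection_order grouping")
        groups[label].append(view_value(r, parameter))
        order_key[label] = key if grouping is Grouping.BY_BATCH else label
    points = [
        (label, summarize(groups[label]))
        for label in sorted(groups, key=lambda lb: (order_key[lb], lb))
    ]
    return TrendView(filter=flt, parameter=parameter, grouping=grouping, points=points)


def batch_view(
    store: Store,
    batch_name: str,
    parameter: ViewParameter,
    ruleset: Optional[RuleSet] = None,
    compound: Optional[str] = None,
) -> tuple[TrendView, dict[str, float]]:
    """One batch in injection order: one point per injection.

    Returns the trend view plus overlay thresholds (resolved from the
    rule set when the selection pins a single compound).
    """
    flt = ResultFilter.build(
        batches=[batch_name],
        compounds=None if compound is None else [compound],
    )
    records = query_results(flt, store)
    if not records:
        raise ValueError(f"unknown batch {batch_name!r} (or empty selection)")
    injections: dict[tuple[str, str], list[Optional[float]]] = defaultdict(list)
    for r in records:  # already ordered by (injection_time, result_key)
        t = "" if r.injection_time is None else to_utc(r.injection_time).isoformat()
        injections[(t, r.sample_id)].append(view_value(r, parameter))
    points = []
    for (t, sample_id) in sorted(injections):
        vals = injections[(t, sample_id)]
        if all(v is None for v in vals):
            continue
        points.append((sample_id, summarize(vals)))
    cutoff, window = _ruleset_cutoff(ruleset, parameter, records)
    overlays: dict[str, float] = {}
    if cutoff is not None:
        overlays["cutoff"] = cutoff
    if window is not None:
        overlays["window_low"], overlays["window_high"] = window
    view = TrendView(
        filter=flt, parameter=parameter,
        grouping=Grouping.BY_INJECTION_ORDER, points=points,
    )
    return view, overlays


@dataclass
class StdASignalView:
    filter: ResultFilter
    points: list[tuple[str, str, Optional[float], FlagStatus]]
    color_code: dict[str, str]  # batch -> "all-pass" | "any-fail" | "not-evaluable"


def std_a_signal_view(
    store: Store, flt: ResultFilter, ruleset: RuleSet
) -> StdASignalView:
    """First-calibrator signal per (batch, compound) with pass/fail.

    Pass/fail is exactly the rule engine's Std-A check on the same
    rows; ``color_code`` rolls each batch up to all-pass / any-fail.
    """
    records = query_results(flt, store)
    cals = [r for r in records if r.sample_type is SampleType.CALIBRATOR]
    if not cals:
        raise ValueError("selection contains no calibrator rows")
    groups: dict[tuple[str, str], list[ResultRecord]] = defaultdict(list)
    for r in cals:
        groups[(r.xml_file_name, r.compound)].append(r)
    points = []
    batch_status: dict[str, set[FlagStatus]] = defaultdict(set)
    for (batch, compound) in sorted(groups):
        group = groups[(batch, compound)]
        cutoffs = ruleset.resolve(compound, group[0].instrument_id)
        flag = check_std_a(group, cutoffs)
        points.append((batch, compound, flag.measured, flag.status))
        batch_status[batch].add(flag.status)
    color_code = {}
    for batch, statuses in batch_status.items():
        if FlagStatus.FAIL in statuses:
            color_code[batch] = "any-fail"
        elif statuses == {FlagStatus.NOT_EVALUABLE}:
            color_code[batch] = "not-evaluable"
        else:
            color_code[batch] = "all-pass"
    return StdASignalView(filter=flt, points=points, color_code=color_code)


@dataclass
class AbsoluteRTView:
    filter: ResultFilter
    per_batch_rt: list[tuple[str, str, float]]          # (batch, compound, mean RT)
    monthly_average: list[tuple[str, str, float]]       # (month, compound, mean RT)
    deviations: list[tuple[str, str, float]]            # (batch, compound, batch − month)


def absolute_rt_view(store: Store, flt: ResultFilter) -> AbsoluteRTView:
    """Per-batch mean retention time against its month's equal-weight
    mean, per compound.

    The monthly mean weights every row equally (not batch-means); a
    batch belongs to the calendar month (UTC) of its first selected
    injection.  ``deviation = batch mean − monthly mean`` exactly.
    """
    records = [
        r for r in query_results(flt, store)
        if r.rt is not None and r.injection_time is not None
    ]
    if not records:
        raise ValueError("selection contains no rows with retention times")
    batch_rows: dict[tuple[str, str], list[ResultRecord]] = defaultdict(list)
    month_values: dict[tuple[str, str], list[float]] = defaultdict(list)
    for r in records:
        batch_rows[(r.xml_file_name, r.compound)].append(r)
        month_values[(_month_label(r), r.compound)].append(r.rt)

    per_batch = []
    deviations = []
    for (batch, compound) in sorted(batch_rows):
        rows = batch_rows[(batch, compound)]
        batch_mean = float(np.mean([r.rt for r in rows]))
        per_batch.append((batch, compound, batch_mean))
        first = min(rows, key=lambda r: to_utc(r.injection_time))
        month = _month_label(first)
        month_mean = float(np.mean(month_values[(month, compound)]))
        deviations.append((batch, compound, batch_mean - month_mean))
    monthly = [
        (month, compound, float(np.mean(vals)))
        for (month, compound), vals in sorted(month_values.items())
    ]
    return AbsoluteRTView(
        filter=flt,
        per_batch_rt=per_batch,
        monthly_average=monthly,
        deviations=deviations,
    )
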
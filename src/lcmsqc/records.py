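"""Typed records for the three-table batch/calibration/results data model.

One analytical batch is a single acquisition run on one instrument:
a calibrator series (Std-A .. Std-F, lowest level first), QC samples and
patient samples injected sequentially.  Every (sample, compound) pair
yields one :class:`ResultRecord` carrying the analyte measurements and
the paired internal-standard (isotope-labelled analog) measurements.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from typing import Iterable, Optional, Sequence


class SampleType(str, enum.Enum):
    """Normalized vocabulary for the free-text sample types in exports."""

    CALIBRATOR = "calibrator"
    QC = "qc"
    PATIENT = "patient"
    BLANK = "blank"

    def __str__(self) -> str:  # stable round-trip through str()
        return self.value


#: Lookup from the dialect's free-text sample types (lower-cased) to the
#: normalized vocabulary.  Unmapped values are a hard error, never a
#: silent fall-through to "patient".
SAMPLE_TYPE_ALIASES: dict[str, SampleType] = {
    "calibrator": SampleType.CALIBRATOR,
    "standard": SampleType.CALIBRATOR,
    "cal": SampleType.CALIBRATOR,
    "qc": SampleType.QC,
    "quality control": SampleType.QC,
    "control": SampleType.QC,
    "patient": SampleType.PATIENT,
    "analyte": SampleType.PATIENT,
    "unknown": SampleType.PATIENT,
    "specimen": SampleType.PATIENT,
    "blank": SampleType.BLANK,
    "double blank": SampleType.BLANK,
}


def normalize_sample_type(raw: str) -> SampleType:
    """Map a dialect sample-type string onto the four-value vocabulary.

    Raises
    ------
    ValueError
        If ``raw`` is not a documented alias.
    """
    try:
        return SAMPLE_TYPE_ALIASES[raw.strip().lower()]
    except KeyError:
        raise ValueError(
            f"unmapped sample type {raw!r}; known aliases: "
            f"{sorted(SAMPLE_TYPE_ALIASES)}"
        ) from None


def to_utc(dt: datetime) -> datetime:
    """Normalize a datetime to UTC; naive datetimes are taken as UTC."""
    if dt.tzinfo is None:
        return dt.replace(tzinfo=timezone.utc)
    return dt.astimezone(timezone.utc)


@dataclass(frozen=True)
class BatchRecord:
    """One row of the batch table (one XML export = one acquisition run)."""

    xml_file_name: str
    timestamp: datetime
    instrument_id: str
    sample_count: int
    lc_batch_name: Optional[str] = None
    injection_time_span: Optional[tuple[datetime, datetime]] = None
    batch_key: Optional[int] = None


@dataclass(frozen=True)
class CalibrationRecord:
    """Per-compound calibration-curve parameters for one batch."""

    xml_file_name: str
    timestamp: datetime
    compound: str
    internal_standard: Optional[str] = None
    weighting: Optional[str] = None
    slope: Optional[float] = None
    r_squared: Optional[float] = None
    curve_type: Optional[str] = None
    origin: Optional[str] = None
    calibration_key: Optional[int] = None


@dataclass(frozen=True)
class ResultRecord:
    """One compound measured in one injection, with its paired internal
    standard.

    All numeric fields are either a finite float or ``None`` (missing /
    non-numeric in the source export); parsing never fabricates zeros.
    ``instrument_id`` is denormalized from the batch so per-instrument
    distribution queries stay single-table.
    """

    xml_file_name: str
    sample_type: SampleType
    sample_id: str
    compound: str
    lc_batch_name: Optional[str] = None
    vial: Optional[str] = None
    injection_time: Optional[datetime] = None
    compound_id: Optional[str] = None
    peak_area: Optional[float] = None
    confirming_ion_area: Optional[float] = None
    rt: Optional[float] = None
    sn: Optional[float] = None
    concentration: Optional[float] = None
    cc: Optional[bool] = None
    internal_standard: Optional[str] = None
    is_id: Optional[str] = None
    is_peak_area: Optional[float] = None
    is_rt: Optional[float] = None
    is_sn: Optional[float] = None
    is_confirming_ion_area: Optional[float] = None
    instrument_id: str = ""
    result_key: Optional[int] = None

    def with_key(self, key: int) -> "ResultRecord":
        return replace(self, result_key=key)


#: ResultRecord numeric fields and their sign constraints
#: ("nonneg" = value >= 0, "pos" = value > 0, "any" = unconstrained).
RESULT_NUMERIC_FIELDS: dict[str, str] = {
    "peak_area": "nonneg",
    "confirming_ion_area": "nonneg",
    "rt": "pos",
    "sn": "nonneg",
    "concentration": "nonneg",
    "is_peak_area": "nonneg",
    "is_rt": "pos",
    "is_sn": "nonneg",
    "is_confirming_ion_area": "nonneg",
}


@dataclass(frozen=True)
class ParseWarning:
    field_path: str
    reason: str


@dataclass
class ParsedBatch:
    """Fully parsed batch: metadata, calibration curves and result rows."""

    batch: BatchRecord
    calibrations: list[CalibrationRecord]
    results: list[ResultRecord]
    parse_warnings: list[ParseWarning] = field(default_factory=list)


@dataclass(frozen=True)
class ResultFilter:
    """Conjunctive result selection: absent field = no restriction.

    ``date_range`` is a half-open ``(start, end]`` interval on
    ``injection_time`` so month-partitioned trend views never
    double-count a boundary injection.  Rows with a null injection time
    never match a date-restricted filter.
    """

    instruments: Optional[frozenset[str]] = None
    compounds: Optional[frozenset[str]] = None
    sample_types: Optional[frozenset[SampleType]] = None
    date_range: Optional[tuple[datetime, datetime]] = None
    batches: Optional[frozenset[str]] = None

    @staticmethod
    def build(
        instruments: Optional[Iterable[str]] = None,
        compounds: Optional[Iterable[str]] = None,
        sample_types: Optional[Iterable[SampleType | str]] = None,
        date_range: Optional[tuple[datetime, datetime]] = None,
        batches: Optional[Iterable[str]] = None,
    ) -> "ResultFilter":
        st = None
        if sample_types is not None:
            st = frozenset(
                s if isinstance(s, SampleType) else SampleType(s)
                for s in sample_types
            )
        return ResultFilter(
            instruments=None if instruments is None else frozenset(instruments),
            compounds=None if compounds is None else frozenset(compounds),
            sample_types=st,
            date_range=date_range,
            batches=None if batches is None else frozenset(batches),
        )

    def matches(self, r: ResultRecord) -> bool:
        if self.instruments is not None and r.instrument_id not in self.instruments:
            return False
        if self.compounds is not None and r.compound not in self.compounds:
            return False
        if self.sample_types is not None and r.sample_type not in self.sample_types:
            return False
        if self.batches is not None and r.xml_file_name not in self.batches:
            return False
        if self.date_range is not None:
            if r.injection_time is None:
                return False
            start, end = (to_utc(self.date_range[0]), to_utc(self.date_range[1]))
            t = to_utc(r.injection_time)
            if not (start < t <= end):
                return False
        return True


_LEVEL_SUFFIX = re.compile(r"[-_ ]([A-Za-z])$")


def calibrator_level(sample_id: str) -> Optional[str]:
    """Extract the level letter from a calibrator sample id.

    The dialect labels calibrators ``Std-A`` .. ``Std-F`` with level A
    the lowest concentration.  Returns the upper-cased letter, or None
    when the id does not follow the convention.
    """
    m = _LEVEL_SUFFIX.search(sample_id.strip())
    return m.group(1).upper() if m else None


def first_calibrator(results: Sequence[ResultRecord]) -> Optional[ResultRecord]:
    """Pick the first (lowest-level, "Std-A") calibrator row.

    Ordering: level letters A < B < ... when all calibrator ids carry
    them; otherwise ascending nominal concentration (nulls last), then
    sample_id for stability.
    """
    cals = [r for r in results if r.sample_type is SampleType.CALIBRATOR]
    if not cals:
        return None
    levels = [calibrator_level(r.sample_id) for r in cals]
    if all(lv is not None for lv in levels):
        return min(zip(levels, cals), key=lambda t: (t[0], t[1].sample_id))[1]
    return min(
        cals,
        key=lambda r: (
            r.concentration is None,
            r.concentration if r.concentration is not None else 0.0,
            r.sample_id,
        ),
    )
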
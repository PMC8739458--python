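"""Reading and writing the batch quantification XML dialect.

Vendor quantification software exports one XML file per analytical
batch.  The exact vendor schema is proprietary, so this module defines a
minimal documented dialect with the same information content (see
``docs/xml_dialect.md``): a ``quant_batch`` root carrying batch
metadata, a ``calibrations`` block with one node per compound, and a
``samples`` block where each ``sample`` holds one ``compound`` node per
analyte with ``peak`` and ``internal_standard`` children.  The parser is
layered so a vendor-specific reader can be slotted in by producing the
same :class:`~lcmsqc.records.ParsedBatch` objects.

Parsing rules:

* absent or non-numeric text in a numeric field becomes ``None`` plus a
  parse warning — never a zero, which would corrupt downstream
  percentile borders;
* all timestamps are normalized to UTC at parse time;
* unknown extra elements are ignored with a warning; a missing
  mandatory element is a structural error.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path
from typing import Optional, Union

from lxml import etree

from .records import (
    BatchRecord,
    CalibrationRecord,
    ParsedBatch,
    ParseWarning,
    RESULT_NUMERIC_FIELDS,
    ResultRecord,
    normalize_sample_type,
    to_utc,
)

__all__ = [
    "QuantXMLError",
    "QuantXMLSyntaxError",
    "DialectError",
    "RawBatchFile",
    "inspect_file",
    "parse_quant_xml",
    "parse_folder",
    "FolderParseResult",
    "write_quant_xml",
]

DIALECT_EXTENSION = ".xml"

_KNOWN_ROOT_CHILDREN = {"calibrations", "samples"}
_KNOWN_SAMPLE_CHILDREN = {"compound"}
_KNOWN_COMPOUND_CHILDREN = {"peak", "internal_standard"}


class QuantXMLError(Exception):
    """Base class for dialect I/O errors."""


class QuantXMLSyntaxError(QuantXMLError):
    """Malformed XML; carries the parser's error position."""

    def __init__(self, path: Union[str, Path], line: int, column: int, detail: str):
        self.path = str(path)
        self.line = line
        self.column = column
        super().__init__(
            f"{path}: malformed XML at line {line}, column {column}: {detail}"
        )


class DialectError(QuantXMLError):
    """Well-formed XML that violates the dialect (missing mandatory node)."""


@dataclass(frozen=True)
class RawBatchFile:
    """Lightweight handle on an on-disk export, prior to full parsing."""

    file_name: str
    acquisition_timestamp: datetime
    instrument_id: str
    sample_count: int
    xml_payload: object  # parsed lxml document


def _parse_tree(path: Union[str, Path]) -> etree._ElementTree:
    try:
        return etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        line, column = exc.position
        raise QuantXMLSyntaxError(path, line, column, exc.msg or str(exc)) from exc


def _require(value: Optional[str], what: str, path: Union[str, Path]) -> str:
    if value is None or value == "":
        raise DialectError(f"{path}: missing mandatory element/attribute {what!r}")
    return value


def _parse_datetime(
    raw: Optional[str],
    field_path: str,
    warnings: list[ParseWarning],
) -> Optional[datetime]:
    if raw is None or raw == "":
        return None
    try:
        return to_utc(datetime.fromisoformat(raw))
    except ValueError:
        warnings.append(ParseWarning(field_path, f"unparseable timestamp {raw!r}"))
        return None


def _parse_number(
    raw: Optional[str],
    field_path: str,
    warnings: list[ParseWarning],
    sign: str = "any",
) -> Optional[float]:
    """Numeric attribute -> finite float or None (+ warning)."""
    if raw is None or raw == "":
        return None
    try:
        value = float(raw)
    except ValueError:
        warnings.append(ParseWarning(field_path, f"non-numeric value {raw!r}"))
        return None
    if not math.isfinite(value):
        warnings.append(ParseWarning(field_path, f"non-finite value {raw!r}"))
        return None
    if sign == "nonneg" and value < 0:
        warnings.append(ParseWarning(field_path, f"negative value {raw!r}"))
        return None
    if sign == "pos" and value <= 0:
        warnings.append(ParseWarning(field_path, f"non-positive value {raw!r}"))
        return None
    return value


def _parse_bool(
    raw: Optional[str], field_path: str, warnings: list[ParseWarning]
) -> Optional[bool]:
    if raw is None or raw == "":
        return None
    low = raw.strip().lower()
    if low in ("true", "1", "yes"):
        return True
    if low in ("false", "0", "no"):
        return False
    warnings.append(ParseWarning(field_path, f"unparseable boolean {raw!r}"))
    return None


def inspect_file(path: Union[str, Path]) -> RawBatchFile:
    """Read batch-level metadata without materializing result rows."""
    tree = _parse_tree(path)
    root = tree.getroot()
    if root.tag != "quant_batch":
        raise DialectError(f"{path}: root element is {root.tag!r}, expected 'quant_batch'")
    warnings: list[ParseWarning] = []
    acquired = _parse_datetime(
        _require(root.get("acquired"), "quant_batch@acquired", path),
        "quant_batch@acquired",
        warnings,
    )
    if acquired is None:
        raise DialectError(f"{path}: unparseable quant_batch@acquired timestamp")
    samples = root.find("samples")
    if samples is None:
        raise DialectError(f"{path}: missing mandatory element 'samples'")
    return RawBatchFile(
        file_name=_require(root.get("file_name"), "quant_batch@file_name", path),
        acquisition_timestamp=acquired,
        instrument_id=_require(root.get("instrument_id"), "quant_batch@instrument_id", path),
        sample_count=len(samples.findall("sample")),
        xml_payload=tree,
    )


def parse_quant_xml(path: Union[str, Path]) -> ParsedBatch:
    """Parse one batch export into typed records.

    Returns one :class:`BatchRecord`, one :class:`CalibrationRecord` per
    compound with a calibration node and one :class:`ResultRecord` per
    (sample, compound) pair — no record is silently dropped.  Result
    keys are assigned sequentially within the batch; the datastore
    replaces them with surrogate keys at load time.
    """
    raw = inspect_file(path)
    root = raw.xml_payload.getroot()
    warnings: list[ParseWarning] = []

    declared = root.get("sample_count")
    if declared is not None and declared != str(raw.sample_count):
        warnings.append(
            ParseWarning(
                "quant_batch@sample_count",
                f"declared {declared} but file contains {raw.sample_count} sample nodes",
            )
        )

    for child in root:
        if child.tag not in _KNOWN_ROOT_CHILDREN:
            warnings.append(
                ParseWarning(str(child.tag), "unknown element ignored")
            )

    lc_batch_name = root.get("lc_batch_name")
    instrument_id = raw.instrument_id
    file_name = raw.file_name

    calibrations: list[CalibrationRecord] = []
    cal_parent = root.find("calibrations")
    if cal_parent is not None:
        for node in cal_parent.findall("calibration"):
            compound = _require(node.get("compound"), "calibration@compound", path)
            fp = f"calibration[{compound}]"
            calibrations.append(
                CalibrationRecord(
                    xml_file_name=file_name,
                    timestamp=raw.acquisition_timestamp,
                    compound=compound,
                    internal_standard=node.get("internal_standard"),
                    weighting=node.get("weighting"),
                    slope=_parse_number(node.get("slope"), f"{fp}@slope", warnings),
                    r_squared=_parse_r_squared(node.get("r_squared"), fp, warnings),
                    curve_type=node.get("curve_type"),
                    origin=node.get("origin"),
                )
            )

    results: list[ResultRecord] = []
    key = 0
    for sample in root.find("samples").findall("sample"):
        sample_id = _require(sample.get("sample_id"), "sample@sample_id", path)
        sp = f"sample[{sample_id}]"
        raw_type = _require(sample.get("sample_type"), f"{sp}@sample_type", path)
        try:
            sample_type = normalize_sample_type(raw_type)
        except ValueError as exc:
            raise DialectError(f"{path}: {sp}: {exc}") from exc
        injection_time = _parse_datetime(
            sample.get("injection_time"), f"{sp}@injection_time", warnings
        )
        vial = sample.get("vial")
        for child in sample:
            if child.tag not in _KNOWN_SAMPLE_CHILDREN:
                warnings.append(ParseWarning(f"{sp}/{child.tag}", "unknown element ignored"))
        for comp in sample.findall("compound"):
            name = _require(comp.get("name"), f"{sp}/compound@name", path)
            cp = f"{sp}/compound[{name}]"
            for child in comp:
                if child.tag not in _KNOWN_COMPOUND_CHILDREN:
                    warnings.append(ParseWarning(f"{cp}/{child.tag}", "unknown element ignored"))
            peak = comp.find("peak")
            ist = comp.find("internal_standard")

            def num(node, attr, field, prefix):
                if node is None:
                    return None
                return _parse_number(
                    node.get(attr),
                    f"{prefix}@{attr}",
                    warnings,
                    RESULT_NUMERIC_FIELDS[field],
                )

            results.append(
                ResultRecord(
                    xml_file_name=file_name,
                    lc_batch_name=lc_batch_name,
                    sample_type=sample_type,
                    sample_id=sample_id,
                    vial=vial,
                    injection_time=injection_time,
                    compound=name,
                    compound_id=comp.get("compound_id"),
                    peak_area=num(peak, "area", "peak_area", f"{cp}/peak"),
                    confirming_ion_area=num(
                        peak, "confirming_area", "confirming_ion_area", f"{cp}/peak"
                    ),
                    rt=num(peak, "rt", "rt", f"{cp}/peak"),
                    sn=num(peak, "sn", "sn", f"{cp}/peak"),
                    concentration=num(peak, "concentration", "concentration", f"{cp}/peak"),
                    cc=_parse_bool(
                        peak.get("cc") if peak is not None else None,
                        f"{cp}/peak@cc",
                        warnings,
                    ),
                    internal_standard=ist.get("name") if ist is not None else None,
                    is_id=ist.get("is_id") if ist is not None else None,
                    is_peak_area=num(ist, "area", "is_peak_area", f"{cp}/internal_standard"),
                    is_rt=num(ist, "rt", "is_rt", f"{cp}/internal_standard"),
                    is_sn=num(ist, "sn", "is_sn", f"{cp}/internal_standard"),
                    is_confirming_ion_area=num(
                        ist, "confirming_area", "is_confirming_ion_area",
                        f"{cp}/internal_standard",
                    ),
                    instrument_id=instrument_id,
                    result_key=key,
                )
            )
            key += 1

    times = [r.injection_time for r in results if r.injection_time is not None]
    span = (min(times), max(times)) if times else None
    batch = BatchRecord(
        xml_file_name=file_name,
        timestamp=raw.acquisition_timestamp,
        instrument_id=instrument_id,
        sample_count=raw.sample_count,
        lc_batch_name=lc_batch_name,
        injection_time_span=span,
    )
    return ParsedBatch(batch=batch, calibrations=calibrations, results=results,
                       parse_warnings=warnings)


def _parse_r_squared(
    raw: Optional[str], field_path: str, warnings: list[ParseWarning]
) -> Optional[float]:
    value = _parse_number(raw, f"{field_path}@r_squared", warnings)
    if value is not None and not (0.0 <= value <= 1.0):
        warnings.append(
            ParseWarning(f"{field_path}@r_squared", f"r_squared {value} outside [0, 1]")
        )
        return None
    return value


@dataclass
class FolderParseResult:
    """Per-file failures are collected, never fatal to the whole folder."""

    batches: list[ParsedBatch]
    failures: list[tuple[str, Exception]]

    def __iter__(self):
        return iter(self.batches)

    def __len__(self) -> int:
        return len(self.batches)


def parse_folder(directory: Union[str, Path]) -> FolderParseResult:
    """Parse every ``*.xml`` file in a directory, lexicographic order.

    An empty directory yields an empty result; a corrupt file is
    recorded under ``failures`` and does not abort the rest.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise NotADirectoryError(str(directory))
    batches: list[ParsedBatch] = []
    failures: list[tuple[str, Exception]] = []
    for path in sorted(directory.iterdir()):
        if path.suffix.lower() != DIALECT_EXTENSION or not path.is_file():
            continue
        try:
            batches.append(parse_quant_xml(path))
        except QuantXMLError as exc:
            failures.append((str(path), exc))
    return FolderParseResult(batches=batches, failures=failures)


def _fmt(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)  # shortest exact round-trip
    if isinstance(value, datetime):
        return to_utc(value).isoformat()
    return str(value)


def _set(node: etree._Element, attr: str, value) -> None:
    if value is not None:
        node.set(attr, _fmt(value))


def write_quant_xml(batch: ParsedBatch, path: Union[str, Path]) -> Path:
    """Emit a ParsedBatch in the dialect; nulls become absent attributes.

    The emitted file reparses to an equal ParsedBatch field-by-field
    (floats are formatted with shortest-exact repr), which is the
    contract the synthetic generator relies on.
    """
    path = Path(path)
    b = batch.batch
    root = etree.Element("quant_batch")
    _set(root, "file_name", b.xml_file_name)
    _set(root, "acquired", b.timestamp)
    _set(root, "instrument_id", b.instrument_id)
    _set(root, "lc_batch_name", b.lc_batch_name)
    _set(root, "sample_count", b.sample_count)

    cal_parent = etree.SubElement(root, "calibrations")
    for cal in batch.calibrations:
        node = etree.SubElement(cal_parent, "calibration")
        _set(node, "compound", cal.compound)
        _set(node, "internal_standard", cal.internal_standard)
        _set(node, "weighting", cal.weighting)
        _set(node, "slope", cal.slope)
        _set(node, "r_squared", cal.r_squared)
        _set(node, "curve_type", cal.curve_type)
        _set(node, "origin", cal.origin)

    samples_parent = etree.SubElement(root, "samples")
    current = None
    current_node = None
    for r in batch.results:
        sample_key = (r.sample_id, r.injection_time)
        if sample_key != current:
            current = sample_key
            current_node = etree.SubElement(samples_parent, "sample")
            _set(current_node, "sample_id", r.sample_id)
            _set(current_node, "sample_type", r.sample_type.value)
            _set(current_node, "vial", r.vial)
            _set(current_node, "injection_time", r.injection_time)
        comp = etree.SubElement(current_node, "compound")
        _set(comp, "name", r.compound)
        _set(comp, "compound_id", r.compound_id)
        peak = etree.SubElement(comp, "peak")
        _set(peak, "area", r.peak_area)
        _set(peak, "confirming_area", r.confirming_ion_area)
        _set(peak, "rt", r.rt)
        _set(peak, "sn", r.sn)
        _set(peak, "concentration", r.concentration)
        _set(peak, "cc", r.cc)
        ist = etree.SubElement(comp, "internal_standard")
        _set(ist, "name", r.internal_standard)
        _set(ist, "is_id", r.is_id)
        _set(ist, "area", r.is_peak_area)
        _set(ist, "rt", r.is_rt)
        _set(ist, "sn", r.is_sn)
        _set(ist, "confirming_area", r.is_confirming_ion_area)

    tree = etree.ElementTree(root)
    try:
        tree.write(str(path), encoding="utf-8", xml_declaration=True, pretty_print=True)
    except (OSError, IOError) as exc:
        raise QuantXMLError(f"cannot write {path}: {exc}") from exc
    return path
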
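"""Relational persistence of the batch / calibration / results model.

The embedded backend is SQLite through the standard library driver; the
DDL (``schema.sql``, shipped with the package) is portable SQL and the
same schema deploys unchanged to a client-server engine.  Historical
rows are never mutated: ingest is append-only and idempotent per XML
file name, and the query surface is read-only.
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass
from datetime import datetime
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .records import (
    BatchRecord,
    CalibrationRecord,
    ParsedBatch,
    ResultFilter,
    ResultRecord,
    SampleType,
    to_utc,
)

__all__ = [
    "Store",
    "SchemaError",
    "LoadOutcome",
    "init_schema",
    "load_batch",
    "query_results",
    "query_batches",
    "export_table",
]


class SchemaError(Exception):
    """Existing database whose schema is incompatible with this model."""


_EXPECTED_COLUMNS = {
    "batch": [
        "batch_key", "xml_file_name", "timestamp", "instrument_id",
        "lc_batch_name", "first_injection", "last_injection", "sample_count",
    ],
    "calibration": [
        "calibration_key", "xml_file_name", "timestamp", "compound",
        "internal_standard", "weighting", "slope", "r_squared",
        "curve_type", "origin",
    ],
    "results": [
        "result_key", "xml_file_name", "lc_batch_name", "sample_type",
        "sample_id", "vial", "injection_time", "compound", "compound_id",
        "peak_area", "confirming_ion_area", "rt", "sn", "concentration",
        "cc", "internal_standard", "is_id", "is_peak_area", "is_rt",
        "is_sn", "is_confirming_ion_area", "instrument_id",
    ],
}


@dataclass
class Store:
    """Handle on an initialized database."""

    conn: sqlite3.Connection
    locator: str

    def close(self) -> None:
        self.conn.close()

    def __enter__(self) -> "Store":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def _ddl() -> str:
    return resources.files("lcmsqc").joinpath("schema.sql").read_text(encoding="utf-8")


def init_schema(target: Union[str, Path] = ":memory:") -> Store:
    """Create (or re-open) the three-table schema; idempotent.

    An existing database with different columns raises
    :class:`SchemaError` without any destructive change.
    """
    locator = str(target)
    conn = sqlite3.connect(locator)
    conn.execute("PRAGMA foreign_keys = ON")
    existing = {
        row[0]
        for row in conn.execute(
            "SELECT name FROM sqlite_master WHERE type = 'table'"
        )
    }
    for table, expected in _EXPECTED_COLUMNS.items():
        if table in existing:
            found = [
                row[1] for row in conn.execute(f"PRAGMA table_info({table})")
            ]
            if found != expected:
                conn.close()
                raise SchemaError(
                    f"table {table!r} exists with columns {found}, "
                    f"expected {expected}; refusing to migrate destructively"
                )
    conn.executescript(_ddl())
    conn.commit()
    return Store(conn=conn, locator=locator)


def _iso(dt: Optional[datetime]) -> Optional[str]:
    return None if dt is None else to_utc(dt).isoformat()


def _dt(text: Optional[str]) -> Optional[datetime]:
    return None if text is None else to_utc(datetime.fromisoformat(text))


@dataclass(frozen=True)
class LoadOutcome:
    batch_key: Optional[int]
    n_calibrations: int
    n_results: int
    duplicate: bool = False


def load_batch(parsed: ParsedBatch, store: Store) -> LoadOutcome:
    """Insert one parsed batch atomically.

    Re-loading a file with an already-ingested ``xml_file_name`` inserts
    nothing and reports a duplicate; a constraint violation rolls back
    the whole batch.
    """
    b = parsed.batch
    row = store.conn.execute(
        "SELECT batch_key FROM batch WHERE xml_file_name = ?", (b.xml_file_name,)
    ).fetchone()
    if row is not None:
        return LoadOutcome(batch_key=row[0], n_calibrations=0, n_results=0,
                           duplicate=True)
    span = b.injection_time_span or (None, None)
    try:
        with store.conn:
            cur = store.conn.execute(
                "INSERT INTO batch (xml_file_name, timestamp, instrument_id,"
                " lc_batch_name, first_injection, last_injection, sample_count)"
                " VALUES (?, ?, ?, ?, ?, ?, ?)",
                (
                    b.xml_file_name, _iso(b.timestamp), b.instrument_id,
                    b.lc_batch_name, _iso(span[0]), _iso(span[1]), b.sample_count,
                ),
            )
            batch_key = cur.lastrowid
            store.conn.executemany(
                "INSERT INTO calibration (xml_file_name, timestamp, compound,"
                " internal_standard, weighting, slope, r_squared, curve_type,"
                " origin) VALUES (?, ?, ?, ?, ?, ?, ?, ?, ?)",
                [
                    (
                        c.xml_file_name, _iso(c.timestamp), c.compound,
                        c.internal_standard, c.weighting, c.slope, c.r_squared,
                        c.curve_type, c.origin,
                    )
                    for c in parsed.calibrations
                ],
            )
            store.conn.executemany(
                "INSERT INTO results (xml_file_name, lc_batch_name, sample_type,"
                " sample_id, vial, injection_time, compound, compound_id,"
                " peak_area, confirming_ion_area, rt, sn, concentration, cc,"
                " internal_standard, is_id, is_peak_area, is_rt, is_sn,"
                " is_confirming_ion_area, instrument_id)"
                " VALUES (?, ?, ?, ?, ?, ?, ?, ?, ?, ?, ?, ?, ?, ?, ?, ?, ?, ?, ?, ?, ?)",
                [
                    (
                        r.xml_file_name, r.lc_batch_name, r.sample_type.value,
                        r.sample_id, r.vial, _iso(r.injection_time), r.compound,
                        r.compound_id, r.peak_area, r.confirming_ion_area, r.rt,
                        r.sn, r.concentration,
                        None if r.cc is None else int(r.cc),
                        r.internal_standard, r.is_id, r.is_peak_area, r.is_rt,
                        r.is_sn, r.is_confirming_ion_area, r.instrument_id,
                    )
                    for r in parsed.results
                ],
            )
    except sqlite3.Error:
        raise
    return LoadOutcome(
        batch_key=batch_key,
        n_calibrations=len(parsed.calibrations),
        n_results=len(parsed.results),
    )


def _filter_clauses(flt: ResultFilter) -> tuple[str, list]:
    clauses, params = [], []

    def in_clause(column: str, values) -> None:
        vals = sorted(values)
        clauses.append(f"{column} IN ({', '.join('?' * len(vals))})")
        params.extend(vals)

    if flt.instruments is not None:
        in_clause("instrument_id", flt.instruments)
    if flt.compounds is not None:
        in_clause("compound", flt.compounds)
    if flt.sample_types is not None:
        in_clause("sample_type", {s.value for s in flt.sample_types})
    if flt.batches is not None:
        in_clause("xml_file_name", flt.batches)
    if flt.date_range is not None:
        start, end = flt.date_range
        # (start, end]; ISO-8601 UTC text compares chronologically
        clauses.append("injection_time > ? AND injection_time <= ?")
        params.extend([_iso(start), _iso(end)])
    where = (" WHERE " + " AND ".join(clauses)) if clauses else ""
    return where, params


def _row_to_result(row: sqlite3.Row) -> ResultRecord:
    return ResultRecord(
        xml_file_name=row["xml_file_name"],
        lc_batch_name=row["lc_batch_name"],
        sample_type=SampleType(row["sample_type"]),
        sample_id=row["sample_id"],
        vial=row["vial"],
        injection_time=_dt(row["injection_time"]),
        compound=row["compound"],
        compound_id=row["compound_id"],
        peak_area=row["peak_area"],
        confirming_ion_area=row["confirming_ion_area"],
        rt=row["rt"],
        sn=row["sn"],
        concentration=row["concentration"],
        cc=None if row["cc"] is None else bool(row["cc"]),
        internal_standard=row["internal_standard"],
        is_id=row["is_id"],
        is_peak_area=row["is_peak_area"],
        is_rt=row["is_rt"],
        is_sn=row["is_sn"],
        is_confirming_ion_area=row["is_confirming_ion_area"],
        instrument_id=row["instrument_id"],
        result_key=row["result_key"],
    )


def query_results(flt: ResultFilter, store: Store) -> list[ResultRecord]:
    """Exactly the rows satisfying the conjunction of present filter
    fields, ordered by (injection_time, result_key).  Read-only."""
    where, params = _filter_clauses(flt)
    store.conn.row_factory = sqlite3.Row
    try:
        rows = store.conn.execute(
            "SELECT * FROM results" + where
            + " ORDER BY injection_time IS NULL, injection_time, result_key",
            params,
        ).fetchall()
    finally:
        store.conn.row_factory = None
    return [_row_to_result(row) for row in rows]


def query_batches(store: Store) -> list[BatchRecord]:
    store.conn.row_factory = sqlite3.Row
    try:
        rows = store.conn.execute(
            "SELECT * FROM batch ORDER BY timestamp, batch_key"
        ).fetchall()
    finally:
        store.conn.row_factory = None
    out = []
    for row in rows:
        first, last = _dt(row["first_injection"]), _dt(row["last_injection"])
        out.append(
            BatchRecord(
                xml_file_name=row["xml_file_name"],
                timestamp=_dt(row["timestamp"]),
                instrument_id=row["instrument_id"],
                sample_count=row["sample_count"],
                lc_batch_name=row["lc_batch_name"],
                injection_time_span=None if first is None else (first, last),
                batch_key=row["batch_key"],
            )
        )
    return out


def query_calibrations(store: Store, xml_file_name: Optional[str] = None) -> list[CalibrationRecord]:
    store.conn.row_factory = sqlite3.Row
    try:
        if xml_file_name is None:
            rows = store.conn.execute(
                "SELECT * FROM calibration ORDER BY calibration_key"
            ).fetchall()
        else:
            rows = store.conn.execute(
                "SELECT * FROM calibration WHERE xml_file_name = ?"
                " ORDER BY calibration_key",
                (xml_file_name,),
            ).fetchall()
    finally:
        store.conn.row_factory = None
    return [
        CalibrationRecord(
            xml_file_name=row["xml_file_name"],
            timestamp=_dt(row["timestamp"]),
            compound=row["compound"],
            internal_standard=row["internal_standard"],
            weighting=row["weighting"],
            slope=row["slope"],
            r_squared=row["r_squared"],
            curve_type=row["curve_type"],
            origin=row["origin"],
            calibration_key=row["calibration_key"],
        )
        for row in rows
    ]


def export_table(store: Store, table: str) -> pd.DataFrame:
    """Whole-table export (CSV-ready DataFrame)."""
    if table not in _EXPECTED_COLUMNS:
        raise ValueError(f"unknown table {table!r}; expected one of {sorted(_EXPECTED_COLUMNS)}")
    return pd.read_sql_query(f"SELECT * FROM {table}", store.conn)
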
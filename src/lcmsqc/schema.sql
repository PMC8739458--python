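-- Three-table relational model for targeted LC-MS/MS batch QC data.
-- STRICT tables: numeric-typed columns reject non-numeric text on insert.
-- Timestamps are stored as ISO-8601 UTC text, so lexicographic order is
-- chronological order.

CREATE TABLE IF NOT EXISTS batch (
    batch_key       INTEGER PRIMARY KEY,
    xml_file_name   TEXT NOT NULL UNIQUE,
    timestamp       TEXT NOT NULL,
    instrument_id   TEXT NOT NULL,
    lc_batch_name   TEXT,
    first_injection TEXT,
    last_injection  TEXT,
    sample_count    INTEGER NOT NULL CHECK (sample_count >= 0)
) STRICT;

CREATE TABLE IF NOT EXISTS calibration (
    calibration_key   INTEGER PRIMARY KEY,
    xml_file_name     TEXT NOT NULL,
    timestamp         TEXT NOT NULL,
    compound          TEXT NOT NULL,
    internal_standard TEXT,
    weighting         TEXT,
    slope             REAL,
    r_squared         REAL CHECK (r_squared IS NULL OR (r_squared >= 0.0 AND r_squared <= 1.0)),
    curve_type        TEXT,
    origin            TEXT,
    UNIQUE (xml_file_name, compound)
) STRICT;

CREATE TABLE IF NOT EXISTS results (
    result_key             INTEGER PRIMARY KEY,
    xml_file_name          TEXT NOT NULL,
    lc_batch_name          TEXT,
    sample_type            TEXT NOT NULL
        CHECK (sample_type IN ('calibrator', 'qc', 'patient', 'blank')),
    sample_id              TEXT NOT NULL,
    vial                   TEXT,
    injection_time         TEXT,
    compound               TEXT NOT NULL,
    compound_id            TEXT,
    peak_area              REAL CHECK (peak_area IS NULL OR peak_area >= 0.0),
    confirming_ion_area    REAL CHECK (confirming_ion_area IS NULL OR confirming_ion_area >= 0.0),
    rt                     REAL CHECK (rt IS NULL OR rt > 0.0),
    sn                     REAL CHECK (sn IS NULL OR sn >= 0.0),
    concentration          REAL CHECK (concentration IS NULL OR concentration >= 0.0),
    cc                     INTEGER CHECK (cc IS NULL OR cc IN (0, 1)),
    internal_standard      TEXT,
    is_id                  TEXT,
    is_peak_area           REAL CHECK (is_peak_area IS NULL OR is_peak_area >= 0.0),
    is_rt                  REAL CHECK (is_rt IS NULL OR is_rt > 0.0),
    is_sn                  REAL CHECK (is_sn IS NULL OR is_sn >= 0.0),
    is_confirming_ion_area REAL CHECK (is_confirming_ion_area IS NULL OR is_confirming_ion_area >= 0.0),
    instrument_id          TEXT NOT NULL
) STRICT;

CREATE INDEX IF NOT EXISTS idx_results_batch ON results (xml_file_name);
CREATE INDEX IF NOT EXISTS idx_results_compound_instrument
    ON results (compound, instrument_id);
CREATE INDEX IF NOT EXISTS idx_results_injection_time ON results (injection_time);
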
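# Batch quantification XML dialect

Vendor quantification packages export one XML file per analytical
batch, but their schemas are proprietary. `lcmsqc` therefore defines a
minimal, documented dialect with the same information content as a
targeted-quantification batch report. The parser
(`lcmsqc.xml_io.parse_quant_xml`) is layered over plain record types,
so a vendor-specific reader can be slotted in by emitting the same
`ParsedBatch` objects.

Files are UTF-8 XML with extension `.xml`. One file = one batch = one
acquisition run on one instrument.

## Grammar

```
quant_batch                       (root; exactly one per file)
  @file_name        mandatory  text, unique per ingestion run
  @acquired         mandatory  ISO-8601 datetime (normalized to UTC at parse)
  @instrument_id    mandatory  text
  @lc_batch_name    optional   text
  @sample_count     optional   integer; cross-checked against the number
                               of sample nodes (mismatch -> warning)

  calibrations                    (optional; 0..1)
    calibration                   (0..n; one per compound)
      @compound          mandatory  text
      @internal_standard optional   text
      @weighting         optional   text label (none, 1/x, 1/x^2)
      @slope             optional   real
      @r_squared         optional   real in [0, 1]
      @curve_type        optional   text label (linear, quadratic)
      @origin            optional   text label (include, exclude, force)

  samples                         (mandatory; exactly 1)
    sample                        (0..n; one per injection)
      @sample_id       mandatory  text; calibrators follow "Std-A".."Std-F"
                                  with level A the lowest concentration
      @sample_type     mandatory  free text, mapped onto
                                  {calibrator, qc, patient, blank}; the
                                  documented aliases include Standard,
                                  Cal -> calibrator; QC, Control -> qc;
                                  Patient, Unknown, Specimen -> patient;
                                  Blank -> blank. Unmapped -> hard error.
      @vial            optional   text (rack:position)
      @injection_time  optional   ISO-8601 datetime

      compound                    (0..n; one per analyte measured)
        @name          mandatory  text
        @compound_id   optional   text
        peak                      (0..1; analyte measurements)
          @area @confirming_area @rt @sn @concentration   optional numerics
          @cc                                             optional boolean
        internal_standard         (0..1; paired IS measurements)
          @name @is_id                                    optional text
          @area @rt @sn @confirming_area                  optional numerics
```

## Null and error semantics

* A **missing optional attribute is a null** — parsing never fabricates
  a value, and the writer omits attributes for null fields, so nulls
  round-trip as absence.
* **Non-numeric text** (`"n/a"`), non-finite values (`inf`, `nan`) and
  sign-violating values (negative areas, non-positive RTs) in numeric
  attributes become **null plus a parse warning**, never a coerced zero
  (zeros would corrupt downstream percentile borders).
* A missing mandatory element/attribute is a **structural error**
  naming the element; malformed XML is a **syntax error** carrying the
  parser's line/column position.
* Unknown extra elements are ignored with a warning.

## Units and conventions

Peak areas are detector area counts; retention times are minutes;
concentrations are ng/mL; S/N and ion ratios are dimensionless.
Timestamps may carry any UTC offset and are converted to UTC at parse.
Floats are written with shortest-exact `repr`, so a
write → parse cycle is bit-exact on every numeric field.
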
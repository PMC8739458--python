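"""Synthetic batch-corpus generator with controllable statistical
structure.

No real instrument exports ship with this package; every other module
is exercised against corpora produced here.  The generator emulates a
targeted urine opioid confirmation assay: each batch holds a calibrator
series (Std-A .. Std-F, ascending concentration), QC samples and
patient samples, one row per (sample, compound) pair, each analyte
paired with an isotope-labelled internal standard.

Statistical model (all draws from one seeded generator, so a fixed
seed reproduces a byte-identical corpus):

* internal-standard peak areas are lognormal — signal intensities are
  positive and right-skewed — scaled per instrument to emulate the
  systematic between-instrument differences (ion optics, detector
  gain) seen in practice, with an optional second lognormal mode for
  bimodal IS distributions;
* the analyte and its internal standard co-elute: IS RT is the
  compound's nominal RT and the analyte RT is nominal × N(1, rrt_sd),
  so relative retention times center on 1.0;
* patient rows suffer matrix-effect ion suppression with a configured
  probability, multiplying both analyte and IS areas;
* a configurable fraction of optional numeric fields is dropped to
  emulate sporadically missing export data.

``plant_failures`` turns a config into one whose corpus contains an
*exact* number of rule violations (recorded row-by-row in a
ground-truth sidecar), trading distributional realism on the affected
rows for the exact counts that construction-oracle tests need.  The
sidecar is for tests only; no production code path reads it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta, timezone
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import xml_io
from .records import (
    BatchRecord,
    CalibrationRecord,
    ParsedBatch,
    ResultRecord,
    SampleType,
)

__all__ = [
    "CompoundSpec",
    "InstrumentSpec",
    "GeneratorConfig",
    "PlantISBelow",
    "PlantRRTOutside",
    "PlantStdABelow",
    "PlantRulesetTransition",
    "PlantError",
    "plant_failures",
    "generate_batches",
    "generate_corpus",
    "CorpusManifest",
    "default_compound_panel",
]


@dataclass(frozen=True)
class CompoundSpec:
    name: str
    internal_standard: str
    nominal_rt: float  # minutes
    expected_ion_ratio: float


@dataclass(frozen=True)
class InstrumentSpec:
    instrument_id: str
    is_area_scale: float = 1.0


_PANEL = [
    # (compound, IS label suffix, nominal RT min, expected ion ratio)
    ("Morphine", "d6", 1.21, 0.62),
    ("Oxymorphone", "d3", 1.38, 0.48),
    ("Hydromorphone", "d6", 1.52, 0.55),
    ("Dihydrocodeine", "d6", 1.70, 0.41),
    ("Codeine", "d6", 1.84, 0.58),
    ("6-Monoacetylmorphine", "d6", 2.02, 0.44),
    ("Oxycodone", "d6", 2.15, 0.52),
    ("Noroxycodone", "d3", 2.26, 0.39),
    ("Hydrocodone", "d6", 2.41, 0.57),
    ("Norhydrocodone", "d3", 2.52, 0.36),
    ("Naloxone", "d5", 2.65, 0.47),
    ("Naltrexone", "d3", 2.78, 0.51),
    ("Tramadol", "d6", 2.95, 0.66),
    ("O-Desmethyltramadol", "d6", 3.10, 0.43),
    ("Tapentadol", "d3", 3.24, 0.49),
    ("Meperidine", "d4", 3.41, 0.61),
    ("Normeperidine", "d4", 3.55, 0.38),
    ("Fentanyl", "d5", 3.72, 0.54),
    ("Norfentanyl", "d5", 3.88, 0.42),
    ("Buprenorphine", "d4", 4.10, 0.35),
    ("Norbuprenorphine", "d3", 4.28, 0.33),
    ("Methadone", "d9", 4.55, 0.68),
    ("EDDP", "d3", 4.72, 0.46),
    ("Propoxyphene", "d5", 4.95, 0.40),
]


def default_compound_panel(n: int = 24) -> tuple[CompoundSpec, ...]:
    """First ``n`` compounds of the 24-compound opioid/metabolite panel."""
    if not 1 <= n <= len(_PANEL):
        raise ValueError(f"n must lie in [1, {len(_PANEL)}]")
    return tuple(
        CompoundSpec(name, f"{name}-{iso}", rt, ratio)
        for name, iso, rt, ratio in _PANEL[:n]
    )


# --- planted-violation specs ------------------------------------------------


class PlantError(ValueError):
    """Requested plant is infeasible for the configured corpus."""


@dataclass(frozen=True)
class PlantISBelow:
    """Exactly ``count`` eligible rows get an IS peak area below
    ``cutoff``; every other eligible row is forced at or above it."""

    count: int
    cutoff: float
    sample_types: tuple[str, ...] = ("calibrator",)


@dataclass(frozen=True)
class PlantRRTOutside:
    """Exactly ``count`` eligible rows get an RRT outside ``window``;
    every other eligible row is forced inside it."""

    count: int
    window: tuple[float, float] = (0.984, 1.024)
    sample_types: tuple[str, ...] = ("patient", "qc")


@dataclass(frozen=True)
class PlantStdABelow:
    """In exactly ``n_batches`` batches the Std-A row of ``compound``
    (default: the panel's first compound) falls below ``cutoff``; all
    other Std-A rows are forced at or above it."""

    n_batches: int
    cutoff: float
    compound: Optional[str] = None


@dataclass(frozen=True)
class PlantRulesetTransition:
    """Plant exact flag transitions between an old and a new rule set.

    ``n_new_fail`` rows get an IS peak area in [is_cutoff_old,
    is_cutoff_new) — they fail the (raised) new IS cutoff but passed
    the old one.  ``n_removed`` rows get an RRT inside
    ``rrt_window_new`` but outside ``rrt_window_old`` — old false
    positives that the (widened) new window no longer flags.  All other
    eligible rows pass both rule sets on both rules.
    """

    n_new_fail: int
    n_removed: int
    is_cutoff_old: float
    is_cutoff_new: float
    rrt_window_old: tuple[float, float]
    rrt_window_new: tuple[float, float]
    sample_types: tuple[str, ...] = ("patient", "qc")

    def __post_init__(self) -> None:
        if not self.is_cutoff_old < self.is_cutoff_new:
            raise PlantError("is_cutoff_new must exceed is_cutoff_old")
        ol, oh = self.rrt_window_old
        nl, nh = self.rrt_window_new
        if not (nl < ol < oh < nh):
            raise PlantError(
                "rrt_window_new must strictly contain rrt_window_old"
            )


Plant = Union[PlantISBelow, PlantRRTOutside, PlantStdABelow, PlantRulesetTransition]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic corpus.

    Defaults model the production assay the toolkit monitors: a
    24-compound opioid panel split across two instruments, six
    calibrator levels, two QC samples per batch, lognormal(μ=11,
    σ=0.4) internal-standard areas, RRT noise of 0.5% around
    co-elution, 5% of patient injections suppressed to 30% signal by
    matrix effects, and a 1% sporadic missing-field rate.
    """

    seed: int = 0
    n_batches: int = 10
    patients_per_batch: int = 10
    n_qc: int = 2
    instruments: tuple[InstrumentSpec, ...] = (
        InstrumentSpec("LCMS-1", 1.0),
        InstrumentSpec("LCMS-2", 1.0),
    )
    compounds: tuple[CompoundSpec, ...] = field(default_factory=default_compound_panel)
    calibrator_levels: tuple[tuple[str, float], ...] = (
        ("A", 1.0), ("B", 5.0), ("C", 10.0), ("D", 25.0), ("E", 50.0), ("F", 100.0),
    )
    is_area_log_mu: float = 11.0
    is_area_log_sigma: float = 0.4
    bimodal_fraction: float = 0.0
    bimodal_log_mu_shift: float = -1.5
    rrt_sd: float = 0.005
    patient_suppression: tuple[float, float] = (0.05, 0.3)
    missing_field_rate: float = 0.01
    sn_log_mu: float = 4.0
    sn_log_sigma: float = 0.6
    concentration_cv: float = 0.08
    start: datetime = datetime(2021, 1, 4, 8, 0, tzinfo=timezone.utc)
    batch_interval_hours: float = 24.0
    injection_interval_minutes: float = 3.0
    plants: tuple[Plant, ...] = ()

    def __post_init__(self) -> None:
        for rate in (self.bimodal_fraction, self.missing_field_rate,
                     self.patient_suppression[0]):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rates must lie in [0, 1], got {rate}")
        labels = [lb for lb, _c in self.calibrator_levels]
        concs = [c for _lb, c in self.calibrator_levels]
        if len(set(labels)) != len(labels) or sorted(labels) != labels:
            raise ValueError("calibrator labels must be unique and ordered")
        if sorted(concs) != concs:
            raise ValueError("calibrator concentrations must ascend with level")
        if any(i.is_area_scale <= 0 for i in self.instruments):
            raise ValueError("instrument is_area_scale must be positive")

    # row bookkeeping -------------------------------------------------
    def rows_per_batch(self, sample_type: SampleType) -> int:
        per_sample = len(self.compounds)
        if sample_type is SampleType.CALIBRATOR:
            return len(self.calibrator_levels) * per_sample
        if sample_type is SampleType.QC:
            return self.n_qc * per_sample
        if sample_type is SampleType.PATIENT:
            return self.patients_per_batch * per_sample
        return 0

    def total_rows(self, sample_types: Sequence[str]) -> int:
        return self.n_batches * sum(
            self.rows_per_batch(SampleType(st)) for st in sample_types
        )


def plant_failures(config: GeneratorConfig, plants: Sequence[Plant]) -> GeneratorConfig:
    """Return a config whose corpus contains exactly the requested
    violations; infeasible requests raise :class:`PlantError`."""
    demand: dict[tuple[str, ...], int] = {}
    for plant in plants:
        if isinstance(plant, PlantStdABelow):
            if plant.n_batches > config.n_batches:
                raise PlantError(
                    f"cannot plant sub-cutoff Std-A in {plant.n_batches} of "
                    f"{config.n_batches} batches"
                )
            name = plant.compound or config.compounds[0].name
            if name not in {c.name for c in config.compounds}:
                raise PlantError(f"unknown compound {name!r}")
            continue
        if isinstance(plant, PlantRulesetTransition):
            count = plant.n_new_fail + plant.n_removed
        else:
            count = plant.count
        key = tuple(sorted(plant.sample_types))
        demand[key] = demand.get(key, 0) + count
    for types, count in demand.items():
        available = config.total_rows(types)
        if count > available:
            raise PlantError(
                f"requested {count} planted rows among sample types {types} "
                f"but the corpus only contains {available}"
            )
    return replace(config, plants=tuple(plants))


# --- generation -------------------------------------------------------------

_MISSABLE_FIELDS = (
    "sn", "confirming_ion_area", "is_sn", "is_confirming_ion_area",
    "concentration", "is_peak_area",
)


def _base_rows(config: GeneratorConfig, rng: np.random.Generator) -> list[dict]:
    """Draw every row's values before plants/missingness are applied."""
    rows: list[dict] = []
    max_conc = config.calibrator_levels[-1][1]
    levels = [c for _lb, c in config.calibrator_levels]
    qc_levels = [levels[min(1, len(levels) - 1)], levels[max(len(levels) - 2, 0)]]
    for b in range(config.n_batches):
        instrument = config.instruments[b % len(config.instruments)]
        file_name = f"batch_{b + 1:04d}.xml"
        acquired = config.start + timedelta(hours=b * config.batch_interval_hours)

        samples: list[tuple[str, SampleType, float]] = []
        for label, conc in config.calibrator_levels:
            samples.append((f"Std-{label}", SampleType.CALIBRATOR, conc))
        for q in range(config.n_qc):
            samples.append((f"QC-{q + 1}", SampleType.QC, qc_levels[q % len(qc_levels)]))
        for p in range(config.patients_per_batch):
            conc = float(np.exp(rng.normal(np.log(30.0), 0.8)))
            samples.append((f"Pat-{b + 1:04d}-{p + 1:03d}", SampleType.PATIENT, conc))

        for s_idx, (sample_id, stype, nominal_conc) in enumerate(samples):
            injection = acquired + timedelta(
                minutes=s_idx * config.injection_interval_minutes
            )
            suppressed = (
                stype is SampleType.PATIENT
                and rng.random() < config.patient_suppression[0]
            )
            for comp in config.compounds:
                mu = config.is_area_log_mu
                if config.bimodal_fraction > 0 and rng.random() < config.bimodal_fraction:
                    mu += config.bimodal_log_mu_shift
                is_area = float(
                    np.exp(rng.normal(mu, config.is_area_log_sigma))
                    * instrument.is_area_scale
                )
                rrt_factor = float(max(rng.normal(1.0, config.rrt_sd), 0.5))
                conc = float(max(nominal_conc * rng.normal(1.0, config.concentration_cv), 0.0))
                peak_area = float(
                    is_area * (conc / max_conc) * np.exp(rng.normal(0.0, 0.05))
                )
                if suppressed:
                    factor = config.patient_suppression[1]
                    is_area *= factor
                    peak_area *= factor
                rows.append(
                    {
                        "batch_index": b,
                        "xml_file_name": file_name,
                        "lc_batch_name": f"LCB-{b + 1:04d}",
                        "acquired": acquired,
                        "instrument_id": instrument.instrument_id,
                        "sample_id": sample_id,
                        "sample_type": stype,
                        "vial": f"{1 + s_idx // 12}:{1 + s_idx % 12}",
                        "injection_time": injection,
                        "compound": comp.name,
                        "compound_id": comp.name.upper()[:3],
                        "internal_standard": comp.internal_standard,
                        "is_id": comp.internal_standard.upper()[:6],
                        "nominal_rt": comp.nominal_rt,
                        "is_rt": comp.nominal_rt,
                        "rt": comp.nominal_rt * rrt_factor,
                        "is_peak_area": is_area,
                        "peak_area": peak_area,
                        "confirming_ion_area": float(
                            peak_area * comp.expected_ion_ratio
                            * max(rng.normal(1.0, 0.03), 0.0)
                        ),
                        "is_confirming_ion_area": float(
                            is_area * 0.5 * max(rng.normal(1.0, 0.03), 0.0)
                        ),
                        "sn": float(np.exp(rng.normal(config.sn_log_mu, config.sn_log_sigma))),
                        "is_sn": float(
                            np.exp(rng.normal(config.sn_log_mu + 1.0, config.sn_log_sigma))
                        ),
                        "concentration": conc,
                        "cc": False,
                        "suppressed": suppressed,
                        "planted": "",
                        "protected": False,
                        "nulled_field": "",
                    }
                )
    return rows


def _eligible(rows: list[dict], sample_types: Sequence[str], taken: set[int]) -> list[int]:
    wanted = {SampleType(st) for st in sample_types}
    return [
        i for i, row in enumerate(rows)
        if row["sample_type"] in wanted and i not in taken
    ]


def _apply_plants(config: GeneratorConfig, rows: list[dict], rng: np.random.Generator) -> None:
    taken: set[int] = set()
    for plant in config.plants:
        if isinstance(plant, PlantISBelow):
            idx = _eligible(rows, plant.sample_types, taken)
            if plant.count > len(idx):
                raise PlantError("not enough eligible rows for PlantISBelow")
            chosen = set(rng.permutation(idx)[: plant.count].tolist())
            for i in idx:
                row = rows[i]
                row["protected"] = True
                if i in chosen:
                    row["is_peak_area"] = plant.cutoff * float(rng.uniform(0.3, 0.95))
                    row["planted"] = "is_below"
                    taken.add(i)
                elif row["is_peak_area"] < plant.cutoff:
                    row["is_peak_area"] = plant.cutoff * float(rng.uniform(1.01, 2.5))
        elif isinstance(plant, PlantRRTOutside):
            low, high = plant.window
            idx = _eligible(rows, plant.sample_types, taken)
            if plant.count > len(idx):
                raise PlantError("not enough eligible rows for PlantRRTOutside")
            chosen = set(rng.permutation(idx)[: plant.count].tolist())
            margin = (high - low) * 1e-3
            for i in idx:
                row = rows[i]
                row["protected"] = True
                if i in chosen:
                    if rng.random() < 0.5:
                        target = high + float(rng.uniform(2, 20)) * margin
                    else:
                        target = low - float(rng.uniform(2, 20)) * margin
                    row["planted"] = "rrt_outside"
                    taken.add(i)
                else:
                    target = float(
                        np.clip(row["rt"] / row["is_rt"], low + margin, high - margin)
                    )
                row["rt"] = row["is_rt"] * target
        elif isinstance(plant, PlantStdABelow):
            compound = plant.compound or config.compounds[0].name
            batches = set(
                rng.permutation(config.n_batches)[: plant.n_batches].tolist()
            )
            for i, row in enumerate(rows):
                if row["sample_type"] is not SampleType.CALIBRATOR:
                    continue
                if row["sample_id"] != f"Std-{config.calibrator_levels[0][0]}":
                    continue
                row["protected"] = True
                if row["compound"] == compound and row["batch_index"] in batches:
                    row["peak_area"] = plant.cutoff * float(rng.uniform(0.3, 0.9))
                    row["planted"] = "std_a_below"
                    taken.add(i)
                elif row["peak_area"] < plant.cutoff:
                    row["peak_area"] = plant.cutoff * float(rng.uniform(1.01, 2.0))
        elif isinstance(plant, PlantRulesetTransition):
            idx = _eligible(rows, plant.sample_types, taken)
            if plant.n_new_fail + plant.n_removed > len(idx):
                raise PlantError("not enough eligible rows for PlantRulesetTransition")
            order = rng.permutation(idx).tolist()
            new_fail = set(order[: plant.n_new_fail])
            removed = set(order[plant.n_new_fail: plant.n_new_fail + plant.n_removed])
            ol, oh = plant.rrt_window_old
            nl, nh = plant.rrt_window_new
            lo_c, hi_c = plant.is_cutoff_old, plant.is_cutoff_new
            margin = (oh - ol) * 1e-3
            for i in idx:
                row = rows[i]
                row["protected"] = True
                inside_old = float(
                    np.clip(row["rt"] / row["is_rt"], ol + margin, oh - margin)
                )
                if i in new_fail:
                    # fails the raised IS cutoff, passes the old one
                    row["is_peak_area"] = lo_c + float(rng.uniform(0.05, 0.95)) * (hi_c - lo_c)
                    row["rt"] = row["is_rt"] * inside_old
                    row["planted"] = "new_fail_is"
                    taken.add(i)
                elif i in removed:
                    # outside the old RRT window, inside the widened one
                    if rng.random() < 0.5:
                        target = float(rng.uniform(oh + margin, nh - margin))
                    else:
                        target = float(rng.uniform(nl + margin, ol - margin))
                    row["rt"] = row["is_rt"] * target
                    if row["is_peak_area"] < hi_c:
                        row["is_peak_area"] = hi_c * float(rng.uniform(1.01, 2.5))
                    row["planted"] = "removed_rrt"
                    taken.add(i)
                else:
                    row["rt"] = row["is_rt"] * inside_old
                    if row["is_peak_area"] < hi_c:
                        row["is_peak_area"] = hi_c * float(rng.uniform(1.01, 2.5))
        else:  # pragma: no cover - exhaustive over Plant union
            raise TypeError(f"unknown plant spec {plant!r}")


def _apply_missingness(config: GeneratorConfig, rows: list[dict], rng: np.random.Generator) -> None:
    if config.missing_field_rate <= 0:
        return
    for row in rows:
        if row["protected"]:
            continue
        if rng.random() < config.missing_field_rate:
            victim = _MISSABLE_FIELDS[int(rng.integers(len(_MISSABLE_FIELDS)))]
            row[victim] = None
            row["nulled_field"] = victim


def _assemble(config: GeneratorConfig, rows: list[dict]) -> list[ParsedBatch]:
    by_batch: dict[str, list[dict]] = {}
    for row in rows:
        by_batch.setdefault(row["xml_file_name"], []).append(row)
    batches = []
    for file_name in sorted(by_batch):
        rws = by_batch[file_name]
        first = rws[0]
        results = [
            ResultRecord(
                xml_file_name=file_name,
                lc_batch_name=row["lc_batch_name"],
                sample_type=row["sample_type"],
                sample_id=row["sample_id"],
                vial=row["vial"],
                injection_time=row["injection_time"],
                compound=row["compound"],
                compound_id=row["compound_id"],
                peak_area=row["peak_area"],
                confirming_ion_area=row["confirming_ion_area"],
                rt=row["rt"],
                sn=row["sn"],
                concentration=row["concentration"],
                cc=row["cc"],
                internal_standard=row["internal_standard"],
                is_id=row["is_id"],
                is_peak_area=row["is_peak_area"],
                is_rt=row["is_rt"],
                is_sn=row["is_sn"],
                is_confirming_ion_area=row["is_confirming_ion_area"],
                instrument_id=row["instrument_id"],
                result_key=k,
            )
            for k, row in enumerate(rws)
        ]
        times = [r.injection_time for r in results if r.injection_time]
        n_samples = len({(r.sample_id) for r in results})
        batch = BatchRecord(
            xml_file_name=file_name,
            timestamp=first["acquired"],
            instrument_id=first["instrument_id"],
            sample_count=n_samples,
            lc_batch_name=first["lc_batch_name"],
            injection_time_span=(min(times), max(times)) if times else None,
        )
        calibrations = [
            CalibrationRecord(
                xml_file_name=file_name,
                timestamp=first["acquired"],
                compound=comp.name,
                internal_standard=comp.internal_standard,
                weighting="1/x",
                slope=round(1.0 / config.calibrator_levels[-1][1], 6),
                r_squared=0.999,
                curve_type="linear",
                origin="exclude",
            )
            for comp in config.compounds
        ]
        batches.append(
            ParsedBatch(batch=batch, calibrations=calibrations, results=results)
        )
    return batches


_TRUTH_COLUMNS = [
    "xml_file_name", "instrument_id", "sample_id", "sample_type", "compound",
    "is_peak_area", "peak_area", "rt", "is_rt", "suppressed", "planted",
    "nulled_field",
]


def generate_batches(config: GeneratorConfig) -> tuple[list[ParsedBatch], pd.DataFrame]:
    """Generate the corpus in memory: parsed batches + ground truth.

    The ground-truth table records every row's final values, which rows
    were suppressed or nulled, and which carry a planted violation —
    the construction oracle for tests.
    """
    rng = np.random.default_rng(config.seed)
    rows = _base_rows(config, rng)
    _apply_plants(config, rows, rng)
    _apply_missingness(config, rows, rng)
    truth = pd.DataFrame(
        [{k: row[k] for k in _TRUTH_COLUMNS} for row in rows],
        columns=_TRUTH_COLUMNS,
    )
    truth["sample_type"] = truth["sample_type"].map(lambda s: s.value)
    return _assemble(config, rows), truth


@dataclass
class CorpusManifest:
    files: list[Path]
    truth_path: Path
    manifest_path: Path
    truth: pd.DataFrame
    config: GeneratorConfig


def _config_summary(config: GeneratorConfig) -> dict:
    d = dataclasses.asdict(config)
    d["start"] = config.start.isoformat()
    d["plants"] = [
        {"kind": type(p).__name__, **dataclasses.asdict(p)} for p in config.plants
    ]
    d["compounds"] = [c.name for c in config.compounds]
    return d


def generate_corpus(config: GeneratorConfig, out_dir: Union[str, Path]) -> CorpusManifest:
    """Emit the corpus as dialect XML files plus ground-truth sidecars.

    Deterministic for a fixed seed: the same config writes a
    byte-identical corpus.  Sidecars (``ground_truth.csv``,
    ``manifest.json``) live next to the batch files and are never read
    by production code.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    batches, truth = generate_batches(config)
    files = [
        xml_io.write_quant_xml(batch, out_dir / batch.batch.xml_file_name)
        for batch in batches
    ]
    truth_path = out_dir / "ground_truth.csv"
    truth.to_csv(truth_path, index=False)
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(
        json.dumps(
            {
                "files": [f.name for f in files],
                "instruments": [dataclasses.asdict(i) for i in config.instruments],
                "config": _config_summary(config),
            },
            indent=2,
            default=str,
        ),
        encoding="utf-8",
    )
    return CorpusManifest(
        files=files, truth_path=truth_path, manifest_path=manifest_path,
        truth=truth, config=config,
    )
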
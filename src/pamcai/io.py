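"""Delimited-text cohort files and YAML configuration.

Cohort layout: comma-separated, one row per participant (wide format with
``baseline_``/``followup_`` column prefixes, matching the trial's
two-timepoint design). Missing values are the explicit token ``NA`` — never
an empty numeric — so a withdrawn participant is distinguishable from a
zero. Intervals serialize as ``lo-hi`` with a degenerate interval collapsed
to a single number; decimal point, never comma.

Compact encodings for the variable-length fields:

* ``barrier_responses``: ``id:severity`` pairs joined by ``;`` (``"1:3;6:5"``)
* ``barrier_outcomes``: ``id:AR`` with A/R each ``0``/``1`` (``"1:10"`` =
  addressed, not resolved)
* ``materials``: ``label=unit_cost`` pairs joined by ``;``; a bare label
  means "price from catalogue"

``cohort_schema()`` returns a JSON-serializable dictionary documenting every
column.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable, Optional, Union

import yaml

from .types import (
    Arm,
    BarrierAssessment,
    BarrierOutcome,
    Education,
    Gender,
    Interval,
    Marital,
    ParticipantRecord,
    PriceTable,
    ResourceUse,
    Smoker,
    TimepointData,
    WearTimeReport,
)

__all__ = [
    "SCHEMA_VERSION",
    "CohortFormatError",
    "read_cohort",
    "write_cohort",
    "cohort_schema",
    "write_schema_json",
    "load_price_table",
    "dump_price_table",
]

SCHEMA_VERSION = "1"

NA = "NA"

_TIMEPOINT_FIELDS = (
    ["hours_awake", "hours_worn_left", "hours_worn_right", "days_per_week"]
    + [f"vcss_q{i}" for i in range(1, 11)]
    + ["civiq14_gis", "eq5d_utility", "eq5d_vas"]
)

COLUMNS = (
    ["schema_version", "participant_id", "arm", "age", "gender", "bmi", "education", "marital", "smoker"]
    + [f"baseline_{f}" for f in _TIMEPOINT_FIELDS]
    + [f"followup_{f}" for f in _TIMEPOINT_FIELDS]
    + [
        "barrier_responses",
        "barrier_outcomes",
        "n_f2f_appointments",
        "n_phone_appointments",
        "n_specialist_vlu_appointments",
        "n_vlu_admissions",
        "materials",
    ]
)


class CohortFormatError(ValueError):
    """A cohort file failed to parse or validate; the message names the
    offending row and column."""


# ---------------------------------------------------------------------------
# scalar/interval formatting

def _fmt_float(x: float) -> str:
    # str() on a Python float is the shortest round-trip representation
    return str(int(x)) if float(x).is_integer() else str(x)


def _fmt_interval(iv: Optional[Interval]) -> str:
    if iv is None:
        return NA
    if iv.is_point:
        return _fmt_float(iv.lo)
    return f"{_fmt_float(iv.lo)}-{_fmt_float(iv.hi)}"


def _parse_interval(text: str) -> Optional[Interval]:
    if text == NA:
        return None
    if "-" in text:
        lo_s, hi_s = text.split("-", 1)
        return Interval(lo=float(lo_s), hi=float(hi_s))
    return Interval.point(float(text))


def _fmt_opt(x: Optional[float]) -> str:
    return NA if x is None else _fmt_float(x)


def _parse_opt_float(text: str) -> Optional[float]:
    return None if text == NA else float(text)


def _parse_opt_int(text: str) -> Optional[int]:
    return None if text == NA else int(text)


# ---------------------------------------------------------------------------
# record <-> row

def _timepoint_to_cells(tp: Optional[TimepointData]) -> dict[str, str]:
    cells = {f: NA for f in _TIMEPOINT_FIELDS}
    if tp is None:
        return cells
    if tp.wear_report is not None:
        wr = tp.wear_report
        cells["hours_awake"] = _fmt_interval(wr.hours_awake)
        cells["hours_worn_left"] = _fmt_interval(wr.hours_worn_left)
        cells["hours_worn_right"] = _fmt_interval(wr.hours_worn_right)
        cells["days_per_week"] = _fmt_interval(wr.days_per_week)
    if tp.vcss_items is not None:
        for i, item in enumerate(tp.vcss_items, start=1):
            cells[f"vcss_q{i}"] = str(item)
    cells["civiq14_gis"] = _fmt_opt(tp.civiq14_gis)
    cells["eq5d_utility"] = _fmt_opt(tp.eq5d_utility)
    cells["eq5d_vas"] = _fmt_opt(tp.eq5d_vas)
    return cells


def _timepoint_from_cells(cells: dict[str, str]) -> Optional[TimepointData]:
    if all(cells[f] == NA for f in _TIMEPOINT_FIELDS):
        return None
    awake = _parse_interval(cells["hours_awake"])
    wear = None
    if awake is not None:
        wear = WearTimeReport(
            hours_awake=awake,
            hours_worn_left=_parse_interval(cells["hours_worn_left"]),
            hours_worn_right=_parse_interval(cells["hours_worn_right"]),
            days_per_week=_parse_interval(cells["days_per_week"]),
        )
    vcss_cells = [cells[f"vcss_q{i}"] for i in range(1, 11)]
    vcss = None
    if any(c != NA for c in vcss_cells):
        vcss = tuple(int(c) for c in vcss_cells)
    return TimepointData(
        wear_report=wear,
        vcss_items=vcss,
        civiq14_gis=_parse_opt_float(cells["civiq14_gis"]),
        eq5d_utility=_parse_opt_float(cells["eq5d_utility"]),
        eq5d_vas=_parse_opt_float(cells["eq5d_vas"]),
    )


def _fmt_responses(a: BarrierAssessment) -> str:
    if not a.responses:
        return NA
    return ";".join(f"{bid}:{sev}" for bid, sev in sorted(a.responses.items()))


def _parse_responses(text: str) -> BarrierAssessment:
    if text == NA or text == "":
        return BarrierAssessment()
    responses = {}
    for chunk in text.split(";"):
        bid_s, sev_s = chunk.split(":")
        responses[int(bid_s)] = int(sev_s)
    return BarrierAssessment(responses=responses)


def _fmt_outcomes(outcomes: Iterable[BarrierOutcome]) -> str:
    parts = [f"{o.barrier_id}:{int(o.addressed)}{int(o.resolved)}" for o in outcomes]
    return ";".join(parts) if parts else NA


def _parse_outcomes(text: str) -> tuple[BarrierOutcome, ...]:
    if text == NA or text == "":
        return ()
    out = []
    for chunk in text.split(";"):
        bid_s, flags = chunk.split(":")
        if len(flags) != 2 or any(c not in "01" for c in flags):
            raise ValueError(f"bad outcome flags {flags!r}")
        out.append(BarrierOutcome(barrier_id=int(bid_s), addressed=flags[0] == "1", resolved=flags[1] == "1"))
    return tuple(out)


def _fmt_materials(materials) -> str:
    if not materials:
        return NA
    parts = []
    for label, cost in materials:
        parts.append(label if cost is None else f"{label}={_fmt_float(cost)}")
    return ";".join(parts)


def _parse_materials(text: str):
    if text == NA or text == "":
        return ()
    out = []
    for chunk in text.split(";"):
        if "=" in chunk:
            label, cost_s = chunk.split("=", 1)
            out.append((label, float(cost_s)))
        else:
            out.append((chunk, None))
    return tuple(out)


def record_to_row(rec: ParticipantRecord) -> dict[str, str]:
    row = {
        "schema_version": SCHEMA_VERSION,
        "participant_id": rec.participant_id,
        "arm": rec.arm.value,
        "age": _fmt_float(rec.age),
        "gender": rec.gender.value,
        "bmi": _fmt_float(rec.bmi),
        "education": rec.education.value,
        "marital": rec.marital.value,
        "smoker": rec.smoker.value,
    }
    for prefix, tp in (("baseline", rec.baseline), ("followup", rec.followup)):
        for field, cell in _timepoint_to_cells(tp).items():
            row[f"{prefix}_{field}"] = cell
    ru = rec.resource_use
    row.update(
        barrier_responses=_fmt_responses(rec.barrier_assessment),
        barrier_outcomes=_fmt_outcomes(rec.barrier_outcomes),
        n_f2f_appointments=str(ru.n_f2f_appointments),
        n_phone_appointments=str(ru.n_phone_appointments),
        n_specialist_vlu_appointments=str(ru.n_specialist_vlu_appointments),
        n_vlu_admissions=str(ru.n_vlu_admissions),
        materials=_fmt_materials(ru.materials),
    )
    return row


def row_to_record(row: dict[str, str]) -> ParticipantRecord:
    baseline = _timepoint_from_cells(
        {f: row[f"baseline_{f}"] for f in _TIMEPOINT_FIELDS}
    )
    if baseline is None:
        baseline = TimepointData()
    followup = _timepoint_from_cells(
        {f: row[f"followup_{f}"] for f in _TIMEPOINT_FIELDS}
    )
    try:
        arm = Arm(row["arm"])
    except ValueError:
        raise ValueError(f"column 'arm': unknown arm label {row['arm']!r}") from None
    return ParticipantRecord(
        participant_id=row["participant_id"],
        arm=arm,
        age=float(row["age"]),
        gender=Gender(row["gender"]),
        bmi=float(row["bmi"]),
        education=Education(row["education"]),
        marital=Marital(row["marital"]),
        smoker=Smoker(row["smoker"]),
        baseline=baseline,
        followup=followup,
        barrier_assessment=_parse_responses(row["barrier_responses"]),
        barrier_outcomes=_parse_outcomes(row["barrier_outcomes"]),
        resource_use=ResourceUse(
            n_f2f_appointments=int(row["n_f2f_appointments"]),
            n_phone_appointments=int(row["n_phone_appointments"]),
            n_specialist_vlu_appointments=int(row["n_specialist_vlu_appointments"]),
            n_vlu_admissions=int(row["n_vlu_admissions"]),
            materials=_parse_materials(row["materials"]),
        ),
    )


# ---------------------------------------------------------------------------
# public API

def read_cohort(path: Union[str, Path], schema_version: str = SCHEMA_VERSION) -> list[ParticipantRecord]:
    """Read and validate a cohort CSV.

    Raises :class:`CohortFormatError` naming the row and column for any
    malformed or out-of-range value; missing follow-up blocks come back as
    ``followup=None``, never as zeros.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise CohortFormatError(f"{path}: empty file (no header)")
        missing = [c for c in COLUMNS if c not in reader.fieldnames]
        if missing:
            raise CohortFormatError(f"{path}: header missing columns {missing}")
        records = []
        for i, row in enumerate(reader, start=2):  # row 1 is the header
            if row.get("schema_version") != schema_version:
                raise CohortFormatError(
                    f"{path}: row {i}: schema_version "
                    f"{row.get('schema_version')!r} != expected {schema_version!r}"
                )
            try:
                records.append(row_to_record(row))
            except (ValueError, KeyError) as exc:
                raise CohortFormatError(f"{path}: row {i}: {exc}") from exc
    return records


def write_cohort(records: Iterable[ParticipantRecord], path: Union[str, Path]) -> None:
    """Write validated records as CSV; ``read_cohort`` round-trips exactly."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=COLUMNS)
        writer.writeheader()
        for rec in records:
            writer.writerow(record_to_row(rec))


def cohort_schema() -> dict:
    """Column dictionary for the cohort CSV (JSON-serializable)."""
    def col(name: str, dtype: str, desc: str) -> dict:
        return {"name": name, "type": dtype, "description": desc}

    interval = "interval: 'lo-hi' or single number; 'NA' when absent"
    cols = [
        col("schema_version", "string", f"file format version; currently '{SCHEMA_VERSION}'"),
        col("participant_id", "string", "participant label, e.g. 'P01'"),
        col("arm", "enum", "usual_care | intervention"),
        col("age", "float", "years"),
        col("gender", "enum", "female | male | other"),
        col("bmi", "float", "kg/m^2"),
        col("education", "enum", "|".join(e.value for e in Education)),
        col("marital", "enum", "single | partnered"),
        col("smoker", "enum", "never | previous | current"),
    ]
    for prefix in ("baseline", "followup"):
        cols += [
            col(f"{prefix}_hours_awake", "interval", interval + "; hours/day, 0-24"),
            col(f"{prefix}_hours_worn_left", "interval", interval + "; hours/day, 0-24"),
            col(f"{prefix}_hours_worn_right", "interval", interval + "; hours/day, 0-24"),
            col(f"{prefix}_days_per_week", "interval", interval + "; days, 0-7"),
        ]
        cols += [
            col(f"{prefix}_vcss_q{i}", "int", "VCSS item, 0-3 ('NA' if not collected)")
            for i in range(1, 11)
        ]
        cols += [
            col(f"{prefix}_civiq14_gis", "float", "CIVIQ-14 global index 0-100; 'NA' if missing"),
            col(f"{prefix}_eq5d_utility", "float", "EQ-5D-5L utility in [-0.6, 1.0]; 'NA' if missing"),
            col(f"{prefix}_eq5d_vas", "float", "EQ-5D-5L VAS 0-100; 'NA' if missing"),
        ]
    cols += [
        col("barrier_responses", "map", "'id:severity' pairs joined by ';', severity 1-5; 'NA' if none"),
        col("barrier_outcomes", "map", "'id:AR' pairs joined by ';', A=addressed, R=resolved, each 0/1"),
        col("n_f2f_appointments", "int", "face-to-face OT appointments"),
        col("n_phone_appointments", "int", "phone/telehealth OT appointments"),
        col("n_specialist_vlu_appointments", "int", "specialist VLU-recurrence appointments"),
        col("n_vlu_admissions", "int", "VLU-related hospital admissions"),
        col("materials", "map", "'label=unit_cost_AUD' pairs joined by ';'; bare label = catalogue price"),
    ]
    return {
        "schema_version": SCHEMA_VERSION,
        "delimiter": ",",
        "missing_token": NA,
        "columns": cols,
    }


def write_schema_json(path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(cohort_schema(), indent=2) + "\n")


def load_price_table(path: Union[str, Path]) -> PriceTable:
    """Load a :class:`PriceTable` from YAML (keys mirror the model fields)."""
    with Path(path).open() as fh:
        data = yaml.safe_load(fh) or {}
    return PriceTable(**data)


def dump_price_table(prices: PriceTable, path: Union[str, Path]) -> None:
    with Path(path).open("w") as fh:
        yaml.safe_dump(prices.model_dump(), fh, sort_keys=False)
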
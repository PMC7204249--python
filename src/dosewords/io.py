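"""Readers, schema validation, and pipeline configuration.

Input formats (all plain text, dates ISO-8601, day granularity):

``patients.csv``
    ``patient_id,sex,birth_year,icd10`` — ``icd10`` is a ``;``-joined list
    of ICD-10 codes (may be empty).
``prescriptions.csv``
    ``patient_id,drug,daily_dose_mg,start_date,end_date,ambiguous`` —
    inclusive date span, ``ambiguous`` in {true,false} (case-insensitive).
``notes.jsonl``
    One JSON object per line: ``patient_id``, ``date``, ``author_category``
    (one of the seven staff categories), ``text``.

Validation reports every malformed row with its line number and enforces
referential integrity (every prescription and note must reference a known
patient).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .ae import DEFAULT_N_DAYS
from .binning import DEFAULT_WIDTHS, MIN_PATIENTS_ANY, MIN_PATIENTS_NOTE_LENGTH
from .equivalents import METHODS
from .errors import ValidationError
from .notes import CATEGORIES, SUBSETS

_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no"}


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")


def _parse_dates(series: pd.Series, path, column: str) -> pd.Series:
    parsed = pd.to_datetime(series, format="%Y-%m-%d", errors="coerce")
    bad = series[parsed.isna()]
    if not bad.empty:
        offenders = [f"line {i + 2}: bad {column} {v!r}" for i, v in bad.items()]
        raise ValidationError(f"{path}: unparseable ISO dates", offenders)
    return parsed


def read_patients(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str}, keep_default_na=False)
    _require_columns(df, ["patient_id", "sex", "birth_year", "icd10"], path)
    offenders = []
    for i, sex in df["sex"].items():
        if sex not in ("M", "F"):
            offenders.append(f"line {i + 2}: sex must be M or F, got {sex!r}")
    dup = df["patient_id"][df["patient_id"].duplicated()]
    offenders += [f"line {i + 2}: duplicate patient_id {v!r}" for i, v in dup.items()]
    if offenders:
        raise ValidationError(f"{path}: invalid patient rows", offenders)
    df["birth_year"] = df["birth_year"].astype(int)
    return df


def read_prescriptions(path, patients: pd.DataFrame | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str, "drug": str})
    _require_columns(
        df,
        ["patient_id", "drug", "daily_dose_mg", "start_date", "end_date", "ambiguous"],
        path,
    )
    df["start_date"] = _parse_dates(df["start_date"], path, "start_date")
    df["end_date"] = _parse_dates(df["end_date"], path, "end_date")
    offenders = []
    for i, row in df.iterrows():
        if row["end_date"] < row["start_date"]:
            offenders.append(
                f"line {i + 2}: end_date {row['end_date'].date()} precedes "
                f"start_date {row['start_date'].date()}"
            )
        if not row["daily_dose_mg"] > 0:
            offenders.append(f"line {i + 2}: nonpositive daily_dose_mg {row['daily_dose_mg']}")
    amb = df["ambiguous"].astype(str).str.strip().str.lower()
    bad = ~amb.isin(_TRUE | _FALSE)
    offenders += [f"line {i + 2}: ambiguous must be true/false, got {v!r}"
                  for i, v in df["ambiguous"][bad].items()]
    if patients is not None:
        orphan = ~df["patient_id"].isin(set(patients["patient_id"]))
        offenders += [f"line {i + 2}: unknown patient_id {v!r}"
                      for i, v in df["patient_id"][orphan].items()]
    if offenders:
        raise ValidationError(f"{path}: invalid prescription rows", offenders)
    df["ambiguous"] = amb.isin(_TRUE)
    df["drug"] = df["drug"].str.lower()
    return df


def read_notes(path, patients: pd.DataFrame | None = None) -> pd.DataFrame:
    rows, offenders = [], []
    known = set(patients["patient_id"]) if patients is not None else None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                offenders.append(f"line {lineno}: invalid JSON ({exc.msg})")
                continue
            missing = [k for k in ("patient_id", "date", "author_category", "text")
                       if k not in rec]
            if missing:
                offenders.append(f"line {lineno}: missing field(s) {missing}")
                continue
            if rec["author_category"] not in CATEGORIES:
                offenders.append(
                    f"line {lineno}: unknown staff category {rec['author_category']!r}"
                )
                continue
            try:
                rec["date"] = pd.Timestamp(rec["date"])
            except ValueError:
                offenders.append(f"line {lineno}: bad date {rec['date']!r}")
                continue
            if known is not None and rec["patient_id"] not in known:
                offenders.append(f"line {lineno}: unknown patient_id {rec['patient_id']!r}")
                continue
            rows.append(rec)
    if offenders:
        raise ValidationError(f"{path}: invalid note records", offenders)
    return pd.DataFrame(rows, columns=["patient_id", "date", "author_category", "text"])


@dataclass
class PipelineConfig:
    """Paths and analysis parameters; the defaults are the study's."""

    patients: Path
    prescriptions: Path
    notes: Path
    out_dir: Path
    conversion_tables: Path | None = None  # None = packaged defaults
    ae_dictionary: Path | None = None      # None = packaged defaults
    methods: tuple[str, ...] = METHODS
    subsets: tuple[str, ...] = ("all", "physicians", "nursing")
    bin_widths: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_WIDTHS))
    min_patients_note_length: int = MIN_PATIENTS_NOTE_LENGTH
    min_patients_ae: int = MIN_PATIENTS_ANY
    n_sample_days: int = DEFAULT_N_DAYS
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValidationError(f"unknown method(s) {sorted(unknown)}")
        unknown = set(self.subsets) - set(SUBSETS)
        if unknown:
            raise ValidationError(f"unknown subset(s) {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        base = Path(path).parent
        for key in ("patients", "prescriptions", "notes", "out_dir",
                    "conversion_tables", "ae_dictionary"):
            if raw.get(key) is not None:
                raw[key] = base / raw[key]
        for key in ("methods", "subsets"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def read_inputs(config: PipelineConfig):
    """Read and validate the three record tables, enforcing integrity."""
    patients = read_patients(config.patients)
    prescriptions = read_prescriptions(config.prescriptions, patients=patients)
    notes = read_notes(config.notes, patients=patients)
    return patients, prescriptions, notes
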
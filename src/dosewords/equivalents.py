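"""Antipsychotic dose-equivalence normalization and per-method cohort building.

Heterogeneous antipsychotic prescriptions (drug, daily dose in mg) are mapped
onto a single daily load per patient and calendar day under one of three
normalization methods:

``ddd``
    Defined daily doses. The table entry is the WHO-style mg-per-DDD, so a
    daily dose in mg is divided by it; the unit of the result is "DDDs".
``olanzapine_eq``
    Olanzapine equivalents. The entry is mg olanzapine per mg of drug; the
    daily dose is multiplied by it (mg olanzapine).
``chlorpromazine_eq``
    Chlorpromazine equivalents, analogously (mg chlorpromazine).

Polypharmacy is handled by summing equivalents over all prescriptions active
on a day. A day on which any active drug lacks a table entry cannot be
normalized ("unconvertible"); a drug without an entry never converts to zero.
Patients are excluded from a method's cohort if any of their prescriptions is
flagged ambiguous, or if any of their treatment days is unconvertible under
that method.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

METHODS = ("ddd", "olanzapine_eq", "chlorpromazine_eq")

#: The antipsychotic formulary over which coverage is counted (the drugs the
#: study population can receive). All 21 are convertible to DDDs.
FORMULARY = (
    "amisulpride",
    "aripiprazole",
    "chlorprothixene",
    "clozapine",
    "flupentixol",
    "haloperidol",
    "levomepromazine",
    "melperone",
    "olanzapine",
    "paliperidone",
    "penfluridol",
    "perphenazine",
    "pimozide",
    "prochlorperazine",
    "quetiapine",
    "risperidone",
    "sertindole",
    "sulpiride",
    "thioridazine",
    "ziprasidone",
    "zuclopenthixol",
)

EXCLUDED_AMBIGUOUS = "ambiguous_prescription"
EXCLUDED_UNCONVERTIBLE = "unconvertible_day"


class _Uncovered(enum.Enum):
    token = 0

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "UNCOVERED"


#: Distinguished result for a drug outside a table's coverage.
UNCOVERED = _Uncovered.token


@dataclass(frozen=True)
class ConversionTable:
    """One normalization method's drug -> conversion factor mapping.

    ``entries`` maps lowercase drug names to strictly positive factors; for
    the ``ddd`` method the factor is mg-per-DDD (divisor), for the equivalent
    methods it is equivalent-mg per mg (multiplier).
    """

    method: str
    entries: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {METHODS}")
        clean = {}
        for drug, factor in self.entries.items():
            factor = float(factor)
            if not factor > 0:
                raise ValueError(f"conversion factor for {drug!r} must be > 0, got {factor}")
            clean[drug.lower()] = factor
        object.__setattr__(self, "entries", clean)

    @property
    def coverage(self) -> frozenset[str]:
        """Set of drug names this method can convert."""
        return frozenset(self.entries)

    def convert(self, drug: str, daily_dose_mg: float) -> float | _Uncovered:
        """Equivalent dose in method units, or :data:`UNCOVERED`."""
        if not daily_dose_mg > 0:
            raise ValueError(f"daily_dose_mg must be positive, got {daily_dose_mg}")
        factor = self.entries.get(drug.lower())
        if factor is None:
            return UNCOVERED
        if self.method == "ddd":
            return daily_dose_mg / factor
        return daily_dose_mg * factor


@dataclass(frozen=True)
class DailyExposure:
    """Summed equivalent dose of one patient on one treatment day."""

    patient_id: str
    date: pd.Timestamp
    method: str
    equivalent_dose: float  # NaN when not convertible
    convertible: bool


@dataclass(frozen=True)
class Cohort:
    """Per-method analysis cohort with an exclusion audit trail."""

    method: str
    patient_ids: frozenset[str]
    exclusion_log: Mapping[str, str] = field(default_factory=dict)

    @property
    def n_included(self) -> int:
        return len(self.patient_ids)

    @property
    def n_excluded(self) -> int:
        return len(self.exclusion_log)


def load_conversion_tables(path=None) -> dict[str, ConversionTable]:
    """Load the three conversion tables from YAML (packaged defaults if ``path`` is None)."""
    if path is None:
        text = resources.files("dosewords.data").joinpath("conversion_factors.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    missing = [m for m in METHODS if m not in raw]
    if missing:
        raise ValueError(f"conversion file lacks method blocks: {missing}")
    return {m: ConversionTable(method=m, entries=raw[m]) for m in METHODS}


def equivalent_dose(drug: str, daily_dose_mg: float, table: ConversionTable):
    """Convert one prescription's daily dose; :data:`UNCOVERED` if the drug has no entry."""
    return table.convert(drug, daily_dose_mg)


def daily_equivalent(
    prescriptions: pd.DataFrame,
    patient_id: str,
    date,
    table: ConversionTable,
) -> DailyExposure | None:
    """Total equivalent dose for one patient-day; ``None`` if it is not a treatment day.

    A treatment day is a calendar day with at least one active prescription
    (start <= date <= end, both inclusive). The result is unconvertible
    (``convertible=False``, dose NaN) if any active drug lacks a table entry.
    """
    date = pd.Timestamp(date)
    active = prescriptions[
        (prescriptions["patient_id"] == patient_id)
        & (prescriptions["start_date"] <= date)
        & (prescriptions["end_date"] >= date)
    ]
    if active.empty:
        return None
    total = 0.0
    for _, row in active.iterrows():
        eq = table.convert(row["drug"], row["daily_dose_mg"])
        if eq is UNCOVERED:
            return DailyExposure(patient_id, date, table.method, float("nan"), False)
        total += eq
    return DailyExposure(patient_id, date, table.method, total, True)


def daily_exposure_table(prescriptions: pd.DataFrame, table: ConversionTable) -> pd.DataFrame:
    """All treatment days for all patients under one method, vectorized.

    Returns a frame with columns ``patient_id, date, equivalent_dose,
    convertible``, one row per (patient, treatment day). ``equivalent_dose``
    is NaN on unconvertible days. Days with no active prescription are simply
    absent (they are not treatment days, not zero-dose days).
    """
    if prescriptions.empty:
        return pd.DataFrame(columns=["patient_id", "date", "equivalent_dose", "convertible"])
    rx = prescriptions.copy()
    drugs = rx["drug"].str.lower()
    factor = drugs.map(table.entries)  # NaN = uncovered
    dose = rx["daily_dose_mg"].astype(float)
    if (dose <= 0).any():
        bad = rx.index[dose <= 0].tolist()
        raise ValueError(f"nonpositive daily_dose_mg at rows {bad}")
    if table.method == "ddd":
        rx["eq"] = dose / factor
    else:
        rx["eq"] = dose * factor
    rx["date"] = [
        pd.date_range(s, e) for s, e in zip(rx["start_date"], rx["end_date"])
    ]
    days = rx[["patient_id", "date", "eq"]].explode("date", ignore_index=True)
    grouped = days.groupby(["patient_id", "date"], sort=True)["eq"]
    out = grouped.agg(equivalent_dose="sum", n="size", n_ok="count").reset_index()
    out["convertible"] = out["n_ok"] == out["n"]
    out.loc[~out["convertible"], "equivalent_dose"] = np.nan
    return out[["patient_id", "date", "equivalent_dose", "convertible"]]


def build_cohort(
    patients: pd.DataFrame,
    prescriptions: pd.DataFrame,
    table: ConversionTable,
) -> Cohort:
    """Apply the exclusion cascade and return the method's cohort.

    Eligible patients are those with >= 1 antipsychotic prescription. A
    patient is excluded first if any prescription is flagged ambiguous, then
    if any treatment day is unconvertible under ``table`` (equivalently: any
    prescribed drug is outside the method's coverage, since every prescription
    is active on at least its start day). Included and excluded patients
    partition the eligible set.
    """
    eligible = prescriptions["patient_id"].unique()
    by_patient = prescriptions.groupby("patient_id")
    ambiguous = by_patient["ambiguous"].any()
    covered = prescriptions["drug"].str.lower().isin(table.coverage)
    all_covered = covered.groupby(prescriptions["patient_id"]).all()

    log: dict[str, str] = {}
    included: list[str] = []
    for pid in eligible:
        if ambiguous[pid]:
            log[pid] = EXCLUDED_AMBIGUOUS
        elif not all_covered[pid]:
            log[pid] = EXCLUDED_UNCONVERTIBLE
        else:
            included.append(pid)
    return Cohort(method=table.method, patient_ids=frozenset(included), exclusion_log=log)


def coverage_matrix(tables: Mapping[str, ConversionTable]) -> dict[str, int]:
    """Covered-drug count per method over the packaged 21-drug formulary."""
    formulary = set(FORMULARY)
    return {m: len(t.coverage & formulary) for m, t in tables.items()}
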
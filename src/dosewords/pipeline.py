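"""End-to-end orchestration and cohort-characteristics reporting.

``run_pipeline`` executes, per normalization method: cohort construction
(exclusion cascade), daily exposure and word-count aggregation, dose binning
with the 100-patient floor for the note-length association, the three-interval
adverse-event-per-word estimate over 125 sampled treatment days (10-patient
floor for the constituent bins), and a Table-style cohort characteristics
summary. Every random choice flows from the single configured seed.

Report percentages use half-away-from-zero rounding: one decimal for
characteristics, integer percent for note shares.
"""

from __future__ import annotations

import json
import logging
import warnings
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import numpy as np
import pandas as pd

from . import ae as ae_mod
from . import binning, notes as notes_mod
from .equivalents import (
    Cohort,
    build_cohort,
    coverage_matrix,
    daily_exposure_table,
    load_conversion_tables,
)
from .errors import InsufficientDataError
from .io import PipelineConfig, read_inputs

logger = logging.getLogger("dosewords")


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round half away from zero (5 rounds up in magnitude), as in the reports."""
    exp = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(exp, rounding=ROUND_HALF_UP))


def pct(count: float, total: float, ndigits: int = 1) -> float:
    """``100 * count / total`` rounded half-away-from-zero to ``ndigits``."""
    if total == 0:
        raise ZeroDivisionError("percentage of an empty total")
    return round_half_up(100.0 * count / total, ndigits)


def note_shares(notes: pd.DataFrame) -> dict[str, int]:
    """Integer-percent share of note counts by physician / nursing / other."""
    total = len(notes)
    phys = int((notes["author_category"] == "physician").sum())
    nurs = int((notes["author_category"] == "nursing").sum())
    return {
        "physicians_pct": int(pct(phys, total, 0)),
        "nursing_pct": int(pct(nurs, total, 0)),
        "other_pct": int(pct(total - phys - nurs, total, 0)),
    }


def word_shares(notes: pd.DataFrame, word_counts: pd.Series | None = None) -> dict[str, int]:
    """Integer-percent share of *words* by physician / nursing / other staff."""
    words = notes_mod.note_word_counts(notes) if word_counts is None else word_counts
    total = int(words.sum())
    by_cat = words.groupby(notes["author_category"]).sum()
    phys = int(by_cat.get("physician", 0))
    nurs = int(by_cat.get("nursing", 0))
    return {
        "physicians_pct": int(pct(phys, total, 0)),
        "nursing_pct": int(pct(nurs, total, 0)),
        "other_pct": int(pct(total - phys - nurs, total, 0)),
    }


def summarize_characteristics(
    patients: pd.DataFrame, cohort: Cohort, reference_year: int
) -> pd.DataFrame:
    """Cohort characteristics: n, male sex n (%), mean age (SD), ICD-10 counts (%).

    Age is computed as ``reference_year - birth_year``. Percentages are per
    cohort patient count, one decimal, half-away-from-zero.
    """
    sub = patients[patients["patient_id"].isin(cohort.patient_ids)]
    n = len(sub)
    if n == 0:
        warnings.warn(f"empty cohort for method {cohort.method}; empty characteristics")
        return pd.DataFrame(columns=["method", "characteristic", "value", "percent"])
    rows = [
        {"characteristic": "n_patients", "value": float(n), "percent": np.nan},
    ]
    male = int((sub["sex"] == "M").sum())
    rows.append({"characteristic": "male_sex", "value": float(male),
                 "percent": pct(male, n)})
    age = reference_year - sub["birth_year"]
    rows.append({"characteristic": "mean_age", "value": round_half_up(age.mean(), 1),
                 "percent": np.nan})
    rows.append({"characteristic": "sd_age", "value": round_half_up(age.std(ddof=1), 1),
                 "percent": np.nan})
    codes = sub["icd10"].str.split(";").explode()
    codes = codes[codes != ""]
    for code, count in codes.value_counts().sort_index().items():
        rows.append({"characteristic": f"icd10_{code}", "value": float(count),
                     "percent": pct(int(count), n)})
    out = pd.DataFrame(rows)
    out.insert(0, "method", cohort.method)
    return out


def run_pipeline(
    config: PipelineConfig,
    tables_override=None,
    frames: tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame] | None = None,
) -> dict:
    """Run the full analysis; write report files and return the results.

    ``frames`` may supply in-memory (patients, prescriptions, notes) tables,
    bypassing file reading (the CLI always reads files).
    """
    if frames is None:
        patients, prescriptions, notes = read_inputs(config)
    else:
        patients, prescriptions, notes = frames
    tables = tables_override or load_conversion_tables(config.conversion_tables)
    dictionary = ae_mod.load_ae_dictionary(config.ae_dictionary)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    ref_year = int(
        np.mean([prescriptions["start_date"].min().year,
                 prescriptions["end_date"].max().year])
    )

    # One pass over the corpus; per-subset daily totals are shared across
    # methods (the exposure join restricts them to each method's cohort).
    per_note_words = notes_mod.note_word_counts(notes)
    subset_counts = {
        s: notes_mod.daily_word_counts(notes, s, word_counts=per_note_words)
        for s in dict.fromkeys(list(config.subsets) + ["all"])
    }

    all_bins, associations, ae_rows, characteristics, exclusions = [], [], [], [], []
    for method in config.methods:
        table = tables[method]
        cohort = build_cohort(patients, prescriptions, table)
        logger.info("method %s: %d included, %d excluded",
                    method, cohort.n_included, cohort.n_excluded)
        for pid, reason in sorted(cohort.exclusion_log.items()):
            exclusions.append({"method": method, "patient_id": pid, "reason": reason})
        characteristics.append(summarize_characteristics(patients, cohort, ref_year))

        rx_inc = prescriptions[prescriptions["patient_id"].isin(cohort.patient_ids)]
        exposures = daily_exposure_table(rx_inc, table)
        scheme = binning.BinningScheme(method=method, width=config.bin_widths[method])

        for subset in config.subsets:
            counts = subset_counts[subset]
            bins = binning.aggregate_bins(
                exposures, counts, scheme,
                min_patients=config.min_patients_note_length, subset=subset,
            )
            all_bins.extend(bins)
            try:
                summary = binning.association_summary(bins)
            except InsufficientDataError as exc:
                logger.warning("association (%s, %s): %s", method, subset, exc)
                summary = {"rho": np.nan, "direction": 0, "n_bins": len(bins)}
            associations.append({"method": method, "subset": subset, **summary})

        # Adverse-event density: interval construction uses the 10-patient
        # floor on all-notes bins; each interval samples n treatment days.
        ae_bins = binning.aggregate_bins(
            exposures, subset_counts["all"], scheme,
            min_patients=config.min_patients_ae, subset="all",
        )
        try:
            intervals = ae_mod.define_ae_intervals(ae_bins, scheme)
        except InsufficientDataError as exc:
            logger.warning("AE intervals (%s): %s", method, exc)
            continue
        rng = np.random.default_rng(config.seed)
        for interval in intervals:
            days = ae_mod.sample_treatment_days(
                interval, exposures, n=config.n_sample_days, rng=rng
            )
            est = ae_mod.estimate_rate(
                interval, days, notes, dictionary, word_counts=per_note_words
            )
            ae_rows.append(est)

    bins_df = binning.bins_frame(all_bins)
    assoc_df = pd.DataFrame(associations)
    ae_df = ae_mod.rates_frame(ae_rows)
    chars_df = (
        pd.concat(characteristics, ignore_index=True)
        if characteristics else pd.DataFrame()
    )
    excl_df = pd.DataFrame(exclusions, columns=["method", "patient_id", "reason"])

    bins_df.to_csv(out_dir / "bins.csv", index=False)
    assoc_df.to_csv(out_dir / "association.csv", index=False)
    ae_df.to_csv(out_dir / "ae_rates.csv", index=False)
    chars_df.to_csv(out_dir / "characteristics.csv", index=False)
    excl_df.to_csv(out_dir / "exclusions.csv", index=False)
    summary = {
        "coverage": coverage_matrix(tables),
        "note_shares": note_shares(notes),
        "word_shares": word_shares(notes, word_counts=per_note_words),
        "associations": assoc_df.replace({np.nan: None}).to_dict(orient="records"),
        "ae_rates": ae_df.to_dict(orient="records"),
        "seed": config.seed,
    }
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {
        "bins": bins_df,
        "associations": assoc_df,
        "ae_rates": ae_df,
        "characteristics": chars_df,
        "exclusions": excl_df,
        "summary": summary,
    }
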
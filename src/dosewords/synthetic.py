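"""Synthetic psychiatric-EHR cohort generator with known ground truth.

The real records this package's analyses were designed for are
restricted-access, so every stage is exercised on a generated stand-in
cohort of patients, antipsychotic prescriptions and free-text notes whose
generative parameters are known exactly:

* Each patient gets one or more prescription episodes (constant daily dose
  over an inclusive date span, drug drawn from a weighted formulary), a
  configurable chance of a second concurrent antipsychotic, and a
  configurable fraction of prescriptions flagged ambiguous.
* For every treatment day and staff category ``c`` the daily word count is
  negative-binomial with mean ``alpha_c * (1 + beta * d)``, where ``d`` is
  the day's true summed dose in defined daily doses; the count is realized
  as that many whitespace-separated tokens.
* Each token is independently an adverse-event dictionary token with
  probability ``r``; all other tokens come from a neutral vocabulary
  disjoint from the dictionary.

Note text is token soup by design: token counts and adverse-event density
are the modelled quantities, narrative realism is a non-goal.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import date
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .equivalents import load_conversion_tables, daily_exposure_table
from .errors import ConfigurationError
from .notes import CATEGORIES

#: Default per-staff-category mean words per treatment day at dose 0
#: (``alpha_c``). Nursing and physician notes dominate, with nursing roughly
#: three quarters of all words and allied staff a few percent, mirroring the
#: staff mix of a psychiatric inpatient record.
DEFAULT_BASELINE_WORDS = {
    "physician": 80.0,
    "nursing": 300.0,
    "physical_therapist": 5.0,
    "occupational_therapist": 5.0,
    "psychologist": 5.0,
    "social_worker": 5.0,
    "secretary": 5.0,
}

#: ICD-10 codes assigned to synthetic patients with the prevalence of each
#: code in a tertiary psychiatric antipsychotic-treated population
#: (schizophrenia most common, heavy substance-use comorbidity).
ICD10_PREVALENCE = {
    "F20": 0.466, "F10": 0.419, "F12": 0.300, "F60": 0.207, "F11": 0.167,
    "Z046": 0.167, "F13": 0.160, "F19": 0.142, "F33": 0.124, "F14": 0.119,
    "F41": 0.102, "F15": 0.079, "F32": 0.076, "F21": 0.066, "F31": 0.062,
    "F22": 0.035, "F25": 0.031, "F23": 0.016,
}

MALE_FRACTION = 0.655
MEAN_AGE, SD_AGE = 40.2, 6.3


@dataclass(frozen=True)
class DrugSpec:
    """One formulary entry: prescribing weight and daily-dose law (mg).

    Doses are drawn log-normally around ``median_dose_mg`` with log-scale
    spread ``sigma``, i.e. half of prescriptions exceed the median dose and
    ~95% fall within a factor ``exp(2*sigma)`` of it.
    """

    name: str
    weight: float
    median_dose_mg: float
    sigma: float = 0.5


def default_formulary() -> list[DrugSpec]:
    """21-drug formulary with second-generation agents dominating prescribing.

    Median doses equal one WHO defined daily dose of each drug, so the
    typical per-prescription load is ~1 DDD and polypharmacy pushes days
    into higher bins.
    """
    ddd = load_conversion_tables()["ddd"].entries
    weights = {
        "olanzapine": 0.20, "risperidone": 0.15, "quetiapine": 0.15,
        "zuclopenthixol": 0.08, "clozapine": 0.07, "haloperidol": 0.06,
        "perphenazine": 0.05, "chlorprothixene": 0.05, "flupentixol": 0.04,
        "amisulpride": 0.03, "aripiprazole": 0.03, "levomepromazine": 0.03,
        "ziprasidone": 0.02, "paliperidone": 0.01, "sulpiride": 0.01,
        "sertindole": 0.01, "pimozide": 0.005, "prochlorperazine": 0.005,
        "thioridazine": 0.005, "melperone": 0.003, "penfluridol": 0.002,
    }
    return [DrugSpec(name=d, weight=w, median_dose_mg=ddd[d]) for d, w in weights.items()]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic cohort."""

    n_patients: int = 500
    date_range: tuple[date, date] = (date(2000, 1, 1), date(2010, 6, 30))
    drug_formulary: list[DrugSpec] = field(default_factory=default_formulary)
    polypharmacy_prob: float = 0.25
    ambiguous_prob: float = 0.05
    baseline_words: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_WORDS)
    )
    dose_slope: float = 0.5      # beta: relative word increase per DDD
    dispersion: float = 1.0      # negative-binomial size; var = m + m^2/size
    ae_rate: float = 0.009       # per-token adverse-event probability r
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        if not self.drug_formulary:
            raise ConfigurationError("drug_formulary must not be empty")
        for p, name in [
            (self.polypharmacy_prob, "polypharmacy_prob"),
            (self.ambiguous_prob, "ambiguous_prob"),
            (self.ae_rate, "ae_rate"),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {p}")
        if self.dose_slope < 0:
            raise ConfigurationError("dose_slope must be >= 0")
        if not self.dispersion > 0:
            raise ConfigurationError("dispersion must be > 0")
        if self.date_range[0] > self.date_range[1]:
            raise ConfigurationError("date_range start must not exceed end")
        bad = set(self.baseline_words) - set(CATEGORIES)
        if bad or not self.baseline_words:
            raise ConfigurationError(
                f"baseline_words keys must be a nonempty subset of {CATEGORIES}, "
                f"got unknown {sorted(bad)}"
            )
        for spec in self.drug_formulary:
            if spec.weight <= 0 or spec.median_dose_mg <= 0 or spec.sigma < 0:
                raise ConfigurationError(f"invalid drug spec {spec}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["date_range"] = [self.date_range[0].isoformat(), self.date_range[1].isoformat()]
        return d


@dataclass
class SyntheticCohort:
    patients: pd.DataFrame
    prescriptions: pd.DataFrame
    notes: pd.DataFrame
    ground_truth: GeneratorConfig
    #: true per-token AE counts per note row, aligned with ``notes.index``
    note_ae_counts: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    #: true summed DDD load per treatment day (patient_id, date, equivalent_dose)
    true_exposures: pd.DataFrame | None = None


def load_vocabulary() -> list[str]:
    text = resources.files("dosewords.data").joinpath("vocabulary.txt").read_text()
    return [w.strip() for w in text.splitlines() if w.strip() and not w.startswith("#")]


def _generate_patients(cfg: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_patients
    ids = [f"P{i:05d}" for i in range(n)]
    sex = np.where(rng.random(n) < MALE_FRACTION, "M", "F")
    mid_year = (cfg.date_range[0].year + cfg.date_range[1].year) // 2
    age = np.clip(np.round(rng.normal(MEAN_AGE, SD_AGE, n)), 18, 85).astype(int)
    birth_year = mid_year - age
    codes, probs = zip(*ICD10_PREVALENCE.items())
    draw = rng.random((n, len(codes))) < np.asarray(probs)
    icd10 = [";".join(c for c, hit in zip(codes, row) if hit) for row in draw]
    return pd.DataFrame(
        {"patient_id": ids, "sex": sex, "birth_year": birth_year, "icd10": icd10}
    )


def _generate_prescriptions(cfg: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    start0 = pd.Timestamp(cfg.date_range[0])
    window = (pd.Timestamp(cfg.date_range[1]) - start0).days
    specs = cfg.drug_formulary
    weights = np.array([s.weight for s in specs], dtype=float)
    weights /= weights.sum()
    rows = []
    for i in range(cfg.n_patients):
        pid = f"P{i:05d}"
        n_ep = 1 + rng.binomial(2, 0.35)
        for _ in range(n_ep):
            duration = int(rng.integers(10, 46))
            offset = int(rng.integers(0, max(1, window - duration + 1)))
            start = start0 + pd.Timedelta(days=offset)
            end = start + pd.Timedelta(days=duration - 1)
            n_drugs = 2 if rng.random() < cfg.polypharmacy_prob else 1
            chosen = rng.choice(len(specs), size=n_drugs, replace=False, p=weights)
            for j in chosen:
                spec = specs[j]
                dose = float(
                    np.round(spec.median_dose_mg * rng.lognormal(0.0, spec.sigma), 1)
                )
                rows.append(
                    {
                        "patient_id": pid,
                        "drug": spec.name,
                        "daily_dose_mg": max(dose, 0.1),
                        "start_date": start,
                        "end_date": end,
                        "ambiguous": bool(rng.random() < cfg.ambiguous_prob),
                    }
                )
    return pd.DataFrame(rows)


def _generate_notes(
    cfg: GeneratorConfig,
    exposures: pd.DataFrame,
    rng: np.random.Generator,
    vocabulary: list[str],
    ae_terms: list[str],
) -> tuple[pd.DataFrame, np.ndarray]:
    """Realize token text for every patient-day x category with words > 0."""
    dose = exposures["equivalent_dose"].to_numpy(dtype=float)
    mult = 1.0 + cfg.dose_slope * dose
    pid = exposures["patient_id"].to_numpy()
    day = exposures["date"].to_numpy()

    pids, days, cats, counts = [], [], [], []
    theta = cfg.dispersion
    for cat in CATEGORIES:
        alpha = cfg.baseline_words.get(cat)
        if alpha is None:
            continue
        mean = alpha * mult
        lam = rng.gamma(shape=theta, scale=mean / theta)
        w = rng.poisson(lam)
        keep = w > 0
        pids.append(pid[keep])
        days.append(day[keep])
        cats.append(np.repeat(cat, keep.sum()))
        counts.append(w[keep])
    pid_all = np.concatenate(pids)
    day_all = np.concatenate(days)
    cat_all = np.concatenate(cats)
    n_words = np.concatenate(counts).astype(np.int64)

    total = int(n_words.sum())
    pool = np.array(list(vocabulary) + list(ae_terms), dtype=object)
    n_vocab = len(vocabulary)
    base_idx = rng.integers(0, n_vocab, total, dtype=np.int64)
    ae_mask = rng.random(total) < cfg.ae_rate
    ae_idx = rng.integers(0, len(ae_terms), total, dtype=np.int64)
    idx = np.where(ae_mask, n_vocab + ae_idx, base_idx)
    tokens = pool[idx].tolist()

    offsets = np.concatenate([[0], np.cumsum(n_words)])
    texts = [
        " ".join(tokens[offsets[i]: offsets[i + 1]]) for i in range(len(n_words))
    ]
    if total:
        ae_counts = np.add.reduceat(ae_mask.astype(np.int64), offsets[:-1])
    else:
        ae_counts = np.zeros(len(n_words), dtype=np.int64)

    notes = pd.DataFrame(
        {
            "patient_id": pid_all,
            "date": pd.to_datetime(day_all),
            "author_category": cat_all,
            "text": texts,
        }
    )
    order = notes.sort_values(
        ["patient_id", "date", "author_category"], kind="mergesort"
    ).index
    notes = notes.loc[order].reset_index(drop=True)
    return notes, np.asarray(ae_counts, dtype=int)[order]


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Generate a full cohort; identical configs give identical cohorts."""
    rng = np.random.default_rng(config.seed)
    vocabulary = load_vocabulary()
    from .ae import load_ae_dictionary  # local import to avoid a cycle at import time

    ae_terms = sorted(load_ae_dictionary())
    overlap = set(vocabulary) & set(ae_terms)
    if overlap:
        raise ConfigurationError(
            f"neutral vocabulary overlaps the AE dictionary: {sorted(overlap)}"
        )

    patients = _generate_patients(config, rng)
    prescriptions = _generate_prescriptions(config, rng)
    ddd_table = load_conversion_tables()["ddd"]
    exposures = daily_exposure_table(prescriptions, ddd_table)
    notes, ae_counts = _generate_notes(config, exposures, rng, vocabulary, ae_terms)
    return SyntheticCohort(
        patients=patients,
        prescriptions=prescriptions,
        notes=notes,
        ground_truth=config,
        note_ae_counts=ae_counts,
        true_exposures=exposures[["patient_id", "date", "equivalent_dose"]],
    )


def write_fixture(cohort: SyntheticCohort, directory) -> dict[str, Path]:
    """Serialize a cohort to ``patients.csv``, ``prescriptions.csv``,
    ``notes.jsonl`` and ``ground_truth.json``; round-trips losslessly through
    the package's readers."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "patients": directory / "patients.csv",
        "prescriptions": directory / "prescriptions.csv",
        "notes": directory / "notes.jsonl",
        "ground_truth": directory / "ground_truth.json",
    }
    cohort.patients.to_csv(paths["patients"], index=False)
    rx = cohort.prescriptions.copy()
    rx["start_date"] = rx["start_date"].dt.strftime("%Y-%m-%d")
    rx["end_date"] = rx["end_date"].dt.strftime("%Y-%m-%d")
    rx["ambiguous"] = rx["ambiguous"].map({True: "true", False: "false"})
    rx.to_csv(paths["prescriptions"], index=False)
    with open(paths["notes"], "w") as fh:
        for row in cohort.notes.itertuples(index=False):
            fh.write(
                json.dumps(
                    {
                        "patient_id": row.patient_id,
                        "date": row.date.strftime("%Y-%m-%d"),
                        "author_category": row.author_category,
                        "text": row.text,
                    }
                )
                + "\n"
            )
    with open(paths["ground_truth"], "w") as fh:
        json.dump(cohort.ground_truth.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
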
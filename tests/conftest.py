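import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from dosewords import GeneratorConfig, generate_cohort, load_ae_dictionary, load_conversion_tables

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def tables():
    return load_conversion_tables()


@pytest.fixture(scope="session")
def ae_dictionary():
    return load_ae_dictionary()


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic cohort shared by read-only tests."""
    return generate_cohort(GeneratorConfig(n_patients=60, seed=11))


@pytest.fixture(scope="session")
def tiny_cohort():
    """A very small cohort for round-trip / CLI tests."""
    return generate_cohort(GeneratorConfig(n_patients=10, seed=3))


def make_prescriptions(rows):
    """Build a prescriptions frame from (pid, drug, dose, start, end, ambiguous)."""
    df = pd.DataFrame(
        rows,
        columns=["patient_id", "drug", "daily_dose_mg", "start_date", "end_date", "ambiguous"],
    )
    df["start_date"] = pd.to_datetime(df["start_date"])
    df["end_date"] = pd.to_datetime(df["end_date"])
    return df


def make_notes(rows):
    """Build a notes frame from (pid, date, category, text)."""
    df = pd.DataFrame(rows, columns=["patient_id", "date", "author_category", "text"])
    df["date"] = pd.to_datetime(df["date"])
    return df
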
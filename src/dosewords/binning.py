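"""Dose binning and the dose / note-length association summary.

Daily equivalent doses are binned into fixed-width intervals starting at 0,
lower-open and upper-closed: bin ``k`` is ``((k-1)*w, k*w]``. Default widths
are 0.5 DDD, 5 mg olanzapine-equivalent, 100 mg chlorpromazine-equivalent.

For every bin, each member patient contributes the arithmetic mean of their
daily word counts over exactly the treatment days whose dose fell in that
bin (a patient may therefore appear in several bins); the bin statistic is
the median of these per-patient means. Bins with fewer than ``min_patients``
members are dropped (100 for the note-length analysis, 10 as the floor for
every analysis). The association is summarized as the Spearman rank
correlation between bin index and bin median.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError

DEFAULT_WIDTHS = {"ddd": 0.5, "olanzapine_eq": 5.0, "chlorpromazine_eq": 100.0}

#: Bin-membership floors: the note-length analysis drops bins with <100
#: patients; bins with <10 patients are dropped from every analysis.
MIN_PATIENTS_NOTE_LENGTH = 100
MIN_PATIENTS_ANY = 10


@dataclass(frozen=True)
class BinningScheme:
    method: str
    width: float

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise ValueError(f"bin width must be positive, got {self.width}")

    def interval(self, index: int) -> tuple[float, float]:
        """(lower, upper] bounds of bin ``index`` (1-based)."""
        return ((index - 1) * self.width, index * self.width)


def default_scheme(method: str) -> BinningScheme:
    if method not in DEFAULT_WIDTHS:
        raise ValueError(f"no default bin width for method {method!r}")
    return BinningScheme(method=method, width=DEFAULT_WIDTHS[method])


@dataclass(frozen=True)
class DoseBin:
    method: str
    subset: str
    index: int
    lower: float
    upper: float
    patient_means: Mapping[str, float]
    median_words: float

    @property
    def n_patients(self) -> int:
        return len(self.patient_means)


def assign_bin(dose: float, scheme: BinningScheme) -> int:
    """Smallest ``k`` with ``dose <= k * width``, i.e. the (lower-open,
    upper-closed] interval containing ``dose``. Nonpositive doses have no bin."""
    if not dose > 0:
        raise ValueError(f"dose must be positive to be binned, got {dose}")
    return int(math.ceil(dose / scheme.width))


def _day_table(
    exposures: pd.DataFrame, daily_counts: pd.DataFrame, scheme: BinningScheme
) -> pd.DataFrame:
    """Convertible positive-dose treatment days joined with word counts.

    Treatment days without notes get ``words = 0``; notes on non-treatment
    days never enter (the join is driven by the exposure side).
    """
    days = exposures.loc[
        exposures["convertible"] & (exposures["equivalent_dose"] > 0),
        ["patient_id", "date", "equivalent_dose"],
    ].copy()
    days = days.merge(daily_counts, on=["patient_id", "date"], how="left")
    days["words"] = days["words"].fillna(0).astype(float)
    days["bin"] = np.ceil(days["equivalent_dose"] / scheme.width).astype(int)
    return days


def patient_bin_mean(
    exposures: pd.DataFrame,
    daily_counts: pd.DataFrame,
    patient_id: str,
    bin_index: int,
    scheme: BinningScheme,
) -> float:
    """One patient's mean daily words over their treatment days in one bin."""
    days = _day_table(exposures, daily_counts, scheme)
    sel = days[(days["patient_id"] == patient_id) & (days["bin"] == bin_index)]
    if sel.empty:
        raise InsufficientDataError(
            f"patient {patient_id!r} has no treatment day in bin {bin_index}"
        )
    return float(sel["words"].mean())


def aggregate_bins(
    exposures: pd.DataFrame,
    daily_counts: pd.DataFrame,
    scheme: BinningScheme,
    min_patients: int,
    subset: str = "all",
) -> list[DoseBin]:
    """Per-patient means and medians for every bin meeting the patient floor.

    ``daily_counts`` must already reflect the desired author subset; the
    ``subset`` argument only labels the result.
    """
    if min_patients < 1:
        raise ValueError("min_patients must be >= 1")
    days = _day_table(exposures, daily_counts, scheme)
    if days.empty:
        warnings.warn("no convertible positive-dose treatment days; empty bin set")
        return []
    means = days.groupby(["bin", "patient_id"], sort=True)["words"].mean()
    bins: list[DoseBin] = []
    for index, per_patient in means.groupby(level="bin"):
        if len(per_patient) < min_patients:
            continue
        lower, upper = scheme.interval(int(index))
        bins.append(
            DoseBin(
                method=scheme.method,
                subset=subset,
                index=int(index),
                lower=lower,
                upper=upper,
                patient_means=dict(per_patient.droplevel("bin")),
                median_words=float(per_patient.median()),
            )
        )
    return bins


def association_summary(bins: list[DoseBin]) -> dict:
    """Spearman rank correlation of (bin index, bin median) and its sign.

    Constant medians are a genuine "no association" outcome and yield rho=0
    rather than scipy's undefined correlation for a zero-variance sequence.
    """
    if len(bins) < 3:
        raise InsufficientDataError(
            f"association summary needs >= 3 surviving bins, got {len(bins)}"
        )
    idx = [b.index for b in bins]
    med = [b.median_words for b in bins]
    if len(set(med)) == 1:
        rho = 0.0
    else:
        rho = float(stats.spearmanr(idx, med).statistic)
    return {"rho": rho, "direction": int(np.sign(rho)), "n_bins": len(bins)}


def bins_frame(bins: list[DoseBin]) -> pd.DataFrame:
    """Flat report table for a list of bins."""
    return pd.DataFrame(
        [
            {
                "method": b.method,
                "subset": b.subset,
                "bin": b.index,
                "lower": b.lower,
                "upper": b.upper,
                "n_patients": b.n_patients,
                "median_words": b.median_words,
            }
            for b in bins
        ],
        columns=["method", "subset", "bin", "lower", "upper", "n_patients", "median_words"],
    )
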
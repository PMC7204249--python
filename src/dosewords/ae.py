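"""Adverse-event density over sampled treatment days in three dose intervals.

The dose axis from 0 up to the upper edge of the highest bin that kept at
least 10 patients is split into three equal-width, contiguous intervals
(low / mid / high), each a union of whole bins; the span is rounded up to a
multiple of three bin widths so the split is exact. Within each interval a
fixed number of treatment days (125 by default) is sampled uniformly without
replacement — days, not patients, so one patient may contribute several
days. All notes from all staff categories on the sampled days are pooled and
the rate is total adverse-event mentions divided by total words (a pooled
ratio, not a mean of per-day ratios).

Adverse-event mentions are whole whitespace tokens whose case-folded form is
in a plain-text dictionary. This exact token matcher stands in for manual
chart review; it is exhaustive on synthetic text whose adverse-event tokens
are drawn from the same dictionary, and deliberately does no negation or
context handling.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .binning import DoseBin, BinningScheme
from .errors import ConfigurationError, InsufficientDataError, UndefinedRateError
from .notes import _WORD_RE, count_words

LABELS = ("low", "mid", "high")
DEFAULT_N_DAYS = 125


@dataclass(frozen=True)
class AEInterval:
    method: str
    label: str
    lower: float
    upper: float
    bin_indices: tuple[int, ...]


@dataclass(frozen=True)
class AEIntervalEstimate:
    interval: AEInterval
    sampled_days: pd.DataFrame  # columns patient_id, date
    ae_count: int
    word_count: int

    @property
    def rate(self) -> float:
        return self.ae_count / self.word_count


def load_ae_dictionary(path=None) -> frozenset[str]:
    """Case-folded AE term set from a one-term-per-line file ('#' comments)."""
    if path is None:
        text = resources.files("dosewords.data").joinpath("ae_terms.txt").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    terms = frozenset(
        line.strip().casefold()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )
    if not terms:
        raise ConfigurationError("adverse-event dictionary is empty")
    return terms


def define_ae_intervals(bins: list[DoseBin], scheme: BinningScheme) -> tuple[AEInterval, ...]:
    """Three equal-width intervals over the surviving-bin dose span.

    ``bins`` must already be filtered to the >=10-patient floor; the span
    (0, k_max * width] is rounded up to a whole multiple of three bins and
    split into thirds.
    """
    if not bins:
        raise InsufficientDataError("no surviving bins to build dose intervals from")
    k_max = max(b.index for b in bins)
    if k_max < 3:
        raise InsufficientDataError(
            f"surviving bins span {k_max} bin-width(s); need at least 3"
        )
    k_total = 3 * math.ceil(k_max / 3)
    per = k_total // 3
    out = []
    for i, label in enumerate(LABELS):
        lo_bin, hi_bin = i * per + 1, (i + 1) * per
        out.append(
            AEInterval(
                method=scheme.method,
                label=label,
                lower=(lo_bin - 1) * scheme.width,
                upper=hi_bin * scheme.width,
                bin_indices=tuple(range(lo_bin, hi_bin + 1)),
            )
        )
    return tuple(out)


def sample_treatment_days(
    interval: AEInterval,
    exposures: pd.DataFrame,
    n: int = DEFAULT_N_DAYS,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Uniform sample (without replacement) of treatment days in the interval.

    Qualifying days are convertible treatment days with
    ``lower < dose <= upper``. If fewer than ``n`` qualify, all are returned
    with a warning. The qualifying set is sorted before sampling so the draw
    depends only on the seed, not on input row order.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    ok = exposures[
        exposures["convertible"]
        & (exposures["equivalent_dose"] > interval.lower)
        & (exposures["equivalent_dose"] <= interval.upper)
    ][["patient_id", "date"]].sort_values(["patient_id", "date"]).reset_index(drop=True)
    if ok.empty:
        raise InsufficientDataError(
            f"no treatment days fall in interval {interval.label} "
            f"({interval.lower}, {interval.upper}]"
        )
    if len(ok) <= n:
        if len(ok) < n:
            warnings.warn(
                f"interval {interval.label}: only {len(ok)} qualifying days, "
                f"requested {n}; using all"
            )
        return ok
    pick = rng.choice(len(ok), size=n, replace=False)
    return ok.iloc[np.sort(pick)].reset_index(drop=True)


def count_ae_mentions(text: str, dictionary: frozenset[str]) -> int:
    """Whitespace tokens of ``text`` whose case-folded form is a dictionary term."""
    if not dictionary:
        raise ConfigurationError("adverse-event dictionary is empty")
    return sum(tok.casefold() in dictionary for tok in _WORD_RE.findall(text))


def estimate_rate(
    interval: AEInterval,
    sampled_days: pd.DataFrame,
    notes: pd.DataFrame,
    dictionary: frozenset[str],
    word_counts: pd.Series | None = None,
) -> AEIntervalEstimate:
    """Pooled AE-per-word rate over all notes (every staff category) on the
    sampled days. ``word_counts`` may supply precomputed per-note counts
    aligned with ``notes.index``."""
    if sampled_days.empty:
        raise InsufficientDataError("no sampled days to estimate a rate from")
    if not dictionary:
        raise ConfigurationError("adverse-event dictionary is empty")
    keys = sampled_days[["patient_id", "date"]]
    picked = notes.reset_index().merge(keys, on=["patient_id", "date"])
    ae = int(sum(count_ae_mentions(t, dictionary) for t in picked["text"]))
    if picked.empty:
        words = 0
    elif word_counts is not None:
        words = int(word_counts[picked["index"]].sum())
    else:
        words = int(picked["text"].str.count(_WORD_RE).sum())
    if words == 0:
        raise UndefinedRateError(
            f"sampled days in interval {interval.label} carry zero words"
        )
    return AEIntervalEstimate(
        interval=interval, sampled_days=sampled_days, ae_count=ae, word_count=words
    )


def rates_frame(estimates: list[AEIntervalEstimate]) -> pd.DataFrame:
    """Flat report table for interval estimates."""
    return pd.DataFrame(
        [
            {
                "method": e.interval.method,
                "interval": e.interval.label,
                "lower": e.interval.lower,
                "upper": e.interval.upper,
                "n_days": len(e.sampled_days),
                "ae_count": e.ae_count,
                "word_count": e.word_count,
                "rate": e.rate,
            }
            for e in estimates
        ],
        columns=[
            "method", "interval", "lower", "upper",
            "n_days", "ae_count", "word_count", "rate",
        ],
    )
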
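"""Word counting and per-day aggregation of clinical notes.

A "word" is a maximal run of non-whitespace characters, where whitespace is
the POSIX set {space, tab, newline, carriage return, form feed, vertical tab}
— i.e. exactly what ``wc -w`` counts. Counting never normalizes or mutates
the note text; a token like ``"agitated."`` is one word.

Daily counts are formed per patient and calendar day for one of three
author subsets: ``all`` (every staff category), ``physicians``, ``nursing``.
A treatment day with no matching notes has a count of zero, not a missing
value.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

from .errors import ValidationError

#: Closed set of note-author staff categories.
CATEGORIES = (
    "physician",
    "nursing",
    "physical_therapist",
    "occupational_therapist",
    "psychologist",
    "social_worker",
    "secretary",
)

#: Analysis subsets -> author categories included (None = no filter).
SUBSETS: dict[str, tuple[str, ...] | None] = {
    "all": None,
    "physicians": ("physician",),
    "nursing": ("nursing",),
}

# wc -w word pattern: maximal runs of characters outside the POSIX space set.
_WORD_RE = re.compile(r"[^ \t\n\r\f\v]+")


@dataclass(frozen=True)
class DailyNoteCount:
    patient_id: str
    date: pd.Timestamp
    subset: str
    words: int


def count_words(text: str) -> int:
    """Number of words in ``text`` under wc -w semantics."""
    return len(_WORD_RE.findall(text))


def _subset_mask(notes: pd.DataFrame, subset: str) -> pd.Series:
    if subset not in SUBSETS:
        raise ValidationError(f"unknown subset {subset!r}; expected one of {sorted(SUBSETS)}")
    cats = SUBSETS[subset]
    if cats is None:
        return pd.Series(True, index=notes.index)
    return notes["author_category"].isin(cats)


def note_word_counts(notes: pd.DataFrame) -> pd.Series:
    """wc -w count of every note's text, aligned with ``notes.index``.

    Computing this once and passing it to :func:`daily_word_counts` avoids
    rescanning the corpus for every subset.
    """
    return notes["text"].str.count(_WORD_RE)


def daily_word_counts(
    notes: pd.DataFrame, subset: str = "all", word_counts: pd.Series | None = None
) -> pd.DataFrame:
    """Per patient-day word totals for one subset (vectorized).

    Returns columns ``patient_id, date, words``. Only patient-days with at
    least one matching note appear; downstream joins against treatment days
    fill absent days with zero. ``word_counts`` may supply precomputed
    :func:`note_word_counts` output.
    """
    mask = _subset_mask(notes, subset)
    sub = notes[mask]
    if sub.empty:
        return pd.DataFrame(columns=["patient_id", "date", "words"])
    words = note_word_counts(sub) if word_counts is None else word_counts[mask]
    frame = pd.DataFrame(
        {"patient_id": sub["patient_id"], "date": sub["date"], "words": words}
    )
    out = frame.groupby(["patient_id", "date"], sort=True)["words"].sum().reset_index()
    return out


def daily_word_count(
    notes: pd.DataFrame, patient_id: str, date, subset: str = "all"
) -> DailyNoteCount:
    """Word total for a single patient-day and subset (zero if no notes)."""
    date = pd.Timestamp(date)
    mask = (
        _subset_mask(notes, subset)
        & (notes["patient_id"] == patient_id)
        & (notes["date"] == date)
    )
    total = int(sum(count_words(t) for t in notes.loc[mask, "text"]))
    return DailyNoteCount(patient_id=patient_id, date=date, subset=subset, words=total)
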
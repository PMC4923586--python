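"""Demographic inference: name-based classifiers and writing-level grading.

Gender is inferred from the author's first name and ethnicity from the
surname by lookup in frequency tables (the SSA baby-name and Census
surname exports convert to the expected layout with a one-line awk/pandas
reshape). A name yields a label only when that label's share among the
name's bearers reaches a dominance threshold — 0.95 for gender, 0.80 for
ethnicity — favoring precision over coverage; anything less dominant stays
unknown rather than guessed.

Writing level is a clamped Flesch-Kincaid grade:

    FKGL = 0.39 * (words / sentences) + 11.8 * (syllables / words) - 15.59

clamped to [0, 16] so short informal posts (which drive the raw formula
negative) land in the lowest bin and jargon-dense posts cannot escape the
top bin. Sentences come from terminal punctuation (minimum one), syllables
from a vowel-group count with a silent-e correction (minimum one per
word). A user's writing level is the mean of their per-post grades, so
prolific users do not distort the formula's inputs.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Mapping

from .corpus import GENDERS, ETHNICITIES, bin_writing_level

log = logging.getLogger(__name__)

GENDER_DOMINANCE = 0.95
ETHNICITY_DOMINANCE = 0.80
GRADE_MIN, GRADE_MAX = 0.0, 16.0

SHARE_TOL = 1e-6


class NameTableError(ValueError):
    pass


@dataclass(frozen=True)
class NameTable:
    """name (lowercase) -> label -> share of bearers; shares sum to 1."""

    labels: tuple[str, ...]
    shares: Mapping[str, Mapping[str, float]]

    def __post_init__(self) -> None:
        for name, dist in self.shares.items():
            if name != name.lower():
                raise NameTableError(f"name {name!r} must be lowercase")
            total = sum(dist.values())
            if abs(total - 1.0) > SHARE_TOL:
                raise NameTableError(
                    f"name {name!r}: shares sum to {total}, expected 1")
            for label in dist:
                if label not in self.labels:
                    raise NameTableError(f"name {name!r}: unknown label {label!r}")

    def classify(self, name: str | None, dominance: float) -> str | None:
        """The label holding >= *dominance* of the name's share, else None."""
        if not name:
            return None
        dist = self.shares.get(name.strip().lower())
        if not dist:
            return None
        label, share = max(dist.items(), key=lambda kv: (kv[1], kv[0]))
        return label if share >= dominance else None


def load_name_table(path, labels: tuple[str, ...]) -> NameTable:
    """Load ``name <TAB> label <TAB> share`` rows into a NameTable."""
    shares: dict[str, dict[str, float]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise NameTableError(f"{path}:{lineno}: expected 3 tab fields")
            name, label, share = fields[0].strip().lower(), fields[1].strip(), fields[2]
            try:
                value = float(share)
            except ValueError:
                raise NameTableError(f"{path}:{lineno}: bad share {share!r}") from None
            shares.setdefault(name, {})[label] = value
    if not shares:
        raise NameTableError(f"{path}: empty name table")
    return NameTable(labels=labels, shares=shares)


def classify_gender(first_name: str | None, table: NameTable,
                    dominance: float = GENDER_DOMINANCE) -> str | None:
    """male/female from the first name, or None below the dominance bar."""
    label = table.classify(first_name, dominance)
    if label is not None and label not in GENDERS:
        raise NameTableError(f"gender table produced label {label!r}")
    return label


def classify_ethnicity(last_name: str | None, table: NameTable,
                       dominance: float = ETHNICITY_DOMINANCE) -> str | None:
    """white/black/asian/hispanic from the surname, or None."""
    label = table.classify(last_name, dominance)
    if label is not None and label not in ETHNICITIES:
        raise NameTableError(f"ethnicity table produced label {label!r}")
    return label


# -- writing level -------------------------------------------------------------

_SENTENCE_END = re.compile(r"[.!?]+")
_WORD = re.compile(r"[A-Za-z][A-Za-z'-]*")
_VOWEL_GROUP = re.compile(r"[aeiouy]+")


def count_syllables(word: str) -> int:
    """Vowel-group syllable heuristic with a silent-e correction, minimum 1."""
    w = word.lower().strip("'-")
    if not w:
        return 1
    groups = _VOWEL_GROUP.findall(w)
    n = len(groups)
    # terminal silent e: "make" -> 1, but keep "le" syllables ("table" -> 2)
    if w.endswith("e") and not w.endswith(("le", "ee", "ye")) and n > 1:
        n -= 1
    return max(n, 1)


def grade_text(text: str) -> float | None:
    """Clamped Flesch-Kincaid grade of one post; None when it has no words."""
    words = _WORD.findall(text)
    if not words:
        return None
    sentences = max(len(_SENTENCE_END.findall(text)), 1)
    syllables = sum(count_syllables(w) for w in words)
    grade = 0.39 * (len(words) / sentences) + 11.8 * (syllables / len(words)) - 15.59
    return min(max(grade, GRADE_MIN), GRADE_MAX)


@dataclass(frozen=True)
class WritingLevel:
    grade: float
    n_posts_used: int

    @property
    def bin(self) -> str:
        return bin_writing_level(self.grade)


def user_writing_level(texts) -> WritingLevel | None:
    """Mean of per-post grades for one user; None if nothing is gradeable."""
    grades = [g for g in (grade_text(t) for t in texts) if g is not None]
    if not grades:
        return None
    return WritingLevel(grade=sum(grades) / len(grades), n_posts_used=len(grades))
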
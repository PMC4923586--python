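"""Dictionary-based medical-concept annotation.

A functional stand-in for MetaMap: posts are mapped to concepts from a
user-supplied dictionary (any UMLS-derived TSV the user is licensed for
drops in) by the same greedy longest-match scan used for sentiment phrases.
Synonyms are normalized with the identical pipeline as post text, so
"heart attacks" in a post matches the synonym "heart attack".

Consumer posts trip generic dictionary entries (the lone letter "i" mapping
to an immunologic-factor concept is the classic case); instead of a manual
cleanup pass, misclassified (surface, concept) pairs live in an editable
blacklist file, and a frequency report supports reviewing candidates for
it. Analysis keeps only the Disorders and Chemicals & Drugs semantic groups
by default; the other thirteen groups are annotated internally but filtered
from output.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .textproc import Token, normalize

log = logging.getLogger(__name__)

#: The 15 coarse UMLS semantic groups.
SEMANTIC_GROUPS = (
    "Activities & Behaviors", "Anatomy", "Chemicals & Drugs",
    "Concepts & Ideas", "Devices", "Disorders", "Genes & Molecular Sequences",
    "Geographic Areas", "Living Beings", "Objects", "Occupations",
    "Organizations", "Phenomena", "Physiology", "Procedures",
)

#: Accepted shorthand for group labels in dictionaries and configs.
GROUP_ALIASES = {
    "drugs": "Chemicals & Drugs",
    "chemicals & drugs": "Chemicals & Drugs",
    "chem": "Chemicals & Drugs",
    "disorders": "Disorders",
    "diso": "Disorders",
}

DEFAULT_GROUPS_KEPT = frozenset({"Disorders", "Chemicals & Drugs"})


class DictionaryError(ValueError):
    pass


def canonical_group(label: str) -> str:
    if label in SEMANTIC_GROUPS:
        return label
    alias = GROUP_ALIASES.get(label.strip().lower())
    if alias is None:
        raise DictionaryError(f"unknown semantic group {label!r}")
    return alias


@dataclass(frozen=True)
class ConceptEntry:
    concept_id: str
    preferred_name: str
    synonyms: tuple[str, ...]          # surface phrases as listed
    semantic_group: str

    def __post_init__(self) -> None:
        if not self.synonyms:
            raise DictionaryError(f"{self.concept_id}: needs >=1 synonym")
        if self.semantic_group not in SEMANTIC_GROUPS:
            raise DictionaryError(
                f"{self.concept_id}: unknown semantic group {self.semantic_group!r}")


class ConceptDictionary:
    """Stem-sequence index over concept synonyms for longest-match lookup."""

    def __init__(self, entries: Iterable[ConceptEntry]):
        self.entries: dict[str, ConceptEntry] = {}
        self.by_stems: dict[tuple[str, ...], ConceptEntry] = {}
        for e in entries:
            if e.concept_id in self.entries:
                prev = self.entries[e.concept_id]
                e = ConceptEntry(e.concept_id, prev.preferred_name,
                                 tuple(dict.fromkeys(prev.synonyms + e.synonyms)),
                                 prev.semantic_group)
            self.entries[e.concept_id] = e
        if not self.entries:
            raise DictionaryError("empty concept dictionary")
        for e in self.entries.values():
            for syn in e.synonyms:
                stems = tuple(t.stem for t in normalize(syn))
                if not stems:
                    continue
                if stems in self.by_stems and self.by_stems[stems].concept_id != e.concept_id:
                    log.warning("synonym %r maps to both %s and %s; keeping first",
                                syn, self.by_stems[stems].concept_id, e.concept_id)
                    continue
                self.by_stems.setdefault(stems, e)
        self.max_len = max(len(s) for s in self.by_stems)


def load_dictionary(path) -> ConceptDictionary:
    """Load ``concept_id <TAB> preferred_name <TAB> syn1|syn2|... <TAB> group``."""
    entries = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise DictionaryError(f"{path}:{lineno}: expected 4 tab fields")
            cid, name, syns, group = fields[:4]
            try:
                group = canonical_group(group)
            except DictionaryError as exc:
                raise DictionaryError(f"{path}:{lineno}: {exc}") from None
            synonyms = tuple(s.strip() for s in syns.split("|") if s.strip())
            entries.append(ConceptEntry(cid.strip(), name.strip(), synonyms, group))
    if not entries:
        raise DictionaryError(f"{path}: empty concept dictionary")
    return ConceptDictionary(entries)


Blacklist = frozenset  # of (surface_lowercase, concept_id) pairs


def load_blacklist(path) -> frozenset[tuple[str, str]]:
    """Load ``surface <TAB> concept_id`` pairs to suppress."""
    pairs = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise DictionaryError(f"{path}:{lineno}: expected 2 tab fields")
            pairs.add((fields[0].strip().lower(), fields[1].strip()))
    return frozenset(pairs)


@dataclass(frozen=True)
class ConceptAnnotation:
    concept_id: str
    surface: str               # matched text as written in the post
    semantic_group: str


def annotate_tokens(tokens: Sequence[Token], dictionary: ConceptDictionary,
                    blacklist: frozenset[tuple[str, str]] = frozenset(),
                    groups_kept: frozenset[str] | None = DEFAULT_GROUPS_KEPT,
                    ) -> list[ConceptAnnotation]:
    """Greedy longest-match concept tagging over normalized tokens.

    Blacklisted (surface, concept) pairs are dropped; concepts outside
    *groups_kept* are matched (consuming their tokens) but excluded from the
    result. Pass ``groups_kept=None`` to keep all 15 groups.
    """
    stems = [t.stem for t in tokens]
    out: list[ConceptAnnotation] = []
    i = 0
    n = len(stems)
    while i < n:
        hit = None
        for length in range(min(dictionary.max_len, n - i), 0, -1):
            entry = dictionary.by_stems.get(tuple(stems[i:i + length]))
            if entry is not None:
                hit = (entry, length)
                break
        if hit is None:
            i += 1
            continue
        entry, length = hit
        surface = " ".join(t.surface for t in tokens[i:i + length])
        i += length
        if (surface.lower(), entry.concept_id) in blacklist:
            continue
        if groups_kept is not None and entry.semantic_group not in groups_kept:
            continue
        out.append(ConceptAnnotation(entry.concept_id, surface, entry.semantic_group))
    return out


def annotate(text: str, dictionary: ConceptDictionary,
             blacklist: frozenset[tuple[str, str]] = frozenset(),
             groups_kept: frozenset[str] | None = DEFAULT_GROUPS_KEPT,
             stopwords=None) -> list[ConceptAnnotation]:
    """Annotate one post's text (see :func:`annotate_tokens`)."""
    return annotate_tokens(normalize(text, stopwords), dictionary,
                           blacklist, groups_kept)


def concept_frequency_report(texts: Iterable[str], dictionary: ConceptDictionary,
                             blacklist: frozenset[tuple[str, str]] = frozenset(),
                             ) -> list[tuple[str, str, str, int]]:
    """(concept_id, preferred_name, surface, count) rows, most frequent first.

    The reviewable analogue of ordering MetaMap output by frequency to spot
    misclassifications worth blacklisting; run with an empty blacklist to
    audit everything, all 15 semantic groups included.
    """
    counts: Counter[tuple[str, str]] = Counter()
    for text in texts:
        for ann in annotate(text, dictionary, blacklist, groups_kept=None):
            counts[(ann.concept_id, ann.surface.lower())] += 1
    rows = [(cid, dictionary.entries[cid].preferred_name, surface, n)
            for (cid, surface), n in counts.items()]
    rows.sort(key=lambda r: (-r[3], r[0], r[2]))
    return rows
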
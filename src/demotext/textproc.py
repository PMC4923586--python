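"""Tokenization, stop-word flagging, stemming, and pluggable POS tagging.

``normalize`` is the single entry point every other stage uses, so that
posts, lexicon phrases, and dictionary synonyms are all normalized the same
way. Tokens are split on whitespace/punctuation; hashtags keep their ``#``
and are exempt from stemming (they are surface identifiers, not English
words). Stop words are *flagged*, not deleted — each downstream stage
decides whether to keep them (sentiment matching does; distinctive-term
counting does not).

Part-of-speech tags are coarse (noun/verb/adj/adv/other) and only serve to
select the matching sentiment-lexicon sense; the default tagger is a small
closed-class + suffix rule tagger, and any external tagger can be plugged in
through the ``tagger`` callable (surfaces in, same-length coarse tags out).
Unknown words tag as "other", which downstream falls back to a
POS-insensitive lexicon lookup, so a weak tagger degrades accuracy
gracefully rather than dropping matches.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from importlib import resources
from typing import Callable, Iterable, Sequence

from .porter import stem

COARSE_TAGS = ("noun", "verb", "adj", "adv", "other")

# Hashtags first so '#flu' is one token; then word-like runs (letters, digits,
# internal apostrophes/hyphens), which keeps drug names like 'b12' intact.
_TOKEN_RE = re.compile(r"#\w[\w'-]*|\w+(?:['-]\w+)*")


@dataclass(frozen=True)
class Token:
    surface: str
    stem: str
    pos: str | None = None
    is_stopword: bool = False


TokenSequence = tuple[Token, ...]
Tagger = Callable[[Sequence[str]], Sequence[str]]


def load_stopwords(path=None) -> frozenset[str]:
    """Load a stop-word file (one word per line, '#' comments)."""
    if path is None:
        text = (resources.files("demotext.data") / "stopwords.txt").read_text("utf-8")
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    words = set()
    for line in text.splitlines():
        line = line.strip().lower()
        if line and not line.startswith("#"):
            words.add(line)
    return frozenset(words)


_DEFAULT_STOPWORDS = None


def default_stopwords() -> frozenset[str]:
    global _DEFAULT_STOPWORDS
    if _DEFAULT_STOPWORDS is None:
        _DEFAULT_STOPWORDS = load_stopwords()
    return _DEFAULT_STOPWORDS


def normalize(text: str, stopwords: frozenset[str] | None = None) -> TokenSequence:
    """Tokenize and stem *text*; stop words flagged, order preserved."""
    if stopwords is None:
        stopwords = default_stopwords()
    tokens = []
    for match in _TOKEN_RE.finditer(text):
        surface = match.group(0)
        lower = surface.lower()
        if surface.startswith("#"):
            token_stem = lower  # hashtags are identifiers; no stemming
        else:
            token_stem = stem(lower)
        if not token_stem:
            continue
        tokens.append(Token(surface=surface, stem=token_stem,
                            is_stopword=lower in stopwords))
    return tuple(tokens)


# -- default rule/suffix tagger ------------------------------------------------

_ADJ = frozenset("""
good bad great big small new old young high low long short hot cold happy sad
angry sick ill healthy chronic severe mild acute painful tired positive
negative afraid anxious strong weak best worst better worse nice fine
""".split())
_ADV = frozenset("""
very really quite too also just never always often sometimes again soon now
here there well almost already still yet maybe perhaps
""".split())
_VERB = frozenset("""
be is are was were been being have has had do does did go goes went take takes
took taking get gets got feel feels felt make makes made think thinks thought
say says said know knows knew see sees saw want wants need needs help helps
hurt hurts ache aches try tries tried
""".split())
_ADJ_SUFFIXES = ("ous", "ful", "ive", "able", "ible", "al", "ic", "ical",
                 "less", "ish", "ary")
_VERB_SUFFIXES = ("ize", "ise", "ate", "ify")
_NOUN_SUFFIXES = ("tion", "sion", "ment", "ness", "ity", "ance", "ence",
                  "ist", "ism", "itis", "osis", "emia", "pathy", "algia")


def rule_suffix_tagger(surfaces: Sequence[str]) -> list[str]:
    """Coarse tagger: closed-class lists, then suffix rules, else 'other'."""
    tags = []
    for surface in surfaces:
        word = surface.lower()
        if not word.isalpha() or word.startswith("#"):
            tags.append("other")
        elif word in _ADJ:
            tags.append("adj")
        elif word in _ADV:
            tags.append("adv")
        elif word in _VERB:
            tags.append("verb")
        elif word.endswith("ly") and len(word) > 4:
            tags.append("adv")
        elif word.endswith(_VERB_SUFFIXES) and len(word) > 5:
            tags.append("verb")
        elif word.endswith(_ADJ_SUFFIXES) and len(word) > 5:
            tags.append("adj")
        elif word.endswith(_NOUN_SUFFIXES) and len(word) > 5:
            tags.append("noun")
        elif word.endswith("ing") or word.endswith("ed"):
            tags.append("verb")
        else:
            tags.append("other")
    return tags


def pos_tag(tokens: Iterable[Token], tagger: Tagger | None = None) -> TokenSequence:
    """Fill the ``pos`` field of every token using *tagger* (default bundled)."""
    tokens = tuple(tokens)
    if tagger is None:
        tagger = rule_suffix_tagger
    tags = list(tagger([t.surface for t in tokens]))
    if len(tags) != len(tokens):
        raise ValueError("tagger returned a different number of tags than tokens")
    for tag in tags:
        if tag not in COARSE_TAGS:
            raise ValueError(f"tagger produced unknown coarse tag {tag!r}")
    return tuple(replace(t, pos=tag) for t, tag in zip(tokens, tags))
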
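"""Health-keyword relevance filter for general social-network posts.

General social networks carry mostly non-health chatter, so posts from
``social_network`` sources are kept only if they contain at least one
phrase from a configurable health-keyword list (drug names, disorders,
hashtags, pharma companies, insurers). Matching is case-insensitive on
token boundaries — the keyword "aids" matches the token "AIDS" but never
the inside of "listening" — and multi-word keywords match as adjacent token
sequences of surface forms (no stemming: drug names are not English
morphology). Drug-review and forum sources are already health-scoped and
pass through unfiltered.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .corpus import Post

log = logging.getLogger(__name__)

KEYWORD_CATEGORIES = ("drug", "hashtag", "disorder", "pharma", "insurance")

_WORD_RE = re.compile(r"#\w[\w'-]*|\w+(?:['-]\w+)*")


class KeywordError(ValueError):
    pass


@dataclass(frozen=True)
class KeywordList:
    """Lowercased keyword phrases with their category."""

    entries: tuple[tuple[str, str], ...]   # (phrase, category)

    def __post_init__(self) -> None:
        seen = set()
        for phrase, category in self.entries:
            if phrase != phrase.lower():
                raise KeywordError(f"keyword {phrase!r} must be lowercase")
            if category not in KEYWORD_CATEGORIES:
                raise KeywordError(f"keyword {phrase!r}: bad category {category!r}")
            if category == "hashtag" and not phrase.startswith("#"):
                raise KeywordError(f"hashtag keyword {phrase!r} must start with '#'")
            if phrase in seen:
                raise KeywordError(f"duplicate keyword {phrase!r}")
            seen.add(phrase)

    @property
    def phrases(self) -> list[str]:
        return [p for p, _ in self.entries]


def load_keywords(path) -> KeywordList:
    """Load ``phrase <TAB> category`` rows ('#' comments allowed)."""
    entries = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or (line.lstrip().startswith("#") and "\t" not in line):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise KeywordError(f"{path}:{lineno}: expected 'phrase<TAB>category'")
            entries.append((fields[0].strip().lower(), fields[1].strip().lower()))
    if not entries:
        raise KeywordError(f"{path}: empty keyword list")
    return KeywordList(tuple(entries))


def _tokenize(text: str) -> list[str]:
    return [m.group(0).lower() for m in _WORD_RE.finditer(text)]


def is_relevant(post: Post, keywords: KeywordList) -> tuple[bool, list[str]]:
    """True iff >=1 keyword phrase occurs in the post on token boundaries."""
    if not keywords.entries:
        raise KeywordError("keyword list is empty")
    tokens = _tokenize(post.text)
    if not tokens:
        return False, []
    matched = []
    token_set = set(tokens)
    for phrase, _category in keywords.entries:
        parts = phrase.split()
        if len(parts) == 1:
            if parts[0] in token_set:
                matched.append(phrase)
        else:
            k = len(parts)
            if any(tokens[i:i + k] == parts for i in range(len(tokens) - k + 1)):
                matched.append(phrase)
    return bool(matched), matched


def filter_corpus(posts: Iterable[Post], keywords: KeywordList,
                  filtered_sources: Sequence[str] = ("social_network",),
                  ) -> tuple[list[Post], Counter]:
    """Keep relevant posts; sources outside *filtered_sources* pass through.

    Returns the kept posts and per-keyword match counts (number of kept
    filtered-source posts each keyword matched).
    """
    kept: list[Post] = []
    counts: Counter = Counter()
    n_filtered_source = 0
    for post in posts:
        if post.source not in filtered_sources:
            kept.append(post)
            continue
        n_filtered_source += 1
        relevant, matched = is_relevant(post, keywords)
        if relevant:
            kept.append(post)
            counts.update(matched)
    if n_filtered_source and not counts:
        log.warning("keyword filter matched no posts out of %d", n_filtered_source)
    return kept, counts
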
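"""Sentiment and emotion scoring against SentiWordNet / EmoLex-style lexicons.

Sentiment entries carry a (positive, negative, objective) triple that sums
to one; the objective score is derived at load time from the positive and
negative columns. Posts are mapped to lexicon phrases by a greedy
longest-match scan (at each position the longest matching phrase wins and
the cursor jumps past it), a post's sentiment is the unweighted mean of its
matched triples, and a group's sentiment is the mean over its scored posts.
Emotion flags come from the NRC-style word-emotion lexicon: a post carries
an emotion iff at least one of its words does, and a group's emotion
percentage is the share of scored posts carrying it.

Group-vs-rest significance: a two-sided two-proportion z-test for emotion
percentages and a Welch two-sample t-test for sentiment means, both at
alpha = 0.05 and without multiple-testing correction (an optional
Benjamini-Hochberg column is offered as a clearly separate extension).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest

from .textproc import Token, TokenSequence, normalize, pos_tag

log = logging.getLogger(__name__)

EMOTIONS = ("anger", "fear", "trust", "disgust",
            "anticipation", "surprise", "joy", "sadness")
#: The three emotion pairs reported by default; joy/sadness are computed too.
REPORTED_EMOTIONS = ("anger", "fear", "trust", "disgust", "anticipation", "surprise")

_POS_MAP = {"a": "adj", "s": "adj", "n": "noun", "v": "verb", "r": "adv",
            "adj": "adj", "noun": "noun", "verb": "verb", "adv": "adv",
            "any": "any", "*": "any", "-": "any"}

SUM_TOL = 1e-6


class LexiconError(ValueError):
    pass


@dataclass(frozen=True)
class SentimentEntry:
    stems: tuple[str, ...]
    pos: str  # coarse tag or "any"
    positive: float
    negative: float

    @property
    def objective(self) -> float:
        return 1.0 - self.positive - self.negative


class SentimentLexicon:
    """Phrase-stem -> sentiment triple index supporting longest-match lookup."""

    def __init__(self, entries: Iterable[SentimentEntry]):
        self.by_stems: dict[tuple[str, ...], dict[str, SentimentEntry]] = {}
        n = 0
        for e in entries:
            self.by_stems.setdefault(e.stems, {})[e.pos] = e
            n += 1
        if n == 0:
            raise LexiconError("empty sentiment lexicon")
        # POS-insensitive fallback: mean over this phrase's POS-specific senses.
        for stems, senses in self.by_stems.items():
            if "any" not in senses:
                pos_mean = float(np.mean([e.positive for e in senses.values()]))
                neg_mean = float(np.mean([e.negative for e in senses.values()]))
                senses["any"] = SentimentEntry(stems, "any", pos_mean, neg_mean)
        self.max_len = max(len(s) for s in self.by_stems)
        self.n_entries = n

    def lookup(self, stems: tuple[str, ...], pos: str | None) -> SentimentEntry | None:
        senses = self.by_stems.get(stems)
        if senses is None:
            return None
        if pos in senses:  # POS-matched sense preferred
            return senses[pos]
        return senses["any"]


def load_sentiment_lexicon(path) -> SentimentLexicon:
    """Load a SentiWordNet-style tab-separated lexicon.

    Accepts both the public 6-column layout
    (``POS  ID  PosScore  NegScore  SynsetTerms  Gloss`` with ``term#rank``
    entries and underscores for spaces) and the compact 4-column dialect
    (``POS  term(s)  PosScore  NegScore``). '#'-prefixed lines are comments.
    Duplicate (stems, POS) rows are averaged; the objective score is derived
    as 1 - positive - negative and must be a valid probability.
    """
    acc: dict[tuple[tuple[str, ...], str], list[tuple[float, float]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) >= 6:  # public layout: POS ID Pos Neg Terms Gloss
                pos_field, p_field, n_field, terms = (
                    fields[0], fields[2], fields[3], fields[4])
            elif len(fields) >= 4:
                pos_field, terms, p_field, n_field = fields[:4]
            else:
                raise LexiconError(f"{path}:{lineno}: expected >=4 tab fields")
            pos = _POS_MAP.get(pos_field.strip().lower())
            if pos is None:
                raise LexiconError(f"{path}:{lineno}: unknown POS {pos_field!r}")
            try:
                p, n = float(p_field), float(n_field)
            except ValueError:
                raise LexiconError(f"{path}:{lineno}: non-numeric scores") from None
            if not (0 <= p <= 1 and 0 <= n <= 1) or p + n > 1 + SUM_TOL:
                raise LexiconError(
                    f"{path}:{lineno}: scores ({p}, {n}) do not leave a valid "
                    f"objective share (positive+negative+objective must equal 1)")
            for term in terms.split():
                term = term.rsplit("#", 1)[0] if "#" in term[1:] else term
                phrase = term.replace("_", " ")
                stems = tuple(t.stem for t in normalize(phrase))
                if not stems:
                    continue
                acc.setdefault((stems, pos), []).append((p, n))
    entries = [SentimentEntry(stems, pos,
                              float(np.mean([v[0] for v in vals])),
                              float(np.mean([v[1] for v in vals])))
               for (stems, pos), vals in acc.items()]
    if not entries:
        raise LexiconError(f"{path}: empty sentiment lexicon")
    return SentimentLexicon(entries)


def load_emotion_lexicon(path) -> dict[str, frozenset[str]]:
    """Load an NRC EmoLex-style file: ``word <TAB> emotion <TAB> 0/1``.

    Returns word stem -> set of flagged emotions. Rows for categories
    outside the eight basic emotions (e.g. EmoLex's positive/negative
    columns) are ignored.
    """
    flags: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise LexiconError(f"{path}:{lineno}: expected 3 tab fields")
            word, emotion, value = fields[0].strip(), fields[1].strip().lower(), fields[2].strip()
            if emotion not in EMOTIONS:
                continue
            if value not in ("0", "1"):
                raise LexiconError(f"{path}:{lineno}: flag must be 0 or 1")
            if value == "1":
                toks = normalize(word)
                if toks:
                    flags.setdefault(toks[0].stem, set()).add(emotion)
    if not flags:
        raise LexiconError(f"{path}: no emotion flags loaded")
    return {w: frozenset(e) for w, e in flags.items()}


# -- matching and per-post scoring --------------------------------------------

@dataclass(frozen=True)
class PhraseMatch:
    start: int
    length: int
    entry: SentimentEntry


def match_phrases(tokens: Sequence[Token], lexicon: SentimentLexicon
                  ) -> list[PhraseMatch]:
    """Greedy left-to-right longest-match of *tokens* against the lexicon."""
    stems = [t.stem for t in tokens]
    matches: list[PhraseMatch] = []
    i = 0
    n = len(stems)
    while i < n:
        hit = None
        for length in range(min(lexicon.max_len, n - i), 0, -1):
            entry = lexicon.lookup(tuple(stems[i:i + length]), tokens[i].pos)
            if entry is not None:
                hit = PhraseMatch(i, length, entry)
                break
        if hit is not None:
            matches.append(hit)
            i += hit.length
        else:
            i += 1
    return matches


@dataclass(frozen=True)
class PostSentiment:
    positive: float
    negative: float
    objective: float
    n_matched: int

    @property
    def scored(self) -> bool:
        return self.n_matched > 0


UNSCORED = PostSentiment(0.0, 0.0, 0.0, 0)


@dataclass(frozen=True)
class PostScore:
    sentiment: PostSentiment
    emotions: frozenset[str]


def score_tokens(tokens: TokenSequence, sentiment: SentimentLexicon,
                 emotion: Mapping[str, frozenset[str]]) -> PostScore:
    matches = match_phrases(tokens, sentiment)
    if matches:
        pos = float(np.mean([m.entry.positive for m in matches]))
        neg = float(np.mean([m.entry.negative for m in matches]))
        obj = float(np.mean([m.entry.objective for m in matches]))
        senti = PostSentiment(pos, neg, obj, len(matches))
    else:
        senti = UNSCORED
    flags: set[str] = set()
    for tok in tokens:
        e = emotion.get(tok.stem)
        if e:
            flags |= e
    return PostScore(senti, frozenset(flags))


def score_post(text: str, sentiment: SentimentLexicon,
               emotion: Mapping[str, frozenset[str]],
               tagger=None, stopwords=None) -> PostScore:
    """Normalize, POS-tag, and score one post's text."""
    tokens = pos_tag(normalize(text, stopwords), tagger)
    return score_tokens(tokens, sentiment, emotion)


# -- group aggregation ---------------------------------------------------------

@dataclass(frozen=True)
class EmotionStat:
    percent: float          # 100 * flagged / scored posts
    n_flagged: int
    p_value: float
    significant: bool


@dataclass(frozen=True)
class GroupScore:
    group: str
    n_posts: int            # posts in the group partition
    n_scored: int           # posts with >=1 sentiment match
    positive: float
    negative: float
    objective: float
    sentiment_p: Mapping[str, float] = field(default_factory=dict)
    emotions: Mapping[str, EmotionStat] = field(default_factory=dict)


def _two_proportion_p(x1: int, n1: int, x2: int, n2: int) -> float:
    """Two-sided two-proportion z-test; 1.0 when the test is degenerate."""
    if n1 == 0 or n2 == 0:
        return 1.0
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return 1.0
    _, p = proportions_ztest([x1, x2], [n1, n2], alternative="two-sided")
    return float(p)


def aggregate_groups(scores_by_group: Mapping[str, Sequence[PostScore]],
                     alpha: float = 0.05,
                     emotions: Sequence[str] = EMOTIONS) -> dict[str, GroupScore]:
    """Per-group sentiment means and emotion percentages with group-vs-rest tests.

    Each group is compared against the union of the other groups: Welch
    t-test on per-post sentiment components, two-proportion z-test on each
    emotion's flagged share. Groups with no scored post are omitted (logged).
    """
    per_group: dict[str, dict] = {}
    for group, scores in scores_by_group.items():
        scored = [s for s in scores if s.sentiment.scored]
        if not scored:
            log.warning("group %r has no scored posts; omitted from report", group)
            continue
        per_group[group] = {
            "n_posts": len(scores),
            "triples": np.array([[s.sentiment.positive, s.sentiment.negative,
                                  s.sentiment.objective] for s in scored]),
            "flags": {e: sum(1 for s in scored if e in s.emotions)
                      for e in emotions},
        }

    out: dict[str, GroupScore] = {}
    for group, g in per_group.items():
        rest_triples = [h["triples"] for other, h in per_group.items()
                        if other != group]
        rest = np.vstack(rest_triples) if rest_triples else np.empty((0, 3))
        n_scored = len(g["triples"])
        n_rest = len(rest)
        sentiment_p = {}
        for idx, comp in enumerate(("positive", "negative", "objective")):
            a, b = g["triples"][:, idx], rest[:, idx]
            if n_rest >= 2 and n_scored >= 2 and (a.var() > 0 or b.var() > 0):
                with warnings.catch_warnings():
                    # near-constant samples trip scipy's precision-loss warning
                    warnings.simplefilter("ignore", RuntimeWarning)
                    _, p = stats.ttest_ind(a, b, equal_var=False)
                sentiment_p[comp] = float(p) if np.isfinite(p) else 1.0
            else:
                # degenerate samples carry no evidence against the null
                sentiment_p[comp] = 1.0
        emo: dict[str, EmotionStat] = {}
        for e in emotions:
            x1 = g["flags"][e]
            x2 = sum(h["flags"][e] for other, h in per_group.items()
                     if other != group)
            p = _two_proportion_p(x1, n_scored, x2, n_rest)
            emo[e] = EmotionStat(percent=100.0 * x1 / n_scored, n_flagged=x1,
                                 p_value=p, significant=p <= alpha)
        mean = g["triples"].mean(axis=0)
        out[group] = GroupScore(group=group, n_posts=g["n_posts"],
                                n_scored=n_scored, positive=float(mean[0]),
                                negative=float(mean[1]), objective=float(mean[2]),
                                sentiment_p=sentiment_p, emotions=emo)
    return out


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values (extension; not applied by default)."""
    if len(p_values) == 0:
        return []
    return list(multipletests(p_values, method="fdr_bh")[1])
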
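"""Synthetic corpora with known demographic structure and planted signal.

No real crawled corpus ships with this package, so every downstream stage
is validated against generated data whose ground truth is known by
construction. The generator is a bag-of-words model: each author belongs to
one value of a chosen demographic attribute, and each token of a post is
drawn i.i.d. from that group's multinomial over

  * planted terms — each with a per-token rate in its target group and a
    (lower) rate elsewhere, giving a closed-form expected relative
    difference per group;
  * positive / negative sentiment-lexicon words, at group-specific
    per-token rates;
  * a uniform background vocabulary (``w0001`` ... style, disjoint from
    every lexicon).

Independently, each post receives a word of emotion *e* with a
group-specific per-post probability, so group emotion percentages have a
known expectation. Users may omit the demographic attribute with a
configured probability (their posts still come from their group's
distribution — they just did not report it). A fixed seed makes the output
byte-identical across runs.

Bag-of-words generation is sufficient here because every statistic
downstream is token- or phrase-based; no claim about syntax, discourse, or
real lexical distributions is made.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .corpus import (Post, UserProfile, write_corpus, REGIONS, GENDERS,
                     ETHNICITIES, AGE_GROUPS, WRITING_LEVEL_BINS)
from .lexicon import EMOTIONS

#: Injection vocabulary — disjoint from background words and from each other.
POSITIVE_WORDS = tuple(f"goodpos{i:02d}" for i in range(1, 11))
NEGATIVE_WORDS = tuple(f"badneg{i:02d}" for i in range(1, 11))
EMOTION_WORDS = {e: tuple(f"{e}cue{i:02d}" for i in range(1, 4)) for e in EMOTIONS}

_AGE_REPRESENTATIVE = {"0-17": 15, "18-34": 25, "35-44": 40, "45-64": 55, "65+": 70}
_REGION_STATE = {"Northeast": "NY", "Midwest": "OH", "South": "TX", "West": "CA"}
_GRADE_REPRESENTATIVE = {"0-5": 3.0, "6-9": 8.0, "10-16": 12.0}


class GeneratorError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedTerm:
    term: str                   # may contain spaces (emitted as adjacent tokens)
    target_group: str
    rate_in_target: float       # per-token probability in the target group
    rate_elsewhere: float

    def rate(self, group: str) -> float:
        return self.rate_in_target if group == self.target_group else self.rate_elsewhere


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int
    group_attribute: str = "gender"
    groups: tuple[str, ...] = ("male", "female")
    posts_per_group: int = 1000
    post_length_mean: float = 15.0          # Poisson, floored at 1 token
    background_vocab_size: int = 500
    planted_terms: tuple[PlantedTerm, ...] = ()
    #: group -> emotion -> per-post probability of an injected emotion word
    emotion_injection: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    #: group -> {"positive": p, "negative": p} per-token rates
    sentiment_injection: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    #: attribute -> probability a user omits the attribute
    missingness: Mapping[str, float] = field(default_factory=dict)
    posts_per_user: int = 1
    source: str = "forum"

    def __post_init__(self) -> None:
        if not self.groups:
            raise GeneratorError("need >=1 group")
        if self.posts_per_group <= 0:
            raise GeneratorError("posts_per_group must be positive")
        if self.background_vocab_size <= 0:
            raise GeneratorError("background vocabulary must be non-empty")
        probs = [p for gm in self.emotion_injection.values() for p in gm.values()]
        probs += [p for gm in self.sentiment_injection.values() for p in gm.values()]
        probs += list(self.missingness.values())
        for t in self.planted_terms:
            probs += [t.rate_in_target, t.rate_elsewhere]
            if t.rate_in_target < t.rate_elsewhere:
                raise GeneratorError(
                    f"planted term {t.term!r}: target rate below elsewhere rate")
            if t.target_group not in self.groups:
                raise GeneratorError(
                    f"planted term {t.term!r}: unknown target group {t.target_group!r}")
        if any(p < 0 or p > 1 for p in probs):
            raise GeneratorError("all probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class GroundTruthManifest:
    """Closed-form expectations implied by the configured rates."""

    group_attribute: str
    groups: tuple[str, ...]
    #: term -> group -> expected RelDif = (r_g - mean_h r_h) / mean_h r_h
    expected_reldif: Mapping[str, Mapping[str, float]]
    #: term -> group -> per-token rate
    rates: Mapping[str, Mapping[str, float]]
    #: group -> emotion -> expected percentage of posts carrying the emotion
    expected_emotion_percent: Mapping[str, Mapping[str, float]]

    def to_json(self) -> dict:
        return asdict(self)


def build_manifest(config: GeneratorConfig) -> GroundTruthManifest:
    expected_reldif: dict[str, dict[str, float]] = {}
    rates: dict[str, dict[str, float]] = {}
    for t in config.planted_terms:
        r = {g: t.rate(g) for g in config.groups}
        mean = sum(r.values()) / len(r)
        rates[t.term] = r
        expected_reldif[t.term] = ({g: (v - mean) / mean for g, v in r.items()}
                                   if mean > 0 else {g: 0.0 for g in r})
    emotion = {g: {e: 100.0 * config.emotion_injection.get(g, {}).get(e, 0.0)
                   for e in EMOTIONS}
               for g in config.groups}
    return GroundTruthManifest(group_attribute=config.group_attribute,
                               groups=config.groups,
                               expected_reldif=expected_reldif, rates=rates,
                               expected_emotion_percent=emotion)


def _make_profile(user_id: str, attribute: str, value: str,
                  rng: np.random.Generator, missing_p: float) -> UserProfile:
    missing = rng.random() < missing_p
    prov = {attribute: "missing" if missing else "reported"}
    if missing:
        return UserProfile(user_id=user_id, provenance=prov)
    if attribute == "gender":
        if value not in GENDERS:
            raise GeneratorError(f"bad gender group {value!r}")
        return UserProfile(user_id=user_id, gender=value, provenance=prov)
    if attribute == "age_group":
        if value not in AGE_GROUPS:
            raise GeneratorError(f"bad age group {value!r}")
        return UserProfile(user_id=user_id, age_years=_AGE_REPRESENTATIVE[value],
                           provenance=prov)
    if attribute == "ethnicity":
        if value not in ETHNICITIES:
            raise GeneratorError(f"bad ethnicity group {value!r}")
        return UserProfile(user_id=user_id, ethnicity=value, provenance=prov)
    if attribute == "region":
        if value not in REGIONS:
            raise GeneratorError(f"bad region group {value!r}")
        return UserProfile(user_id=user_id, region=value,
                           location_state=_REGION_STATE[value], provenance=prov)
    if attribute == "writing_level_bin":
        if value not in WRITING_LEVEL_BINS:
            raise GeneratorError(f"bad writing-level bin {value!r}")
        return UserProfile(user_id=user_id,
                           writing_level_grade=_GRADE_REPRESENTATIVE[value],
                           provenance=prov)
    raise GeneratorError(f"unknown group attribute {attribute!r}")


def generate_corpus(config: GeneratorConfig
                    ) -> tuple[list[Post], list[UserProfile], GroundTruthManifest]:
    """Generate posts + profiles per the config; deterministic under the seed."""
    rng = np.random.default_rng(config.seed)
    background = [f"w{i:04d}" for i in range(config.background_vocab_size)]
    missing_p = config.missingness.get(config.group_attribute, 0.0)

    posts: list[Post] = []
    profiles: list[UserProfile] = []
    uid_counter = 0
    pid_counter = 0
    for group in config.groups:
        senti = config.sentiment_injection.get(group, {})
        p_pos = senti.get("positive", 0.0)
        p_neg = senti.get("negative", 0.0)
        planted_rates = [t.rate(group) for t in config.planted_terms]
        # categorical over token slots:
        # [planted terms..., positive, negative, background]
        slot_p = planted_rates + [p_pos, p_neg]
        p_background = 1.0 - sum(slot_p)
        if p_background < 0:
            raise GeneratorError(
                f"group {group!r}: per-token rates sum above 1")
        slot_p = np.array(slot_p + [p_background])
        slot_cum = np.cumsum(slot_p)
        slot_cum[-1] = 1.0
        emo = config.emotion_injection.get(group, {})

        n_users = -(-config.posts_per_group // config.posts_per_user)
        user_ids = []
        for _ in range(n_users):
            uid = f"u{uid_counter:06d}"
            uid_counter += 1
            profiles.append(_make_profile(uid, config.group_attribute, group,
                                          rng, missing_p))
            user_ids.append(uid)

        lengths = np.maximum(rng.poisson(config.post_length_mean,
                                         config.posts_per_group), 1)
        n_planted = len(config.planted_terms)
        planted_tokens = [t.term.split() for t in config.planted_terms]
        emo_probs = np.array([emo.get(e, 0.0) for e in EMOTIONS])
        for i in range(config.posts_per_group):
            length = int(lengths[i])
            # inverse-CDF categorical draw over token slots
            slots = np.searchsorted(slot_cum, rng.random(length), side="right")
            # vectorized word picks per category; only the needed ones used
            bg = rng.integers(len(background), size=length)
            pick_pos = rng.integers(len(POSITIVE_WORDS), size=length)
            pick_neg = rng.integers(len(NEGATIVE_WORDS), size=length)
            words: list[str] = []
            for j, s in enumerate(slots):
                if s < n_planted:
                    words.extend(planted_tokens[s])
                elif s == n_planted:
                    words.append(POSITIVE_WORDS[pick_pos[j]])
                elif s == n_planted + 1:
                    words.append(NEGATIVE_WORDS[pick_neg[j]])
                else:
                    words.append(background[bg[j]])
            if emo_probs.any():
                hits = rng.random(len(EMOTIONS)) < emo_probs
                cues = rng.integers(3, size=len(EMOTIONS))
                for k, e in enumerate(EMOTIONS):
                    if hits[k]:
                        words.append(EMOTION_WORDS[e][cues[k]])
            posts.append(Post(post_id=f"p{pid_counter:07d}",
                              user_id=user_ids[i // config.posts_per_user],
                              text=" ".join(words), source=config.source))
            pid_counter += 1
    return posts, profiles, build_manifest(config)


def generate_corpus_files(config: GeneratorConfig, outdir: str | Path
                          ) -> GroundTruthManifest:
    """Generate and write posts.jsonl / users.jsonl / manifest.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    posts, profiles, manifest = generate_corpus(config)
    write_corpus(posts, profiles, outdir / "posts.jsonl", outdir / "users.jsonl")
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest.to_json(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


# -- fixture lexicons ----------------------------------------------------------

_REAL_SENTIMENT_ROWS = [
    # POS, phrase, PosScore, NegScore (objective derived)
    ("a", "good", 0.75, 0.0),
    ("a", "happy", 0.875, 0.0),
    ("a", "bad", 0.0, 0.625),
    ("a", "painful", 0.0, 0.75),
    ("n", "pain", 0.0, 0.5),
    ("n", "relief", 0.625, 0.0),
    ("n", "heart_attack", 0.0, 0.25),
    ("n", "heart", 0.0, 0.0),
    ("v", "hurt", 0.0, 0.625),
    ("v", "help", 0.5, 0.0),
    ("r", "sadly", 0.0, 0.5),
    ("a", "anxious", 0.0, 0.5),
]

_REAL_EMOTION_ROWS = [
    ("angry", "anger"), ("rage", "anger"), ("afraid", "fear"), ("panic", "fear"),
    ("trust", "trust"), ("reliable", "trust"), ("disgust", "disgust"),
    ("hope", "anticipation"), ("expect", "anticipation"),
    ("surprise", "surprise"), ("joy", "joy"), ("grief", "sadness"),
]


def write_fixture_lexicons(outdir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write fixture sentiment/emotion lexicons matching the generator vocabulary.

    The sentiment lexicon covers the generator's injection words (positive
    words at 0.75/0.00, negative at 0.00/0.625), a handful of real words,
    and the two-token phrase "heart attack" so longest-match code paths are
    exercised; every row's scores leave a valid objective share. The emotion
    lexicon flags the generator's per-emotion cue words plus real examples.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sentiment_path = outdir / "sentiment_lexicon.tsv"
    emotion_path = outdir / "emotion_lexicon.tsv"

    with open(sentiment_path, "w", encoding="utf-8") as fh:
        fh.write("# POS\tterm\tPosScore\tNegScore (synthetic fixture lexicon)\n")
        for word in POSITIVE_WORDS:
            fh.write(f"any\t{word}\t0.75\t0.0\n")
        for word in NEGATIVE_WORDS:
            fh.write(f"any\t{word}\t0.0\t0.625\n")
        for pos, phrase, p, n in _REAL_SENTIMENT_ROWS:
            fh.write(f"{pos}\t{phrase}\t{p}\t{n}\n")

    with open(emotion_path, "w", encoding="utf-8") as fh:
        fh.write("# word\temotion\tflag (synthetic fixture lexicon)\n")
        for e in EMOTIONS:
            for word in EMOTION_WORDS[e]:
                fh.write(f"{word}\t{e}\t1\n")
        for word, e in _REAL_EMOTION_ROWS:
            fh.write(f"{word}\t{e}\t1\n")

    return {"sentiment": sentiment_path, "emotion": emotion_path}
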
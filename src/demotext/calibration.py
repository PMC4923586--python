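"""Monte-Carlo calibration of the group-vs-rest emotion comparison.

The emotion tables flag cells by a two-proportion z-test at alpha = 0.05.
These simulations check that the flag means what it claims on corpora the
generator produces: under a null configuration (identical emotion injection
in every group) the rejection rate should sit near alpha, and under a
configured group difference the target comparison should reject nearly
always. Both routines run the *real* chain — generate posts, normalize,
match against the lexicons, aggregate, test — not a shortcut on the
Bernoulli flags, so they also exercise the scoring path end to end.

POS tagging is skipped here: the fixture lexicon's injection words are
POS-agnostic, so tags cannot change any match.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .corpus import partition_posts
from .lexicon import SentimentLexicon, aggregate_groups, score_tokens
from .synthetic import GeneratorConfig, generate_corpus
from .textproc import normalize

_NO_STOPWORDS = frozenset()


def _replicate(seed: int, groups: Sequence[str], n_posts_per_group: int,
               emotion_injection: Mapping[str, Mapping[str, float]],
               post_length_mean: float, sentiment_rate: float,
               slex: SentimentLexicon, elex, alpha: float):
    config = GeneratorConfig(
        seed=seed, group_attribute="gender", groups=tuple(groups),
        posts_per_group=n_posts_per_group, post_length_mean=post_length_mean,
        background_vocab_size=200,
        emotion_injection=emotion_injection,
        sentiment_injection={g: {"positive": sentiment_rate} for g in groups})
    posts, profiles, _ = generate_corpus(config)
    partition = partition_posts(posts, {p.user_id: p for p in profiles}, "gender")
    scores = {g: [score_tokens(normalize(p.text, _NO_STOPWORDS), slex, elex)
                  for p in ps]
              for g, ps in partition.items()}
    return aggregate_groups(scores, alpha=alpha)


def _spawn_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)


def null_rejection_rate(slex: SentimentLexicon, elex,
                        emotion_rates: Mapping[str, float],
                        n_posts_per_group: int = 500, n_reps: int = 1000,
                        groups: Sequence[str] = ("male", "female"),
                        alpha: float = 0.05, post_length_mean: float = 8.0,
                        sentiment_rate: float = 0.2, seed: int = 0) -> float:
    """Fraction of group-vs-rest emotion comparisons flagged under the null.

    Every group receives identical *emotion_rates*, so each flagged
    comparison is a type-I error; a calibrated test yields a fraction
    near *alpha*.
    """
    injection = {g: dict(emotion_rates) for g in groups}
    tested = list(emotion_rates)
    n_comparisons = 0
    n_rejections = 0
    for s in _spawn_seeds(seed, n_reps):
        result = _replicate(int(s), groups, n_posts_per_group, injection,
                            post_length_mean, sentiment_rate, slex, elex, alpha)
        for gs in result.values():
            for e in tested:
                n_comparisons += 1
                if gs.emotions[e].significant:
                    n_rejections += 1
    return n_rejections / n_comparisons


def emotion_power(slex: SentimentLexicon, elex,
                  emotion: str, rate_target: float, rate_rest: float,
                  n_posts_per_group: int = 1000, n_reps: int = 200,
                  groups: Sequence[str] = ("male", "female"),
                  target_group: str = "male",
                  alpha: float = 0.05, post_length_mean: float = 8.0,
                  sentiment_rate: float = 0.2, seed: int = 0) -> float:
    """Fraction of replicates where the injected difference is flagged.

    The target group receives *emotion* at *rate_target* per post, the
    other groups at *rate_rest*; returns the rejection frequency of the
    target group's comparison against the rest.
    """
    injection = {g: {emotion: rate_target if g == target_group else rate_rest}
                 for g in groups}
    hits = 0
    for s in _spawn_seeds(seed, n_reps):
        result = _replicate(int(s), groups, n_posts_per_group, injection,
                            post_length_mean, sentiment_rate, slex, elex, alpha)
        if result[target_group].emotions[emotion].significant:
            hits += 1
    return hits / n_reps
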
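import numpy as np
import pytest

from demotext.lexicon import (LexiconError, PostScore, PostSentiment,
                              SentimentEntry, SentimentLexicon,
                              aggregate_groups, load_emotion_lexicon,
                              load_sentiment_lexicon, match_phrases,
                              score_post, score_tokens, bh_adjust)
from demotext.textproc import normalize, pos_tag


def greedy_oracle(stems, keys):
    """Independent maximal-matcher: at each position collect every matching
    length ascending and take the maximum; advance past it."""
    out = []
    i = 0
    while i < len(stems):
        lengths = [L for L in range(1, len(stems) - i + 1)
                   if tuple(stems[i:i + L]) in keys]
        if lengths:
            L = max(lengths)
            out.append((i, L))
            i += L
        else:
            i += 1
    return out


class TestLoader:
    def test_objective_derived_from_pos_neg(self, tmp_path):
        f = tmp_path / "s.tsv"
        f.write_text("a\tgood\t0.75\t0.0\n")
        lex = load_sentiment_lexicon(f)
        entry = lex.lookup(("good",), "adj")
        assert entry.objective == pytest.approx(0.25)
        assert entry.positive + entry.negative + entry.objective == pytest.approx(1.0)

    def test_duplicate_senses_averaged(self, tmp_path):
        f = tmp_path / "s.tsv"
        f.write_text("a\tgood\t0.75\t0.0\na\tgood\t0.25\t0.1\n")
        lex = load_sentiment_lexicon(f)
        entry = lex.lookup(("good",), "adj")
        assert entry.positive == pytest.approx(0.5)
        assert entry.negative == pytest.approx(0.05)

    def test_sum_violation_rejected_with_line_number(self, tmp_path):
        f = tmp_path / "s.tsv"
        f.write_text("a\tgood\t0.75\t0.0\na\tbad\t0.8\t0.4\n")
        with pytest.raises(LexiconError, match=":2:"):
            load_sentiment_lexicon(f)

    def test_empty_file_rejected(self, tmp_path):
        f = tmp_path / "s.tsv"
        f.write_text("# header only\n")
        with pytest.raises(LexiconError, match="empty"):
            load_sentiment_lexicon(f)

    def test_public_six_column_layout(self, tmp_path):
        f = tmp_path / "swn.tsv"
        f.write_text("# POS\tID\tPosScore\tNegScore\tSynsetTerms\tGloss\n"
                     "a\t00001740\t0.125\t0\table#1 unable#2\tcapable of\n"
                     "n\t00002500\t0\t0.5\theart_attack#1\tinfarction\n")
        lex = load_sentiment_lexicon(f)
        assert lex.lookup(("abl",), "adj").positive == pytest.approx(0.125)
        assert lex.lookup(("unabl",), "adj") is not None
        assert lex.lookup(("heart", "attack"), "noun").negative == pytest.approx(0.5)

    def test_entries_stemmed(self, fixture_lexicon_paths):
        lex = load_sentiment_lexicon(fixture_lexicon_paths["sentiment"])
        # 'painful' is stored stemmed, so inflected text matches
        assert lex.lookup(("pain",), "noun") is not None

    def test_emotion_lexicon_flags(self, emotion_lexicon):
        assert "anger" in emotion_lexicon["angercue01"]
        assert "fear" in emotion_lexicon["panic"]

    def test_emotion_bad_flag_value_rejected(self, tmp_path):
        f = tmp_path / "e.tsv"
        f.write_text("word\tanger\t2\n")
        with pytest.raises(LexiconError, match="0 or 1"):
            load_emotion_lexicon(f)


class TestMatchPhrases:
    def test_longest_match_wins_over_prefix(self, sentiment_lexicon):
        toks = pos_tag(normalize("heart attack hurt"))
        matches = match_phrases(toks, sentiment_lexicon)
        spans = [(m.start, m.length) for m in matches]
        assert (0, 2) in spans           # "heart attack", never lone "heart"
        assert (2, 1) in spans           # "hurt"

    def test_no_overlap_returns_empty(self, sentiment_lexicon):
        toks = pos_tag(normalize("zzz qqq www"))
        assert match_phrases(toks, sentiment_lexicon) == []

    def test_greedy_equals_exhaustive_oracle_on_random_strings(self):
        rng = np.random.default_rng(42)
        vocab = ["alpha", "beta", "gamma", "delta", "eps", "zeta", "eta", "theta"]
        phrases = [("alpha",), ("beta",), ("alpha", "beta"),
                   ("beta", "gamma", "delta"), ("gamma",), ("delta", "eps"),
                   ("zeta", "eta"), ("eta",), ("alpha", "beta", "gamma")]
        lex = SentimentLexicon([SentimentEntry(p, "any", 0.5, 0.25)
                                for p in phrases])
        keys = set(lex.by_stems)
        for _ in range(200):
            stems = [vocab[i] for i in rng.integers(len(vocab), size=20)]
            toks = normalize(" ".join(stems))
            got = [(m.start, m.length) for m in match_phrases(toks, lex)]
            assert got == greedy_oracle([t.stem for t in toks], keys)

    def test_pos_specific_sense_preferred(self, tmp_path):
        f = tmp_path / "s.tsv"
        f.write_text("a\tgood\t0.9\t0.0\nn\tgood\t0.1\t0.0\n")
        lex = load_sentiment_lexicon(f)
        assert lex.lookup(("good",), "adj").positive == pytest.approx(0.9)
        assert lex.lookup(("good",), "noun").positive == pytest.approx(0.1)
        # unknown POS falls back to the POS-insensitive mean
        assert lex.lookup(("good",), "other").positive == pytest.approx(0.5)


class TestScorePost:
    def test_mean_of_matched_triples(self, sentiment_lexicon, emotion_lexicon):
        score = score_post("good bad", sentiment_lexicon, emotion_lexicon)
        assert score.sentiment.positive == pytest.approx(0.375)
        assert score.sentiment.negative == pytest.approx(0.3125)
        assert score.sentiment.objective == pytest.approx(0.3125)
        assert score.sentiment.n_matched == 2

    def test_zero_matches_is_unscored(self, sentiment_lexicon, emotion_lexicon):
        score = score_post("zzz qqq", sentiment_lexicon, emotion_lexicon)
        assert not score.sentiment.scored

    def test_single_match_equals_entry(self, sentiment_lexicon, emotion_lexicon):
        score = score_post("happy", sentiment_lexicon, emotion_lexicon)
        assert score.sentiment.positive == pytest.approx(0.875)
        assert score.sentiment.n_matched == 1

    def test_triple_sums_to_one_when_scored(self, sentiment_lexicon,
                                            emotion_lexicon):
        score = score_post("good bad pain relief hurt", sentiment_lexicon,
                           emotion_lexicon)
        total = (score.sentiment.positive + score.sentiment.negative
                 + score.sentiment.objective)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_emotion_flags_from_any_word(self, sentiment_lexicon, emotion_lexicon):
        score = score_post("so much rage and panic", sentiment_lexicon,
                           emotion_lexicon)
        assert {"anger", "fear"} <= score.emotions

    def test_scoring_is_per_post_pure(self, sentiment_lexicon, emotion_lexicon):
        texts = ["good bad", "happy pain", "zzz", "hurt relief good"]
        once = [score_post(t, sentiment_lexicon, emotion_lexicon) for t in texts]
        shuffled = [score_post(t, sentiment_lexicon, emotion_lexicon)
                    for t in reversed(texts)]
        assert once == list(reversed(shuffled))


def ps(pos, neg, emotions=()):
    return PostScore(PostSentiment(pos, neg, 1 - pos - neg, 1),
                     frozenset(emotions))


class TestAggregateGroups:
    def test_group_mean(self):
        groups = {"male": [ps(0.4, 0.1), ps(0.6, 0.1)],
                  "female": [ps(0.2, 0.3), ps(0.2, 0.3)]}
        out = aggregate_groups(groups)
        assert out["male"].positive == pytest.approx(0.5)
        assert out["female"].negative == pytest.approx(0.3)

    def test_group_triple_sums_to_one(self):
        groups = {"a": [ps(0.4, 0.1), ps(0.3, 0.25)],
                  "b": [ps(0.1, 0.2), ps(0.0, 0.9)]}
        for gs in aggregate_groups(groups).values():
            assert gs.positive + gs.negative + gs.objective == \
                pytest.approx(1.0, abs=1e-6)

    def test_all_posts_flagged_gives_100_percent(self):
        groups = {"a": [ps(0.5, 0.1, {"anger"})] * 3,
                  "b": [ps(0.5, 0.1)] * 3}
        out = aggregate_groups(groups)
        assert out["a"].emotions["anger"].percent == pytest.approx(100.0)
        assert out["b"].emotions["anger"].percent == pytest.approx(0.0)

    def test_unscored_posts_excluded_from_denominator(self):
        unscored = PostScore(PostSentiment(0, 0, 0, 0), frozenset())
        groups = {"a": [ps(0.5, 0.1, {"joy"}), unscored],
                  "b": [ps(0.5, 0.1)] * 2}
        out = aggregate_groups(groups)
        assert out["a"].n_scored == 1
        assert out["a"].n_posts == 2
        assert out["a"].emotions["joy"].percent == pytest.approx(100.0)

    def test_empty_group_omitted_with_warning(self, caplog):
        unscored = PostScore(PostSentiment(0, 0, 0, 0), frozenset())
        groups = {"a": [ps(0.5, 0.1)], "b": [unscored]}
        with caplog.at_level("WARNING"):
            out = aggregate_groups(groups)
        assert "b" not in out
        assert "no scored posts" in caplog.text

    def test_bh_adjustment_monotone(self):
        raw = [0.001, 0.02, 0.04, 0.8]
        adj = bh_adjust(raw)
        assert all(a >= r for a, r in zip(adj, raw))
        assert adj == sorted(adj)
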
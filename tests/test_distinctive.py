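import math

import pytest
from hypothesis import given, settings, strategies as st

from demotext.corpus import Post, UserProfile, partition_posts
from demotext.distinctive import (AnalysisError, build_freq_table,
                                  distinctive_items, min_occurrence_threshold,
                                  relative_differences, top_distinctive)
from demotext.synthetic import GeneratorConfig, PlantedTerm, generate_corpus
from demotext.textproc import normalize


def term_stream(post):
    return [t.stem for t in normalize(post.text) if not t.is_stopword]


def make_partition(spec):
    """spec: {group: [text, ...]} -> {group: [Post, ...]}"""
    out = {}
    i = 0
    for group, texts in spec.items():
        out[group] = [Post(f"p{i + j}", f"u{i + j}", t)
                      for j, t in enumerate(texts)]
        i += len(texts)
    return out


def brute_force_chain(partition, k=10, min_reldif=0.1):
    """Independent recount: plain dict arithmetic, no package counting code."""
    n_total = sum(len(ps) for ps in partition.values())
    threshold = max(0.0001 * n_total, 30)
    totals = {}
    per_group = {g: {} for g in partition}
    for g, posts in partition.items():
        for post in posts:
            for item in term_stream(post):
                totals[item] = totals.get(item, 0) + 1
                per_group[g][item] = per_group[g].get(item, 0) + 1
    kept = sorted(item for item, n in totals.items() if n >= threshold)
    freq = {item: {g: per_group[g].get(item, 0) / len(partition[g])
                   for g in partition} for item in kept}
    avg = {item: sum(freq[item].values()) / len(partition) for item in kept}
    reldif = {item: {g: (freq[item][g] - avg[item]) / avg[item]
                     for g in partition} for item in kept}
    top = {}
    for g in partition:
        rows = [(item, reldif[item][g]) for item in kept
                if reldif[item][g] > min_reldif]
        rows.sort(key=lambda r: (-r[1], -avg[r[0]], r[0]))
        top[g] = [item for item, _ in rows[:k]]
    return freq, avg, reldif, top


class TestThreshold:
    @pytest.mark.parametrize("n,expected", [
        (1_000_000, 100), (50_000, 30), (300_000, 30), (0, 30), (299_999, 30),
        (300_010, 31),
    ])
    def test_max_of_permille_and_floor(self, n, expected):
        assert min_occurrence_threshold(n) == expected

    def test_negative_rejected(self):
        with pytest.raises(AnalysisError):
            min_occurrence_threshold(-1)


class TestFreqTable:
    def test_eq1_arithmetic(self):
        # 10 occurrences of a term across 200 posts in one group -> freq 0.05
        male = ["hdterm filler"] * 10 + ["filler words"] * 190
        female = ["hdterm stuff"] * 30 + ["other stuff"] * 170
        partition = make_partition({"male": male, "female": female})
        table = build_freq_table(partition, term_stream)
        assert table.freq("hdterm", "male") == pytest.approx(10 / 200)
        assert table.freq("hdterm", "female") == pytest.approx(30 / 200)

    def test_items_below_threshold_absent(self):
        # 12 total occurrences < floor of 30 -> filtered out
        male = ["rareterm x"] * 6 + ["common y"] * 194
        female = ["rareterm z"] * 6 + ["common w"] * 194
        partition = make_partition({"male": male, "female": female})
        table = build_freq_table(partition, term_stream)
        assert "rareterm" not in table.occurrences
        assert "common" in table.occurrences

    def test_fewer_than_two_groups_rejected(self):
        partition = make_partition({"only": ["a b"] * 5})
        with pytest.raises(AnalysisError, match=">=2"):
            build_freq_table(partition, term_stream)

    def test_per_post_counting_option(self):
        male = ["dup dup dup"] * 30 + ["x"] * 10
        female = ["dup"] * 30 + ["y"] * 10
        partition = make_partition({"male": male, "female": female})
        occurrence = build_freq_table(partition, term_stream)
        binary = build_freq_table(partition, term_stream, per_post=True)
        assert occurrence.occurrences["dup"]["male"] == 90
        assert binary.occurrences["dup"]["male"] == 30


class TestRelDif:
    def test_two_group_hand_arithmetic(self):
        male = ["target a"] * 60 + ["b c"] * 940
        female = ["target d"] * 20 + ["e f"] * 980
        partition = make_partition({"male": male, "female": female})
        table = build_freq_table(partition, term_stream)
        (result,) = [r for r in relative_differences(table) if r.item == "target"]
        assert result.avg_freq == pytest.approx(0.04)
        assert result.reldif["male"] == pytest.approx(0.5)
        assert result.reldif["female"] == pytest.approx(-0.5)

    def test_equal_frequencies_give_zero(self):
        partition = make_partition({"a": ["xitem x"] * 50, "b": ["xitem y"] * 50})
        table = build_freq_table(partition, term_stream)
        (result,) = [r for r in relative_differences(table) if r.item == "xitem"]
        assert result.reldif["a"] == pytest.approx(0.0)
        assert result.reldif["b"] == pytest.approx(0.0)

    def test_four_group_hand_arithmetic(self):
        # freqs (.02,.02,.02,.10) -> RelDif (-.5,-.5,-.5,+1.5)
        spec = {"ne": 20, "mw": 20, "so": 20, "we": 100}
        partition = make_partition({
            g: ["item filler"] * n + ["filler pad"] * (1000 - n)
            for g, n in spec.items()})
        table = build_freq_table(partition, term_stream)
        (result,) = [r for r in relative_differences(table) if r.item == "item"]
        assert result.reldif == pytest.approx(
            {"ne": -0.5, "mw": -0.5, "so": -0.5, "we": 1.5})
        assert sum(result.reldif.values()) == pytest.approx(0.0, abs=1e-9)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.lists(st.integers(0, 5), min_size=40, max_size=80),
                    min_size=2, max_size=4))
    def test_sum_zero_and_antisymmetry_properties(self, group_specs):
        partition = make_partition({
            f"g{gi}": [f"tok{v} pad" for v in vals]
            for gi, vals in enumerate(group_specs)})
        try:
            table = build_freq_table(partition, term_stream)
        except AnalysisError:
            return
        results = relative_differences(table)
        for r in results:
            assert sum(r.reldif.values()) == pytest.approx(0.0, abs=1e-9)
            assert all(v > -1.0 - 1e-12 for v in r.reldif.values())
            if len(group_specs) == 2:
                a, b = r.reldif.values()
                assert a == pytest.approx(-b, abs=1e-12)

    def test_invariance_under_corpus_duplication(self):
        male = ["target a"] * 60 + ["b c"] * 140
        female = ["target d"] * 20 + ["e f"] * 180
        partition = make_partition({"male": male, "female": female})
        doubled = {g: ps + [Post(p.post_id + "dup", p.user_id, p.text)
                            for p in ps]
                   for g, ps in partition.items()}
        r1 = {r.item: r.reldif for r in
              relative_differences(build_freq_table(partition, term_stream))}
        r2 = {r.item: r.reldif for r in
              relative_differences(build_freq_table(doubled, term_stream))}
        for item in r1:
            assert r1[item] == pytest.approx(r2[item], abs=1e-12)


class TestTopDistinctive:
    def _results(self):
        male = ["aterm x"] * 60 + ["bterm y"] * 50 + ["pad z"] * 890
        female = ["aterm x"] * 20 + ["bterm y"] * 50 + ["pad z"] * 930
        partition = make_partition({"male": male, "female": female})
        return relative_differences(build_freq_table(partition, term_stream))

    def test_below_floor_gives_empty_list(self):
        results = self._results()
        top = top_distinctive(results, min_reldif=10.0)
        assert top["male"] == [] and top["female"] == []

    def test_k1_returns_argmax(self):
        top = top_distinctive(self._results(), k=1)
        assert [r.item for r in top["male"]] == ["aterm"]

    def test_display_filters(self):
        results = self._results()
        top = top_distinctive(results, block=frozenset({"aterm"}))
        assert "aterm" not in [r.item for r in top["male"]]
        top = top_distinctive(results, allow=frozenset({"pad"}))
        assert all(r.item == "pad" for rows in top.values() for r in rows)

    def test_tie_break_by_avg_freq_then_lexicographic(self):
        male = ["tie1 x"] * 40 + ["tie2 y"] * 40 + ["tie3 z"] * 40 + ["pad"] * 880
        female = ["pad pad"] * 1000
        partition = make_partition({"male": male, "female": female})
        results = relative_differences(build_freq_table(partition, term_stream))
        top = top_distinctive(results)
        items = [r.item for r in top["male"]]
        # tie1/tie2/tie3 all have identical freq and reldif -> lexicographic
        assert items.index("tie1") < items.index("tie2") < items.index("tie3")


class TestOracleEquivalence:
    def test_chain_matches_brute_force_on_small_corpus(self):
        config = GeneratorConfig(
            seed=11, groups=("male", "female"), posts_per_group=100,
            post_length_mean=12.0, background_vocab_size=8,
            planted_terms=(PlantedTerm("qtermax", "male", 0.05, 0.01),))
        posts, profiles, _ = generate_corpus(config)
        partition = partition_posts(posts, {p.user_id: p for p in profiles},
                                    "gender")
        table, results, top = distinctive_items(partition, term_stream,
                                                attribute="gender")
        freq_o, avg_o, reldif_o, top_o = brute_force_chain(partition)
        assert sorted(r.item for r in results) == sorted(freq_o)
        for r in results:
            assert r.avg_freq == pytest.approx(avg_o[r.item], abs=1e-12)
            for g in partition:
                assert r.freq[g] == pytest.approx(freq_o[r.item][g], abs=1e-12)
                assert r.reldif[g] == pytest.approx(reldif_o[r.item][g], abs=1e-12)
        for g in partition:
            assert [r.item for r in top[g]] == top_o[g]

    def test_planted_term_recovered_in_target_top10(self):
        config = GeneratorConfig(
            seed=5, groups=("male", "female"), posts_per_group=2000,
            post_length_mean=15.0, background_vocab_size=300,
            planted_terms=(PlantedTerm("qtermax", "male", 0.03, 0.01),))
        posts, profiles, _ = generate_corpus(config)
        partition = partition_posts(posts, {p.user_id: p for p in profiles},
                                    "gender")
        _, _, top = distinctive_items(partition, term_stream)
        assert "qtermax" in [r.item for r in top["male"]]
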
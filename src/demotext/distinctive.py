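"""Distinctive-term and distinctive-concept statistics.

For a demographic attribute (say gender) the corpus is partitioned by
attribute value, and for every item x (a term stem or a concept id) each
group g gets a per-post frequency

    Freq_g(x) = occurrences of x in g's posts / number of posts in g,

items below a minimum-occurrence threshold having been dropped: an item
must occur at least max(0.01% of the annotated posts for the attribute, 30)
times in total. A group's distinctiveness for x is the relative difference

    RelDif_g(x) = (Freq_g(x) - AvgFreq(x)) / AvgFreq(x),

where AvgFreq(x) is the *unweighted* mean of the per-group frequencies —
e.g. with four regions, the mean of the four regional frequencies. With the
unweighted mean, RelDif sums to zero over groups for every item, and with
two groups the values are exactly antisymmetric. Reports keep, per group,
the top-k items with RelDif above a display floor (0.1 by default: within
10% of the cross-group average is not worth calling distinctive).
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

from .corpus import Post

log = logging.getLogger(__name__)

#: item stream: maps one post to its countable items (term stems or concept ids)
ItemStream = Callable[[Post], Iterable[str]]


class AnalysisError(ValueError):
    pass


def min_occurrence_threshold(n_annotated_posts: int) -> int:
    """Minimum total occurrences for an item to be analyzed.

    0.01% of the annotated posts for the attribute, floored at 30; the
    ceiling keeps the integer-occurrence semantics of the percentage exact.
    """
    if n_annotated_posts < 0:
        raise AnalysisError("post count must be non-negative")
    return math.ceil(max(1e-4 * n_annotated_posts, 30))


@dataclass(frozen=True)
class FreqTable:
    attribute: str
    n_posts: Mapping[str, int]                      # group -> posts in group
    occurrences: Mapping[str, Mapping[str, int]]    # item -> group -> count
    threshold: int

    def freq(self, item: str, group: str) -> float:
        return self.occurrences[item].get(group, 0) / self.n_posts[group]

    @property
    def items(self) -> list[str]:
        return sorted(self.occurrences)

    @property
    def groups(self) -> list[str]:
        return sorted(self.n_posts)


def build_freq_table(partition: Mapping[str, Sequence[Post]],
                     item_stream: ItemStream,
                     attribute: str = "",
                     per_post: bool = False,
                     threshold_per_group: bool = False) -> FreqTable:
    """Count item occurrences per group and apply the occurrence threshold.

    *item_stream* yields each post's countable items; every yielded
    occurrence counts (``per_post=True`` instead counts each item at most
    once per post). The threshold denominator is the attribute-wide total of
    annotated posts (``threshold_per_group=True`` thresholds each group on
    its own size instead, keeping items passing in any group).
    """
    groups = {g: posts for g, posts in partition.items() if len(posts) > 0}
    if len(groups) < 2:
        raise AnalysisError(
            f"need >=2 non-empty groups to compare (got {len(groups)}); "
            "relative differences are undefined otherwise")
    counts: dict[str, Counter] = {g: Counter() for g in groups}
    for g, posts in groups.items():
        for post in posts:
            items = item_stream(post)
            if per_post:
                items = set(items)
            counts[g].update(items)

    n_posts = {g: len(posts) for g, posts in groups.items()}
    if threshold_per_group:
        thr = {g: min_occurrence_threshold(n) for g, n in n_posts.items()}
        keep = {item for g, c in counts.items() for item, k in c.items()
                if k >= thr[g]}
        threshold = min(thr.values())
    else:
        threshold = min_occurrence_threshold(sum(n_posts.values()))
        totals: Counter = Counter()
        for c in counts.values():
            totals.update(c)
        keep = {item for item, k in totals.items() if k >= threshold}

    occurrences = {item: {g: counts[g][item] for g in groups if counts[g][item]}
                   for item in keep}
    return FreqTable(attribute=attribute, n_posts=n_posts,
                     occurrences=occurrences, threshold=threshold)


@dataclass(frozen=True)
class RelDifResult:
    item: str
    avg_freq: float
    freq: Mapping[str, float]       # group -> Freq_g(item)
    reldif: Mapping[str, float]     # group -> RelDif_g(item)


def relative_differences(table: FreqTable) -> list[RelDifResult]:
    """Per-item relative differences against the unweighted cross-group mean."""
    groups = table.groups
    results = []
    for item in table.items:
        freqs = {g: table.freq(item, g) for g in groups}
        avg = sum(freqs.values()) / len(groups)
        # avg > 0: items absent everywhere were thresholded out
        reldif = {g: (f - avg) / avg for g, f in freqs.items()}
        results.append(RelDifResult(item=item, avg_freq=avg,
                                    freq=freqs, reldif=reldif))
    return results


@dataclass(frozen=True)
class RankedItem:
    rank: int
    item: str
    freq: float
    avg_freq: float
    reldif: float


def top_distinctive(results: Sequence[RelDifResult], k: int = 10,
                    min_reldif: float = 0.1,
                    allow: frozenset[str] | None = None,
                    block: frozenset[str] = frozenset(),
                    ) -> dict[str, list[RankedItem]]:
    """Per group, the top-k items by RelDif above the display floor.

    *allow*/*block* are the reproducible analogue of a manual
    health-relatedness screen: if *allow* is given only those items are
    displayed, and *block* items are always hidden; both apply before
    truncation and are logged. Ties break by higher average frequency, then
    lexicographically. A group where nothing clears the floor gets an empty
    list (a table's "N/A" cell).
    """
    groups = sorted({g for r in results for g in r.reldif})
    dropped = [r.item for r in results
               if (allow is not None and r.item not in allow) or r.item in block]
    if dropped:
        log.info("display filter hid %d item(s): %s", len(dropped),
                 ", ".join(sorted(dropped)[:20]))
    out: dict[str, list[RankedItem]] = {}
    for g in groups:
        rows = [r for r in results
                if r.reldif[g] > min_reldif
                and (allow is None or r.item in allow)
                and r.item not in block]
        rows.sort(key=lambda r: (-r.reldif[g], -r.avg_freq, r.item))
        out[g] = [RankedItem(rank=i + 1, item=r.item, freq=r.freq[g],
                             avg_freq=r.avg_freq, reldif=r.reldif[g])
                  for i, r in enumerate(rows[:k])]
    return out


def distinctive_items(partition: Mapping[str, Sequence[Post]],
                      item_stream: ItemStream, attribute: str = "",
                      k: int = 10, min_reldif: float = 0.1,
                      allow: frozenset[str] | None = None,
                      block: frozenset[str] = frozenset(),
                      ) -> tuple[FreqTable, list[RelDifResult],
                                 dict[str, list[RankedItem]]]:
    """Full chain: count, threshold, relative differences, top-k."""
    table = build_freq_table(partition, item_stream, attribute)
    results = relative_differences(table)
    top = top_distinctive(results, k=k, min_reldif=min_reldif,
                          allow=allow, block=block)
    return table, results, top
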
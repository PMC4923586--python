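# Methods

This note documents the models and procedures the package implements, the
parameter choices that matter, what the synthetic-data generator does and
does not emulate, and the numerical conventions. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Analysis model

The unit of analysis is the *post*; users enter only through their
demographic attributes and through writing-level aggregation. All
statistics are per-post: a user with many posts contributes once per post.
This follows directly from the frequency definition (occurrences divided by
post count); no user down-weighting is applied anywhere, and none is
implied by the formulas.

Five attributes are supported: gender (male/female), age group
(`0-17, 18-34, 35-44, 45-64, 65+`, closed integer bins), ethnicity
(white/black/asian/hispanic), US Census region (Northeast/Midwest/South/
West, from the standard state→region table), and writing level
(`0-5, 6-9, 10-16`). For each attribute, posts whose author lacks the
attribute are excluded from that attribute's analysis — they are not pooled
into an "unknown" bin — so each attribute has its own denominator of
*annotated posts*.

## Distinctive items

For item *x* and group *g* of attribute *A*:

* `Freq_g(x) = occ_g(x) / n_g` where `occ_g(x)` counts every token
  occurrence (not distinct posts; a per-post binary variant is available
  via `per_post=True`) and `n_g` counts all posts in the group partition.
* `AvgFreq(x)` is the unweighted mean of the per-group frequencies; with
  four regions it is the plain mean of the four regional frequencies.
* `RelDif_g(x) = (Freq_g(x) − AvgFreq(x)) / AvgFreq(x)`.

Occurrence threshold: an item is analyzed only if its total occurrences
across all annotated posts for the attribute reach `max(0.0001·N, 30)`,
with `N` the attribute-wide total of annotated posts (a per-group variant
sits behind `threshold_per_group=True`). The implementation returns
`ceil(max(0.0001·N, 30))` as an integer: occurrence counts are integers, so
the ceiling leaves the ≥-comparison unchanged while keeping the threshold
printable as a whole number.

Reports keep, per group, the top-k (default 10) items with `RelDif > 0.1`.
The 0.1 floor hides items within 10% of the cross-group average — close
enough to the average not to be distinctive. Ties in RelDif break by higher
average frequency, then lexicographically; tie order is otherwise
meaningless and this rule exists purely for determinism. An optional
allow/block list stands in for a manual "health-related terms only" screen:
unlike manual curation it is a reviewable input file, applied before
truncation and logged.

Algebraic consequences of the unweighted mean, asserted in tests on every
run: `Σ_g RelDif_g(x) = 0` per item; exact antisymmetry with two groups;
invariance under duplicating every post; `RelDif > −1` always (an item
absent everywhere would have been thresholded out).

Concepts use the identical machinery with concept ids as items; a concept
occurrence is one dictionary match (again switchable to per-post).

## Sentiment and emotion

Sentiment entries carry (positive, negative) scores; the objective score is
derived as `1 − positive − negative` at load time and each row must leave a
valid probability (tolerance 1e-6, violations rejected with the line
number). Duplicate senses of one (phrase, POS) collapse to their unweighted
mean — no sense-rank weighting, since sense ranks are not part of the
compact lexicon dialect. Both the public 6-column SentiWordNet layout and a
compact 4-column `POS  term  pos  neg` dialect parse; phrases are stemmed
with the same pipeline as posts so inflected text matches.

Matching is a left-to-right greedy longest-match scan: at each token
position the longest lexicon phrase starting there is taken and the cursor
advances past it, so "heart attack" never also scores a lone "heart". At
equal length a POS-matched sense is preferred; a token with an unknown or
unmatched POS falls back to the POS-insensitive mean of that phrase's
senses. POS tags therefore refine but never gate a match, which lets the
bundled rule/suffix tagger (closed-class lists + suffix heuristics,
"other" for unknowns) degrade gracefully; any external tagger can be
plugged in through a surfaces-in/coarse-tags-out callable. Tags are
computed on surfaces before stemming.

A post's sentiment is the unweighted mean of its matched triples (which
therefore still sums to 1). Posts with zero matches are *unscored* and
excluded from all group denominators — scoring them as fully objective
would make groups with unmatched vocabulary look artificially objective. A
group's sentiment is the plain mean over its scored posts ("normalized by
the number of posts" is exactly what a mean does; no second division).

Emotions: a post carries emotion *e* iff at least one of its words is
flagged *e* in the word-emotion lexicon; a group's emotion percentage is
`100 · flagged/scored`. All eight basic emotions are computed; the default
report shows the three complementary pairs anger–fear, trust–disgust,
anticipation–surprise.

Significance (the sources state only a P ≤ .05 flag versus the union of
the other groups, not a test): a two-sided two-proportion z-test for
emotion percentages and a Welch two-sample t-test for sentiment means —
the simplest standard tests matching the reported statistic types. Raw
p-values are reported without multiple-testing correction; a
Benjamini–Hochberg helper (`bh_adjust`) is provided as a clearly separate
extension. Degenerate comparisons (empty rest, pooled proportion 0 or 1,
zero-variance sentiment samples) return p = 1: no evidence, never a flag.

Calibration is verified by simulation through the full generate→score→test
chain (`demotext.calibration`): under identical injection in both groups
(500 posts/group, 1000 replicates) the rejection rate must stay near 0.05,
and a 0.40-vs-0.25 per-post injection gap (1000 posts/group) must be
detected in ≥95% of 200 replicates.

## Concept annotation

The dictionary tagger is a deliberate functional stand-in for a full
biomedical named-entity mapper: it trades variant generation and
disambiguation for exact reproducibility and license-free operation. Any
UMLS-derived TSV (`concept_id, preferred_name, synonyms, semantic_group`)
drops in; synonyms are normalized with the same tokenizer/stemmer as posts.
The 15 coarse semantic-group labels are fixed; "Drugs" is accepted as an
alias for "Chemicals & Drugs". Matching reuses the greedy longest-match
contract. Output keeps only Disorders and Chemicals & Drugs by default —
other groups are matched (consuming their tokens) but filtered.

Consumer text trips generic entries — the classic case is the bare letter
"i" matching an immunologic-factor concept. Instead of one-off manual
deletion, suppression lives in a blacklist file of (surface, concept) pairs
applied at annotation time, and `concept_frequency_report` produces the
frequency-ordered audit view used to grow it. Only the mechanism plus the
two bundled example pairs are provided; a full cleanup list is necessarily
corpus-specific.

## Demographic inference

Name classifiers return the label whose share among the name's bearers
reaches a dominance threshold, else unknown: 0.95 for gender, 0.80 for
ethnicity (four labels make 0.95 unattainably strict for many common
surnames). The thresholds favor precision over coverage — a wrong label
poisons a whole user's posts, while an unknown merely shrinks a
denominator. Both values are keyword arguments, not constants. The bundled
name tables are small synthetic fixtures in the layout of SSA baby-name and
census surname exports (`name  label  share`, shares summing to 1 per
name); real exports convert with a one-line reshape.

Writing level uses the Flesch–Kincaid grade
`0.39·(words/sentences) + 11.8·(syllables/words) − 15.59` with these
documented modifications: the result is clamped to [0, 16] so the three
reporting bins cover the whole range (short informal posts drive the raw
formula negative; jargon can push it past any ceiling); sentence count
comes from terminal-punctuation runs with a floor of one; syllables come
from a vowel-group count with a silent-e correction and a floor of one per
word. A user's grade is the mean of per-post grades — pooling token counts
instead would let prolific users shift the formula's inputs. Bin edges are
`[0,6) → 0-5`, `[6,10) → 6-9`, `[10,16] → 10-16`; the sources print only
the labels, so the half-open edges are this package's documented choice.

## Synthetic-data generator

The generator emulates exactly the structure the statistics consume:
group-conditional token multinomials (background vocabulary + planted terms
+ sentiment words), per-post Bernoulli emotion injection, per-attribute
missingness, and one-user-per-post authorship (multi-post users optional).
Post length is Poisson (floored at one token). The manifest carries the
closed forms implied by the configured rates: `RelDif` from the rate vector
(`(r_g − mean r)/(mean r)`, which a 0.03-vs-0.01 two-group plant makes
+0.5/−0.5) and emotion percentages from the injection probabilities.

It deliberately does *not* emulate syntax, discourse, topic correlation,
Zipfian vocabularies, temporal dynamics, or user networks. Passing tests
therefore certify the *statistical machinery* — counting, thresholds,
identities, test calibration, determinism — not robustness to real
language; on real corpora the lexicon-coverage and dictionary-coverage
caveats below dominate.

Default study sizes: parameter recovery uses 2 groups × 5,000 posts with 10
planted terms at 0.03/0.01; calibration uses 500 posts/group × 1,000 null
replicates and 1,000 posts/group × 200 powered replicates; oracle
equivalence uses 200 posts (exact, so size only affects coverage). These
sizes give the planted effects standard errors an order of magnitude below
the assertion bands while keeping the whole validation suite in the
minutes range on one CPU.

## Numerical conventions and edge cases

* Tolerances: sentiment sum-to-one 1e-6 (loader and scores); RelDif
  sum-to-zero 1e-9 in assertions; oracle equivalence 1e-12.
* Empty/degenerate inputs: empty corpora, empty lexicons/dictionaries and
  <2 non-empty groups are errors; empty *groups* and unscoreable posts are
  warnings + exclusion; malformed corpus lines are counted and skipped
  unless they exceed half the file.
* Determinism: fixed seed ⇒ byte-identical generated corpora and report
  bundles; all iteration orders are sorted; the run manifest hashes the
  *contents* of input files plus parameters, so relocating identical inputs
  does not change the hash.
* The Porter stemmer implements the original published algorithm; tokens
  with digits or non-ASCII letters and all hashtags pass through
  unstemmed. The stemmer is intentionally not idempotent on arbitrary
  strings (a stripped suffix can expose another); it is idempotent on the
  fixture vocabulary, which is what the pipeline relies on.

## Known limitations

* Lexicon/dictionary coverage bounds everything: slang ("omg"), consumer
  abbreviations ("ivf"), and misspellings match nothing and silently
  reduce the scored/annotated denominators.
* No negation or word-sense handling ("no pain" scores "pain"; POS is the
  only disambiguator).
* Term variants are not merged beyond stemming: an abbreviation and its
  expansion count as different terms.
* Name-based inference is US-centric and inherits the biases of whatever
  name tables are supplied; the bundled tables are synthetic fixtures, not
  population data.
* The keyword filter is a recall/precision trade made upstream of every
  statistic; its keyword list is configuration, not a package claim.
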
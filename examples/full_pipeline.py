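"""End-to-end run: simulate a corpus, analyze it, inspect the bundle.

Generates a two-group corpus with one planted term and an anger-rate gap,
writes the matching fixture lexicons, runs the full pipeline, and prints
the stage counts plus the distinctive-terms table for the gender attribute.
Identical config + seed reproduces the bundle byte for byte.
"""

import tempfile
from pathlib import Path

from demotext import (GeneratorConfig, PlantedTerm, RunConfig,
                      generate_corpus_files, run, write_fixture_lexicons)

gen = GeneratorConfig(
    seed=11, groups=("male", "female"), posts_per_group=1000,
    post_length_mean=12.0, background_vocab_size=200,
    planted_terms=(PlantedTerm("qtermax", "male", 0.04, 0.01),),
    emotion_injection={"male": {"anger": 0.4}, "female": {"anger": 0.2}},
    sentiment_injection={g: {"positive": 0.1, "negative": 0.05}
                         for g in ("male", "female")},
    missingness={"gender": 0.1})

with tempfile.TemporaryDirectory() as tmp:
    d = Path(tmp)
    generate_corpus_files(gen, d)
    lex = write_fixture_lexicons(d)
    config = RunConfig(corpus=d / "posts.jsonl",
                       sentiment_lexicon=lex["sentiment"],
                       emotion_lexicon=lex["emotion"],
                       attributes=("gender",), out=d / "reports", seed=11)
    result = run(config)

    print("stage counts:")
    for key, val in result.counts.items():
        print(f"  {key}: {val}")
    print("\ndistinctive terms by gender:")
    print((result.outdir / "terms_gender.tsv").read_text())
    print("emotions by gender ('*' = P<=.05 vs rest):")
    print((result.outdir / "emotions_gender.tsv").read_text())
# About 10% of users omit gender, so posts_annotated_gender < posts_read;
# the planted term heads the male list with RelDif near +0.5.
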
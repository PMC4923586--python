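"""Score posts against sentiment/emotion lexicons and compare groups.

Builds the fixture lexicons, scores a handful of hand-written posts, then
aggregates two synthetic groups with different anger-injection rates and
prints the emotion table with group-vs-rest significance markers.
"""

import tempfile
from pathlib import Path

from demotext import (GeneratorConfig, generate_corpus, load_emotion_lexicon,
                      load_sentiment_lexicon, partition_posts, score_post,
                      write_fixture_lexicons)
from demotext.lexicon import aggregate_groups
from demotext.pipeline import report_emotion_table

with tempfile.TemporaryDirectory() as tmp:
    paths = write_fixture_lexicons(Path(tmp))
    slex = load_sentiment_lexicon(paths["sentiment"])
    elex = load_emotion_lexicon(paths["emotion"])

for text in ("I had a heart attack and it hurt",
             "feeling happy and good today",
             "nothing matching here"):
    s = score_post(text, slex, elex)
    if s.sentiment.scored:
        print(f"{text!r}: pos={s.sentiment.positive:.3f} "
              f"neg={s.sentiment.negative:.3f} obj={s.sentiment.objective:.3f} "
              f"({s.sentiment.n_matched} matches)")
    else:
        print(f"{text!r}: unscored (no lexicon match)")

# Group comparison: male posts get an anger cue word in 40% of posts,
# female posts in 20%; the two-proportion z-test should flag the gap.
config = GeneratorConfig(seed=7, groups=("male", "female"), posts_per_group=800,
                         post_length_mean=10.0, background_vocab_size=100,
                         emotion_injection={"male": {"anger": 0.40},
                                            "female": {"anger": 0.20}},
                         sentiment_injection={g: {"positive": 0.15}
                                              for g in ("male", "female")})
posts, profiles, _ = generate_corpus(config)
partition = partition_posts(posts, {p.user_id: p for p in profiles}, "gender")
scores = {g: [score_post(p.text, slex, elex) for p in ps]
          for g, ps in partition.items()}
print("\n" + report_emotion_table(aggregate_groups(scores)))
# '*' marks cells where the group differs from the union of the other
# groups at P <= .05; anger should carry the marker in both rows, with
# percentages near the injected 40% and 20%.
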
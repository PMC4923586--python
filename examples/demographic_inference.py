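"""Infer demographics: name classifiers and writing-level grading.

First names map to gender and surnames to ethnicity only when one label
holds a dominant share of the name's bearers (0.95 / 0.80); ambiguous
names stay unknown. Writing level is a clamped Flesch-Kincaid grade,
averaged over a user's posts and binned as 0-5 / 6-9 / 10-16.
"""

from demotext import (classify_ethnicity, classify_gender, grade_text,
                      load_name_table, user_writing_level)
from demotext.corpus import ETHNICITIES, GENDERS
from demotext.pipeline import _PKG_DATA

first = load_name_table(_PKG_DATA / "names_first.tsv", GENDERS)
last = load_name_table(_PKG_DATA / "names_last.tsv", ETHNICITIES)

for name in ("Mary", "James", "Taylor", "Zzyzx"):
    print(f"first name {name:<7} -> {classify_gender(name, first)}")
for name in ("Garcia", "Nguyen", "Lee", "Smith"):
    print(f"surname    {name:<7} -> {classify_ethnicity(name, last)}")

texts = ["The cat sat on the mat.",
         "Subsequent observations nevertheless demonstrated considerable "
         "variability throughout the longitudinal evaluation."]
for t in texts:
    print(f"\n{t!r}\n  grade = {grade_text(t):.2f}")
wl = user_writing_level(texts)
print(f"\nuser mean grade = {wl.grade:.2f} -> bin {wl.bin}")
# Taylor and Lee stay unknown: no label reaches the dominance bar, and a
# forced guess would mislabel a large minority of bearers. The second text's
# polysyllabic words push its grade toward the clamp ceiling of 16.
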
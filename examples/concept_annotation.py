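"""Annotate posts with medical concepts from the bundled dictionary.

Shows greedy longest-match (two-token "heart attack" beats lone "heart"),
semantic-group filtering (Anatomy is matched but not reported), and the
misclassification blacklist (the letter "i" would otherwise map to an
immunologic-factor concept).
"""

from demotext import annotate, load_blacklist, load_dictionary
from demotext.pipeline import _PKG_DATA

dictionary = load_dictionary(_PKG_DATA / "concepts.tsv")
blacklist = load_blacklist(_PKG_DATA / "blacklist.tsv")

texts = [
    "I think i had a heart attack last night",
    "my migraines are worse than my headaches",
    "taking lisinopril for high blood pressure",
    "my liver hurts",
]
for text in texts:
    anns = annotate(text, dictionary, blacklist)
    print(f"{text!r}")
    for a in anns:
        print(f"    {a.concept_id}  {a.surface!r}  [{a.semantic_group}]")
    if not anns:
        print("    (no Disorders / Chemicals & Drugs annotations)")

print("\nwithout the blacklist, the post 'i' alone would annotate as:")
print("   ", annotate("i", dictionary, frozenset()))
# Only Disorders and Chemicals & Drugs concepts are reported by default;
# 'my liver hurts' matches an Anatomy concept internally and prints none.
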
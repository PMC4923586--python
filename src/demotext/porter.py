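"""Porter suffix-stripping stemmer.

Implements the original 1980 algorithm (steps 1a-5b) so that inflectional
variants collapse to a shared root before frequency counting and lexicon
lookup, e.g. ``headaches -> headach``, ``running -> run``. The algorithm is
defined on lowercase ASCII words; tokens containing digits or non-ASCII
letters are returned unchanged by :func:`stem` (they carry no English
morphology worth stripping).
"""

from __future__ import annotations

from functools import lru_cache

_VOWELS = frozenset("aeiou")


class _Word:
    """Mutable word buffer with the measure/condition helpers of the algorithm."""

    __slots__ = ("b", "k")

    def __init__(self, word: str) -> None:
        self.b = list(word)
        self.k = len(word) - 1  # index of last letter of the current stem

    def _cons(self, i: int) -> bool:
        ch = self.b[i]
        if ch in _VOWELS:
            return False
        if ch == "y":
            return True if i == 0 else not self._cons(i - 1)
        return True

    def measure(self, j: int) -> int:
        """Number of VC sequences in b[0..j]."""
        n = 0
        i = 0
        while True:
            if i > j:
                return n
            if not self._cons(i):
                break
            i += 1
        i += 1
        while True:
            while True:
                if i > j:
                    return n
                if self._cons(i):
                    break
                i += 1
            i += 1
            n += 1
            while True:
                if i > j:
                    return n
                if not self._cons(i):
                    break
                i += 1
            i += 1

    def vowel_in_stem(self, j: int) -> bool:
        return any(not self._cons(i) for i in range(j + 1))

    def double_cons(self, j: int) -> bool:
        if j < 1:
            return False
        return self.b[j] == self.b[j - 1] and self._cons(j)

    def cvc(self, i: int) -> bool:
        """cons-vowel-cons ending at i, where the final cons is not w, x or y."""
        if i < 2 or not self._cons(i) or self._cons(i - 1) or not self._cons(i - 2):
            return False
        return self.b[i] not in ("w", "x", "y")

    def ends(self, s: str) -> int | None:
        """Return the index just before suffix s if the stem ends with it."""
        length = len(s)
        j = self.k - length + 1
        if j < 0 or "".join(self.b[j : self.k + 1]) != s:
            return None
        return j - 1

    def set_to(self, j: int, s: str) -> None:
        """Replace everything after index j with s."""
        self.b[j + 1 :] = list(s)
        self.k = j + len(s)


def _step1ab(w: _Word) -> None:
    if w.b[w.k] == "s":
        if (j := w.ends("sses")) is not None:
            w.set_to(j, "ss")
        elif (j := w.ends("ies")) is not None:
            w.set_to(j, "i")
        elif w.k >= 1 and w.b[w.k - 1] != "s":
            w.k -= 1
    if (j := w.ends("eed")) is not None:
        if w.measure(j) > 0:
            w.k -= 1
        return
    hit = None
    for suf in ("ed", "ing"):
        if (j := w.ends(suf)) is not None:
            if w.vowel_in_stem(j):
                hit = j
            break
    if hit is None:
        return
    w.set_to(hit, "")
    for old, new in (("at", "ate"), ("bl", "ble"), ("iz", "ize")):
        if (j := w.ends(old)) is not None:
            w.set_to(j, new)
            return
    if w.double_cons(w.k) and w.b[w.k] not in ("l", "s", "z"):
        w.k -= 1
    elif w.measure(w.k) == 1 and w.cvc(w.k):
        w.set_to(w.k, "e")


def _step1c(w: _Word) -> None:
    if w.b[w.k] == "y" and w.vowel_in_stem(w.k - 1):
        w.b[w.k] = "i"


_STEP2 = (
    ("ational", "ate"), ("tional", "tion"), ("enci", "ence"), ("anci", "ance"),
    ("izer", "ize"), ("abli", "able"), ("alli", "al"), ("entli", "ent"),
    ("eli", "e"), ("ousli", "ous"), ("ization", "ize"), ("ation", "ate"),
    ("ator", "ate"), ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
    ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"), ("biliti", "ble"),
)

_STEP3 = (
    ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
    ("ical", "ic"), ("ful", ""), ("ness", ""),
)

_STEP4 = (
    "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement",
    "ment", "ent", "ion", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
)


def _map_suffixes(w: _Word, table) -> None:
    for old, new in table:
        if (j := w.ends(old)) is not None:
            if w.measure(j) > 0:
                w.set_to(j, new)
            return


def _step4(w: _Word) -> None:
    for suf in _STEP4:
        if (j := w.ends(suf)) is not None:
            if suf == "ion" and (j < 0 or w.b[j] not in ("s", "t")):
                return
            if w.measure(j) > 1:
                w.k = j
            return


def _step5(w: _Word) -> None:
    if w.b[w.k] == "e":
        m = w.measure(w.k - 1)
        if m > 1 or (m == 1 and not w.cvc(w.k - 1)):
            w.k -= 1
    if w.b[w.k] == "l" and w.double_cons(w.k) and w.measure(w.k - 1) > 1:
        w.k -= 1


@lru_cache(maxsize=262144)
def stem(word: str) -> str:
    """Return the Porter stem of *word* (lowercased first).

    Words of length <= 2 and tokens that are not pure ASCII letters are
    returned lowercase-unchanged.
    """
    word = word.lower()
    if len(word) <= 2 or not word.isascii() or not word.isalpha():
        return word
    w = _Word(word)
    _step1ab(w)
    _step1c(w)
    _map_suffixes(w, _STEP2)
    _map_suffixes(w, _STEP3)
    _step4(w)
    _step5(w)
    return "".join(w.b[: w.k + 1])
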
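"""Porter stemming algorithm.

Classic rule-based suffix stripper for English (Porter, 1980). Implemented
here so stemming behaviour is pinned to this module rather than to an
external NLP distribution whose word lists or rule variants may drift.
Operates on lower-case ASCII-ish tokens; non-alphabetic tokens are returned
unchanged.
"""

from __future__ import annotations

_VOWELS = "aeiou"


def _is_consonant(word: str, i: int) -> bool:
    ch = word[i]
    if ch in _VOWELS:
        return False
    if ch == "y":
        return i == 0 or not _is_consonant(word, i - 1)
    return True


def _measure(stem: str) -> int:
    """Number of VC sequences in [C](VC)^m[V] decomposition."""
    m = 0
    prev_vowel = False
    for i in range(len(stem)):
        if _is_consonant(stem, i):
            if prev_vowel:
                m += 1
            prev_vowel = False
        else:
            prev_vowel = True
    return m


def _contains_vowel(stem: str) -> bool:
    return any(not _is_consonant(stem, i) for i in range(len(stem)))


def _ends_double_consonant(word: str) -> bool:
    return (
        len(word) >= 2
        and word[-1] == word[-2]
        and _is_consonant(word, len(word) - 1)
    )


def _ends_cvc(word: str) -> bool:
    if len(word) < 3:
        return False
    if not (
        _is_consonant(word, len(word) - 3)
        and not _is_consonant(word, len(word) - 2)
        and _is_consonant(word, len(word) - 1)
    ):
        return False
    return word[-1] not in "wxy"


def _replace(word: str, suffix: str, repl: str, min_measure: int) -> str | None:
    if not word.endswith(suffix):
        return None
    stem = word[: len(word) - len(suffix)]
    if _measure(stem) > min_measure - 1:
        return stem + repl
    return word


def _step1(word: str) -> str:
    # plurals and -ed / -ing
    if word.endswith("sses"):
        word = word[:-2]
    elif word.endswith("ies"):
        word = word[:-2]
    elif word.endswith("ss"):
        pass
    elif word.endswith("s"):
        word = word[:-1]

    if word.endswith("eed"):
        stem = word[:-3]
        if _measure(stem) > 0:
            word = word[:-1]
    elif word.endswith("ed") and _contains_vowel(word[:-2]):
        word = word[:-2]
        word = _step1_fixup(word)
    elif word.endswith("ing") and _contains_vowel(word[:-3]):
        word = word[:-3]
        word = _step1_fixup(word)

    if word.endswith("y") and _contains_vowel(word[:-1]):
        word = word[:-1] + "i"
    return word


def _step1_fixup(word: str) -> str:
    if word.endswith(("at", "bl", "iz")):
        return word + "e"
    if _ends_double_consonant(word) and not word.endswith(("l", "s", "z")):
        return word[:-1]
    if _measure(word) == 1 and _ends_cvc(word):
        return word + "e"
    return word


_STEP2 = [
    ("ational", "ate"), ("tional", "tion"), ("enci", "ence"), ("anci", "ance"),
    ("izer", "ize"), ("abli", "able"), ("alli", "al"), ("entli", "ent"),
    ("eli", "e"), ("ousli", "ous"), ("ization", "ize"), ("ation", "ate"),
    ("ator", "ate"), ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
    ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"), ("biliti", "ble"),
]

_STEP3 = [
    ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
    ("ical", "ic"), ("ful", ""), ("ness", ""),
]

_STEP4 = [
    "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement",
    "ment", "ent", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
]


def stem(word: str) -> str:
    """Return the Porter stem of ``word`` (lower-cased first).

    Words of length <= 2 and tokens containing non-letters are returned
    as-is (lower-cased), so identifiers and numbers pass through.
    """
    word = word.lower()
    if len(word) <= 2 or not word.isalpha():
        return word

    word = _step1(word)

    for suffix, repl in _STEP2:
        out = _replace(word, suffix, repl, 1)
        if out is not None:
            word = out
            break

    for suffix, repl in _STEP3:
        out = _replace(word, suffix, repl, 1)
        if out is not None:
            word = out
            break

    for suffix in _STEP4:
        if word.endswith(suffix):
            stem_ = word[: len(word) - len(suffix)]
            if suffix == "ion" and not stem_.endswith(("s", "t")):
                continue
            if _measure(stem_) > 1:
                word = stem_
            break
    else:
        # special -ion handling: strip only after s/t
        if word.endswith("ion") and word[:-3].endswith(("s", "t")):
            if _measure(word[:-3]) > 1:
                word = word[:-3]

    # step 5a
    if word.endswith("e"):
        stem_ = word[:-1]
        m = _measure(stem_)
        if m > 1 or (m == 1 and not _ends_cvc(stem_)):
            word = stem_
    # step 5b
    if _measure(word) > 1 and _ends_double_consonant(word) and word.endswith("l"):
        word = word[:-1]
    return word
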
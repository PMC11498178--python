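"""English suffix stemming for dictionary-key normalization.

A self-contained implementation of Porter's 1980 suffix-stripping algorithm.
Only the behavior matters here: inflectional variants of finding terms
("flattened"/"flatten", "creases"/"crease") must collapse to one dictionary
key.  The stemmer is injectable wherever keys are built, so a different
Porter-family stemmer can be substituted without touching the dictionary
logic.
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
    """Number of vowel->consonant transitions ([C](VC)^m[V])."""
    m = 0
    prev_cons = None
    for i in range(len(stem)):
        cons = _is_consonant(stem, i)
        if prev_cons is False and cons:
            m += 1
        prev_cons = cons
    return m


def _contains_vowel(stem: str) -> bool:
    return any(not _is_consonant(stem, i) for i in range(len(stem)))


def _ends_double_consonant(stem: str) -> bool:
    return (len(stem) >= 2 and stem[-1] == stem[-2]
            and _is_consonant(stem, len(stem) - 1))


def _ends_cvc(stem: str) -> bool:
    """consonant-vowel-consonant ending, final consonant not w, x or y."""
    if len(stem) < 3:
        return False
    return (_is_consonant(stem, len(stem) - 3)
            and not _is_consonant(stem, len(stem) - 2)
            and _is_consonant(stem, len(stem) - 1)
            and stem[-1] not in "wxy")


def _replace(word: str, suffix: str, replacement: str) -> str:
    return word[: len(word) - len(suffix)] + replacement


def _step1a(w: str) -> str:
    if w.endswith("sses"):
        return _replace(w, "sses", "ss")
    if w.endswith("ies"):
        return _replace(w, "ies", "i")
    if w.endswith("ss"):
        return w
    if w.endswith("s"):
        return w[:-1]
    return w


def _step1b(w: str) -> str:
    if w.endswith("eed"):
        stem = w[:-3]
        return _replace(w, "eed", "ee") if _measure(stem) > 0 else w
    flag = False
    if w.endswith("ed") and _contains_vowel(w[:-2]):
        w, flag = w[:-2], True
    elif w.endswith("ing") and _contains_vowel(w[:-3]):
        w, flag = w[:-3], True
    if flag:
        if w.endswith(("at", "bl", "iz")):
            return w + "e"
        if _ends_double_consonant(w) and w[-1] not in "lsz":
            return w[:-1]
        if _measure(w) == 1 and _ends_cvc(w):
            return w + "e"
    return w


def _step1c(w: str) -> str:
    if w.endswith("y") and _contains_vowel(w[:-1]):
        return w[:-1] + "i"
    return w


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
    "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement", "ment",
    "ent", "ion", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
]


def _rule_pass(w: str, rules, min_measure: int) -> str:
    for suffix, replacement in rules:
        if w.endswith(suffix):
            stem = w[: len(w) - len(suffix)]
            if _measure(stem) > min_measure - 1:
                return stem + replacement
            return w
    return w


def _step4(w: str) -> str:
    for suffix in _STEP4:
        if w.endswith(suffix):
            stem = w[: len(w) - len(suffix)]
            if suffix == "ion" and (not stem or stem[-1] not in "st"):
                return w
            return stem if _measure(stem) > 1 else w
    return w


def _step5(w: str) -> str:
    if w.endswith("e"):
        stem = w[:-1]
        m = _measure(stem)
        if m > 1 or (m == 1 and not _ends_cvc(stem)):
            w = stem
    if _measure(w) > 1 and _ends_double_consonant(w) and w.endswith("l"):
        w = w[:-1]
    return w


def porter_stem(word: str) -> str:
    """Stem one lower-case word; words of length <= 2 are returned as-is."""
    if len(word) <= 2:
        return word
    w = _step1a(word)
    w = _step1b(w)
    w = _step1c(w)
    w = _rule_pass(w, _STEP2, min_measure=1)
    w = _rule_pass(w, _STEP3, min_measure=1)
    w = _step4(w)
    w = _step5(w)
    return w
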
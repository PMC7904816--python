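"""Light inflectional stemmer for relation words.

Relation words harvested from parse trees are inflected verbs and
deverbal nouns ("causes", "caused", "associated", "implicated").  For
aggregation they are reduced to a common stem so that e.g. "causes" and
"caused" count as the same relation.  Only the inflectional suffixes
-s/-es/-ed/-ing are stripped (with the classic AT->ATE / BL->BLE /
IZ->IZE / doubled-consonant repairs), which maps

    causes -> cause      associated -> associate
    caused -> cause      implicated -> implicate

Heavier derivational stemming is deliberately avoided: it would collapse
"associate" to "associ" and lose the surface readability of the output
triplets.  Chunked relation words such as "common_cause" are stemmed per
underscore-separated component.
"""

from __future__ import annotations

import re

_VOWEL = set("aeiou")


def _has_vowel(word: str) -> bool:
    return any(c in _VOWEL or (c == "y" and i > 0) for i, c in enumerate(word))


def _measure(word: str) -> int:
    """Number of vowel->consonant transitions (Porter's m)."""
    pattern = ""
    for i, c in enumerate(word):
        is_v = c in _VOWEL or (c == "y" and i > 0 and word[i - 1] not in _VOWEL)
        pattern += "V" if is_v else "C"
    return len(re.findall("VC", pattern))


def _ends_cvc(word: str) -> bool:
    if len(word) < 3:
        return False
    c1, v, c2 = word[-3], word[-2], word[-1]
    return (
        c1 not in _VOWEL
        and (v in _VOWEL or v == "y")
        and c2 not in _VOWEL
        and c2 not in "wxy"
    )


def _stem_token(word: str) -> str:
    w = word.lower()
    if len(w) <= 3:
        return w
    # plural / 3rd-person -s
    if w.endswith("sses"):
        w = w[:-2]
    elif w.endswith("ies"):
        w = w[:-3] + "i"
    elif w.endswith("ss"):
        pass
    elif w.endswith("s"):
        w = w[:-1]
    # past / progressive
    stripped = None
    if w.endswith("eed"):
        if _measure(w[:-3]) > 0:
            w = w[:-1]
    elif w.endswith("ed") and _has_vowel(w[:-2]):
        stripped = w[:-2]
    elif w.endswith("ing") and _has_vowel(w[:-3]):
        stripped = w[:-3]
    if stripped is not None:
        if stripped.endswith(("at", "bl", "iz")):
            w = stripped + "e"
        elif (
            len(stripped) >= 2
            and stripped[-1] == stripped[-2]
            and stripped[-1] not in "lsz"
            and stripped[-1] not in _VOWEL
        ):
            w = stripped[:-1]
        elif _measure(stripped) == 1 and _ends_cvc(stripped):
            w = stripped + "e"
        else:
            w = stripped
    return w


def stem(word: str) -> str:
    """Stem a relation word; multi-part chunks are stemmed per component."""
    return "_".join(_stem_token(part) for part in word.split("_") if part)
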
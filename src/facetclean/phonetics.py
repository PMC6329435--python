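"""Phonetic word coders used by the key-collision clustering stages.

Two coders are provided:

``metaphone``
    A Metaphone-family consonant-skeleton code for English pronunciation
    (the classic rule set: vowels are kept only word-initially, consonant
    digraphs such as CH/SH/TH/PH collapse to single codes, soft/hard C and G
    are disambiguated by the following letter). Words that differ only in
    vowel content or ordering — the typical hurried-typing error — receive
    the same code.

``cologne``
    The Kölner Phonetik digit code: context-sensitive letter→digit rules,
    adjacent duplicate codes collapsed, zeros (vowels) deleted except in the
    leading position. Designed for German orthography but effective on
    Latin binomial nomenclature.

Both operate on single words; non-alphabetic characters are ignored after
ASCII folding.
"""

from __future__ import annotations

from ._fold import fold

_VOWELS = "AEIOU"


def _letters(word: str) -> str:
    return "".join(ch for ch in fold(word).upper() if ch.isalpha())


def metaphone(word: str) -> str:
    """Return the classic-Metaphone code of a single word.

    Empty or letter-free input yields the empty code.
    """
    w = _letters(word)
    if not w:
        return ""
    # word-initial exceptions
    if w[:2] in ("AE", "GN", "KN", "PN", "WR"):
        w = w[1:]
    elif w[0] == "X":
        w = "S" + w[1:]
    elif w[:2] == "WH":
        w = "W" + w[2:]

    out: list[str] = []
    i, n = 0, len(w)
    while i < n:
        c = w[i]
        if i > 0 and c == w[i - 1] and c != "C":
            i += 1
            continue
        prev = w[i - 1] if i > 0 else ""
        nxt = w[i + 1] if i + 1 < n else ""
        nxt2 = w[i + 2] if i + 2 < n else ""

        if c in _VOWELS:
            if i == 0:
                out.append(c)
        elif c == "B":
            if not (i == n - 1 and prev == "M"):
                out.append("B")
        elif c == "C":
            if nxt == "I" and nxt2 == "A":
                out.append("X")
            elif nxt == "H":
                out.append("K" if prev == "S" else "X")
                i += 1  # the H is part of the digraph
            elif nxt in "IEY":
                out.append("S")
            else:
                out.append("K")
        elif c == "D":
            if nxt == "G" and nxt2 in "EIY":
                out.append("J")
            else:
                out.append("T")
        elif c == "F":
            out.append("F")
        elif c == "G":
            if nxt == "H":
                if i + 2 < n and w[i + 2] in _VOWELS:
                    out.append("K")
                # -GH at end or before a consonant is silent
                i += 1
            elif nxt == "N":
                # -GN and -GNED are silent
                if not (i + 2 >= n or (w[i + 2:i + 4] == "ED" and i + 4 >= n)):
                    out.append("K")
            elif prev == "D" and nxt in "EIY":
                pass  # coded as J at the D
            elif nxt in "EIY":
                out.append("J")
            else:
                out.append("K")
        elif c == "H":
            if prev in _VOWELS and nxt not in _VOWELS:
                pass
            elif prev in "CSPTG":
                pass  # trailing half of a digraph
            else:
                out.append("H")
        elif c == "J":
            out.append("J")
        elif c == "K":
            if prev != "C":
                out.append("K")
        elif c in "LMNR":
            out.append(c)
        elif c == "P":
            if nxt == "H":
                out.append("F")
                i += 1
            else:
                out.append("P")
        elif c == "Q":
            out.append("K")
        elif c == "S":
            if nxt == "H":
                out.append("X")
                i += 1
            elif nxt == "I" and nxt2 in ("O", "A"):
                out.append("X")
            else:
                out.append("S")
        elif c == "T":
            if nxt == "H":
                out.append("0")  # theta
                i += 1
            elif nxt == "I" and nxt2 in ("O", "A"):
                out.append("X")
            elif nxt == "C" and nxt2 == "H":
                pass  # -TCH-: the T is silent
            else:
                out.append("T")
        elif c == "V":
            out.append("F")
        elif c == "W":
            if nxt in _VOWELS:
                out.append("W")
        elif c == "X":
            out.append("KS")
        elif c == "Y":
            if nxt in _VOWELS:
                out.append("Y")
        elif c == "Z":
            out.append("S")
        i += 1
    return "".join(out)


def cologne(word: str) -> str:
    """Return the Kölner Phonetik digit code of a single word.

    A letter-free token consisting of digits is treated as an
    already-computed code and returned unchanged (making the keyer
    idempotent); other input with no codable letters yields the empty code.
    """
    w = _letters(word)
    if not w:
        digits = "".join(ch for ch in word if ch.isdigit())
        return digits
    codes: list[str] = []
    for i, c in enumerate(w):
        prev = w[i - 1] if i > 0 else ""
        nxt = w[i + 1] if i + 1 < len(w) else ""
        if c in "AEIJOUY":
            d = "0"
        elif c == "H":
            d = ""
        elif c == "B":
            d = "1"
        elif c == "P":
            d = "3" if nxt == "H" else "1"
        elif c in "DT":
            d = "8" if nxt in "CSZ" else "2"
        elif c in "FVW":
            d = "3"
        elif c in "GKQ":
            d = "4"
        elif c == "C":
            if i == 0:
                d = "4" if nxt in "AHKLOQRUX" else "8"
            elif prev in "SZ":
                d = "8"
            elif nxt in "AHKOQUX":
                d = "4"
            else:
                d = "8"
        elif c == "X":
            d = "8" if prev in "CKQ" else "48"
        elif c == "L":
            d = "5"
        elif c in "MN":
            d = "6"
        elif c == "R":
            d = "7"
        elif c in "SZ":
            d = "8"
        else:
            d = ""
        codes.append(d)
    raw = "".join(codes)
    collapsed: list[str] = []
    for ch in raw:
        if not collapsed or collapsed[-1] != ch:
            collapsed.append(ch)
    if not collapsed:
        return ""
    return collapsed[0] + "".join(ch for ch in collapsed[1:] if ch != "0")
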
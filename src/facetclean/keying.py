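"""Key-collision key functions.

Key collision clusters a column of strings by mapping every value to a
normalised *key* and grouping values that share one. Each key function keeps
only what it considers the significant part of a string:

- ``fingerprint_key``: case-, punctuation- and token-order-insensitive.
- ``ngram_fingerprint_key``: the sorted set of distinct character n-grams;
  at n=1 anagrams (adjacent-transposition typos) collide.
- ``phonetic_en_key``: Metaphone-family English pronunciation code.
- ``phonetic_cologne_key``: Kölner Phonetik digit code.

All four are deterministic and idempotent on their own output. An empty key
is never treated as a collision by the clustering engine.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._fold import fold
from .phonetics import cologne, metaphone

KEY_METHODS = ("fingerprint", "ngram_fingerprint", "phonetic_en", "phonetic_cologne")


@dataclass(frozen=True)
class KeySpec:
    """Configuration of one key-collision stage.

    Parameters
    ----------
    method : str
        One of ``fingerprint``, ``ngram_fingerprint``, ``phonetic_en``,
        ``phonetic_cologne``.
    ngram_size : int, default 2
        Character n-gram length; meaningful only for ``ngram_fingerprint``.
        The default pipeline runs both size 2 and size 1.
    """

    method: str
    ngram_size: int = 2

    def __post_init__(self) -> None:
        if self.method not in KEY_METHODS:
            raise ValueError(
                f"unknown key method {self.method!r}; expected one of {KEY_METHODS}"
            )
        if self.ngram_size < 1:
            raise ValueError("ngram_size must be >= 1")

    @property
    def method_id(self) -> str:
        if self.method == "ngram_fingerprint":
            return f"ngram_fingerprint(n={self.ngram_size})"
        return self.method


def fingerprint_key(value: str) -> str:
    """Whitespace/case/punctuation/token-order-insensitive key.

    Steps: trim; lowercase; fold accents to ASCII; replace punctuation and
    control characters with spaces; split on whitespace; drop duplicate
    tokens; sort; rejoin with single spaces. Punctuation becomes a token
    boundary (not deletion), so ``"G.lamblia"`` keys as ``"g lamblia"`` and
    does not collide with ``"Lamblia"``.
    """
    s = fold(value.strip().lower())
    s = "".join(ch if ch.isalnum() else " " for ch in s)
    return " ".join(sorted(set(s.split())))


def ngram_fingerprint_key(value: str, n: int = 2) -> str:
    """Sorted distinct character n-grams of the punctuation-free string.

    Whitespace is removed entirely, so the key spans token boundaries.
    Strings shorter than ``n`` (after stripping) yield the empty key.
    For ``n=1`` two strings collide exactly when their character *sets*
    coincide, which unites anagram-class typos such as transpositions.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    s = fold(value.lower())
    s = "".join(ch for ch in s if ch.isalnum())
    grams = {s[i:i + n] for i in range(len(s) - n + 1)}
    return "".join(sorted(grams))


def _tokenwise(value: str, coder) -> str:
    return " ".join(
        code for code in (coder(tok) for tok in value.strip().split()) if code
    )


def phonetic_en_key(value: str) -> str:
    """English-pronunciation key (Metaphone-family consonant skeleton).

    Multi-token values are keyed token-by-token and joined with single
    spaces. Empty input yields the empty key.
    """
    return _tokenwise(value, metaphone)


def phonetic_cologne_key(value: str) -> str:
    """Kölner Phonetik digit key, token-by-token for multi-token values."""
    return _tokenwise(value, cologne)


def key_for(value: str, spec: KeySpec) -> str:
    """Apply the key function selected by *spec* to *value*."""
    if spec.method == "fingerprint":
        return fingerprint_key(value)
    if spec.method == "ngram_fingerprint":
        return ngram_fingerprint_key(value, spec.ngram_size)
    if spec.method == "phonetic_en":
        return phonetic_en_key(value)
    return phonetic_cologne_key(value)
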
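"""Distance functions: oracle equivalence, metric axioms, conventions."""

import itertools
import random
import sys
from functools import lru_cache

import edlib
import pytest
from hypothesis import given
from hypothesis import strategies as st

from facetclean.distance import (
    DistanceSpec,
    Order2Compressor,
    compression_distance,
    inconsistency_rate,
    levenshtein,
    normalized_levenshtein,
)


@lru_cache(maxsize=None)
def lev_recursive(a: str, b: str) -> int:
    """Independent brute-force oracle: textbook recursion on suffixes."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    return min(
        lev_recursive(a[1:], b) + 1,
        lev_recursive(a, b[1:]) + 1,
        lev_recursive(a[1:], b[1:]) + (a[0] != b[0]),
    )


def all_abc_strings(max_len: int):
    for length in range(max_len + 1):
        for tup in itertools.product("abc", repeat=length):
            yield "".join(tup)


@pytest.mark.parametrize("a,b,expected", [
    ("native", "negative", 2),
    ("negaitve", "negative", 2),
    ("", "abc", 3),
    ("kitten", "sitting", 3),
    ("x", "x", 0),
    ("  Negative ", "negative", 0),  # trimmed and lowercased before comparing
])
def test_levenshtein_examples(a, b, expected):
    assert levenshtein(a, b) == expected


def test_levenshtein_matches_recursive_oracle_on_abc_universe():
    sys.setrecursionlimit(10000)
    strings = list(all_abc_strings(5))
    for a in strings:
        for b in strings:
            assert levenshtein(a, b) == lev_recursive(a, b), (a, b)


def test_levenshtein_matches_edlib_on_random_words():
    rnd = random.Random(0)
    alphabet = "abcdefghij"
    for _ in range(500):
        a = "".join(rnd.choice(alphabet) for _ in range(rnd.randint(0, 15)))
        b = "".join(rnd.choice(alphabet) for _ in range(rnd.randint(0, 15)))
        expected = edlib.align(a, b)["editDistance"] if (a or b) else 0
        assert levenshtein(a, b) == expected


short = st.text(alphabet="abcde", max_size=8)


@given(short, short, short)
def test_levenshtein_metric_axioms(a, b, c):
    dab, dba = levenshtein(a, b), levenshtein(b, a)
    assert dab == dba
    assert (dab == 0) is (a == b)
    assert dab <= levenshtein(a, c) + levenshtein(c, b)


@pytest.mark.parametrize("a,b,expected", [
    ("eolimax", "endolimax", 2 / 9),
    ("negaitve", "negative", 2 / 8),
    ("same", "same", 0.0),
])
def test_normalized_levenshtein_examples(a, b, expected):
    assert normalized_levenshtein(a, b) == pytest.approx(expected)


def test_normalized_levenshtein_two_empty_is_error():
    with pytest.raises(ValueError, match="empty"):
        normalized_levenshtein("", "   ")


@given(short, short)
def test_normalized_levenshtein_in_unit_interval(a, b):
    if not a.strip() and not b.strip():
        return
    assert 0 <= normalized_levenshtein(a, b) <= 1


def test_normalized_levenshtein_disjoint_alphabets():
    assert normalized_levenshtein("aaaa", "bbbb") == 1.0


@pytest.mark.parametrize("typo,correct,expected", [
    ("native", "negative", 33),   # 2 of the typo's 6 characters diverge
    ("lamdlia", "lamblia", 14),   # 100 * 1/7
    ("same", "same", 0),
])
def test_inconsistency_rate_examples(typo, correct, expected):
    assert inconsistency_rate(typo, correct) == expected


def test_inconsistency_rate_empty_typo_is_error():
    with pytest.raises(ValueError, match="non-empty"):
        inconsistency_rate("  ", "negative")


def test_compression_distance_symmetric_and_floor():
    d_self = compression_distance("negative", "negative")
    d_edit = compression_distance("negative", "native")
    d_far = compression_distance("negative", "clonorchis")
    assert compression_distance("abcd", "wxyz") == compression_distance("wxyz", "abcd")
    assert d_self == pytest.approx(1.0)  # the built-in model's floor
    assert d_self <= d_edit <= d_far


def test_compression_distance_separates_edits_from_unrelated():
    """One-edit variants score closer than random unrelated strings in at
    least 95% of 1000 seeded trials."""
    rnd = random.Random(123)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    wins = 0
    for _ in range(1000):
        a = "".join(rnd.choice(alphabet) for _ in range(20))
        unrelated = "".join(rnd.choice(alphabet) for _ in range(20))
        i = rnd.randrange(20)
        variant = a[:i] + rnd.choice(alphabet.replace(a[i], "")) + a[i + 1:]
        if compression_distance(a, unrelated) > compression_distance(a, variant):
            wins += 1
    assert wins >= 950


def test_compressor_pluggable_and_validated():
    class LengthCompressor:
        def cost_bits(self, data: bytes) -> float:
            return 8.0 * len(data)

    # a length-only compressor cannot discriminate: every ratio is 1
    assert compression_distance("abc", "xyz", LengthCompressor()) == 1.0
    with pytest.raises(ValueError):
        Order2Compressor(alpha=0)


def test_distancespec_validation():
    with pytest.raises(ValueError, match="unknown distance method"):
        DistanceSpec("jaro", 0.2)
    with pytest.raises(ValueError, match="threshold"):
        DistanceSpec("levenshtein", -1)
    with pytest.raises(ValueError, match="in \\[0, 1\\]"):
        DistanceSpec("normalized_levenshtein", 1.5)
    with pytest.raises(ValueError, match="block_chars"):
        DistanceSpec("levenshtein", 2, block_chars=0)
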
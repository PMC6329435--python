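"""String distances for nearest-neighbour clustering.

Nearest-neighbour clustering joins two values when their string distance
falls within a radius. All comparisons are performed on lowercased,
whitespace-trimmed forms: case variants are the business of the key-collision
stages, and distance should not double-count them.

Two normalisation conventions coexist deliberately:

- clustering uses ``normalized_levenshtein`` — edits divided by the *longer*
  length — which separates near-misses on short words ("negaitve" vs
  "negative": 2/8 = 0.25) from recoverable drops on longer words
  ("eolimax" vs "endolimax": 2/9 ≈ 0.222) at the default radius 0.23;
- ``inconsistency_rate`` divides by the *shorter* length, the convention
  used when reporting how badly a typo diverges from its correct word
  ("native" vs "negative": 2/6 → 33%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

DISTANCE_METHODS = ("levenshtein", "normalized_levenshtein", "compression")


@dataclass(frozen=True)
class DistanceSpec:
    """Configuration of one nearest-neighbour stage.

    Parameters
    ----------
    method : str
        ``levenshtein`` (integer radius), ``normalized_levenshtein``
        (radius in [0, 1]; the default stage uses 0.23), or ``compression``
        (normalized compression distance with the built-in order-2 model).
    threshold : float
        Cluster radius: values at distance <= threshold are joined.
    block_chars : int, default 6
        Length of the shared substring required for a candidate pair when
        blocking is active (large facets only).
    """

    method: str
    threshold: float
    block_chars: int = 6

    def __post_init__(self) -> None:
        if self.method not in DISTANCE_METHODS:
            raise ValueError(
                f"unknown distance method {self.method!r}; "
                f"expected one of {DISTANCE_METHODS}"
            )
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")
        if self.method == "normalized_levenshtein" and self.threshold > 1:
            raise ValueError("normalized_levenshtein threshold must be in [0, 1]")
        if self.block_chars < 1:
            raise ValueError("block_chars must be >= 1")

    @property
    def method_id(self) -> str:
        return f"{self.method}({self.threshold:g})"


def _norm(s: str) -> str:
    return s.strip().lower()


def levenshtein(a: str, b: str) -> int:
    """Minimum number of single-character edits turning *a* into *b*.

    Computed on lowercased, trimmed forms. Symmetric, satisfies the triangle
    inequality, and is zero exactly for equal (normalised) strings.
    """
    a, b = _norm(a), _norm(b)
    if a == b:
        return 0
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def normalized_levenshtein(a: str, b: str) -> float:
    """Edit distance divided by the longer (normalised) length; in [0, 1].

    Raises ``ValueError`` when both strings are empty after trimming (the
    ratio is undefined).
    """
    na, nb = _norm(a), _norm(b)
    longest = max(len(na), len(nb))
    if longest == 0:
        raise ValueError("normalized_levenshtein undefined for two empty strings")
    return levenshtein(na, nb) / longest


def inconsistency_rate(typo: str, correct: str) -> int:
    """Percent divergence of a typo from its correct word.

    Defined as 100 x edits / shorter length, rounded to the nearest integer
    percent: "native" diverges from "negative" by 2 of its 6 characters, 33%.
    Raises ``ValueError`` for an empty typo.
    """
    t, c = _norm(typo), _norm(correct)
    if not t:
        raise ValueError("inconsistency_rate requires a non-empty typo string")
    return round(100 * levenshtein(t, c) / min(len(t), len(c) or len(t)))


class Order2Compressor:
    """Order-2 adaptive byte model scored by ideal arithmetic-code length.

    For each byte the model predicts p(byte | previous two bytes) from the
    counts seen so far in the same string, with additive smoothing ``alpha``
    over the 256-symbol alphabet, and charges -log2 p bits. Only the code
    *length* is computed; no bitstream is emitted. Deterministic.
    """

    def __init__(self, alpha: float = 1 / 16) -> None:
        if alpha <= 0:
            raise ValueError("alpha must be positive")
        self.alpha = alpha

    def cost_bits(self, data: bytes) -> float:
        alpha = self.alpha
        counts: dict[tuple, int] = {}
        totals: dict[tuple, int] = {}
        bits = 0.0
        ctx = (256, 256)  # out-of-band padding context
        for byte in data:
            t = totals.get(ctx, 0)
            c = counts.get((ctx, byte), 0)
            bits -= math.log2((c + alpha) / (t + 256 * alpha))
            counts[(ctx, byte)] = c + 1
            totals[ctx] = t + 1
            ctx = (ctx[1], byte)
        return bits


_DEFAULT_COMPRESSOR = Order2Compressor()


def compression_distance(a: str, b: str, compressor=None) -> float:
    """Normalized compression distance with a pluggable byte compressor.

    ``d(a, b) = (C(ab) + C(ba)) / (C(aa) + C(bb))`` where ``C`` is the
    compressed length in bits. Exactly symmetric by construction; ``d(a, a)``
    sits at the compressor's floor (1.0 for the built-in model). Any object
    with a deterministic ``cost_bits(bytes) -> float`` can be supplied.
    """
    comp = compressor or _DEFAULT_COMPRESSOR
    xa = _norm(a).encode("utf-8")
    xb = _norm(b).encode("utf-8")
    num = comp.cost_bits(xa + xb) + comp.cost_bits(xb + xa)
    den = comp.cost_bits(xa + xa) + comp.cost_bits(xb + xb)
    if den == 0:
        return 0.0
    return num / den


def distance_for(a: str, b: str, spec: DistanceSpec) -> float:
    """Apply the distance selected by *spec* to the pair (*a*, *b*)."""
    if spec.method == "levenshtein":
        return levenshtein(a, b)
    if spec.method == "normalized_levenshtein":
        return normalized_levenshtein(a, b)
    return compression_distance(a, b)
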
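"""Synthetic report corpora with gold standards, plus packaged fixtures.

The generator emulates the value column of a parasite-examination report
archive: a closed vocabulary of correct terms (one dominant "Negative"
result plus Latin binomials of intestinal helminths and protozoa), Zipf-like
term frequencies, and a small fraction of records carrying data-entry
errors. Error channels mirror the classes observed in such archives:
single-character substitutions, deletions, insertions, adjacent
transpositions, punctuation/spacing variants, case variants, and (off by
default) token drops and genus abbreviations like "G.lamblia".

Every emitted corruption is recorded in a gold standard mapping wrong
string -> source term, so cleaning performance can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .cluster import FacetTable
from .evaluate import GoldStandard

# The "Negative" result dominates a screening archive; the binomials below
# are common stool-examination findings. Only the first five names appear in
# the packaged fixtures; the remainder are plausible filler, not an
# authoritative vocabulary of any particular dataset.
DEFAULT_TERMS: tuple[str, ...] = (
    "Negative",
    "Clonorchis sinensis",
    "Endolimax nana",
    "Entamoeba coli",
    "Giardia lamblia",
    "Entamoeba histolytica",
    "Ascaris lumbricoides",
    "Trichuris trichiura",
    "Enterobius vermicularis",
    "Ancylostoma duodenale",
    "Necator americanus",
    "Strongyloides stercoralis",
    "Taenia saginata",
    "Taenia solium",
    "Diphyllobothrium latum",
    "Hymenolepis nana",
    "Fasciola hepatica",
    "Fasciolopsis buski",
    "Paragonimus westermani",
    "Metagonimus yokogawai",
    "Blastocystis hominis",
    "Iodamoeba butschlii",
    "Chilomastix mesnili",
    "Cryptosporidium parvum",
    "Cyclospora cayetanensis",
    "Isospora belli",
    "Trichostrongylus orientalis",
    "Trichomonas hominis",
    "Balantidium coli",
    "Dientamoeba fragilis",
)

_LETTERS = "abcdefghijklmnopqrstuvwxyz"


@dataclass
class Vocabulary:
    """Correct terms with relative sampling weights (Zipf-like by default)."""

    terms: list[str]
    weights: Optional[Sequence[float]] = None
    zipf_s: float = 1.0

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError("vocabulary must contain at least one term")
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("vocabulary terms must be distinct")
        if self.weights is None:
            ranks = np.arange(1, len(self.terms) + 1, dtype=float)
            self.weights = 1.0 / ranks ** self.zipf_s
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(self.terms),) or (w <= 0).any():
            raise ValueError("weights must be positive, one per term")
        self.weights = w / w.sum()


def default_vocabulary() -> Vocabulary:
    """30-term stool-parasite vocabulary, "Negative" rank-1 dominant."""
    return Vocabulary(list(DEFAULT_TERMS))


@dataclass
class TypoModel:
    """Per-channel corruption probabilities for the corpus generator.

    Channel rates are relative weights for choosing the corruption applied
    to a record that carries an error (a record errs with probability
    ``typo_fraction``). ``second_edit`` is the probability that a corrupted
    record receives one additional single-character edit, so the default
    model stays within two edits of the source term — single-slip errors
    dominate real typing. ``token_drop`` and ``abbreviation`` produce
    heavier, deliberately hard-to-recover variants and default to 0.
    """

    substitution: float = 0.30
    deletion: float = 0.20
    insertion: float = 0.15
    transposition: float = 0.15
    punct_space: float = 0.10
    case_variant: float = 0.10
    token_drop: float = 0.0
    abbreviation: float = 0.0
    second_edit: float = 0.10
    typo_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("substitution", "deletion", "insertion", "transposition",
                     "punct_space", "case_variant", "token_drop",
                     "abbreviation", "second_edit", "typo_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if (self.substitution + self.deletion + self.insertion
                + self.transposition + self.punct_space + self.case_variant
                + self.token_drop + self.abbreviation) <= 0:
            raise ValueError("at least one corruption channel must be active")

    def channel_weights(self) -> tuple[list[str], np.ndarray]:
        names = ["substitution", "deletion", "insertion", "transposition",
                 "punct_space", "case_variant", "token_drop", "abbreviation"]
        w = np.array([getattr(self, n) for n in names], dtype=float)
        keep = w > 0
        w = w[keep]
        return [n for n, k in zip(names, keep) if k], w / w.sum()


def _char_edit(s: str, rng: np.random.Generator) -> str:
    """One random single-character substitution/deletion/insertion/swap."""
    ops = ["substitution", "deletion", "insertion", "transposition"]
    op = ops[rng.integers(len(ops))]
    return _apply_channel(s, op, rng)


def _apply_channel(s: str, channel: str, rng: np.random.Generator) -> str:
    if channel == "substitution":
        pos = [i for i, ch in enumerate(s) if ch.isalpha()]
        if not pos:
            return s
        i = pos[rng.integers(len(pos))]
        new = _LETTERS[rng.integers(26)]
        if s[i].isupper():
            new = new.upper()
        if new == s[i]:
            new = _LETTERS[(_LETTERS.index(new.lower()) + 1) % 26]
        return s[:i] + new + s[i + 1:]
    if channel == "deletion":
        if len(s) < 2:
            return s
        i = int(rng.integers(len(s)))
        return s[:i] + s[i + 1:]
    if channel == "insertion":
        i = int(rng.integers(len(s) + 1))
        return s[:i] + _LETTERS[rng.integers(26)] + s[i:]
    if channel == "transposition":
        pos = [i for i in range(len(s) - 1) if s[i] != s[i + 1]]
        if not pos:
            return s
        i = pos[rng.integers(len(pos))]
        return s[:i] + s[i + 1] + s[i] + s[i + 2:]
    if channel == "punct_space":
        if " " in s:
            i = [i for i, ch in enumerate(s) if ch == " "][0]
            if rng.random() < 0.5:
                return s[:i] + s[i + 1:]          # join tokens
            return s[:i] + "." + s[i + 1:]        # space -> period
        return s + "."                             # stray trailing period
    if channel == "case_variant":
        choices = [s.lower(), s.upper(),
                   (s[0].swapcase() + s[1:]) if s else s]
        choices = [c for c in choices if c != s]
        return choices[rng.integers(len(choices))] if choices else s
    if channel == "token_drop":
        toks = s.split()
        if len(toks) < 2:
            return s
        i = int(rng.integers(len(toks)))
        return " ".join(toks[:i] + toks[i + 1:])
    if channel == "abbreviation":
        toks = s.split()
        if len(toks) < 2:
            return s
        return toks[0][0].upper() + "." + " ".join(toks[1:])
    raise ValueError(f"unknown channel {channel!r}")


def generate_corpus(
    vocab: Vocabulary, model: TypoModel, n_records: int,
) -> tuple[list[str], GoldStandard]:
    """Draw a seeded corpus of report values plus its gold standard.

    Each record is one vocabulary term, corrupted with probability
    ``model.typo_fraction``. Corruption is rejected and redrawn when it
    reproduces the source term, collides with a different vocabulary term,
    or collides with a wrong string already attributed to a different term —
    the emitted gold standard is therefore closed and unambiguous.
    """
    if n_records < 1:
        raise ValueError("n_records must be >= 1")
    rng = np.random.default_rng(model.seed)
    term_set = set(vocab.terms)
    channels, cweights = model.channel_weights()
    records: list[str] = []
    mapping: dict[str, str] = {}
    for _ in range(n_records):
        term = vocab.terms[rng.choice(len(vocab.terms), p=vocab.weights)]
        if rng.random() >= model.typo_fraction:
            records.append(term)
            continue
        wrong = term
        for _attempt in range(100):
            cand = _apply_channel(term, channels[rng.choice(len(channels), p=cweights)], rng)
            if rng.random() < model.second_edit:
                cand = _char_edit(cand, rng)
            if (cand != term and cand not in term_set
                    and mapping.get(cand, term) == term):
                wrong = cand
                break
        if wrong == term:  # could not corrupt safely; emit verbatim
            records.append(term)
            continue
        mapping[wrong] = term
        records.append(wrong)
    gold = GoldStandard(mapping=mapping, correct=set(vocab.terms))
    return records, gold


# ---------------------------------------------------------------------------
# packaged desk fixtures

def table1_fixture() -> tuple[FacetTable, GoldStandard]:
    """The seven-typo failure-matrix fixture.

    Four correct words at count 100 each plus seven typo strings at count 1:
    "Native" and "Negaitve" for "Negative"; "Eolimax" and "Endolix" for
    "Endolimax"; "Etamoeba" for "Entamoeba"; "Lamdlia" and "G.lamblia" for
    "Lamblia". 11 distinct values, total word count 407.
    """
    mapping = {
        "Native": "Negative",
        "Negaitve": "Negative",
        "Eolimax": "Endolimax",
        "Endolix": "Endolimax",
        "Etamoeba": "Entamoeba",
        "Lamdlia": "Lamblia",
        "G.lamblia": "Lamblia",
    }
    counts: dict[str, int] = {t: 100 for t in
                              ("Negative", "Endolimax", "Entamoeba", "Lamblia")}
    counts.update({w: 1 for w in mapping})
    return FacetTable(counts), GoldStandard(mapping=mapping)


def fig2_fixture() -> tuple[FacetTable, GoldStandard]:
    """The liver-fluke merge-list fixture.

    "Clonorchis sinensis" at high count plus its five observed wrong
    spellings at low counts; the gold standard maps every variant to the
    frequency-dominant canonical.
    """
    canonical = "Clonorchis sinensis"
    variants = {
        "clonorchis sinesis": 4,
        "clnorchis sinensis": 2,
        "clonorchis cinensis": 1,
        "clonrchis sinensis": 1,
        "clornorchis sinensis": 1,
    }
    counts = {canonical: 900, **variants}
    mapping = {v: canonical for v in variants}
    return FacetTable(counts), GoldStandard(mapping=mapping)
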
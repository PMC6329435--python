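"""Correction-rate and accuracy metrics against a gold standard.

Terminology (fixed throughout the package):

- a *pattern* is a class of wrong strings for one correct term (by default
  each distinct wrong string is its own pattern);
- *words* are occurrences: a wrong string appearing three times in the
  column contributes three typographical-error words;
- a wrong string counts as *corrected* only when the cleaning plan maps it
  to exactly its gold correct string — joining some other cluster does not
  count.

Rates are percentages reported to two decimals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from .cluster import FacetTable, MergePlan

logger = logging.getLogger(__name__)


@dataclass
class GoldStandard:
    """Reference mapping wrong string -> correct string.

    ``pattern_of`` groups wrong strings into error patterns; when omitted,
    each distinct wrong string is its own pattern. ``correct`` is the set of
    known-correct terms; when omitted it defaults to the mapping's targets,
    but a vocabulary can declare terms that never appear corrupted.
    """

    mapping: dict[str, str]
    pattern_of: dict[str, str] = field(default_factory=dict)
    correct: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.pattern_of:
            self.pattern_of = {w: w for w in self.mapping}
        missing = [w for w in self.mapping if w not in self.pattern_of]
        if missing:
            raise ValueError(f"pattern_of lacks wrong strings: {missing[:5]}")
        if not self.correct:
            self.correct = set(self.mapping.values())
        else:
            self.correct = set(self.correct) | set(self.mapping.values())


@dataclass
class CleaningReport:
    """Correction rates plus the residual (uncorrected) wrong strings."""

    pattern_rate: float
    word_rate: float
    accuracy: float
    residuals: list[str]
    n_patterns: int = 0
    n_words: int = 0

    def __post_init__(self) -> None:
        for name in ("pattern_rate", "word_rate", "accuracy"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must lie in [0, 100], got {v}")


def pattern_correction_rate(corrected_patterns: int, total_patterns: int) -> float:
    """100 x corrected / total error patterns, to two decimals."""
    if total_patterns < 1:
        raise ValueError("pattern correction rate undefined for zero patterns")
    if not 0 <= corrected_patterns <= total_patterns:
        raise ValueError("corrected_patterns must lie in [0, total_patterns]")
    return round(100 * corrected_patterns / total_patterns, 2)


def word_correction_rate(corrected_words: int, total_words: int) -> float:
    """100 x corrected / total typographical-error words, to two decimals."""
    if total_words < 1:
        raise ValueError("word correction rate undefined for zero words")
    if not 0 <= corrected_words <= total_words:
        raise ValueError("corrected_words must lie in [0, total_words]")
    return round(100 * corrected_words / total_words, 2)


def score(plan: MergePlan, gold: GoldStandard, facet: FacetTable,
          total_patterns: Optional[int] = None) -> CleaningReport:
    """Score a cleaning plan against the gold standard on the original facet.

    A facet value is *wrong* when it appears in ``gold.mapping``; it is
    corrected when the plan's resolved mapping sends it to its gold correct
    string. Accuracy is occurrence-weighted over the whole facet: the share
    of word occurrences that resolve to a correct string after cleaning
    (wrong values to their gold target, correct values left untouched).

    A facet value in neither the mapping nor the correct-term set is flagged
    with a ``ValueError`` naming it. ``total_patterns`` overrides the
    pattern denominator (default: patterns with >= 1 wrong string in the
    facet).
    """
    resolved = plan.resolved()
    unknown = [v for v in facet if v not in gold.mapping and v not in gold.correct]
    if unknown:
        raise ValueError(
            f"facet value {unknown[0]!r} is neither a gold wrong string nor a "
            f"known correct term ({len(unknown)} such values)"
        )

    wrongs = [v for v in facet if v in gold.mapping]
    corrected = {w: resolved.get(w) == gold.mapping[w] for w in wrongs}
    residuals = [w for w in wrongs if not corrected[w]]

    patterns: dict[str, bool] = {}
    for w in wrongs:
        pid = gold.pattern_of[w]
        patterns[pid] = patterns.get(pid, True) and corrected[w]
    n_patterns = total_patterns if total_patterns is not None else len(patterns)
    n_corr_patterns = sum(patterns.values())

    total_words = sum(facet[w] for w in wrongs)
    corr_words = sum(facet[w] for w in wrongs if corrected[w])

    good_occ = 0
    for v, c in facet.items():
        final = resolved.get(v, v)
        target = gold.mapping.get(v, v)
        if final == target:
            good_occ += c
    total_occ = facet.total()

    report = CleaningReport(
        pattern_rate=pattern_correction_rate(n_corr_patterns, n_patterns)
        if n_patterns else 100.0,
        word_rate=word_correction_rate(corr_words, total_words)
        if total_words else 100.0,
        accuracy=round(100 * good_occ / total_occ, 4) if total_occ else 100.0,
        residuals=residuals,
        n_patterns=n_patterns,
        n_words=total_words,
    )
    logger.info(
        "cleaning score: pattern rate %.2f%% (%d patterns), word rate %.2f%% "
        "(%d words), accuracy %.4f%%, %d residual(s)",
        report.pattern_rate, report.n_patterns, report.word_rate,
        report.n_words, report.accuracy, len(report.residuals),
    )
    return report
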
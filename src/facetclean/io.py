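"""Readers, writers and term-extraction preprocessing.

All tabular artefacts are plain CSV/TSV (delimiter sniffed on read, UTF-8
with BOM tolerance). File layouts:

- mapping:      wrong, canonical, stage, method
- gold:         wrong, correct, pattern_id  (a row with wrong == correct
                declares a correct term without mapping anything)
- review:       cluster_id, stage, method, member, count,
                proposed_canonical, decision, canonical_override
- facet:        value, count
- report:       metric, value rows followed by residual rows
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .cluster import FacetTable, MergePlan, MergeRecord
from .distance import normalized_levenshtein
from .evaluate import CleaningReport, GoldStandard

logger = logging.getLogger(__name__)

# loose gate so typo-bearing mentions survive dictionary extraction
DICTIONARY_GATE = 0.35


@dataclass
class ExtractionSpec:
    """How to pull target terms out of free-text reports.

    ``regex`` mode returns maximal pattern matches; ``dictionary`` mode
    returns token spans within normalised edit distance ``gate`` of a
    dictionary term (loose by default so misspelled mentions are kept);
    ``both`` unions the two.
    """

    patterns: list[str] = field(default_factory=list)
    dictionary: list[str] = field(default_factory=list)
    mode: str = "regex"
    gate: float = DICTIONARY_GATE

    def __post_init__(self) -> None:
        if self.mode not in ("regex", "dictionary", "both"):
            raise ValueError(f"unknown extraction mode {self.mode!r}")
        if not self.patterns and not self.dictionary:
            raise ValueError("extraction requires >= 1 pattern or a dictionary")


def _compile(patterns: Sequence[str]) -> list[re.Pattern]:
    out = []
    for p in patterns:
        try:
            out.append(re.compile(p, re.IGNORECASE))
        except re.error as exc:
            raise ValueError(f"invalid extraction pattern {p!r}: {exc}") from exc
    return out


def _regex_spans(report: str, compiled: list[re.Pattern]) -> list[tuple[int, int, str]]:
    spans = []
    for pat in compiled:
        for m in pat.finditer(report):
            if m.group():
                spans.append((m.start(), m.end(), m.group()))
    return spans


def _dictionary_spans(report: str, terms: Sequence[str],
                      gate: float) -> list[tuple[int, int, str]]:
    tokens = [(m.start(), m.end()) for m in re.finditer(r"\S+", report)]
    spans = []
    for term in terms:
        k = max(1, len(term.split()))
        for i in range(len(tokens) - k + 1):
            start, end = tokens[i][0], tokens[i + k - 1][1]
            chunk = report[start:end]
            if normalized_levenshtein(chunk, term) <= gate:
                spans.append((start, end, chunk))
    return spans


def extract_terms(reports: Sequence[str], spec: ExtractionSpec) -> list[str]:
    """Extract target-term mentions from raw reports, order preserved.

    Overlapping candidate spans are resolved greedily, longest-first at each
    position, so only maximal matches are returned.
    """
    compiled = _compile(spec.patterns) if spec.mode in ("regex", "both") else []
    out: list[str] = []
    for report in reports:
        spans: list[tuple[int, int, str]] = []
        if spec.mode in ("regex", "both"):
            spans += _regex_spans(report, compiled)
        if spec.mode in ("dictionary", "both"):
            spans += _dictionary_spans(report, spec.dictionary, spec.gate)
        spans.sort(key=lambda s: (s[0], -(s[1] - s[0])))
        last_end = -1
        for start, end, text in spans:
            if start >= last_end:
                out.append(text)
                last_end = end
    return out


# ---------------------------------------------------------------------------
# tabular io

def _sniff_sep(path: str | Path) -> str:
    with open(path, "r", encoding="utf-8-sig", newline="") as fh:
        first = fh.readline()
    try:
        return csv.Sniffer().sniff(first, delimiters=",;\t|").delimiter
    except csv.Error:
        return ","


def read_column(path: str | Path, column_name: str) -> list[str]:
    """Read one string column from a CSV/TSV file (delimiter sniffed)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    df = pd.read_csv(path, sep=_sniff_sep(path), encoding="utf-8-sig",
                     dtype=str, keep_default_na=False)
    if column_name not in df.columns:
        raise ValueError(
            f"column {column_name!r} not found in {path}; "
            f"available columns: {list(df.columns)}"
        )
    return df[column_name].tolist()


def read_lines(path: str | Path) -> list[str]:
    """Read a plain-text corpus, one record per line."""
    with open(path, "r", encoding="utf-8-sig") as fh:
        return [line.rstrip("\n") for line in fh]


def write_lines(values: Sequence[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for v in values:
            fh.write(v + "\n")


def write_facet(facet: FacetTable, path: str | Path) -> None:
    pd.DataFrame(facet.items(), columns=["value", "count"]).to_csv(
        path, index=False, lineterminator="\n")


def read_facet(path: str | Path) -> FacetTable:
    df = pd.read_csv(path, dtype={"value": str, "count": int},
                     keep_default_na=False)
    return FacetTable(dict(zip(df["value"], df["count"])))


def write_mapping(plan: MergePlan, path: str | Path) -> None:
    """Write accepted merges as CSV: wrong, canonical, stage, method."""
    rows = [(r.wrong, r.canonical, r.stage_index, r.method)
            for r in plan.accepted()]
    pd.DataFrame(rows, columns=["wrong", "canonical", "stage", "method"]).to_csv(
        path, index=False, lineterminator="\n")


def read_mapping(path: str | Path) -> MergePlan:
    df = pd.read_csv(path, dtype={"wrong": str, "canonical": str,
                                  "stage": int, "method": str},
                     keep_default_na=False)
    records = [
        MergeRecord(wrong=row.wrong, canonical=row.canonical,
                    stage_index=int(row.stage), method=row.method, count=0)
        for row in df.itertuples()
    ]
    return MergePlan(records)


def write_gold(gold: GoldStandard, path: str | Path) -> None:
    """Write a gold standard: wrong, correct, pattern_id.

    Correct terms that never appear corrupted are declared with
    wrong == correct rows (empty pattern_id).
    """
    rows = [(w, c, gold.pattern_of[w]) for w, c in gold.mapping.items()]
    rows += [(t, t, "") for t in sorted(gold.correct)]
    pd.DataFrame(rows, columns=["wrong", "correct", "pattern_id"]).to_csv(
        path, index=False, lineterminator="\n")


def read_gold(path: str | Path) -> GoldStandard:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    mapping, pattern_of, correct = {}, {}, set()
    for row in df.itertuples():
        if row.wrong == row.correct:
            correct.add(row.correct)
        else:
            mapping[row.wrong] = row.correct
            pattern_of[row.wrong] = row.pattern_id or row.wrong
    return GoldStandard(mapping=mapping, pattern_of=pattern_of, correct=correct)


def write_report(report: CleaningReport, path: str | Path) -> None:
    """Write a cleaning report as CSV and log a human-readable summary."""
    rows = [("pattern_rate", report.pattern_rate),
            ("word_rate", report.word_rate),
            ("accuracy", report.accuracy),
            ("n_patterns", report.n_patterns),
            ("n_words", report.n_words)]
    rows += [("residual", r) for r in report.residuals]
    pd.DataFrame(rows, columns=["metric", "value"]).to_csv(
        path, index=False, lineterminator="\n")
    logger.info("pattern rate %.2f%% | word rate %.2f%% | accuracy %.4f%% | "
                "residuals: %s", report.pattern_rate, report.word_rate,
                report.accuracy, ", ".join(report.residuals) or "none")


REVIEW_COLUMNS = ["cluster_id", "stage", "method", "member", "count",
                  "proposed_canonical", "decision", "canonical_override"]


def write_review(plan: MergePlan, path: str | Path) -> None:
    """Write proposed merges for manual review (decision prefilled accept)."""
    rows = []
    cluster_ids: dict[tuple[int, str], int] = {}
    for r in plan.records:
        key = (r.stage_index, r.canonical)
        cid = cluster_ids.setdefault(key, len(cluster_ids))
        rows.append((cid, r.stage_index, r.method, r.wrong, r.count,
                     r.canonical, "accept", ""))
    pd.DataFrame(rows, columns=REVIEW_COLUMNS).to_csv(
        path, index=False, lineterminator="\n")


def read_review(path: str | Path) -> dict[str, tuple[str, Optional[str]]]:
    """Read an edited review file into member -> (decision, override)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    out: dict[str, tuple[str, Optional[str]]] = {}
    for row in df.itertuples():
        out[row.member] = (row.decision or "accept",
                           row.canonical_override or None)
    return out
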
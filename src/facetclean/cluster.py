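"""Facet construction, clustering and the sequential cleaning pipeline.

The cleaning process works on a *text facet* — the table of distinct string
values in a column with their occurrence counts — and proceeds in ordered
stages. Key-collision stages group values sharing a normalised key;
nearest-neighbour stages join values within a distance radius (connected
components, so a typo of a typo still reaches the canonical). After every
stage the proposed merges are applied and the facet rewritten, mirroring an
interactive merge-then-recluster workflow. The canonical value of a cluster
is its most frequent member — in a column dominated by correctly entered
values, frequency identifies the correct spelling.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

from .distance import DistanceSpec, distance_for
from .keying import KeySpec, key_for

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# facet

@dataclass
class FacetTable:
    """Distinct string values of a column with their occurrence counts.

    ``counts`` preserves first-occurrence order; all counts are >= 1 and the
    total equals the length of the original column.
    """

    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for v, c in self.counts.items():
            if c < 1:
                raise ValueError(f"facet count for {v!r} must be >= 1, got {c}")

    def __len__(self) -> int:
        return len(self.counts)

    def __iter__(self):
        return iter(self.counts)

    def __contains__(self, value: str) -> bool:
        return value in self.counts

    def __getitem__(self, value: str) -> int:
        return self.counts[value]

    def items(self):
        return self.counts.items()

    def total(self) -> int:
        """Total word count (sum of occurrence counts)."""
        return sum(self.counts.values())

    def merged(self, mapping: Mapping[str, str]) -> "FacetTable":
        """Rewrite the facet, replacing each mapped value by its target.

        Counts of merged values accumulate onto the target; the total word
        count is conserved. Order follows the first appearance of each
        resulting value in the original order.
        """
        out: dict[str, int] = {}
        for v, c in self.counts.items():
            tgt = mapping.get(v, v)
            out[tgt] = out.get(tgt, 0) + c
        return FacetTable(out)


def build_facet(values: Sequence[str]) -> FacetTable:
    """Count occurrences of each distinct value, preserving first-seen order."""
    return FacetTable(dict(Counter(values)))


# ---------------------------------------------------------------------------
# clusters

@dataclass(frozen=True)
class Cluster:
    """A set of facet values proposed as variants of one canonical value."""

    members: tuple[tuple[str, int], ...]  # (value, count), count-desc order
    canonical: str
    method_id: str
    stage_index: int

    @property
    def values(self) -> tuple[str, ...]:
        return tuple(v for v, _ in self.members)


def choose_canonical(members: Iterable[tuple[str, int]]) -> str:
    """Most frequent member; ties go to the lexicographically smallest value.

    Facet values are distinct, so the count/lexicographic pair is always
    decisive; first-occurrence order never needs to break a tie in practice.
    """
    members = list(members)
    if not members:
        raise ValueError("choose_canonical requires at least one member")
    return min(members, key=lambda vc: (-vc[1], vc[0]))[0]


def _make_cluster(group: list[tuple[str, int]], method_id: str,
                  stage_index: int) -> Cluster:
    ordered = tuple(sorted(group, key=lambda vc: (-vc[1], vc[0])))
    return Cluster(ordered, choose_canonical(group), method_id, stage_index)


def key_collision_cluster(facet: FacetTable, spec: KeySpec,
                          stage_index: int = 0) -> list[Cluster]:
    """Group facet values sharing a non-empty key; singletons are dropped.

    An empty key is not a collision: values that normalise to nothing are
    never clustered with each other.
    """
    groups: dict[str, list[tuple[str, int]]] = {}
    for v, c in facet.items():
        k = key_for(v, spec)
        if k:
            groups.setdefault(k, []).append((v, c))
    return [
        _make_cluster(g, spec.method_id, stage_index)
        for _, g in sorted(groups.items())
        if len(g) >= 2
    ]


# exhaustive pair generation below this facet size; blocking above
EXHAUSTIVE_LIMIT = 2000


def _candidate_pairs(values: list[str], spec: DistanceSpec) -> Iterable[tuple[int, int]]:
    n = len(values)
    if n <= EXHAUSTIVE_LIMIT:
        for i in range(n):
            for j in range(i + 1, n):
                yield i, j
        return
    # blocking: candidate pairs share >= 1 substring of length block_chars
    w = spec.block_chars
    blocks: dict[str, list[int]] = {}
    for idx, v in enumerate(values):
        s = v.strip().lower()
        subs = {s[i:i + w] for i in range(len(s) - w + 1)} if len(s) >= w else {s}
        for sub in subs:
            blocks.setdefault(sub, []).append(idx)
    seen: set[tuple[int, int]] = set()
    for members in blocks.values():
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                pair = (members[a], members[b])
                if pair not in seen:
                    seen.add(pair)
                    yield pair


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def nn_cluster(facet: FacetTable, spec: DistanceSpec,
               stage_index: int = 0, exhaustive: Optional[bool] = None) -> list[Cluster]:
    """Nearest-neighbour clustering: connected components at the radius.

    Candidate pairs come from substring blocking for large facets and from
    exhaustive enumeration otherwise (or always, with ``exhaustive=True``).
    Pairs at distance <= ``spec.threshold`` are joined; components of size
    >= 2 become clusters. Empty (all-whitespace) values are never clustered.
    """
    values = [v for v in facet if v.strip()]
    if exhaustive is True:
        pairs: Iterable[tuple[int, int]] = (
            (i, j) for i in range(len(values)) for j in range(i + 1, len(values))
        )
    else:
        pairs = _candidate_pairs(values, spec)
    uf = _UnionFind(len(values))
    for i, j in pairs:
        if distance_for(values[i], values[j], spec) <= spec.threshold:
            uf.union(i, j)
    comps: dict[int, list[tuple[str, int]]] = {}
    for idx, v in enumerate(values):
        comps.setdefault(uf.find(idx), []).append((v, facet[v]))
    clusters = [
        _make_cluster(g, spec.method_id, stage_index)
        for g in comps.values()
        if len(g) >= 2
    ]
    clusters.sort(key=lambda cl: cl.members[0][0])
    return clusters


# ---------------------------------------------------------------------------
# merge plan and pipeline

@dataclass(frozen=True)
class MergeRecord:
    """One proposed value-merge: *wrong* rewritten to *canonical*."""

    wrong: str
    canonical: str
    stage_index: int
    method: str
    count: int
    decision: str = "accept"  # accept | reject | proposed


@dataclass
class MergePlan:
    """Ordered record of every merge proposed (and possibly applied)."""

    records: list[MergeRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def accepted(self) -> list[MergeRecord]:
        return [r for r in self.records if r.decision == "accept"]

    def resolved(self) -> dict[str, str]:
        """Final wrong -> canonical mapping, following cross-stage chains.

        A value merged at stage *s* whose canonical is itself merged at a
        later stage resolves to the final canonical.
        """
        direct = {r.wrong: r.canonical for r in self.accepted()}
        out: dict[str, str] = {}
        for wrong in direct:
            tgt = wrong
            seen = {tgt}
            while tgt in direct:
                tgt = direct[tgt]
                if tgt in seen:  # defensive: cycles cannot arise from stages
                    break
                seen.add(tgt)
            out[wrong] = tgt
        return out


@dataclass
class PipelineConfig:
    """Ordered stage list of the cleaning pipeline plus merge policy.

    The default order runs every key-collision method (cheap, precise) before
    the nearest-neighbour radius search: fingerprint, n-gram fingerprint at
    n=2 then n=1, the English phonetic keyer, the Cologne phonetic keyer,
    then normalised edit distance at radius 0.23.
    """

    key_stages: list[KeySpec] = field(default_factory=lambda: list(DEFAULT_KEY_STAGES))
    nn_stages: list[DistanceSpec] = field(default_factory=lambda: list(DEFAULT_NN_STAGES))
    auto_accept: bool = True
    review_path: Optional[str] = None

    def stages(self) -> list[object]:
        return list(self.key_stages) + list(self.nn_stages)


DEFAULT_KEY_STAGES: tuple[KeySpec, ...] = (
    KeySpec("fingerprint"),
    KeySpec("ngram_fingerprint", ngram_size=2),
    KeySpec("ngram_fingerprint", ngram_size=1),
    KeySpec("phonetic_en"),
    KeySpec("phonetic_cologne"),
)

DEFAULT_NN_THRESHOLD = 0.23

DEFAULT_NN_STAGES: tuple[DistanceSpec, ...] = (
    DistanceSpec("normalized_levenshtein", DEFAULT_NN_THRESHOLD),
)


def default_config(**overrides) -> PipelineConfig:
    """The default pipeline configuration (see ``PipelineConfig``)."""
    return PipelineConfig(**overrides)


def run_pipeline(
    facet: FacetTable,
    config: Optional[PipelineConfig] = None,
    decisions: Optional[Mapping[str, tuple[str, Optional[str]]]] = None,
) -> tuple[MergePlan, FacetTable]:
    """Run the staged cleaning pipeline on a facet.

    For each stage in order: cluster the current facet, decide each proposed
    merge, apply the accepted ones and rewrite the facet (counts of merged
    values accumulate onto their canonical). Returns the cumulative
    ``MergePlan`` and the final facet. Deterministic given config and facet.

    Merge policy:

    - ``config.auto_accept`` (default): every proposed merge is accepted.
    - otherwise, with ``decisions`` (a mapping ``wrong -> (decision,
      canonical_override)`` as read from an edited review file): only rows
      marked ``accept`` are applied, honouring any canonical override.
    - otherwise (no decisions yet): nothing is applied; proposals are
      recorded with decision ``proposed`` and, if ``config.review_path`` is
      set, written there for editing. Proposal clustering is computed with
      provisional acceptance so later stages see the merged facet.
    """
    config = config or default_config()
    plan = MergePlan()
    current = facet
    proposal_mode = not config.auto_accept and decisions is None
    for idx, spec in enumerate(config.stages()):
        if len(current) == 0:
            break
        if isinstance(spec, KeySpec):
            clusters = key_collision_cluster(current, spec, stage_index=idx)
        else:
            clusters = nn_cluster(current, spec, stage_index=idx)
        applied: dict[str, str] = {}
        n_merges = 0
        for cl in clusters:
            for v, c in cl.members:
                if v == cl.canonical:
                    continue
                canonical = cl.canonical
                if config.auto_accept:
                    decision = "accept"
                elif proposal_mode:
                    decision = "proposed"
                else:
                    decision, override = decisions.get(v, ("reject", None))
                    if override:
                        canonical = override
                plan.records.append(MergeRecord(
                    wrong=v, canonical=canonical, stage_index=idx,
                    method=cl.method_id, count=c, decision=decision,
                ))
                logger.debug("stage %d (%s): %r -> %r [%s]",
                             idx, cl.method_id, v, canonical, decision)
                if decision == "accept" or proposal_mode:
                    # proposal mode applies provisionally so later stages
                    # cluster the facet a full acceptance would produce
                    applied[v] = canonical
                    n_merges += 1
        logger.info("stage %d (%s): %d clusters, %d merges",
                    idx, getattr(spec, "method_id", str(spec)),
                    len(clusters), n_merges)
        current = current.merged(applied)
    if proposal_mode:
        if config.review_path:
            from .io import write_review
            write_review(plan, config.review_path)
        return plan, facet  # nothing actually merged without decisions
    return plan, current


def apply_review(facet: FacetTable, config: PipelineConfig,
                 review_path: str) -> tuple[MergePlan, FacetTable]:
    """Re-run the pipeline applying only the merges accepted in a review file."""
    from .io import read_review
    decisions = read_review(review_path)
    cfg = replace(config, auto_accept=False)
    return run_pipeline(facet, cfg, decisions=decisions)
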
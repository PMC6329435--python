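"""Facet, clustering and pipeline behaviour."""

import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

import facetclean.cluster as cluster_mod
from facetclean.cluster import (
    FacetTable,
    PipelineConfig,
    apply_review,
    build_facet,
    choose_canonical,
    default_config,
    key_collision_cluster,
    nn_cluster,
    run_pipeline,
)
from facetclean.distance import DistanceSpec
from facetclean.keying import KeySpec
from facetclean.synth import TypoModel, default_vocabulary, generate_corpus


def test_build_facet_counts():
    facet = build_facet(["negative", "negative", "native"])
    assert dict(facet.items()) == {"negative": 2, "native": 1}
    assert facet.total() == 3
    assert len(build_facet([])) == 0
    assert dict(build_facet(["x"] * 1000).items()) == {"x": 1000}


def test_facet_rejects_nonpositive_counts():
    with pytest.raises(ValueError, match=">= 1"):
        FacetTable({"x": 0})


def test_facet_merge_conserves_total():
    facet = FacetTable({"a": 5, "b": 2, "c": 1})
    merged = facet.merged({"b": "a", "c": "a"})
    assert dict(merged.items()) == {"a": 8}
    assert merged.total() == facet.total()


@pytest.mark.parametrize("members,expected", [
    ([("Clonorchis sinensis", 900), ("clonorchis sinesis", 4)], "Clonorchis sinensis"),
    ([("a", 1)], "a"),
    ([("b", 2), ("a", 2)], "a"),  # count tie -> lexicographically smallest
])
def test_choose_canonical(members, expected):
    assert choose_canonical(members) == expected


def test_choose_canonical_empty_is_error():
    with pytest.raises(ValueError):
        choose_canonical([])


def test_key_collision_transposition_cluster():
    facet = FacetTable({"Negative": 5000, "Negaitve": 3})
    (only,) = key_collision_cluster(facet, KeySpec("ngram_fingerprint", 1))
    assert set(only.values) == {"Negative", "Negaitve"}
    assert only.canonical == "Negative"


def test_key_collision_native_never_clusters():
    facet = FacetTable({"Negative": 5000, "Native": 2})
    for spec in default_config().key_stages:
        assert key_collision_cluster(facet, spec) == []


def test_key_collision_singleton_and_empty_key():
    assert key_collision_cluster(FacetTable({"x": 1}), KeySpec("fingerprint")) == []
    # values normalising to the empty key never cluster with each other
    facet = FacetTable({"!!": 1, "??": 1})
    assert key_collision_cluster(facet, KeySpec("fingerprint")) == []


def test_nn_cluster_endolimax_group():
    facet = FacetTable({"Endolimax": 800, "Eolimax": 2, "Endolix": 1})
    (only,) = nn_cluster(facet, DistanceSpec("normalized_levenshtein", 0.23))
    assert set(only.values) == {"Endolimax", "Eolimax", "Endolix"}
    assert only.canonical == "Endolimax"


def test_nn_cluster_transposition_outside_radius():
    facet = FacetTable({"Negative": 5000, "Negaitve": 3})
    assert nn_cluster(facet, DistanceSpec("normalized_levenshtein", 0.23)) == []


def test_run_pipeline_table1(table1):
    facet, gold = table1
    plan, final = run_pipeline(facet)
    assert set(final) == {"Negative", "Endolimax", "Entamoeba", "Lamblia", "Native"}
    assert final.total() == facet.total()
    resolved = plan.resolved()
    for typo, correct in gold.mapping.items():
        if typo != "Native":
            assert resolved[typo] == correct


def test_run_pipeline_empty_stages_is_identity(table1):
    facet, _ = table1
    plan, final = run_pipeline(facet, PipelineConfig(key_stages=[], nn_stages=[]))
    assert len(plan) == 0
    assert dict(final.items()) == dict(facet.items())


def test_run_pipeline_is_a_fixed_point(table1):
    facet, _ = table1
    _, once = run_pipeline(facet)
    plan2, twice = run_pipeline(once)
    assert len(plan2) == 0
    assert dict(twice.items()) == dict(once.items())


def test_pipeline_invariant_under_input_permutation(table1):
    facet, _ = table1
    values = [v for v, c in facet.items() for _ in range(c)]
    rnd = random.Random(5)
    plan_ref, final_ref = run_pipeline(build_facet(values))
    for _ in range(3):
        rnd.shuffle(values)
        plan, final = run_pipeline(build_facet(values))
        assert plan.resolved() == plan_ref.resolved()
        assert dict(final.items()) == dict(final_ref.items())


@given(st.lists(st.sampled_from(
    ["negative", "Negative", "negaitve", "native", "endolimax", "eolimax",
     "entamoeba", "lamblia", "g.lamblia", "clonorchis sinensis"]),
    min_size=1, max_size=60))
def test_pipeline_conserves_word_count(values):
    facet = build_facet(values)
    _, final = run_pipeline(facet)
    assert final.total() == facet.total() == len(values)


def test_blocked_equals_exhaustive_on_small_facet(monkeypatch):
    """Forcing the blocking path on a <=500-value facet reproduces the
    exhaustive-pairwise clustering exactly."""
    records, _ = generate_corpus(
        default_vocabulary(), TypoModel(typo_fraction=0.15, seed=3), 500)
    facet = build_facet(records)
    assert len(facet) <= 500
    spec = DistanceSpec("normalized_levenshtein", 0.23, block_chars=3)
    exhaustive = nn_cluster(facet, spec, exhaustive=True)
    monkeypatch.setattr(cluster_mod, "EXHAUSTIVE_LIMIT", 0)
    blocked = nn_cluster(facet, spec)
    assert [set(c.values) for c in blocked] == [set(c.values) for c in exhaustive]
    assert [c.canonical for c in blocked] == [c.canonical for c in exhaustive]


def test_review_workflow_respects_rejections(tmp_path, table1):
    facet, _ = table1
    review = tmp_path / "review.csv"
    cfg = PipelineConfig(auto_accept=False, review_path=str(review))
    plan, final = run_pipeline(facet, cfg)
    assert review.exists()
    assert dict(final.items()) == dict(facet.items())  # nothing applied yet
    assert all(r.decision == "proposed" for r in plan.records)

    text = review.read_text()
    # reject the transposition merge, accept the rest
    lines = text.splitlines()
    edited = [lines[0]] + [
        line.replace(",accept,", ",reject,") if "Negaitve" in line else line
        for line in lines[1:]
    ]
    review.write_text("\n".join(edited) + "\n")

    plan2, final2 = apply_review(facet, cfg, str(review))
    assert "Negaitve" in final2
    assert "Eolimax" not in final2
    assert plan2.resolved().get("Eolimax") == "Endolimax"
    assert "Negaitve" not in plan2.resolved()
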
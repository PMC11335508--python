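"""Name normalization, similarity matrices, evidence rules, resolution."""

import itertools

import numpy as np
import pytest

from piload.model import PIContact
from piload.names import (
    EvidenceProfile,
    NO_OVERLAP,
    ResolutionParams,
    STRONG_MATCH,
    WEAK_MATCH,
    build_similarity_matrix,
    candidate_pairs,
    compare_evidence,
    name_similarity,
    normalize_name,
    resolve_pis,
    variant_accounting,
)
from piload.synthetic import GeneratorConfig, generate_registry


# --- normalization ------------------------------------------------------------


@pytest.mark.parametrize(
    "raw,normalized,signature",
    [
        ("Dr. A. K. Sharma", "a k sharma", "aks"),
        ("SHARMA, A K", "sharma a k", "sak"),
        ("Prof Dr Anita Kumari Sharma", "anita kumari sharma", "aks"),
        ("  Smt.  Geeta   Verma ", "geeta verma", "gv"),
        ("Dr", "dr", "d"),  # a lone honorific token is kept, never emptied
    ],
)
def test_normalize_name(raw, normalized, signature):
    key = normalize_name(raw)
    assert key.normalized == normalized
    assert key.initials_signature == signature
    assert key.tokens == tuple(normalized.split())


def test_normalize_rejects_empty():
    with pytest.raises(ValueError):
        normalize_name("   ")


def test_normalize_idempotent_on_generated_names():
    records, _ = generate_registry(GeneratorConfig(n_pis=600, seed=17))
    names = [r.pi.name_raw for r in records if r.pi.name_raw][:1000]
    assert len(names) >= 900
    for raw in names:
        once = normalize_name(raw)
        twice = normalize_name(once.normalized)
        assert twice == once


# --- similarity ---------------------------------------------------------------


def test_identical_names_score_one_under_both_metrics():
    a = normalize_name("Dr A K Sharma")
    b = normalize_name("A. K. Sharma")
    assert name_similarity(a, b, "edit") == 1.0
    assert name_similarity(a, b, "token") == 1.0


def test_token_similarity_hand_computed():
    # |{a,k,sharma} ∩ {a,sharma}| / |{a,k,sharma} ∪ {a,sharma}| = 2/3
    a = normalize_name("a k sharma")
    b = normalize_name("a sharma")
    assert name_similarity(a, b, "token") == pytest.approx(2 / 3)


def test_token_similarity_matches_initialized_given_names():
    full = normalize_name("Anita Kumari Sharma")
    initials = normalize_name("A K Sharma")
    assert name_similarity(full, initials, "token") == 1.0
    # but a conflicting initial does not match
    other = normalize_name("B K Sharma")
    assert name_similarity(full, other, "token") < 1.0


def test_edit_similarity_single_typo():
    a = normalize_name("anil kumar sharma")  # length 17
    b = normalize_name("anil kumar sharna")
    assert name_similarity(a, b, "edit") == pytest.approx(1 - 1 / 17)


def test_similarity_symmetric_on_random_pairs():
    records, _ = generate_registry(GeneratorConfig(n_pis=40, seed=2))
    keys = [normalize_name(r.pi.name_raw) for r in records if r.pi.name_raw][:20]
    for a, b in itertools.combinations(keys, 2):
        for metric in ("edit", "token"):
            assert name_similarity(a, b, metric) == name_similarity(b, a, metric)


def test_unknown_metric_fatal():
    a = normalize_name("a b")
    with pytest.raises(ValueError):
        name_similarity(a, a, "jaro")


def test_similarity_matrix_equals_brute_force():
    records, _ = generate_registry(GeneratorConfig(n_pis=40, seed=9))
    keys = [normalize_name(r.pi.name_raw) for r in records if r.pi.name_raw][:20]
    for metric in ("edit", "token"):
        mat = build_similarity_matrix(keys, metric)
        assert np.allclose(mat, mat.T)
        assert np.allclose(np.diag(mat), 1.0)
        for i in range(len(keys)):
            for j in range(len(keys)):
                assert mat[i, j] == pytest.approx(name_similarity(keys[i], keys[j], metric))


def test_single_name_matrix():
    mat = build_similarity_matrix([normalize_name("a k sharma")])
    assert mat.shape == (1, 1) and mat[0, 0] == 1.0


def test_candidate_pairs_equal_brute_force_double_loop():
    records, _ = generate_registry(GeneratorConfig(n_pis=30, seed=31))
    keys = list({normalize_name(r.pi.name_raw) for r in records if r.pi.name_raw})[:15]
    keys.sort(key=lambda k: k.normalized)
    mats = {m: build_similarity_matrix(keys, m) for m in ("edit", "token")}
    threshold = 0.8
    got = {(a.normalized, b.normalized) for a, b, _ in candidate_pairs(mats, keys, threshold)}
    expected = set()
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            score = max(
                name_similarity(keys[i], keys[j], "edit"),
                name_similarity(keys[i], keys[j], "token"),
            )
            if score >= threshold:
                expected.add((keys[i].normalized, keys[j].normalized))
    assert got == expected


def test_candidate_pairs_threshold_boundaries():
    keys = [normalize_name(n) for n in ("a k sharma", "a k sharma", "b verma")]
    mats = {m: build_similarity_matrix(keys, m) for m in ("edit", "token")}
    exact = candidate_pairs(mats, keys, 1.0)
    assert [(a.normalized, b.normalized) for a, b, _ in exact] == [("a k sharma", "a k sharma")]
    everything = candidate_pairs(mats, keys, 1e-9)
    assert len(everything) == 3
    scores = [s for _, _, s in everything]
    assert scores == sorted(scores, reverse=True)


# --- evidence -----------------------------------------------------------------


def _profile(**kw):
    return EvidenceProfile.from_contact(PIContact(name_raw="x", **kw))


def test_shared_email_is_strong_despite_different_affiliations():
    a = _profile(email="X@Y.in", affiliation="Akola General Hospital")
    b = _profile(email="x@y.in", affiliation="Udupi Research Foundation")
    assert compare_evidence(a, b) == STRONG_MATCH


def test_phone_suffix_match_is_strong():
    a = _profile(phone="+91-98765 43210")
    b = _profile(phone="09876543210")
    assert compare_evidence(a, b) == STRONG_MATCH


def test_empty_profiles_no_overlap():
    assert compare_evidence(_profile(), _profile()) == NO_OVERLAP


def test_shared_postal_only_is_weak():
    a = _profile(postal_code="560100", email="a@b.in")
    b = _profile(postal_code="560100", email="c@d.in")
    assert compare_evidence(a, b) == WEAK_MATCH


def test_affiliation_overlap_weak_after_stopwords():
    a = _profile(affiliation="Sunrise Akola Institute of Medical Sciences")
    b = _profile(affiliation="Sunrise Akola Medical College")
    assert compare_evidence(a, b) == WEAK_MATCH
    c = _profile(affiliation="Crescent Udupi General Hospital")
    assert compare_evidence(a, c) == NO_OVERLAP


def test_compare_evidence_symmetric():
    a = _profile(email="x@y.in", postal_code="1")
    b = _profile(phone="9876543210", postal_code="1")
    assert compare_evidence(a, b) == compare_evidence(b, a)


# --- resolution ---------------------------------------------------------------


def test_exact_email_merges_honorific_variant():
    result = resolve_pis(
        [
            ("R1", PIContact(name_raw="Dr A Kumar", email="x@y.in")),
            ("R2", PIContact(name_raw="A. Kumar", email="x@y.in")),
        ]
    )
    assert len(result.clusters) == 1
    assert result.clusters[0].member_record_ids == {"R1", "R2"}
    assert result.variant_count == 1  # two raw spellings, one person


def test_same_spelling_conflicting_evidence_splits():
    result = resolve_pis(
        [
            ("R1", PIContact(name_raw="A Kumar", email="x@y.in")),
            ("R2", PIContact(name_raw="A Kumar", email="z@w.in")),
        ]
    )
    assert len(result.clusters) == 2
    assert result.variant_count == 0
    assert not result.ambiguous_record_ids


def test_identical_name_no_evidence_policy():
    pair = [
        ("R1", PIContact(name_raw="A Kumar")),
        ("R2", PIContact(name_raw="A Kumar")),
    ]
    merged = resolve_pis(pair)
    assert len(merged.clusters) == 1  # default: same spelling, same person
    split = resolve_pis(pair, ResolutionParams(identical_name_no_evidence="ambiguous"))
    assert len(split.clusters) == 0
    assert split.ambiguous_record_ids == {"R1", "R2"}


def test_bare_record_under_contested_spelling_is_ambiguous():
    result = resolve_pis(
        [
            ("R1", PIContact(name_raw="A Kumar", email="x@y.in")),
            ("R2", PIContact(name_raw="A Kumar", email="z@w.in")),
            ("R3", PIContact(name_raw="A Kumar")),  # cannot pick a side
        ]
    )
    assert len(result.clusters) == 2
    assert result.ambiguous_record_ids == {"R3"}


def test_multi_name_field_goes_to_ambiguous():
    result = resolve_pis(
        [
            ("R1", PIContact(name_raw="A Kumar / B Singh / C Rao", email="x@y.in")),
            ("R2", PIContact(name_raw="A Kumar", email="x@y.in")),
        ]
    )
    assert result.ambiguous_record_ids == {"R1"}
    assert "A Kumar / B Singh / C Rao" in result.ambiguous_names
    assert len(result.clusters) == 1


def test_weak_evidence_never_merges_different_names_by_default():
    result = resolve_pis(
        [
            ("R1", PIContact(name_raw="Asha Shah", postal_code="560001")),
            ("R2", PIContact(name_raw="Usha Shah", postal_code="560001")),
        ]
    )
    assert len(result.clusters) == 2
    allowed = resolve_pis(
        [
            ("R1", PIContact(name_raw="Asha Shah", postal_code="560001")),
            ("R2", PIContact(name_raw="Usha Shah", postal_code="560001")),
        ],
        ResolutionParams(weak_merges_different_names=True),
    )
    assert len(allowed.clusters) == 1


def test_record_torn_between_two_clusters_is_set_aside():
    result = resolve_pis(
        [
            ("A1", PIContact(name_raw="Anil Kumar Verma", email="anil@v.in")),
            ("A2", PIContact(name_raw="Anil Kumar Verma", email="anil@v.in")),
            ("B1", PIContact(name_raw="Geeta Menon", phone="9876543210")),
            ("B2", PIContact(name_raw="Geeta Menon", phone="9876543210")),
            # evidence points at both clusters; name matches neither
            ("T1", PIContact(name_raw="P Rao", email="anil@v.in", phone="9876543210")),
        ]
    )
    assert "P Rao" in result.ambiguous_names
    assert "T1" in result.ambiguous_record_ids
    assert len(result.clusters) == 2


def test_partition_and_determinism_on_default_noise(default_pipeline, default_registry):
    records, _ = default_registry
    result = default_pipeline.resolution
    kept_ids = {r.registry_id for r in default_pipeline.kept_records}
    clustered = [rid for c in result.clusters for rid in c.member_record_ids]
    assert len(clustered) == len(set(clustered))  # pairwise disjoint
    assert set(clustered) | set(result.ambiguous_record_ids) == kept_ids
    assert set(clustered) & set(result.ambiguous_record_ids) == set()
    # rerun -> identical result including cluster ids
    rerun = resolve_pis([(r.registry_id, r.pi) for r in default_pipeline.kept_records])
    assert [c.cluster_id for c in rerun.clusters] == [c.cluster_id for c in result.clusters]
    assert [c.member_record_ids for c in rerun.clusters] == [
        c.member_record_ids for c in result.clusters
    ]
    assert rerun.ambiguous_record_ids == result.ambiguous_record_ids


def test_variant_accounting_identity(default_pipeline):
    """spellings-in-clusters = clusters + variants (a spelling beyond a
    cluster's first is a variant), and every kept spelling is either
    resolved or ambiguous."""
    result = default_pipeline.resolution
    resolved_spellings = set().union(*(c.variant_names_absorbed for c in result.clusters))
    all_spellings = {r.pi.name_raw for r in default_pipeline.kept_records}
    assert resolved_spellings | set(result.ambiguous_names) == all_spellings
    assert result.variant_count == sum(
        len(c.variant_names_absorbed) - 1 for c in result.clusters
    )
    assert result.variant_count >= 0


def test_variant_accounting_helper():
    assert variant_accounting(4095, 179) == 3916
    with pytest.raises(ValueError):
        variant_accounting(10, 11)


def test_audit_merges_are_transitively_honoured(default_pipeline):
    result = default_pipeline.resolution
    cluster_of_name = {}
    counts = {}
    for c in result.clusters:
        n = c.canonical_name.normalized
        counts[n] = counts.get(n, 0) + 1
        cluster_of_name[n] = c.cluster_id
    for entry in result.audit_log:
        if entry["action"] != "merge_variant":
            continue
        a, b = entry["names"]
        # where each merged name maps to a unique cluster, it must be the same one
        if counts.get(a) == 1 and counts.get(b) == 1:
            assert cluster_of_name[a] == cluster_of_name[b]
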
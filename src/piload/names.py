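"""PI identity resolution: who is the same investigator under another spelling?

A registry has no investigator IDs, so the same person appears under many
raw spellings ("Dr. A. K. Sharma", "Anil Kumar Sharma", "SHARMA, A K") and
different people can share one spelling. Resolution proceeds in three
layers:

1. **Normalization** — strip honorifics and punctuation, case-fold, collapse
   whitespace. Records whose names normalize identically form blocks.
2. **Evidence** — contact fields (email, phone, fax, postal code,
   affiliation) canonicalized into an :class:`EvidenceProfile`. A shared
   email or phone/fax line is *strong* evidence of identity; a shared postal
   code or substantially overlapping affiliation is *weak*.
3. **Similarity** — two similarity matrices over normalized names
   (normalized edit-distance and token-set overlap) propose candidate
   variant pairs above a threshold; a candidate pair merges only on strong
   evidence. Weak evidence alone never merges *different* spellings, only
   supports unifying records that already share a spelling.

Merge decisions close under union-find (an equivalence relation). Names the
rules cannot settle — a field holding several person names, or a record
whose evidence ties it to two clusters that the rules refuse to merge — are
set aside as ambiguous rather than forced into a cluster.
"""

from __future__ import annotations

import itertools
import re
import string
from dataclasses import dataclass, field

import edlib
import networkx as nx
import numpy as np

from .model import PIContact

DEFAULT_HONORIFICS = (
    "dr", "prof", "professor", "mr", "mrs", "ms", "miss", "shri", "smt", "sri", "col", "maj",
)

#: generic affiliation words that carry no identity signal
AFFILIATION_STOPWORDS = frozenset(
    {
        "hospital", "institute", "institution", "college", "university", "centre",
        "center", "clinic", "medical", "research", "sciences", "science", "ltd",
        "pvt", "limited", "private", "laboratories", "labs", "lab", "dept",
        "department", "of", "the", "and", "for", "india",
    }
)

_MULTI_NAME_SEPARATORS = re.compile(r"[/;\n]| & | and ", re.IGNORECASE)

_PUNCT_TABLE = str.maketrans({c: " " for c in string.punctuation})


@dataclass(frozen=True)
class NameKey:
    """A normalized name: canonical string, its tokens, and an initials signature."""

    normalized: str
    tokens: tuple[str, ...]
    initials_signature: str


def normalize_name(raw: str, honorifics: tuple[str, ...] = DEFAULT_HONORIFICS) -> NameKey:
    """Normalize a raw PI name to a :class:`NameKey`.

    Strips leading honorific tokens, case-folds, removes punctuation and
    collapses whitespace. Idempotent: normalizing a normalized string is a
    no-op. Raises ``ValueError`` on an empty name (those records should have
    been dropped at the cohort filter's pi_present stage).
    """
    if not raw or not raw.strip():
        raise ValueError("cannot normalize an empty name")
    s = raw.casefold().translate(_PUNCT_TABLE)
    tokens = s.split()
    hon = set(honorifics)
    while len(tokens) > 1 and tokens[0] in hon:
        tokens = tokens[1:]
    normalized = " ".join(tokens)
    signature = "".join(t[0] for t in tokens)
    return NameKey(normalized=normalized, tokens=tuple(tokens), initials_signature=signature)


def looks_like_multiple_names(raw: str) -> bool:
    """True if a PI field appears to hold several person names."""
    parts = [p for p in _MULTI_NAME_SEPARATORS.split(raw) if p.strip()]
    return len(parts) > 1


# ---------------------------------------------------------------------------
# similarity


def _token_matches(sa: frozenset[str], sb: frozenset[str]) -> int:
    """Size of a maximum matching between two token sets.

    Tokens match when equal, or when one is a single letter equal to the
    other's first letter ("k" ~ "kumar"): registry names routinely reduce
    given names to initials, and a token metric blind to that misses the
    most common variant process. Exact matches are taken first; the
    remaining initial-compatibility graph is solved as a maximum matching,
    so the count (hence the score) is symmetric and deterministic.
    """
    exact = sa & sb
    ra = sorted(sa - exact)
    rb = sorted(sb - exact)
    adj = [
        [
            j
            for j, y in enumerate(rb)
            if (len(x) == 1 and y[0] == x) or (len(y) == 1 and x[0] == y)
        ]
        for x in ra
    ]
    # augmenting-path bipartite maximum matching (token sets are tiny)
    match_of_b: dict[int, int] = {}

    def _augment(i: int, seen: set[int]) -> bool:
        for j in adj[i]:
            if j in seen:
                continue
            seen.add(j)
            if j not in match_of_b or _augment(match_of_b[j], seen):
                match_of_b[j] = i
                return True
        return False

    matched = sum(_augment(i, set()) for i in range(len(ra)))
    return len(exact) + matched


def name_similarity(a: NameKey, b: NameKey, metric: str = "edit") -> float:
    """Similarity in [0, 1] between two normalized names.

    ``edit``: 1 - Levenshtein(a, b) / max(len); catches typos and spacing.
    ``token``: generalized Jaccard overlap of token sets with
    initial-to-name token matching; catches reordering, dropped tokens and
    initialized given names. Plain token sets (no initials involved) score
    exactly their Jaccard overlap. Both metrics are symmetric and score 1.0
    iff the names are equivalent under the metric.
    """
    if metric == "edit":
        if a.normalized == b.normalized:
            return 1.0
        d = edlib.align(a.normalized, b.normalized, task="distance")["editDistance"]
        longest = max(len(a.normalized), len(b.normalized))
        return 1.0 - d / longest if longest else 1.0
    if metric == "token":
        sa, sb = frozenset(a.tokens), frozenset(b.tokens)
        if not sa and not sb:
            return 1.0
        m = _token_matches(sa, sb)
        return m / (len(sa) + len(sb) - m)
    raise ValueError(f"unknown similarity metric: {metric!r}")


def build_similarity_matrix(names: list[NameKey], metric: str = "edit") -> np.ndarray:
    """Symmetric pairwise similarity matrix with unit diagonal."""
    if not names:
        raise ValueError("names must be non-empty")
    n = len(names)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = name_similarity(names[i], names[j], metric)
    return mat


def candidate_pairs(
    matrices: np.ndarray | dict[str, np.ndarray],
    names: list[NameKey],
    threshold: float,
) -> list[tuple[NameKey, NameKey, float]]:
    """Name pairs scoring >= threshold under ANY supplied metric's matrix.

    Returns (name_i, name_j, best_score) for i < j, sorted by descending
    score with ties broken lexicographically on the normalized pair.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    mats = matrices if isinstance(matrices, dict) else {"only": matrices}
    n = len(names)
    out = []
    for i in range(n):
        for j in range(i + 1, n):
            score = max(float(m[i, j]) for m in mats.values())
            if score >= threshold:
                out.append((names[i], names[j], score))
    out.sort(key=lambda t: (-t[2], t[0].normalized, t[1].normalized))
    return out


# ---------------------------------------------------------------------------
# evidence


def canonical_email(email: str) -> str:
    return email.strip().lower()


def canonical_phone(phone: str) -> str:
    """Digits only; numbers with >= 8 digits compared on their 8-digit suffix
    (country and trunk prefixes vary freely in registry data)."""
    digits = re.sub(r"\D", "", phone)
    return digits[-8:] if len(digits) >= 8 else digits


def affiliation_tokens(affiliation: str) -> frozenset[str]:
    toks = affiliation.casefold().translate(_PUNCT_TABLE).split()
    return frozenset(t for t in toks if t not in AFFILIATION_STOPWORDS)


@dataclass(frozen=True)
class EvidenceProfile:
    emails: frozenset[str] = frozenset()
    phones: frozenset[str] = frozenset()
    faxes: frozenset[str] = frozenset()
    affiliation_tokens: frozenset[str] = frozenset()
    postal_codes: frozenset[str] = frozenset()

    @classmethod
    def from_contact(cls, pi: PIContact) -> "EvidenceProfile":
        return cls(
            emails=frozenset({canonical_email(pi.email)} if pi.email else ()),
            phones=frozenset({canonical_phone(pi.phone)} if pi.phone else ()),
            faxes=frozenset({canonical_phone(pi.fax)} if pi.fax else ()),
            affiliation_tokens=affiliation_tokens(pi.affiliation) if pi.affiliation else frozenset(),
            postal_codes=frozenset({pi.postal_code.strip()} if pi.postal_code else ()),
        )

    def merged(self, other: "EvidenceProfile") -> "EvidenceProfile":
        return EvidenceProfile(
            emails=self.emails | other.emails,
            phones=self.phones | other.phones,
            faxes=self.faxes | other.faxes,
            affiliation_tokens=self.affiliation_tokens | other.affiliation_tokens,
            postal_codes=self.postal_codes | other.postal_codes,
        )

    @property
    def is_empty(self) -> bool:
        return not (
            self.emails or self.phones or self.faxes or self.affiliation_tokens or self.postal_codes
        )

    def strong_identifiers(self) -> frozenset[str]:
        """Tagged identifiers whose exact sharing means strong evidence."""
        return frozenset(
            itertools.chain(
                (f"email:{e}" for e in self.emails),
                (f"line:{p}" for p in self.phones | self.faxes),
            )
        )


STRONG_MATCH = "strong_match"
WEAK_MATCH = "weak_match"
NO_OVERLAP = "no_overlap"


def compare_evidence(
    a: EvidenceProfile, b: EvidenceProfile, affiliation_jaccard: float = 0.5
) -> str:
    """Verdict on whether two evidence profiles point at one person.

    Strong: a shared email, or a shared phone/fax line. Weak: no strong
    identifier shared but a shared postal code, or affiliation-token Jaccard
    at or above the configured cutoff. Symmetric.
    """
    if a.strong_identifiers() & b.strong_identifiers():
        return STRONG_MATCH
    if a.postal_codes & b.postal_codes:
        return WEAK_MATCH
    if a.affiliation_tokens and b.affiliation_tokens:
        union = a.affiliation_tokens | b.affiliation_tokens
        jac = len(a.affiliation_tokens & b.affiliation_tokens) / len(union)
        if jac >= affiliation_jaccard:
            return WEAK_MATCH
    return NO_OVERLAP


# ---------------------------------------------------------------------------
# resolution


@dataclass(frozen=True)
class ResolutionParams:
    similarity_threshold: float = 0.85
    honorifics: tuple[str, ...] = DEFAULT_HONORIFICS
    affiliation_jaccard: float = 0.5
    #: policy for identical spellings where no record carries any evidence
    identical_name_no_evidence: str = "merge"  # or "ambiguous"
    #: whether weak evidence may merge *different* spellings (default: never)
    weak_merges_different_names: bool = False
    metrics: tuple[str, ...] = ("edit", "token")


@dataclass
class PICluster:
    cluster_id: str
    canonical_name: NameKey
    member_record_ids: frozenset[str]
    variant_names_absorbed: frozenset[str]
    evidence: EvidenceProfile

    @property
    def n_trials(self) -> int:
        return len(self.member_record_ids)


@dataclass
class ResolutionResult:
    clusters: list[PICluster]
    ambiguous_names: frozenset[str]
    ambiguous_record_ids: frozenset[str]
    variant_count: int
    audit_log: list[dict] = field(default_factory=list)

    @property
    def n_unique_pis(self) -> int:
        return len(self.clusters)

    def record_to_cluster(self) -> dict[str, str]:
        return {
            rid: c.cluster_id for c in self.clusters for rid in c.member_record_ids
        }


def variant_accounting(distinct_raw_names: int, variant_count: int) -> int:
    """Unique investigators implied by name-variant bookkeeping: the distinct
    raw spellings that were resolved, minus the spellings absorbed as
    variants of an already-identified person."""
    if variant_count < 0 or variant_count > distinct_raw_names:
        raise ValueError("variant_count must be in [0, distinct_raw_names]")
    return distinct_raw_names - variant_count


@dataclass
class _Candidate:
    """A candidate person: records sharing one NameKey, unified by evidence."""

    key: NameKey
    record_ids: list[str]
    raw_names: set[str]
    evidence: EvidenceProfile


def resolve_pis(
    records: list[tuple[str, PIContact]],
    params: ResolutionParams | None = None,
) -> ResolutionResult:
    """Resolve (registry_id, PIContact) pairs into unique-investigator clusters.

    Every input record lands in exactly one cluster or in the ambiguous set.
    Deterministic: no randomness, cluster IDs assigned by sorted canonical
    name. See the module docstring for the algorithm.
    """
    params = params or ResolutionParams()
    audit: list[dict] = []
    ambiguous_names: set[str] = set()
    ambiguous_record_ids: set[str] = set()

    # --- step 0: set aside fields holding several person names
    usable: list[tuple[str, PIContact]] = []
    for rid, pi in records:
        if pi.is_absent:
            raise ValueError(f"record {rid} has no PI name (filter upstream)")
        if looks_like_multiple_names(pi.name_raw):
            ambiguous_names.add(pi.name_raw)
            ambiguous_record_ids.add(rid)
            audit.append({"action": "set_aside_multi_name", "record": rid, "name": pi.name_raw})
        else:
            usable.append((rid, pi))

    # --- step 1: normalize and block on identical NameKeys
    blocks: dict[NameKey, list[tuple[str, PIContact]]] = {}
    for rid, pi in usable:
        key = normalize_name(pi.name_raw, params.honorifics)
        blocks.setdefault(key, []).append((rid, pi))

    # --- step 2: within-block evidence split -> candidate persons
    candidates: list[_Candidate] = []
    for key in sorted(blocks, key=lambda k: k.normalized):
        members = sorted(blocks[key], key=lambda t: t[0])
        profiles = {rid: EvidenceProfile.from_contact(pi) for rid, pi in members}
        with_ev = [rid for rid, _ in members if not profiles[rid].is_empty]
        without_ev = [rid for rid, _ in members if profiles[rid].is_empty]
        g = nx.Graph()
        g.add_nodes_from(with_ev)
        for ra, rb in itertools.combinations(with_ev, 2):
            if compare_evidence(profiles[ra], profiles[rb], params.affiliation_jaccard) != NO_OVERLAP:
                g.add_edge(ra, rb)
        components = [sorted(c) for c in nx.connected_components(g)]
        components.sort(key=lambda c: c[0])
        raw_by_rid = {rid: pi.name_raw for rid, pi in members}

        if without_ev:
            if len(components) == 0:
                if params.identical_name_no_evidence == "merge":
                    components = [sorted(without_ev)]
                else:
                    for rid in without_ev:
                        ambiguous_record_ids.add(rid)
                        ambiguous_names.add(raw_by_rid[rid])
                        audit.append({"action": "set_aside_no_evidence", "record": rid})
                    components = []
                without_ev = []
            elif len(components) == 1 and params.identical_name_no_evidence == "merge":
                components[0] = sorted(components[0] + without_ev)
                without_ev = []
            else:
                # several evidence-distinct people share this spelling: a bare
                # record cannot be assigned to any of them
                for rid in without_ev:
                    ambiguous_record_ids.add(rid)
                    ambiguous_names.add(raw_by_rid[rid])
                    audit.append(
                        {"action": "set_aside_contested_spelling", "record": rid, "name": raw_by_rid[rid]}
                    )
                without_ev = []
        if len(components) > 1:
            audit.append(
                {
                    "action": "split_identical_spelling",
                    "name": key.normalized,
                    "n_persons": len(components),
                }
            )
        for comp in components:
            ev = EvidenceProfile()
            for rid in comp:
                ev = ev.merged(profiles[rid])
            candidates.append(
                _Candidate(
                    key=key,
                    record_ids=list(comp),
                    raw_names={raw_by_rid[rid] for rid in comp},
                    evidence=ev,
                )
            )

    # --- step 3: cross-spelling candidate pairs, merged on strong evidence
    keys = sorted({c.key for c in candidates}, key=lambda k: k.normalized)
    merges: list[tuple[int, int]] = []
    if len(keys) > 1:
        mats = {m: build_similarity_matrix(keys, m) for m in params.metrics}
        pairs = candidate_pairs(mats, keys, params.similarity_threshold)
        by_key: dict[NameKey, list[int]] = {}
        for idx, c in enumerate(candidates):
            by_key.setdefault(c.key, []).append(idx)
        for ka, kb, score in pairs:
            if ka == kb:
                continue
            for ia in by_key[ka]:
                for ib in by_key[kb]:
                    verdict = compare_evidence(
                        candidates[ia].evidence, candidates[ib].evidence, params.affiliation_jaccard
                    )
                    if verdict == STRONG_MATCH or (
                        verdict == WEAK_MATCH and params.weak_merges_different_names
                    ):
                        merges.append((ia, ib))
                        audit.append(
                            {
                                "action": "merge_variant",
                                "names": [ka.normalized, kb.normalized],
                                "score": round(score, 4),
                                "evidence": verdict,
                            }
                        )

    # --- step 4: union-find closure
    g = nx.Graph()
    g.add_nodes_from(range(len(candidates)))
    g.add_edges_from(merges)
    groups = [sorted(c) for c in nx.connected_components(g)]

    # --- step 5: contradiction check — a record whose contact evidence points
    # at two distinct clusters it does not belong to cannot be assigned; such
    # a raw spelling is set aside rather than forced into either cluster.
    raw_contact: dict[str, str] = {rid: pi.name_raw for rid, pi in usable}
    pi_by_rid: dict[str, PIContact] = dict(usable)
    group_of_rec: dict[str, int] = {}
    rec_candidate: dict[str, _Candidate] = {}
    for gi, grp in enumerate(groups):
        for idx in grp:
            for rid in candidates[idx].record_ids:
                group_of_rec[rid] = gi
                rec_candidate[rid] = candidates[idx]
    rec_profile = {
        rid: EvidenceProfile.from_contact(pi_by_rid[rid]) for rid in group_of_rec
    }
    ident_to_recs: dict[str, list[str]] = {}
    for rid, prof in rec_profile.items():
        for ident in prof.strong_identifiers():
            ident_to_recs.setdefault(ident, []).append(rid)
    contested_raw: set[str] = set()
    for rid, prof in rec_profile.items():
        foreign = {
            group_of_rec[other]
            for ident in prof.strong_identifiers()
            for other in ident_to_recs[ident]
            if other != rid
        } - {group_of_rec[rid]}
        if len(foreign) >= 2:
            contested_raw.add(raw_contact[rid])
            audit.append(
                {
                    "action": "set_aside_cross_cluster_evidence",
                    "record": rid,
                    "name": raw_contact[rid],
                    "n_foreign_clusters": len(foreign),
                }
            )

    # --- step 6: emit clusters, dropping contested raw names into the ambiguous set
    clusters: list[PICluster] = []
    prelim = []
    for grp in groups:
        rec_ids: list[str] = []
        raws: set[str] = set()
        ev = EvidenceProfile()
        key_votes: dict[NameKey, int] = {}
        for idx in grp:
            cand = candidates[idx]
            keep_ids = [
                rid for rid in cand.record_ids if raw_contact[rid] not in contested_raw
            ]
            dropped = [rid for rid in cand.record_ids if rid not in keep_ids]
            for rid in dropped:
                ambiguous_record_ids.add(rid)
                ambiguous_names.add(raw_contact[rid])
            if keep_ids:
                rec_ids.extend(keep_ids)
                raws |= {raw_contact[rid] for rid in keep_ids}
                for rid in keep_ids:
                    ev = ev.merged(rec_profile[rid])
                key_votes[cand.key] = key_votes.get(cand.key, 0) + len(keep_ids)
        if not rec_ids:
            continue
        canonical = max(key_votes, key=lambda k: (key_votes[k], k.normalized))
        prelim.append((canonical, sorted(rec_ids), raws, ev))
    prelim.sort(key=lambda t: (t[0].normalized, t[1][0]))
    width = max(4, len(str(len(prelim))))
    for i, (canonical, rec_ids, raws, ev) in enumerate(prelim, start=1):
        clusters.append(
            PICluster(
                cluster_id=f"PI{i:0{width}d}",
                canonical_name=canonical,
                member_record_ids=frozenset(rec_ids),
                variant_names_absorbed=frozenset(raws),
                evidence=ev,
            )
        )

    # a variant is a raw spelling absorbed into a cluster beyond its first:
    # counting per cluster keeps the tally non-negative even when one
    # spelling legitimately splits into several investigators
    variant_count = sum(len(c.variant_names_absorbed) - 1 for c in clusters)
    return ResolutionResult(
        clusters=clusters,
        ambiguous_names=frozenset(ambiguous_names),
        ambiguous_record_ids=frozenset(ambiguous_record_ids),
        variant_count=variant_count,
        audit_log=audit,
    )
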
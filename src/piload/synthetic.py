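"""Synthetic registry generator with ground-truth investigator identities.

Emulates the statistical structure the analysis has to survive in a real
registry dump: a heavy-tailed trials-per-PI distribution (most
investigators run one trial; a rare few run dozens), name-variant processes
(honorifics, initialized given names, typos, token swaps, case changes),
partial contact-evidence coverage, ineligible decoy records for every
cohort-filter stage, and missing/zero timeline fields. Every record carries
a ground-truth PI label, so resolution quality is measurable as pairwise
precision/recall against known identities.

All randomness flows from one :class:`numpy.random.Generator` seeded in the
config: a fixed seed reproduces the dataset byte for byte.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field as dc_field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from . import _lexicon as lex
from .model import CalendarDuration, PIContact, RawTrialRecord
from .names import ResolutionResult

# applied in this order so that structural edits (initials, swaps, typos)
# act on the bare name before decoration (honorific, casing) is layered on
VARIANT_PROCESSES = (
    "initialize_given_names",
    "token_swap",
    "typo_edit1",
    "honorific_add",
    "case_change",
)


def _default_variant_rates() -> dict[str, float]:
    return {
        "honorific_add": 0.15,
        "initialize_given_names": 0.10,
        "typo_edit1": 0.03,
        "token_swap": 0.03,
        "case_change": 0.10,
    }


def _default_evidence_coverage() -> dict[str, float]:
    return {"email": 0.90, "phone": 0.70, "fax": 0.10, "affiliation": 0.80, "postal": 0.60}


def _default_ineligible_rates() -> dict[str, float]:
    return {
        "trial_type": 0.05,
        "study_type": 0.05,
        "pg_thesis": 0.04,
        "country": 0.03,
        "pi_missing": 0.03,
    }


def _default_trials_distribution() -> dict:
    # head matches the reported single/double/triple fractions of a national
    # registry; the remaining mass is a power-law tail producing rare
    # high-burden investigators
    return {"head": {1: 0.757, 2: 0.136, 3: 0.043}, "tail_alpha": 1.8, "tail_max": 108}


@dataclass
class GeneratorConfig:
    n_pis: int = 200
    trials_per_pi_distribution: dict = dc_field(default_factory=_default_trials_distribution)
    variant_process_rates: dict[str, float] = dc_field(default_factory=_default_variant_rates)
    evidence_coverage: dict[str, float] = dc_field(default_factory=_default_evidence_coverage)
    email_stability: float = 0.90
    ineligible_record_rate: dict[str, float] = dc_field(default_factory=_default_ineligible_rates)
    multi_name_rate: float = 0.002
    start_window: tuple[date, date] = (date(2009, 1, 1), date(2023, 4, 1))
    duration_median_months: float = 18.0
    duration_sigma: float = 0.6
    completion_present_prob: float = 0.40
    sabotage_rates: dict[str, float] = dc_field(
        default_factory=lambda: {"missing_start": 0.004, "zero_duration": 0.004}
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_pis < 1:
            raise ValueError("n_pis must be >= 1")
        head = self.trials_per_pi_distribution.get("head", {})
        if any(p < 0 for p in head.values()) or any(k < 1 for k in head):
            raise ValueError("head distribution needs counts >= 1 with probabilities >= 0")
        head_mass = sum(head.values())
        if head_mass > 1 + 1e-9:
            raise ValueError("head probabilities exceed 1")
        tail_min = (max(head) + 1) if head else 1
        if head_mass < 1 - 1e-9 and self.trials_per_pi_distribution.get("tail_max", 0) < tail_min:
            raise ValueError("infeasible trials-per-PI distribution: tail has empty support")
        if head_mass == 0 and not head and self.trials_per_pi_distribution.get("tail_max", 0) < 1:
            raise ValueError("infeasible trials-per-PI distribution: no probability mass")
        for name, probs in (
            ("variant_process_rates", self.variant_process_rates),
            ("evidence_coverage", self.evidence_coverage),
            ("ineligible_record_rate", self.ineligible_record_rate),
            ("sabotage_rates", self.sabotage_rates),
        ):
            for k, p in probs.items():
                if not 0 <= p <= 1:
                    raise ValueError(f"{name}[{k}] = {p} outside [0, 1]")
        for name, p in (
            ("email_stability", self.email_stability),
            ("multi_name_rate", self.multi_name_rate),
            ("completion_present_prob", self.completion_present_prob),
        ):
            if not 0 <= p <= 1:
                raise ValueError(f"{name} = {p} outside [0, 1]")
        if self.start_window[1] < self.start_window[0]:
            raise ValueError("start_window end precedes start")


@dataclass
class TruePI:
    pi_id: str
    name: str  # canonical display form, e.g. "Anita Kumari Sharma"
    emails: tuple[str, str]
    phone: str
    fax: str
    affiliation: str
    postal_code: str


@dataclass
class GroundTruth:
    record_pi: dict[str, str]  # registry_id -> true pi_id
    pis: dict[str, TruePI]
    eligibility: dict[str, dict[str, bool]]  # registry_id -> stage -> passes
    count_vector: dict[str, int]  # pi_id -> eligible PI-bearing records
    variant_spellings: list[tuple[str, str, str]]  # (registry_id, displayed, canonical)
    multi_name_record_ids: set[str] = dc_field(default_factory=set)
    timeline_flags: dict[str, dict[str, bool]] = dc_field(default_factory=dict)

    def eligible_ids(self) -> set[str]:
        return {rid for rid, st in self.eligibility.items() if all(st.values())}


# ---------------------------------------------------------------------------
# variant processes


def make_variant(name: str, process: str, rng: np.random.Generator) -> str:
    """Apply one name-variant process to a display-form name."""
    tokens = name.split()
    if process == "honorific_add":
        hon = lex.HONORIFIC_FORMS[rng.integers(len(lex.HONORIFIC_FORMS))]
        return f"{hon} {name}"
    if process == "initialize_given_names":
        if len(tokens) < 2:
            return name
        return " ".join([t[0].upper() for t in tokens[:-1]] + [tokens[-1]])
    if process == "typo_edit1":
        letters = "abcdefghijklmnopqrstuvwxyz"
        for _ in range(20):  # resample until the edit really changes the string
            chars = list(name)
            positions = [i for i, c in enumerate(chars) if c.isalpha()]
            i = positions[rng.integers(len(positions))]
            op = ("substitute", "insert", "delete")[rng.integers(3)]
            if op == "substitute":
                c = letters[rng.integers(26)]
                if c == chars[i].lower():
                    continue
                chars[i] = c
            elif op == "insert":
                chars.insert(i, letters[rng.integers(26)])
            else:
                if len([c for c in chars if c.isalpha()]) <= 2:
                    continue
                del chars[i]
            out = "".join(chars)
            if out.split() != [] and all(t for t in out.split()):
                return out
        return name
    if process == "token_swap":
        if len(tokens) < 2:
            return name
        i, j = rng.choice(len(tokens), size=2, replace=False)
        tokens[i], tokens[j] = tokens[j], tokens[i]
        return " ".join(tokens)
    if process == "case_change":
        forms = (name.upper(), name.lower(), name.title())
        candidates = [f for f in forms if f != name] or [name]
        return candidates[rng.integers(len(candidates))]
    raise ValueError(f"unknown variant process: {process!r}")


# ---------------------------------------------------------------------------
# generation


def _sample_unique_names(rng: np.random.Generator, n: int) -> list[str]:
    """Distinct canonical display names (distinct after case-folding too)."""
    names: list[str] = []
    seen: set[str] = set()
    attempts = 0
    while len(names) < n:
        attempts += 1
        if attempts > 100 * n + 1000:
            raise ValueError(f"cannot sample {n} distinct names from the lexicon")
        given = lex.GIVEN_NAMES[rng.integers(len(lex.GIVEN_NAMES))]
        sur = lex.SURNAMES[rng.integers(len(lex.SURNAMES))]
        if rng.random() < 0.55:
            mid = lex.MIDDLE_NAMES[rng.integers(len(lex.MIDDLE_NAMES))]
            name = f"{given} {mid} {sur}"
        else:
            name = f"{given} {sur}"
        if name.casefold() not in seen:
            seen.add(name.casefold())
            names.append(name)
    return names


def _sample_trial_count(rng: np.random.Generator, dist: dict) -> int:
    head: dict[int, float] = dist.get("head", {})
    ks = sorted(head)
    head_mass = sum(head[k] for k in ks)
    u = rng.random()
    acc = 0.0
    for k in ks:
        acc += head[k]
        if u < acc:
            return k
    # tail: discrete power law over [tail_min, tail_max]
    lo = (max(ks) + 1) if ks else 1
    hi = int(dist.get("tail_max", 108))
    alpha = float(dist.get("tail_alpha", 1.8))
    support = np.arange(lo, hi + 1)
    w = support.astype(float) ** -alpha
    w /= w.sum()
    return int(rng.choice(support, p=w))


def _sample_start(rng: np.random.Generator, window: tuple[date, date]) -> date:
    span = (window[1] - window[0]).days
    return window[0] + timedelta(days=int(rng.integers(span + 1)))


def _sample_duration(rng: np.random.Generator, cfg: GeneratorConfig) -> CalendarDuration:
    months = max(1, int(round(rng.lognormal(np.log(cfg.duration_median_months), cfg.duration_sigma))))
    return CalendarDuration(years=months // 12, months=months % 12)


def generate_registry(config: GeneratorConfig) -> tuple[list[RawTrialRecord], GroundTruth]:
    """Generate a registry dump with ground truth; deterministic per seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    names = _sample_unique_names(rng, config.n_pis)
    pis: dict[str, TruePI] = {}
    for i, name in enumerate(names, start=1):
        pid = f"T{i:04d}"
        toks = name.lower().split()
        dom = lex.EMAIL_DOMAINS[rng.integers(len(lex.EMAIL_DOMAINS))]
        dom2 = lex.EMAIL_DOMAINS[rng.integers(len(lex.EMAIL_DOMAINS))]
        emails = (
            f"{toks[0]}.{toks[-1]}.{i}@{dom}",
            f"{toks[-1]}.{toks[0]}{i}@{dom2}",
        )
        phone = "9" + "".join(str(rng.integers(10)) for _ in range(9))
        fax = "080" + "".join(str(rng.integers(10)) for _ in range(8))
        affiliation = "{} {} {}".format(
            lex.ORG_DESCRIPTORS[rng.integers(len(lex.ORG_DESCRIPTORS))],
            lex.CITIES[rng.integers(len(lex.CITIES))],
            lex.ORG_TYPES[rng.integers(len(lex.ORG_TYPES))],
        )
        postal = "".join(str(rng.integers(10)) for _ in range(6))
        pis[pid] = TruePI(pid, name, emails, phone, fax, affiliation, postal)

    truth = GroundTruth(record_pi={}, pis=pis, eligibility={}, count_vector={}, variant_spellings=[])
    records: list[RawTrialRecord] = []
    counter = itertools.count(1)
    pi_ids = sorted(pis)

    for pid in pi_ids:
        pi = pis[pid]
        n_trials = _sample_trial_count(rng, config.trials_per_pi_distribution)
        truth.count_vector[pid] = 0
        for _ in range(n_trials):
            seq = next(counter)
            start = _sample_start(rng, config.start_window)
            rid = f"CTRI/{start.year}/{start.month:02d}/{seq:06d}"

            stages = {s: True for s in ("trial_type", "study_type", "pg_thesis", "country", "pi_present")}
            type_of_trial = "Interventional"
            types_of_study = frozenset({("Drug", "Vaccine", "Biological", "Preventive", "Dentistry", "Stem Cell Therapy")[rng.integers(6)]})
            pg = ("No", "NA")[rng.integers(2)]
            countries = frozenset({"India"})
            rates = config.ineligible_record_rate
            if rng.random() < rates.get("trial_type", 0):
                type_of_trial = "Observational"
                stages["trial_type"] = False
            if rng.random() < rates.get("study_type", 0):
                types_of_study = frozenset({("Ayurveda", "Homeopathy", "Siddha", "Unani")[rng.integers(4)]})
                stages["study_type"] = False
            if rng.random() < rates.get("pg_thesis", 0):
                pg = "Yes"
                stages["pg_thesis"] = False
            if rng.random() < rates.get("country", 0):
                countries = frozenset({("Nepal", "Bangladesh", "Sri Lanka")[rng.integers(3)]})
                stages["country"] = False
            pi_missing = rng.random() < rates.get("pi_missing", 0)
            if pi_missing:
                stages["pi_present"] = False

            # displayed name: canonical form run through sampled variant processes
            displayed = pi.name
            if not pi_missing:
                for proc in VARIANT_PROCESSES:
                    if rng.random() < config.variant_process_rates.get(proc, 0):
                        displayed = make_variant(displayed, proc, rng)
                if rng.random() < config.multi_name_rate and len(pi_ids) > 1:
                    other = pis[pi_ids[int(rng.integers(len(pi_ids)))]]
                    if other.pi_id != pid:
                        displayed = f"{displayed} / {other.name}"
                        truth.multi_name_record_ids.add(rid)
                if displayed != pi.name:
                    truth.variant_spellings.append((rid, displayed, pi.name))

            cov = config.evidence_coverage
            if pi_missing:
                contact = PIContact()
            else:
                email = None
                if rng.random() < cov.get("email", 0):
                    email = pi.emails[0] if rng.random() < config.email_stability else pi.emails[1]
                contact = PIContact(
                    name_raw=displayed,
                    email=email,
                    phone=pi.phone if rng.random() < cov.get("phone", 0) else None,
                    fax=pi.fax if rng.random() < cov.get("fax", 0) else None,
                    affiliation=pi.affiliation if rng.random() < cov.get("affiliation", 0) else None,
                    postal_code=pi.postal_code if rng.random() < cov.get("postal", 0) else None,
                )

            # timeline fields, with sabotage
            missing_start = rng.random() < config.sabotage_rates.get("missing_start", 0)
            zero_duration = rng.random() < config.sabotage_rates.get("zero_duration", 0)
            duration = CalendarDuration() if zero_duration else _sample_duration(rng, config)
            completion_present = rng.random() < config.completion_present_prob
            completion = None
            if completion_present:
                delay = int(rng.integers(0, 180))
                completion = (
                    start
                    + timedelta(days=30 * (duration.years * 12 + duration.months) + duration.days)
                    + timedelta(days=delay)
                )

            records.append(
                RawTrialRecord(
                    registry_id=rid,
                    type_of_trial=type_of_trial,
                    types_of_study=types_of_study,
                    post_graduate_thesis=pg,
                    countries_of_recruitment=countries,
                    pi=contact,
                    date_first_enrollment=None if missing_start else start,
                    estimated_duration=duration,
                    date_study_completion=completion,
                )
            )
            truth.record_pi[rid] = pid
            truth.eligibility[rid] = stages
            truth.timeline_flags[rid] = {
                "missing_start": missing_start,
                "zero_duration": zero_duration,
                "completion_present": completion_present,
            }
            if all(stages.values()):
                truth.count_vector[pid] += 1

    truth.count_vector = {p: c for p, c in truth.count_vector.items() if c > 0}
    return records, truth


# ---------------------------------------------------------------------------
# serialization (round-trips through registry ingest)

_DATE_FMT = "%d/%m/%Y"


def records_to_frame(records: list[RawTrialRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "registry_id": r.registry_id,
                "type_of_trial": r.type_of_trial,
                "types_of_study": ", ".join(sorted(r.types_of_study)),
                "post_graduate_thesis": r.post_graduate_thesis or "NA",
                "countries_of_recruitment": ", ".join(sorted(r.countries_of_recruitment)),
                "pi_name": r.pi.name_raw,
                "pi_email": r.pi.email or "",
                "pi_phone": r.pi.phone or "",
                "pi_fax": r.pi.fax or "",
                "pi_affiliation": r.pi.affiliation or "",
                "pi_address": r.pi.address or "",
                "pi_postal_code": r.pi.postal_code or "",
                "date_first_enrollment": r.date_first_enrollment.strftime(_DATE_FMT)
                if r.date_first_enrollment
                else "NA",
                "estimated_duration": str(r.estimated_duration)
                if r.estimated_duration is not None
                else "NA",
                "date_study_completion": r.date_study_completion.strftime(_DATE_FMT)
                if r.date_study_completion
                else "NA",
            }
        )
    return pd.DataFrame(rows)


def write_registry(records: list[RawTrialRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# resolution scoring


@dataclass(frozen=True)
class ResolutionScore:
    precision: float
    recall: float
    f1: float
    cluster_count_error: int  # predicted clusters minus true PIs among resolved records
    n_records_scored: int


def evaluate_resolution(result: ResolutionResult, truth: GroundTruth) -> ResolutionScore:
    """Pairwise precision/recall/F1 of a resolution against ground truth.

    Scored over all record pairs among clustered records (records the
    resolver set aside as ambiguous are outside the pairing). A pair is a
    true positive when the two records share both a predicted cluster and a
    true PI label.
    """
    from math import comb

    resolved = [rid for c in result.clusters for rid in c.member_record_ids]
    unlabeled = [rid for rid in resolved if rid not in truth.record_pi]
    if unlabeled:
        raise ValueError(f"records missing ground-truth labels: {sorted(unlabeled)[:5]}")

    predicted_pairs = sum(comb(c.n_trials, 2) for c in result.clusters)
    true_counts: dict[str, int] = {}
    tp = 0
    for c in result.clusters:
        by_true: dict[str, int] = {}
        for rid in c.member_record_ids:
            by_true[truth.record_pi[rid]] = by_true.get(truth.record_pi[rid], 0) + 1
        tp += sum(comb(n, 2) for n in by_true.values())
    for rid in resolved:
        t = truth.record_pi[rid]
        true_counts[t] = true_counts.get(t, 0) + 1
    true_pairs = sum(comb(n, 2) for n in true_counts.values())

    precision = tp / predicted_pairs if predicted_pairs else 1.0
    recall = tp / true_pairs if true_pairs else 1.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return ResolutionScore(
        precision=precision,
        recall=recall,
        f1=f1,
        cluster_count_error=len(result.clusters) - len(true_counts),
        n_records_scored=len(resolved),
    )
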
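"""Cohort filter cascade with stage-by-stage accounting.

Selects interventional trials of the eligible study types, excludes
postgraduate-thesis studies, requires India among the recruiting countries,
and finally drops records with no PI details at all. The cascade is a
funnel: each record is attributed to its FIRST failing stage, so the report
reproduces the flow-diagram semantics of a shortlisting figure (each box's
kept count feeds the next box).

All value matching is case-insensitive after trimming, with "N/A"
normalized to "NA". A record with an absent *Post Graduate Thesis* field is
treated as "NA" (kept): in a flattened dump, absence is indistinguishable
from NA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import RawTrialRecord

STAGES = ("trial_type", "study_type", "pg_thesis", "country", "pi_present")


def _norm(value: str | None) -> str:
    v = (value or "").strip().lower()
    return "na" if v in {"n/a", ""} else v


@dataclass(frozen=True)
class FilterCriteria:
    required_trial_type: str = "Interventional"
    eligible_study_types: frozenset[str] = frozenset(
        {"Biological", "Preventive", "Dentistry", "Drug", "Stem Cell Therapy", "Vaccine"}
    )
    pg_thesis_allowed: frozenset[str] = frozenset({"No", "NA"})
    required_country: str = "India"
    require_pi_details: bool = True

    def __post_init__(self) -> None:
        if not self.eligible_study_types or not self.pg_thesis_allowed:
            raise ValueError("criteria sets must be non-empty")


@dataclass(frozen=True)
class Verdict:
    keep: bool
    stage: str
    reason: str | None = None  # failing value, for auditability


@dataclass
class StageLine:
    stage: str
    input_count: int
    kept_count: int
    excluded_count: int


@dataclass
class FilterReport:
    """Funnel accounting: every stage satisfies input = kept + excluded and
    each stage's kept count is the next stage's input count."""

    stages: list[StageLine] = field(default_factory=list)
    final_kept_ids: list[str] = field(default_factory=list)
    exclusion_reasons: dict[str, tuple[str, str | None]] = field(default_factory=dict)

    def validate(self) -> None:
        for line in self.stages:
            if line.input_count != line.kept_count + line.excluded_count:
                raise AssertionError(f"stage {line.stage}: conservation violated")
        for a, b in zip(self.stages, self.stages[1:]):
            if a.kept_count != b.input_count:
                raise AssertionError(f"funnel broken between {a.stage} and {b.stage}")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame([vars(s) for s in self.stages])


def evaluate_stage(
    record: RawTrialRecord, stage: str, criteria: FilterCriteria
) -> Verdict:
    """Apply one cascade stage to one record."""
    if stage == "trial_type":
        ok = _norm(record.type_of_trial) == _norm(criteria.required_trial_type)
        return Verdict(ok, stage, None if ok else record.type_of_trial)
    if stage == "study_type":
        eligible = {_norm(t) for t in criteria.eligible_study_types}
        have = {_norm(t) for t in record.types_of_study}
        ok = bool(eligible & have)
        return Verdict(ok, stage, None if ok else ", ".join(sorted(record.types_of_study)))
    if stage == "pg_thesis":
        allowed = {_norm(v) for v in criteria.pg_thesis_allowed}
        ok = _norm(record.post_graduate_thesis) in allowed
        return Verdict(ok, stage, None if ok else record.post_graduate_thesis)
    if stage == "country":
        ok = _norm(criteria.required_country) in {
            _norm(c) for c in record.countries_of_recruitment
        }
        return Verdict(ok, stage, None if ok else ", ".join(sorted(record.countries_of_recruitment)))
    if stage == "pi_present":
        if not criteria.require_pi_details:
            return Verdict(True, stage)
        ok = not record.pi.is_absent
        return Verdict(ok, stage, None if ok else "(no PI details)")
    raise ValueError(f"unknown filter stage: {stage!r}")


def apply_cohort_filter(
    records: list[RawTrialRecord], criteria: FilterCriteria | None = None
) -> tuple[list[RawTrialRecord], FilterReport]:
    """Run the full cascade, excluding each record at its first failing stage.

    The kept list preserves input order. The final kept SET is the plain
    conjunction of all predicates; only the attribution of exclusions
    depends on stage order.
    """
    criteria = criteria or FilterCriteria()
    report = FilterReport()
    current = list(records)
    for stage in STAGES:
        kept: list[RawTrialRecord] = []
        excluded = 0
        for rec in current:
            verdict = evaluate_stage(rec, stage, criteria)
            if verdict.keep:
                kept.append(rec)
            else:
                excluded += 1
                report.exclusion_reasons[rec.registry_id] = (stage, verdict.reason)
        report.stages.append(
            StageLine(stage, input_count=len(current), kept_count=len(kept), excluded_count=excluded)
        )
        current = kept
    report.final_kept_ids = [r.registry_id for r in current]
    report.validate()
    return current, report
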
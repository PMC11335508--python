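"""Per-trial activity intervals and active-year (Gantt) attribution.

Registry records often lack a *Date of Study Completion*. The pipeline's
conservative imputation adds the *Estimated Duration of Trial* plus a
3-month allowance for recruitment delay to the enrollment start date. A
recorded completion date always wins over imputation. Records with no start
date, or with neither a completion date nor a usable (non-zero) duration,
cannot be placed on a timeline and are excluded with an explicit reason.

Month arithmetic is calendar arithmetic with day-of-month clamping
(Jan 31 + 1 month = Feb 28/29), not fixed 30- or 90-day offsets.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

from dateutil.relativedelta import relativedelta

from .model import CalendarDuration, RawTrialRecord
from .names import ResolutionResult

#: recruitment-delay allowance added when the completion date is imputed
IMPUTATION_ALLOWANCE_MONTHS = 3

MISSING_START = "missing_start"
ZERO_DURATION_NO_COMPLETION = "zero_duration_no_completion"
COMPLETION_BEFORE_START = "completion_before_start"


class CompletionBeforeStartError(ValueError):
    pass


@dataclass(frozen=True)
class TrialInterval:
    registry_id: str
    cluster_id: str
    start: date
    end: date
    end_imputed: bool

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"{self.registry_id}: end {self.end} precedes start {self.start}")


@dataclass(frozen=True)
class ExclusionRecord:
    registry_id: str
    reason: str


def estimate_completion(
    start: date,
    duration: CalendarDuration | None,
    completion: date | None,
) -> tuple[date, bool]:
    """Resolve a trial's end date.

    A recorded completion date is used verbatim (even if shorter than
    start + duration would suggest). Otherwise the end is imputed as
    start + duration + 3 calendar months; the duration must then be present
    and non-zero.
    """
    if completion is not None:
        if completion < start:
            raise CompletionBeforeStartError(
                f"completion {completion} precedes start {start}"
            )
        return completion, False
    if duration is None or duration.is_zero:
        raise ValueError("cannot impute completion without a non-zero duration")
    # the allowance extends the duration itself, so start + (duration + 3 months)
    # is applied in a single calendar step (months first, day-clamped, then days)
    end = start + relativedelta(
        years=duration.years,
        months=duration.months + IMPUTATION_ALLOWANCE_MONTHS,
        days=duration.days,
    )
    return end, True


def build_intervals(
    records: list[RawTrialRecord], resolution: ResolutionResult
) -> tuple[list[TrialInterval], list[ExclusionRecord]]:
    """One interval per resolvable clustered record, plus enumerated exclusions.

    Records the resolver set aside as ambiguous are outside the per-PI
    analysis and are skipped silently. For the rest, conservation holds:
    len(intervals) + len(exclusions) = number of clustered records.
    """
    cluster_of = resolution.record_to_cluster()
    intervals: list[TrialInterval] = []
    exclusions: list[ExclusionRecord] = []
    for rec in records:
        cluster_id = cluster_of.get(rec.registry_id)
        if cluster_id is None:
            if rec.registry_id not in resolution.ambiguous_record_ids:
                raise ValueError(f"record {rec.registry_id} unknown to the resolution")
            continue
        if rec.date_first_enrollment is None:
            exclusions.append(ExclusionRecord(rec.registry_id, MISSING_START))
            continue
        if rec.date_study_completion is None and (
            rec.estimated_duration is None or rec.estimated_duration.is_zero
        ):
            exclusions.append(ExclusionRecord(rec.registry_id, ZERO_DURATION_NO_COMPLETION))
            continue
        try:
            end, imputed = estimate_completion(
                rec.date_first_enrollment, rec.estimated_duration, rec.date_study_completion
            )
        except CompletionBeforeStartError:
            exclusions.append(ExclusionRecord(rec.registry_id, COMPLETION_BEFORE_START))
            continue
        intervals.append(
            TrialInterval(
                registry_id=rec.registry_id,
                cluster_id=cluster_id,
                start=rec.date_first_enrollment,
                end=end,
                end_imputed=imputed,
            )
        )
    return intervals, exclusions


def active_years(interval: TrialInterval) -> list[int]:
    """Calendar years the trial's [start, end] window overlaps (inclusive,
    hence always the contiguous range year(start)..year(end))."""
    return list(range(interval.start.year, interval.end.year + 1))
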
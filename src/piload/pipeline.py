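"""End-to-end convenience wrapper: records in, summaries out.

Chains the cohort filter, PI resolution, interval construction and the
distribution/high-burden summaries, keeping every intermediate result so
callers (tests, CLI, reporting scripts) can audit any stage.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cohort import FilterCriteria, FilterReport, apply_cohort_filter
from .model import RawTrialRecord
from .names import ResolutionParams, ResolutionResult, resolve_pis
from .summarize import (
    DEFAULT_HIGH_BURDEN_THRESHOLD,
    DistributionTable,
    HighBurdenTable,
    bucket_distribution,
    high_burden_table,
    trials_per_pi,
)
from .timeline import ExclusionRecord, TrialInterval, build_intervals


@dataclass
class PipelineResult:
    kept_records: list[RawTrialRecord]
    filter_report: FilterReport
    resolution: ResolutionResult
    intervals: list[TrialInterval]
    timeline_exclusions: list[ExclusionRecord]
    counts: dict[str, int]
    distribution: DistributionTable
    high_burden: HighBurdenTable


def run_pipeline(
    records: list[RawTrialRecord],
    criteria: FilterCriteria | None = None,
    resolution_params: ResolutionParams | None = None,
    high_burden_threshold: int = DEFAULT_HIGH_BURDEN_THRESHOLD,
) -> PipelineResult:
    kept, report = apply_cohort_filter(records, criteria)
    resolution = resolve_pis([(r.registry_id, r.pi) for r in kept], resolution_params)
    intervals, exclusions = build_intervals(kept, resolution)
    counts = trials_per_pi(resolution)
    if not counts:
        raise ValueError("no resolvable records survived the cohort filter")
    return PipelineResult(
        kept_records=kept,
        filter_report=report,
        resolution=resolution,
        intervals=intervals,
        timeline_exclusions=exclusions,
        counts=counts,
        distribution=bucket_distribution(counts, high_burden_threshold),
        high_burden=high_burden_table(counts, intervals, high_burden_threshold),
    )
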
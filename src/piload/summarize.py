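"""Trials-per-PI distributions and the high-burden investigator table.

The headline outputs of the analysis: how many investigators ran exactly
one, two, three, or more than three trials (with rounded percentages), and,
for investigators above a high-burden threshold (default 20 trials), how
many of their trials were active in each calendar year and which year
peaked.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .names import ResolutionResult
from .timeline import TrialInterval, active_years

DEFAULT_HIGH_BURDEN_THRESHOLD = 20


def percent(numerator: int, denominator: int, decimals: int = 1) -> float:
    """100 * n / d rounded half-away-from-zero to ``decimals`` places.

    Decimal arithmetic, not binary floats, decides the rounding: 0.5 at the
    last kept digit always rounds away from zero.
    """
    if denominator <= 0:
        raise ValueError("denominator must be > 0")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must be in [0, denominator]")
    q = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return float(q.quantize(Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP))


def trials_per_pi(resolution: ResolutionResult) -> dict[str, int]:
    """Trial count per resolved cluster; sums to the number of resolved records."""
    return {c.cluster_id: c.n_trials for c in resolution.clusters}


@dataclass
class DistributionTable:
    histogram: dict[int, int]  # trials-per-PI -> number of PIs
    total_pis: int
    bucket_counts: dict[str, int]  # "1", "2", "3", ">3", ">=<threshold>"
    bucket_percentages: dict[str, float]
    high_burden_threshold: int

    def validate(self) -> None:
        base = ["1", "2", "3", ">3"]
        if sum(self.bucket_counts[b] for b in base) != self.total_pis:
            raise AssertionError("buckets 1/2/3/>3 must partition the PIs")
        if sum(self.histogram.values()) != self.total_pis:
            raise AssertionError("histogram must sum to total_pis")


def bucket_distribution(
    counts: dict[str, int] | list[int],
    high_burden_threshold: int = DEFAULT_HIGH_BURDEN_THRESHOLD,
    decimals: int = 1,
) -> DistributionTable:
    """Bucket a trials-per-PI count vector into the reporting distribution."""
    values = list(counts.values()) if isinstance(counts, dict) else list(counts)
    if any(v < 1 for v in values):
        raise ValueError("every PI must have at least one trial")
    hist = dict(sorted(Counter(values).items()))
    total = len(values)
    hb_key = f">={high_burden_threshold}"
    bucket_counts = {
        "1": sum(1 for v in values if v == 1),
        "2": sum(1 for v in values if v == 2),
        "3": sum(1 for v in values if v == 3),
        ">3": sum(1 for v in values if v > 3),
        hb_key: sum(1 for v in values if v >= high_burden_threshold),
    }
    pct = (
        {k: percent(c, total, decimals) for k, c in bucket_counts.items()}
        if total
        else {k: 0.0 for k in bucket_counts}
    )
    table = DistributionTable(
        histogram=hist,
        total_pis=total,
        bucket_counts=bucket_counts,
        bucket_percentages=pct,
        high_burden_threshold=high_burden_threshold,
    )
    table.validate()
    return table


@dataclass
class HighBurdenRow:
    cluster_id: str
    total_trials: int
    yearly_counts: dict[int, int]
    peak_year: int
    peak_count: int


@dataclass
class HighBurdenTable:
    rows: list[HighBurdenRow]
    year_range: tuple[int, int] | None  # inclusive; None when the table is empty

    def to_frame(self):
        import pandas as pd

        if not self.rows:
            return pd.DataFrame(columns=["cluster_id", "total_trials", "peak_year", "peak_count"])
        lo, hi = self.year_range
        recs = []
        for r in self.rows:
            rec = {"cluster_id": r.cluster_id, "total_trials": r.total_trials}
            rec.update({str(y): r.yearly_counts.get(y, 0) for y in range(lo, hi + 1)})
            rec.update({"peak_year": r.peak_year, "peak_count": r.peak_count})
            recs.append(rec)
        return pd.DataFrame(recs)


def high_burden_table(
    counts: dict[str, int],
    intervals: list[TrialInterval],
    min_trials: int = DEFAULT_HIGH_BURDEN_THRESHOLD,
) -> HighBurdenTable:
    """Per-year active-trial counts for investigators with >= min_trials trials.

    A trial counts in every calendar year its interval overlaps. Rows are
    sorted by total trials descending (ties by cluster id); the peak year is
    the earliest year attaining the row's maximum.
    """
    unknown = {iv.cluster_id for iv in intervals} - set(counts)
    if unknown:
        raise ValueError(f"intervals reference unknown clusters: {sorted(unknown)}")
    eligible = {cid for cid, n in counts.items() if n >= min_trials}
    rows: list[HighBurdenRow] = []
    included = [iv for iv in intervals if iv.cluster_id in eligible]
    if not included:
        return HighBurdenTable(rows=[], year_range=None)
    lo = min(iv.start.year for iv in included)
    hi = max(iv.end.year for iv in included)
    for cid in sorted(eligible, key=lambda c: (-counts[c], c)):
        yearly: Counter[int] = Counter()
        for iv in included:
            if iv.cluster_id == cid:
                yearly.update(active_years(iv))
        if not yearly:
            continue
        peak_count = max(yearly.values())
        peak_year = min(y for y, n in yearly.items() if n == peak_count)
        rows.append(
            HighBurdenRow(
                cluster_id=cid,
                total_trials=counts[cid],
                yearly_counts=dict(sorted(yearly.items())),
                peak_year=peak_year,
                peak_count=peak_count,
            )
        )
    return HighBurdenTable(rows=rows, year_range=(lo, hi))


def plot_distribution(table: DistributionTable, path=None):
    """Histogram of PIs per trials-per-PI count (log-friendly long tail)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    xs = sorted(table.histogram)
    ax.bar(xs, [table.histogram[x] for x in xs], color="#4878a8")
    ax.set_xlabel("Trials per PI")
    ax.set_ylabel("Number of PIs")
    ax.set_yscale("log")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
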
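"""Core data model for registry records.

The analysis consumes flattened trial-registry dumps (CTRI-style). Each record
carries the trial classification fields used by the cohort filter, the
"Details of Principal Investigator or overall Trial Coordinator" contact
block used for identity resolution, and the three timeline fields (date of
first enrollment, estimated duration, date of study completion).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date


@dataclass(frozen=True)
class CalendarDuration:
    """An estimated trial duration expressed in calendar units.

    Zero durations are meaningful (they trigger a downstream exclusion rule
    when no completion date is present) and are therefore distinct from an
    absent duration.
    """

    years: int = 0
    months: int = 0
    days: int = 0

    def __post_init__(self) -> None:
        if self.years < 0 or self.months < 0 or self.days < 0:
            raise ValueError(f"duration components must be >= 0, got {self}")

    @property
    def is_zero(self) -> bool:
        return self.years == 0 and self.months == 0 and self.days == 0

    def __str__(self) -> str:
        return f"{self.years} Years {self.months} Months {self.days} Days"


@dataclass(frozen=True)
class PIContact:
    """The PI name plus the contact-evidence fields used for disambiguation.

    An empty ``name_raw`` means the registry record carried no PI details at
    all; such records are dropped by the cohort filter's final stage.
    """

    name_raw: str = ""
    email: str | None = None
    phone: str | None = None
    fax: str | None = None
    affiliation: str | None = None
    address: str | None = None
    postal_code: str | None = None

    def __post_init__(self) -> None:
        # stored strings are whitespace-trimmed; blank optionals collapse to None
        object.__setattr__(self, "name_raw", self.name_raw.strip())
        for f in ("email", "phone", "fax", "affiliation", "address", "postal_code"):
            v = getattr(self, f)
            if v is not None:
                v = v.strip()
                object.__setattr__(self, f, v if v else None)

    @property
    def is_absent(self) -> bool:
        return not self.name_raw


@dataclass(frozen=True)
class RawTrialRecord:
    """One registry entry, typed.

    ``types_of_study`` and ``countries_of_recruitment`` are sets because the
    registry stores multiple values in one free-text field; the cohort filter
    tests set membership, never string equality on the joined field.
    """

    registry_id: str
    type_of_trial: str = ""
    types_of_study: frozenset[str] = frozenset()
    post_graduate_thesis: str | None = None
    countries_of_recruitment: frozenset[str] = frozenset()
    pi: PIContact = field(default_factory=PIContact)
    date_first_enrollment: date | None = None
    estimated_duration: CalendarDuration | None = None
    date_study_completion: date | None = None

    def __post_init__(self) -> None:
        if not self.registry_id or not self.registry_id.strip():
            raise ValueError("registry_id must be non-empty")
        object.__setattr__(self, "registry_id", self.registry_id.strip())
        for f in ("types_of_study", "countries_of_recruitment"):
            vals = frozenset(v.strip() for v in getattr(self, f))
            if "" in vals:
                raise ValueError(f"{f} contains an empty string")
            object.__setattr__(self, f, vals)
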
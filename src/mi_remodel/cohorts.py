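"""Cohort labels for the two myocardial regions across three time points.

The study design samples the infarct core (``C``) and the remote
myocardium (``R``) at 6, 30 and 45 days after infarction, giving six
cohorts (C6, C30, C45, R6, R30, R45) whose expression is reported as a
log2 ratio against a shared control group.
"""

from __future__ import annotations

from dataclasses import dataclass

REGIONS = ("C", "R")
DAYS = (6, 30, 45)

#: Label of the shared control group (the reference of every log2 ratio).
CONTROL = "CTRL"


@dataclass(frozen=True, order=True)
class CohortLabel:
    """A (region, day) pair rendered as e.g. ``C6`` or ``R45``."""

    region: str
    day: int

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"region must be one of {REGIONS}, got {self.region!r}")
        if self.day not in DAYS:
            raise ValueError(f"day must be one of {DAYS}, got {self.day!r}")

    def __str__(self) -> str:
        return f"{self.region}{self.day}"

    @classmethod
    def parse(cls, label: str) -> "CohortLabel":
        label = label.strip()
        if not label or label[0] not in REGIONS:
            raise ValueError(f"cannot parse cohort label {label!r}")
        try:
            day = int(label[1:])
        except ValueError as exc:
            raise ValueError(f"cannot parse cohort label {label!r}") from exc
        return cls(label[0], day)


CORE_COHORTS = tuple(f"C{d}" for d in DAYS)
REMOTE_COHORTS = tuple(f"R{d}" for d in DAYS)
ALL_COHORTS = CORE_COHORTS + REMOTE_COHORTS


def validate_cohort(label: str) -> str:
    """Return *label* if it names one of the six cohorts, else raise."""
    CohortLabel.parse(label)
    return label
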
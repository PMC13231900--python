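"""Core longitudinal PK data structures.

Units are fixed throughout the package: time in hours since each subject's
first dose, concentrations in mg/L (whole blood at the data layer), dose
amounts in mg, body weight in kg, postmenstrual/gestational age in weeks,
postnatal age in days, serum creatinine in µmol/L.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "LLOQ",
    "Covariates",
    "DoseEvent",
    "Observation",
    "SubjectRecord",
    "PKDataset",
    "ValidationError",
]

#: Lower limit of quantification of the whole-blood assay, mg/L.
LLOQ = 0.25


class ValidationError(ValueError):
    """A dataset or record violates a structural invariant."""


@dataclass(frozen=True)
class Covariates:
    """Baseline covariates of one neonate.

    ``scr`` may be ``None`` (missing creatinine); ``sex`` is 1 for male,
    0 for female.
    """

    wt: float
    pma: float
    ga: float
    pna: float
    scr: float | None = None
    sex: int = 1

    def __post_init__(self) -> None:
        if not self.wt > 0:
            raise ValidationError(f"wt must be > 0, got {self.wt}")
        if not self.pma > 0:
            raise ValidationError(f"pma must be > 0, got {self.pma}")
        if self.pma < self.ga:
            raise ValidationError(
                f"pma ({self.pma}) must be >= ga ({self.ga})"
            )
        if self.pna < 0:
            raise ValidationError(f"pna must be >= 0, got {self.pna}")
        if self.scr is not None and not self.scr > 0:
            raise ValidationError(f"scr must be > 0 when present, got {self.scr}")
        if self.sex not in (0, 1):
            raise ValidationError(f"sex must be 0 (female) or 1 (male), got {self.sex}")

    def value(self, name: str) -> float:
        """Numeric covariate lookup by lower-case name (for covariate models)."""
        v = getattr(self, name)
        if v is None:
            raise ValidationError(f"covariate {name!r} is missing")
        return float(v)


@dataclass(frozen=True)
class DoseEvent:
    """A single intravenous infusion: ``amount`` mg over ``infusion_duration`` h."""

    time: float
    amount: float
    infusion_duration: float

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValidationError(f"dose time must be >= 0, got {self.time}")
        if not self.amount > 0:
            raise ValidationError(f"dose amount must be > 0, got {self.amount}")
        if not self.infusion_duration > 0:
            raise ValidationError(
                f"infusion_duration must be > 0, got {self.infusion_duration}"
            )

    @property
    def rate(self) -> float:
        """Infusion rate in mg/h."""
        return self.amount / self.infusion_duration


@dataclass(frozen=True)
class Observation:
    """A timed blood-concentration measurement.

    ``blq_flag`` marks observations below the assay LLOQ (0.25 mg/L).
    """

    time: float
    conc: float
    blq_flag: bool = False

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValidationError(f"observation time must be >= 0, got {self.time}")
        if not self.blq_flag and not self.conc > 0:
            raise ValidationError(
                f"conc must be > 0 for a quantifiable observation, got {self.conc}"
            )


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    covariates: Covariates
    doses: tuple[DoseEvent, ...]
    observations: tuple[Observation, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "doses", tuple(self.doses))
        object.__setattr__(self, "observations", tuple(self.observations))
        if not self.doses:
            raise ValidationError(f"subject {self.subject_id}: doses must be non-empty")
        for seq, what in ((self.doses, "dose"), (self.observations, "observation")):
            times = [e.time for e in seq]
            if any(b < a for a, b in zip(times, times[1:])):
                raise ValidationError(
                    f"subject {self.subject_id}: {what} times must be non-decreasing"
                )


@dataclass(frozen=True)
class PKDataset:
    """A validated collection of subjects plus provenance metadata."""

    subjects: tuple[SubjectRecord, ...]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "subjects", tuple(self.subjects))
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate subject_ids: {dup}")
        if self.n_observations == 0:
            raise ValidationError("dataset must contain at least one observation")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_observations(self) -> int:
        return sum(len(s.observations) for s in self.subjects)

    def with_subjects(self, subjects) -> "PKDataset":
        return replace(self, subjects=tuple(subjects))


def is_missing(x) -> bool:
    """True for None or NaN covariate entries."""
    return x is None or (isinstance(x, float) and math.isnan(x))
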
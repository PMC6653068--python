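"""Domain types for longitudinal SLE cohort data.

A cohort is a set of patients, each with a time-ordered series of clinic
visits. Every visit carries 17 biological parameters (13 routine laboratory
measurements, with anti-dsDNA expressed as fold above the assay's upper limit
of normal, plus 4 serum cytokines) and the SLEDAI-2k disease-activity score,
a nonnegative integer. Visit times are integer days since that patient's
baseline visit (day 0); downstream analyses use visit order only, so absolute
calendar dates are never needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The fixed, ordered 17-parameter panel shared by all visits of all patients.
PARAMETERS: tuple[str, ...] = (
    "CRP", "C3", "C4", "Hb", "WCC", "platelets", "neutrophils",
    "lymphocytes", "ESR", "dsDNA_fold_ULN", "UPCR", "urine_WCC", "urine_RBC",
    "MIF", "CCL2", "CCL19", "CXCL10",
)

#: Serum cytokine subset of the panel (elevated in the small high-variance group).
CYTOKINES: tuple[str, ...] = ("MIF", "CCL2", "CCL19", "CXCL10")

N_PARAMETERS = len(PARAMETERS)

#: Minimum number of visits for a patient to enter the analysis.
MIN_VISITS = 3


class CohortError(ValueError):
    """Raised for schema, parse, or validation failures on cohort data."""


@dataclass(frozen=True)
class VisitRecord:
    """One clinic visit: day offset, 17 parameter values, SLEDAI-2k score."""

    patient_id: str
    day: int
    values: np.ndarray  # shape (17,)
    sledai: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.shape != (N_PARAMETERS,):
            raise CohortError(
                f"visit of {self.patient_id}: expected {N_PARAMETERS} parameter "
                f"values, got shape {self.values.shape}"
            )


@dataclass
class PatientSeries:
    """All visits of one patient, strictly increasing in day.

    Stored array-backed for fast distance and regression computations:
    ``days`` (n,), ``values`` (n, 17), ``sledai`` (n,).
    """

    patient_id: str
    days: np.ndarray
    values: np.ndarray
    sledai: np.ndarray

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=int)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.sledai = np.asarray(self.sledai, dtype=float)

    @property
    def n_visits(self) -> int:
        return len(self.days)

    @property
    def visits(self) -> list[VisitRecord]:
        return [
            VisitRecord(self.patient_id, int(d), v, int(s))
            for d, v, s in zip(self.days, self.values, self.sledai)
        ]

    @classmethod
    def from_visits(cls, visits: list[VisitRecord]) -> "PatientSeries":
        if not visits:
            raise CohortError("cannot build a PatientSeries from zero visits")
        pid = visits[0].patient_id
        order = np.argsort([v.day for v in visits], kind="stable")
        visits = [visits[i] for i in order]
        return cls(
            patient_id=pid,
            days=np.array([v.day for v in visits]),
            values=np.vstack([v.values for v in visits]),
            sledai=np.array([v.sledai for v in visits], dtype=float),
        )


@dataclass
class Cohort:
    """A collection of patient series plus per-patient binary characteristics.

    ``characteristics`` maps patient_id -> {flag_name: 0/1}. ``normalized``
    records whether parameter values are pooled z-scores rather than raw
    assay units.
    """

    patients: list[PatientSeries]
    characteristics: dict[str, dict[str, int]] = field(default_factory=dict)
    normalized: bool = False

    @property
    def patient_ids(self) -> list[str]:
        return [p.patient_id for p in self.patients]

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def n_visits(self) -> int:
        return sum(p.n_visits for p in self.patients)

    def patient(self, patient_id: str) -> PatientSeries:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise KeyError(patient_id)

    def stacked_values(self) -> np.ndarray:
        """All visits of all patients pooled, shape (total_visits, 17)."""
        return np.vstack([p.values for p in self.patients])

    def characteristic_names(self) -> list[str]:
        names: list[str] = []
        for flags in self.characteristics.values():
            for k in flags:
                if k not in names:
                    names.append(k)
        return names


def validate_cohort(cohort: Cohort, min_visits: int = MIN_VISITS) -> list[str]:
    """Check every type invariant; return violation messages (never raises).

    Each message names the offending patient and the rule violated. An empty
    list means the cohort is valid.
    """
    messages: list[str] = []
    seen: set[str] = set()
    for p in cohort.patients:
        pid = p.patient_id
        if pid in seen:
            messages.append(f"{pid}: duplicate patient_id")
        seen.add(pid)
        if p.n_visits < min_visits:
            messages.append(
                f"{pid}: has {p.n_visits} visits; at least {min_visits} "
                "visits are required"
            )
        if p.n_visits and p.days[0] < 0:
            messages.append(f"{pid}: negative day {p.days[0]} (baseline is day 0)")
        if np.any(np.diff(p.days) <= 0):
            messages.append(f"{pid}: visit days are not strictly increasing")
        if p.values.shape != (p.n_visits, N_PARAMETERS):
            messages.append(
                f"{pid}: values shape {p.values.shape} does not match "
                f"({p.n_visits}, {N_PARAMETERS})"
            )
        if not np.all(np.isfinite(p.values)):
            messages.append(f"{pid}: non-finite parameter values")
        if np.any(p.sledai < 0):
            messages.append(f"{pid}: SLEDAI-2k must be >= 0")
    for pid in cohort.characteristics:
        if pid not in seen:
            messages.append(
                f"{pid}: characteristics refer to a patient not in the cohort"
            )
    if cohort.normalized and cohort.n_patients:
        pooled = np.vstack([p.values for p in cohort.patients])
        if pooled.shape[0] > 1:
            means = pooled.mean(axis=0)
            sds = pooled.std(axis=0, ddof=1)
            bad = [
                PARAMETERS[k]
                for k in range(N_PARAMETERS)
                # constant columns are zeroed by normalization, so sd 0 with
                # mean 0 is legitimate
                if abs(means[k]) > 1e-6 or (sds[k] > 0 and abs(sds[k] - 1) > 1e-6)
            ]
            if bad:
                messages.append(
                    "cohort: normalized=True but parameters are not pooled "
                    f"z-scores: {', '.join(bad)}"
                )
    return messages
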
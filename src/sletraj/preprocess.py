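"""Cohort filtering, fold-ULN conversion, pooled z-normalization, summaries.

The pooled z-normalization centres and scales each of the 17 parameters over
ALL visits of ALL patients (sample sd, n-1 denominator); the SLEDAI-2k score
is never normalized. Magnitude-based comparison of patients with unequal
visit counts uses a fixed-length per-patient summary: the per-parameter mean
(optionally median) of the z-scored visit values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .core import N_PARAMETERS, PARAMETERS, Cohort, CohortError, PatientSeries

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SummaryVector:
    """Fixed-length magnitude profile of one patient (17 reals)."""

    patient_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (N_PARAMETERS,) or not np.all(np.isfinite(v)):
            raise CohortError(
                f"summary for {self.patient_id} must be {N_PARAMETERS} finite reals"
            )


def fold_uln(value: float, uln: float) -> float:
    """Convert an assay value to fold above the upper limit of normal."""
    if uln <= 0:
        raise ValueError(f"ULN must be positive, got {uln}")
    if value < 0:
        raise ValueError(f"assay value must be nonnegative, got {value}")
    return value / uln


def filter_cohort(cohort: Cohort, min_visits: int = 3) -> Cohort:
    """Retain exactly the patients with at least ``min_visits`` visits."""
    kept, excluded = [], []
    for p in cohort.patients:
        (kept if p.n_visits >= min_visits else excluded).append(p)
    if excluded:
        logger.info(
            "excluded %d patient(s) with fewer than %d visits: %s",
            len(excluded), min_visits, ", ".join(p.patient_id for p in excluded),
        )
    keep_ids = {p.patient_id for p in kept}
    chars = {pid: f for pid, f in cohort.characteristics.items() if pid in keep_ids}
    return Cohort(patients=kept, characteristics=chars, normalized=cohort.normalized)


def z_normalize(cohort: Cohort) -> Cohort:
    """Pooled z-normalization of the 17 parameters across all visit records.

    A constant parameter (sd = 0) is set to all zeros with a warning rather
    than producing NaNs. Rejects an already-normalized cohort.
    """
    if cohort.normalized:
        raise CohortError("cohort is already z-normalized")
    pooled = cohort.stacked_values()
    if pooled.shape[0] < 2:
        raise CohortError("z-normalization needs at least 2 visit records")
    mean = pooled.mean(axis=0)
    sd = pooled.std(axis=0, ddof=1)
    constant = sd == 0
    if constant.any():
        logger.warning(
            "constant parameter(s) set to zero during normalization: %s",
            ", ".join(np.array(PARAMETERS)[constant]),
        )
    safe_sd = np.where(constant, 1.0, sd)
    patients = [
        PatientSeries(
            patient_id=p.patient_id,
            days=p.days.copy(),
            values=np.where(constant, 0.0, (p.values - mean) / safe_sd),
            sledai=p.sledai.copy(),
        )
        for p in cohort.patients
    ]
    return Cohort(patients=patients,
                  characteristics={k: dict(v) for k, v in cohort.characteristics.items()},
                  normalized=True)


def summarize_patients(cohort: Cohort, aggregate: str = "mean") -> list[SummaryVector]:
    """One 17-vector per patient: per-parameter mean (or median) over visits."""
    if not cohort.normalized:
        raise CohortError("summaries are defined on a z-normalized cohort")
    if aggregate not in ("mean", "median"):
        raise ValueError(f"aggregate must be 'mean' or 'median', got {aggregate!r}")
    agg = np.mean if aggregate == "mean" else np.median
    return [SummaryVector(p.patient_id, agg(p.values, axis=0)) for p in cohort.patients]


def preprocess(cohort: Cohort, min_visits: int = 3) -> Cohort:
    """Default order: exclude short series first, then z-normalize, so that
    excluded patients do not influence the cohort statistics."""
    return z_normalize(filter_cohort(cohort, min_visits=min_visits))


def subset(cohort: Cohort, patient_ids: list[str]) -> Cohort:
    """Cohort restricted to the given patients (order preserved)."""
    wanted = set(patient_ids)
    patients = [p for p in cohort.patients if p.patient_id in wanted]
    chars = {pid: dict(f) for pid, f in cohort.characteristics.items() if pid in wanted}
    return replace(cohort, patients=patients, characteristics=chars)
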
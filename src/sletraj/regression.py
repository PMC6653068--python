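"""Linear models of disease activity with patient-aware validation.

Two designs predict the per-visit SLEDAI-2k score from the 17 z-scored
biological parameters:

* time-agnostic — current-visit parameters only (17 coefficients + intercept,
  18 free parameters);
* time-dependent — current-visit plus previous-visit parameters (34
  coefficients + intercept, 35 free parameters). Each patient's first visit
  contributes no row: lags never cross patients and are never imputed.

Validation is leave-one-patient-out (LOPO): all visits of one patient form
the held-out fold, so within-patient correlation can never leak between the
training and test sides. The bootstrap comparison likewise resamples at the
patient level (80% train / 20% test by default, 1,000 iterations). Error
scores are the mean squared residual (and the mean absolute residual for
reporting); predictions stay on the raw linear scale, unclamped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import Cohort, CohortError

logger = logging.getLogger(__name__)

MODES = ("time_agnostic", "time_dependent")


@dataclass
class DesignMatrix:
    """Per-visit rows: predictors X (without intercept column), response y."""

    mode: str
    X: np.ndarray
    y: np.ndarray
    row_keys: list[tuple[str, int]]  # (patient_id, day)

    @property
    def n_rows(self) -> int:
        return len(self.y)

    @property
    def n_free_parameters(self) -> int:
        """Coefficients plus the fitted intercept."""
        return self.X.shape[1] + 1

    def patient_rows(self, patient_id: str) -> np.ndarray:
        return np.array([k[0] == patient_id for k in self.row_keys])


@dataclass
class LinearFit:
    coef: np.ndarray
    intercept: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        return X @ self.coef + self.intercept


@dataclass
class PredictionSet:
    """Per-visit predicted vs actual disease activity with residuals."""

    entries: list[tuple[str, int, float, float]]  # (pid, day, actual, predicted)

    @property
    def residuals(self) -> np.ndarray:
        return np.array([a - p for _, _, a, p in self.entries])

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class ErrorSummary:
    mean_square: float
    mean_absolute: float
    n: int


def build_design(cohort: Cohort, mode: str) -> DesignMatrix:
    """Stack visit rows into a regression design for the requested mode."""
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    if not cohort.normalized:
        raise CohortError("regression designs are built on a z-normalized cohort")
    X_rows, y_rows, keys = [], [], []
    for p in cohort.patients:
        if mode == "time_agnostic":
            start = 0
        else:
            start = 1
            if p.n_visits < 2:
                logger.info("patient %s has <2 visits; no lagged rows", p.patient_id)
                continue
        for i in range(start, p.n_visits):
            row = p.values[i]
            if mode == "time_dependent":
                row = np.concatenate([p.values[i], p.values[i - 1]])
            X_rows.append(row)
            y_rows.append(p.sledai[i])
            keys.append((p.patient_id, int(p.days[i])))
    if not X_rows:
        raise CohortError("design matrix has no rows")
    return DesignMatrix(mode=mode, X=np.vstack(X_rows),
                        y=np.array(y_rows, dtype=float), row_keys=keys)


def _fit_ols(X: np.ndarray, y: np.ndarray) -> LinearFit:
    A = np.column_stack([np.ones(len(y)), X])
    coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < A.shape[1]:
        # name one collinear culprit via the QR diagonal
        _, R = np.linalg.qr(A)
        diag = np.abs(np.diag(R))
        bad = np.flatnonzero(diag < 1e-10 * max(diag.max(), 1.0))
        cols = ", ".join(str(int(b) - 1) for b in bad) or "unknown"
        raise np.linalg.LinAlgError(
            f"design is rank deficient (rank {rank} < {A.shape[1]}); "
            f"collinear predictor column(s): {cols}"
        )
    return LinearFit(coef=coef[1:], intercept=float(coef[0]))


def fit_linear(design: DesignMatrix) -> LinearFit:
    """Ordinary least squares with intercept; rejects rank-deficient designs."""
    if design.n_rows <= design.X.shape[1] + 1:
        raise CohortError(
            f"need more rows ({design.n_rows}) than free parameters "
            f"({design.n_free_parameters})"
        )
    return _fit_ols(design.X, design.y)


def lopo_cv(cohort: Cohort, mode: str) -> PredictionSet:
    """Leave-one-patient-out cross-validated predictions.

    For each patient, the model is fitted on every other patient's rows and
    scored on all of that patient's eligible rows. Folds whose fit fails are
    skipped with a warning and recorded in the fold log.
    """
    if cohort.n_patients < 3:
        raise CohortError("LOPO needs at least 3 patients")
    design = build_design(cohort, mode)
    entries: list[tuple[str, int, float, float]] = []
    for p in cohort.patients:
        held = design.patient_rows(p.patient_id)
        if not held.any():
            continue
        try:
            fit = _fit_ols(design.X[~held], design.y[~held])
        except np.linalg.LinAlgError as exc:
            logger.warning("LOPO fold for %s skipped: %s", p.patient_id, exc)
            continue
        preds = fit.predict(design.X[held])
        for (pid, day), actual, pred in zip(
            [k for k, h in zip(design.row_keys, held) if h],
            design.y[held], preds,
        ):
            entries.append((pid, day, float(actual), float(pred)))
    return PredictionSet(entries=entries)


def error_summary(pred: PredictionSet) -> ErrorSummary:
    """Mean squared and mean absolute prediction error."""
    if not len(pred):
        raise ValueError("prediction set is empty")
    r = pred.residuals
    return ErrorSummary(mean_square=float(np.mean(r ** 2)),
                        mean_absolute=float(np.mean(np.abs(r))), n=len(r))


def bootstrap_error(
    cohort: Cohort,
    mode: str,
    n_iter: int = 1000,
    train_frac: float = 0.8,
    seed: int | None = None,
) -> np.ndarray:
    """Patient-level train/test bootstrap of the mean squared error.

    Each iteration splits patients (not visits) without replacement into
    train_frac / (1 - train_frac), fits on the training rows and scores the
    mean squared residual on the test rows. Degenerate splits (no test rows
    or a singular training design) are resampled and logged.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    design = build_design(cohort, mode)
    ids = np.array(cohort.patient_ids)
    pid_of_row = np.array([k[0] for k in design.row_keys])
    n_train = max(1, int(round(train_frac * len(ids))))
    if n_train >= len(ids):
        n_train = len(ids) - 1
    rng = np.random.default_rng(seed)
    scores = np.empty(n_iter)
    resampled = 0
    for it in range(n_iter):
        while True:
            train_ids = set(rng.choice(ids, size=n_train, replace=False))
            train = np.isin(pid_of_row, list(train_ids))
            test = ~train
            if not test.any() or not train.any():
                resampled += 1
                continue
            try:
                fit = _fit_ols(design.X[train], design.y[train])
            except np.linalg.LinAlgError:
                resampled += 1
                continue
            break
        resid = design.y[test] - fit.predict(design.X[test])
        scores[it] = float(np.mean(resid ** 2))
    if resampled:
        logger.info("%d degenerate bootstrap split(s) were resampled", resampled)
    return scores


def compare_models(scores_a: np.ndarray, scores_b: np.ndarray) -> dict:
    """Paired bootstrap comparison of two error-score vectors.

    Reports mean(scores_a - scores_b), the 2.5/97.5 percentile interval of
    the paired differences, and a two-sided bootstrap p-value with a
    continuity floor of 1/n_iter. A positive difference means model b has the
    lower error.
    """
    a, b = np.asarray(scores_a, float), np.asarray(scores_b, float)
    if a.shape != b.shape:
        raise ValueError("score vectors must have equal length (paired iterations)")
    diff = a - b
    n = len(diff)
    ci = np.percentile(diff, [2.5, 97.5])
    frac_le = np.mean(diff <= 0)
    frac_ge = np.mean(diff >= 0)
    p = max(2 * min(frac_le, frac_ge), 1.0 / n)
    return {
        "mean_difference": float(diff.mean()),
        "ci_low": float(ci[0]),
        "ci_high": float(ci[1]),
        "p_value": float(min(p, 1.0)),
        "n_iter": n,
    }
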
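"""CSV readers and writers for cohort data.

Interchange formats (comma-separated, UTF-8, "." decimal, header required):

* visits CSV: ``patient_id,day,sledai,<17 parameter columns>``
* characteristics CSV: ``patient_id,<binary flag columns>`` with 0/1 cells
* a companion JSON sidecar (``<visits>.meta.json``) records whether values
  are pooled z-scores.

Floats are written with 17 significant digits so a write/read round trip is
value-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    N_PARAMETERS,
    PARAMETERS,
    Cohort,
    CohortError,
    PatientSeries,
    validate_cohort,
)

_FIXED_COLS = ["patient_id", "day", "sledai"]


def _sidecar_path(visits_path: str | Path) -> Path:
    p = Path(visits_path)
    return p.with_name(p.name + ".meta.json")


def read_cohort(
    visits_path: str | Path,
    characteristics_path: str | Path | None = None,
    drop_incomplete: bool = False,
) -> Cohort:
    """Read a cohort from a visits CSV and optional characteristics CSV.

    Rows are grouped by patient and sorted by day; parameter columns are
    mapped onto the fixed panel order regardless of file column order.
    Missing parameter cells raise by default (incomplete records are excluded
    from the study design); ``drop_incomplete=True`` drops the offending
    patient instead.
    """
    # round_trip parsing: the fast default parser may lose the last ulp,
    # breaking the bit-exact write/read contract
    df = pd.read_csv(visits_path, dtype={"patient_id": str},
                     float_precision="round_trip")
    missing = [c for c in _FIXED_COLS + list(PARAMETERS) if c not in df.columns]
    if missing:
        raise CohortError(f"visits CSV is missing column(s): {', '.join(missing)}")
    extra = [c for c in df.columns if c not in _FIXED_COLS + list(PARAMETERS)]
    if extra:
        raise CohortError(f"visits CSV has unexpected column(s): {', '.join(extra)}")

    numeric_cols = ["day", "sledai"] + list(PARAMETERS)
    for col in numeric_cols:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
            raise CohortError(f"non-numeric value in column {col!r} at row {row}")
        df[col] = converted

    incomplete = df[numeric_cols].isna().any(axis=1)
    if incomplete.any():
        if drop_incomplete:
            dropped = sorted(df.loc[incomplete, "patient_id"].unique())
            df = df[~df["patient_id"].isin(dropped)]
        else:
            row = int(np.flatnonzero(incomplete.to_numpy())[0]) + 2
            raise CohortError(
                f"missing cell at row {row}; incomplete records are excluded "
                "(pass drop_incomplete=True to drop the patient instead)"
            )

    dup = df.duplicated(subset=["patient_id", "day"])
    if dup.any():
        r = df.loc[dup, ["patient_id", "day"]].iloc[0]
        raise CohortError(
            f"duplicate visit for patient {r['patient_id']} on day {int(r['day'])}"
        )

    patients = []
    for pid, grp in df.groupby("patient_id", sort=True):
        grp = grp.sort_values("day")
        patients.append(
            PatientSeries(
                patient_id=str(pid),
                days=grp["day"].to_numpy(dtype=int),
                values=grp[list(PARAMETERS)].to_numpy(dtype=float),
                sledai=grp["sledai"].to_numpy(dtype=float),
            )
        )

    characteristics: dict[str, dict[str, int]] = {}
    if characteristics_path is not None:
        cdf = pd.read_csv(characteristics_path, dtype={"patient_id": str})
        if "patient_id" not in cdf.columns:
            raise CohortError("characteristics CSV is missing column patient_id")
        flag_cols = [c for c in cdf.columns if c != "patient_id"]
        for _, row in cdf.iterrows():
            characteristics[str(row["patient_id"])] = {
                c: int(row[c]) for c in flag_cols
            }

    normalized = False
    sidecar = _sidecar_path(visits_path)
    if sidecar.exists():
        normalized = bool(json.loads(sidecar.read_text()).get("normalized", False))

    return Cohort(patients=patients, characteristics=characteristics,
                  normalized=normalized)


def write_cohort(
    cohort: Cohort,
    visits_path: str | Path,
    characteristics_path: str | Path | None = None,
) -> None:
    """Write a cohort to CSV (plus the normalization sidecar JSON).

    ``read_cohort(write_cohort(c))`` reproduces ``c`` exactly: float cells
    carry 17 significant digits.
    """
    rows = []
    for p in cohort.patients:
        for i in range(p.n_visits):
            rows.append(
                [p.patient_id, int(p.days[i]), float(p.sledai[i])]
                + [float(v) for v in p.values[i]]
            )
    df = pd.DataFrame(rows, columns=_FIXED_COLS + list(PARAMETERS))
    df.to_csv(visits_path, index=False, float_format="%.17g")

    _sidecar_path(visits_path).write_text(
        json.dumps({"normalized": cohort.normalized, "n_parameters": N_PARAMETERS},
                   sort_keys=True)
        + "\n"
    )

    if characteristics_path is not None:
        names = cohort.characteristic_names()
        crows = [
            [pid] + [cohort.characteristics.get(pid, {}).get(n, 0) for n in names]
            for pid in sorted(cohort.characteristics)
        ]
        pd.DataFrame(crows, columns=["patient_id"] + names).to_csv(
            characteristics_path, index=False
        )


__all__ = ["read_cohort", "write_cohort", "validate_cohort"]
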
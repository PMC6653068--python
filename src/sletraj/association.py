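"""Group-vs-outcome association and biomarker-activity concordance.

Subgroup membership is related to binary clinical characteristics through
2x2 contingency tables. The odds ratio point estimate is the cross-product
(a*d)/(b*c) — identical to the OR from a logistic regression on a single
binary group covariate — with a Wald confidence interval
exp(ln OR +/- 1.96*sqrt(1/a + 1/b + 1/c + 1/d)). Characteristics present in
fewer than 5% of patients, and any table with a zero cell, fall back to
conditional exact inference (Fisher-type two-sided p and the conditional
maximum-likelihood OR of the noncentral hypergeometric model).

Concordance profiling flags each consecutive-visit interval of a patient as
synchronized when the biomarker and the disease-activity score move in the
same direction (matching signs of the consecutive differences, with 0 as its
own sign), and reports the percentage of synchronized intervals together
with the Pearson correlation of the raw series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .clustering import ClusterLabels

Z_95 = 1.959963984540054  # two-sided 95% normal quantile

RARE_FRACTION = 0.05


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts: a = exposed with outcome, b = exposed without, c = unexposed
    with, d = unexposed without ("exposed" = the comparison group)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise ValueError(f"cell counts must be nonnegative integers: {cells}")
        if sum(cells) < 1:
            raise ValueError("table must contain at least one observation")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass
class AssociationResult:
    or_point: float  # may be inf / 0.0 sentinels
    ci_low: float
    ci_high: float
    p_wald: float
    p_exact: float | None
    method: str  # "wald_logistic" | "exact"
    rare_flag: bool


def odds_ratio(table: ContingencyTable2x2,
               haldane: bool = False) -> AssociationResult:
    """Cross-product odds ratio with Wald CI; exact fallback on zero cells.

    Degenerate tables yield infinite/zero sentinels rather than exceptions
    (``haldane=True`` applies the 0.5 continuity correction instead).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if haldane and 0 in (a, b, c, d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    degenerate = 0 in (a, b, c, d)
    if degenerate:
        p_exact, _ = exact_test(table)
        if b * c == 0 and a * d == 0:
            point = float("nan")
        elif b * c == 0:
            point = float("inf")
        else:
            point = 0.0
        return AssociationResult(or_point=point, ci_low=0.0, ci_high=float("inf"),
                                 p_wald=float("nan"), p_exact=p_exact,
                                 method="exact", rare_flag=True)
    point = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ci_low = float(np.exp(np.log(point) - Z_95 * se))
    ci_high = float(np.exp(np.log(point) + Z_95 * se))
    z = np.log(point) / se
    p_wald = float(2 * stats.norm.sf(abs(z)))
    return AssociationResult(or_point=float(point), ci_low=ci_low, ci_high=ci_high,
                             p_wald=p_wald, p_exact=None,
                             method="wald_logistic", rare_flag=False)


def exact_test(table: ContingencyTable2x2) -> tuple[float, float]:
    """Conditional exact inference on a 2x2 table.

    Returns the two-sided Fisher-type p-value (sum of hypergeometric
    probabilities no larger than the observed table's) and the conditional
    maximum-likelihood odds ratio (infinite when a zero margin forces
    separation).
    """
    arr = table.as_array()
    p = float(stats.fisher_exact(arr, alternative="two-sided")[1])
    cmle = float(stats.contingency.odds_ratio(arr, kind="conditional").statistic)
    return p, cmle


def rare_flag(table: ContingencyTable2x2, cohort_n: int) -> bool:
    """True when the characteristic occurs in <5% of the cohort."""
    if cohort_n <= 0:
        raise ValueError("cohort_n must be positive")
    return (table.a + table.c) / cohort_n < RARE_FRACTION


def table_from_labels(
    labels: ClusterLabels,
    characteristics: dict[str, dict[str, int]],
    flag: str,
    exposed_label: int,
) -> ContingencyTable2x2:
    """2x2 counts of one characteristic against group membership."""
    a = b = c = d = 0
    missing = 0
    for pid, lab in zip(labels.ids, labels.labels):
        flags = characteristics.get(pid, {})
        if flag not in flags:
            missing += 1
            continue
        outcome = int(flags[flag])
        if lab == exposed_label:
            a += outcome
            b += 1 - outcome
        else:
            c += outcome
            d += 1 - outcome
    if a + b + c + d == 0:
        raise ValueError(f"characteristic {flag!r} has no observed values")
    return ContingencyTable2x2(a, b, c, d)


def associate_all(
    labels: ClusterLabels,
    characteristics: dict[str, dict[str, int]],
    cohort_n: int | None = None,
    exposed_label: int | None = None,
) -> list[dict]:
    """Associate every characteristic with two-group membership.

    ``exposed_label`` defaults to the smaller group. Rare characteristics
    (<5% of patients) are tested with conditional exact inference; the rest
    with the cross-product OR and Wald CI. Returns one row per characteristic
    mirroring the published table layout.
    """
    if labels.k != 2:
        raise ValueError(f"association needs exactly 2 groups, got k={labels.k}")
    if cohort_n is None:
        cohort_n = len(labels.ids)
    if exposed_label is None:
        sizes = labels.sizes()
        exposed_label = min(sizes, key=lambda l: (sizes[l], l))
    names: list[str] = []
    for flags in characteristics.values():
        for k in flags:
            if k not in names:
                names.append(k)
    rows = []
    for flag in names:
        try:
            t = table_from_labels(labels, characteristics, flag, exposed_label)
        except ValueError:
            continue
        rare = rare_flag(t, cohort_n)
        res = odds_ratio(t)
        if rare and res.method != "exact":
            p_exact, cmle = exact_test(t)
            res = AssociationResult(or_point=res.or_point, ci_low=res.ci_low,
                                    ci_high=res.ci_high, p_wald=res.p_wald,
                                    p_exact=p_exact, method="exact",
                                    rare_flag=True)
        rows.append({
            "characteristic": flag,
            "n_exposed_with": t.a, "n_exposed_without": t.b,
            "n_unexposed_with": t.c, "n_unexposed_without": t.d,
            "OR": res.or_point, "CI_low": res.ci_low, "CI_high": res.ci_high,
            "p": res.p_exact if res.method == "exact" else res.p_wald,
            "method": res.method,
        })
    return rows


@dataclass
class ConcordanceProfile:
    patient_id: str
    interval_flags: tuple[bool, ...]
    percent_sync: float
    pearson_r: float


def concordance_profile(
    biomarker: np.ndarray, activity: np.ndarray, patient_id: str = ""
) -> ConcordanceProfile:
    """Per-interval synchronization of a biomarker with disease activity."""
    x = np.asarray(biomarker, dtype=float)
    y = np.asarray(activity, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("need two equal-length series with at least 2 visits")
    flags = tuple(bool(s) for s in np.sign(np.diff(x)) == np.sign(np.diff(y)))
    if np.std(x) == 0 or np.std(y) == 0:
        r = float("nan")
    else:
        r = float(np.corrcoef(x, y)[0, 1])
    return ConcordanceProfile(
        patient_id=patient_id,
        interval_flags=flags,
        percent_sync=float(100.0 * np.mean(flags)),
        pearson_r=r,
    )
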
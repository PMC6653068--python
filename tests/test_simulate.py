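"""Synthetic cohort generator: structure, determinism, truth scoring."""

import numpy as np
import pytest
from scipy import stats

from sletraj.clustering import ClusterLabels
from sletraj.core import CYTOKINES, PARAMETERS
from sletraj.io import write_cohort
from sletraj.preprocess import preprocess, summarize_patients
from sletraj.regression import build_design, fit_linear
from sletraj.simulate import (
    SimConfig,
    SimTruth,
    simulate_cohort,
    simulate_latent_activity,
    truth_alignment_score,
)

CYT_IDX = [PARAMETERS.index(c) for c in CYTOKINES]


def small_config(**kwargs):
    defaults = dict(n_group1A=12, n_group1B=6, n_group2=4, seed=0)
    defaults.update(kwargs)
    return SimConfig(**defaults)


# ------------------------------------------------------------- latent ------

def test_latent_tempo_doubling_traverses_waveform_at_double_speed():
    rng = np.random.default_rng(0)
    t1 = simulate_latent_activity(9, 1.0, rng, noise_sd=1e-12, phase=0.3)
    rng = np.random.default_rng(0)
    t2 = simulate_latent_activity(5, 2.0, rng, noise_sd=1e-12, phase=0.3)
    # trajectory 2 at visit i equals trajectory 1 at visit 2i
    assert np.allclose(t2, t1[::2], atol=1e-9)


def test_latent_noise_zero_limit_is_deterministic_waveform():
    rng = np.random.default_rng(4)
    t = simulate_latent_activity(8, 1.3, rng, amplitude=2.0, period=8.0,
                                 noise_sd=1e-15, phase=1.0)
    i = np.arange(8)
    expected = 2.0 * np.sin(2 * np.pi * 1.3 * i / 8.0 + 1.0)
    assert np.allclose(t, expected, atol=1e-10)


def test_latent_argument_errors():
    rng = np.random.default_rng(0)
    with pytest.raises(ValueError):
        simulate_latent_activity(2, 1.0, rng)
    with pytest.raises(ValueError):
        simulate_latent_activity(5, 0.0, rng)


def test_mapped_sledai_mean_near_target():
    cfg = SimConfig(n_group1A=1000, n_group1B=0, n_group2=0, seed=11)
    cohort, _ = simulate_cohort(cfg)  # 1,000 trajectories
    sled = np.concatenate([p.sledai for p in cohort.patients])
    assert len(sled) >= 5000
    assert abs(sled.mean() - 4.0) < 0.5
    assert np.all(sled >= 0)
    assert np.all(sled == np.round(sled))


# ------------------------------------------------------------- cohort ------

def test_group_sizes_and_visit_bounds():
    cohort, truth = simulate_cohort(SimConfig(seed=5))
    assert cohort.n_patients == 110
    counts = {g: sum(1 for v in truth.labels.values() if v == g)
              for g in ("1A", "1B", "2")}
    assert counts == {"1A": 69, "1B": 32, "2": 9}
    for p in cohort.patients:
        assert 5 <= p.n_visits <= 11
        assert p.days[0] == 0
        assert np.all(np.diff(p.days) >= 30) and np.all(np.diff(p.days) <= 90)


def test_same_seed_byte_identical_csvs(tmp_path):
    for run in ("a", "b"):
        cohort, _ = simulate_cohort(small_config(seed=42))
        write_cohort(cohort, tmp_path / f"{run}_v.csv", tmp_path / f"{run}_c.csv")
    assert (tmp_path / "a_v.csv").read_bytes() == (tmp_path / "b_v.csv").read_bytes()
    assert (tmp_path / "a_c.csv").read_bytes() == (tmp_path / "b_c.csv").read_bytes()
    cohort, _ = simulate_cohort(small_config(seed=43))
    write_cohort(cohort, tmp_path / "c_v.csv")
    assert (tmp_path / "a_v.csv").read_bytes() != (tmp_path / "c_v.csv").read_bytes()


def test_cytokine_shift_null_case_type_I_error():
    # cytokine_shift=0 and no sd inflation: group-2 vs group-1 MIF means
    # should differ significantly in at most ~alpha of replicates
    rejections = 0
    n_rep = 200
    for rep in range(n_rep):
        cfg = SimConfig(n_group1A=0, n_group1B=12, n_group2=8,
                        cytokine_shift=0.0, group2_sd_inflation=1.0, seed=rep)
        cohort, truth = simulate_cohort(cfg)
        mif = PARAMETERS.index("MIF")
        g1 = np.concatenate([p.values[:, mif] for p in cohort.patients
                             if truth.labels[p.patient_id] == "1B"])
        g2 = np.concatenate([p.values[:, mif] for p in cohort.patients
                             if truth.labels[p.patient_id] == "2"])
        if stats.ttest_ind(g1, g2, equal_var=False).pvalue < 0.05:
            rejections += 1
    assert rejections <= 0.10 * n_rep


def test_group2_cytokines_elevated_after_normalization():
    cohort, truth = simulate_cohort(SimConfig(seed=3))
    norm = preprocess(cohort)
    summaries = {s.patient_id: s.values for s in summarize_patients(norm)}
    g2 = np.array([summaries[p] for p, g in truth.labels.items() if g == "2"])
    g1 = np.array([summaries[p] for p, g in truth.labels.items() if g != "2"])
    for idx in CYT_IDX:
        assert g2[:, idx].mean() > g1[:, idx].mean() + 1.0


def test_subgroups_have_no_magnitude_signal():
    # 1A and 1B are magnitude-matched by design: their summary-vector means
    # should not be separated by a large margin in any parameter
    cohort, truth = simulate_cohort(SimConfig(seed=6))
    norm = preprocess(cohort)
    summaries = {s.patient_id: s.values for s in summarize_patients(norm)}
    a = np.array([summaries[p] for p, g in truth.labels.items() if g == "1A"])
    b = np.array([summaries[p] for p, g in truth.labels.items() if g == "1B"])
    assert np.all(np.abs(a.mean(axis=0) - b.mean(axis=0)) < 0.5)


def test_outcome_or_convergence_large_sample():
    from sletraj.association import ContingencyTable2x2, odds_ratio

    cfg = SimConfig(n_group1A=10000, n_group1B=10000, n_group2=0, seed=9)
    cohort, truth = simulate_cohort(cfg)
    a = b = c = d = 0
    for pid, flags in cohort.characteristics.items():
        if truth.labels[pid] == "1B":
            a += flags["sfi_flare"]
            b += 1 - flags["sfi_flare"]
        else:
            c += flags["sfi_flare"]
            d += 1 - flags["sfi_flare"]
    res = odds_ratio(ContingencyTable2x2(a, b, c, d))
    assert 3.0 <= res.or_point <= 4.6


def test_infeasible_or_rejected():
    # the odds-solved probability is mathematically below 1 for any finite
    # odds ratio, but rounds to exactly 1.0 once the implied odds exceed
    # float precision; such degenerate configurations must be rejected
    with pytest.raises(ValueError, match="p >= 1"):
        SimConfig(outcome_ors={"sfi_flare": 1e18},
                  baseline_outcome_prob={"sfi_flare": 0.99})


def test_config_validation_errors():
    with pytest.raises(ValueError):
        SimConfig(visits_min=2)
    with pytest.raises(ValueError):
        SimConfig(tempo_range=(0.0, 1.0))
    with pytest.raises(ValueError):
        SimConfig(noise_sd=0.0)
    with pytest.raises(ValueError):
        SimConfig(outcome_ors={"unknown_flag": 2.0})


def test_lag_coefficient_recovery_within_3_se():
    # 1A-only cohort with known lag structure: the time-dependent OLS must
    # recover each planted lag coefficient within +/-3 standard errors
    cfg = SimConfig(n_group1A=69, n_group1B=0, n_group2=0,
                    visits_min=8, visits_max=8, seed=21)
    cohort, _ = simulate_cohort(cfg)
    norm = preprocess(cohort)
    design = build_design(norm, "time_dependent")
    fit = fit_linear(design)
    resid = design.y - fit.predict(design.X)
    dof = design.n_rows - design.n_free_parameters
    sigma2 = float(resid @ resid) / dof
    A = np.column_stack([np.ones(design.n_rows), design.X])
    cov = sigma2 * np.linalg.inv(A.T @ A)
    se = np.sqrt(np.diag(cov))[1:]
    # planted lag coefficients act on the generator's z-draws; the fitted
    # design is pooled-z-normalized raw values, i.e. the z-draws divided by
    # their pooled sd, so the identifiable coefficient is scaled by that sd
    pooled = cohort.stacked_values()
    sd_raw = pooled.std(axis=0, ddof=1)
    from sletraj.simulate import _RAW_SD

    effective = cfg.effective_lag_coef * (sd_raw / _RAW_SD)
    lag_hat = fit.coef[17:]
    lag_se = se[17:]
    misses = np.abs(lag_hat - effective) > 3 * lag_se
    # 34 three-sigma intervals: allow a single chance miss
    assert misses.sum() <= 1


# ---------------------------------------------------------- truth scores ---

def _truth_two_group(ids, planted):
    labels = {pid: ("2" if pid in planted else "1A") for pid in ids}
    return SimTruth(labels=labels, latent={}, tempo={})


def test_truth_alignment_identical_is_one():
    ids = [f"P{i}" for i in range(10)]
    truth = _truth_two_group(ids, set(ids[:3]))
    pred = ClusterLabels(ids=ids, labels=[2] * 3 + [1] * 7, k=2)
    assert truth_alignment_score(pred, truth) == pytest.approx(1.0)


def test_truth_alignment_all_in_one_cluster_not_positive():
    ids = [f"P{i}" for i in range(10)]
    truth = _truth_two_group(ids, set(ids[:3]))
    pred = ClusterLabels(ids=ids, labels=[1] * 10, k=1)
    assert truth_alignment_score(pred, truth) <= 0.0


def test_truth_alignment_permutation_null(rng):
    ids = [f"P{i}" for i in range(40)]
    truth = _truth_two_group(ids, set(ids[:20]))
    scores = []
    for _ in range(100):
        lab = rng.permutation([1] * 20 + [2] * 20)
        scores.append(truth_alignment_score(
            ClusterLabels(ids=ids, labels=lab, k=2), truth))
    assert abs(np.mean(scores)) < 0.05


def test_truth_alignment_unknown_patient_rejected():
    truth = _truth_two_group(["P0", "P1", "P2"], {"P0"})
    pred = ClusterLabels(ids=["P0", "QQ"], labels=[1, 2], k=2)
    with pytest.raises(ValueError, match="QQ"):
        truth_alignment_score(pred, truth)


def test_truth_alignment_subgroup_level():
    cohort, truth = simulate_cohort(small_config())
    ids = cohort.patient_ids
    perfect = ClusterLabels(
        ids=ids,
        labels=[{"1A": 1, "1B": 2, "2": 3}[truth.labels[p]] for p in ids],
        k=3)
    assert truth_alignment_score(perfect, truth, level="subgroup") == pytest.approx(1.0)
    with pytest.raises(ValueError):
        truth_alignment_score(perfect, truth, level="bogus")
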
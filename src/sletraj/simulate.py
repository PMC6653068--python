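"""Synthetic longitudinal SLE cohort generator.

Real lupus-registry data are not publicly deposited, so the pipeline is
exercised on simulated cohorts that carry the statistical structure the
analysis assumes, with known ground truth:

* Subgroup 1A (default n = 69): each patient follows a smooth latent disease
  activity trajectory — a shared low-frequency waveform entered at a common
  baseline state (small phase jitter) but traversed at a patient-specific
  tempo, plus a small random walk. Every biological parameter loads on the
  latent trajectory (concordant dynamics), and the SLEDAI-2k score
  additionally receives a contribution from the previous visit's parameters,
  so a time-dependent (lagged) regression is genuinely better specified than
  a time-agnostic one. Time warping can align these patients; magnitude
  cannot distinguish them from subgroup 1B.
* Subgroup 1B (default n = 32): parameters are pure noise matched to
  subgroup 1A's marginal scale (no magnitude signal); disease activity
  follows its own latent trajectory at a random phase, independent of the
  parameters (discordant dynamics).
* Group 2 (default n = 9): cytokine means shifted upward and all parameter
  spreads inflated — a small, high-variance, high-cytokine subset that
  magnitude-based clustering should isolate.

SLEDAI-2k is produced by an affine map of the latent signal centred at 4
(the registry cohort's median time-adjusted mean), clamped at 0 and rounded
to an integer. Binary adverse-outcome flags are drawn once per patient, with
Subgroup 1B probabilities solved from configured odds ratios against the
Subgroup 1A baselines. Everything is reproducible from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .core import CYTOKINES, N_PARAMETERS, PARAMETERS, Cohort, PatientSeries
from .clustering import ClusterLabels

_CYTOKINE_IDX = np.array([PARAMETERS.index(c) for c in CYTOKINES])

# plausible raw-unit location/scale per parameter, so that the generated CSVs
# look like assay values and pooled z-normalization has real work to do
_RAW_MEAN = np.array([5.0, 1.0, 0.2, 125.0, 7.0, 250.0, 4.5, 1.5,
                      20.0, 1.5, 30.0, 10.0, 10.0, 40.0, 200.0, 500.0, 300.0])
_RAW_SD = np.array([6.0, 0.25, 0.08, 15.0, 2.5, 70.0, 2.0, 0.7,
                    15.0, 1.5, 40.0, 12.0, 12.0, 20.0, 90.0, 260.0, 180.0])


def _default_lag_coef() -> np.ndarray:
    coef = np.zeros(N_PARAMETERS)
    coef[_CYTOKINE_IDX] = 0.4
    return coef


@dataclass
class SimConfig:
    """Generator settings; defaults emulate the registry cohort's structure."""

    n_group1A: int = 69
    n_group1B: int = 32
    n_group2: int = 9
    visits_min: int = 5
    visits_max: int = 11
    cytokine_shift: float = 3.0       # z-units added to cytokine means, group 2
    group2_sd_inflation: float = 1.5
    concordance_coef: np.ndarray = field(
        default_factory=lambda: np.full(N_PARAMETERS, 0.8))
    lag_coef: np.ndarray = field(default_factory=_default_lag_coef)
    tempo_range: tuple[float, float] = (0.5, 2.0)
    noise_sd: float = 0.5             # parameter noise around the latent signal
    concordant_phase_sd: float = 0.4  # baseline phase jitter in subgroup 1A (rad)
    sledai_center: float = 4.0        # target mean of the mapped SLEDAI-2k
    sledai_scale: float = 1.2
    sledai_noise_sd: float = 0.5
    latent_amplitude: float = 1.2
    latent_period: float = 8.0        # visits per sinusoid cycle at tempo 1
    latent_walk_sd: float = 0.15
    outcome_ors: dict[str, float] = field(default_factory=lambda: {
        "sfi_flare": 3.733,
        "slicc_sdi_ge1": 2.631,
        "sledai_gt4": 5.492,
        "musculoskeletal": 7.68,
        "biologics": 15.692,
    })
    baseline_outcome_prob: dict[str, float] = field(default_factory=lambda: {
        "sfi_flare": 45 / 69,
        "slicc_sdi_ge1": 34 / 69,
        "sledai_gt4": 44 / 69,
        "musculoskeletal": 5 / 69,
        "biologics": 1 / 69,
    })
    seed: int = 0

    def __post_init__(self) -> None:
        self.concordance_coef = np.asarray(self.concordance_coef, dtype=float)
        self.lag_coef = np.asarray(self.lag_coef, dtype=float)
        if min(self.n_group1A, self.n_group1B, self.n_group2) < 0:
            raise ValueError("group sizes must be nonnegative")
        if self.visits_min < 3:
            raise ValueError("visits_min must be >= 3 (shorter series are excluded)")
        if self.visits_max < self.visits_min:
            raise ValueError("visits_max must be >= visits_min")
        lo, hi = self.tempo_range
        if not (0 < lo <= hi):
            raise ValueError("tempo_range must satisfy 0 < low <= high")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.group2_sd_inflation < 1:
            raise ValueError("group2_sd_inflation must be >= 1")
        for v in (self.concordance_coef, self.lag_coef):
            if v.shape != (N_PARAMETERS,):
                raise ValueError(f"coefficient vectors must have length {N_PARAMETERS}")
        for name, p in self.baseline_outcome_prob.items():
            if not 0 < p < 1:
                raise ValueError(f"baseline probability for {name!r} must be in (0,1)")
        for name, oratio in self.outcome_ors.items():
            p = self.baseline_outcome_prob.get(name)
            if p is None:
                raise ValueError(f"outcome {name!r} has an OR but no baseline")
            if not np.isfinite(oratio) or oratio <= 0:
                raise ValueError(f"odds ratio for {name!r} must be finite and > 0")
            if self.exposed_prob(name) >= 1:
                raise ValueError(f"OR/baseline pair for {name!r} implies p >= 1")

    def exposed_prob(self, name: str) -> float:
        """Subgroup-1B probability implied by the configured OR and baseline."""
        p = self.baseline_outcome_prob[name]
        odds = self.outcome_ors[name] * p / (1 - p)
        return odds / (1 + odds)

    @property
    def effective_lag_coef(self) -> np.ndarray:
        """Lag coefficients on the SLEDAI scale (after the affine map)."""
        return self.sledai_scale * self.lag_coef

    @property
    def marginal_param_sd(self) -> np.ndarray:
        """Nominal per-parameter marginal sd of subgroup 1A values, used as
        the noise scale of the magnitude-matched subgroup 1B and group 2."""
        latent_var = self.latent_amplitude ** 2 / 2
        return np.sqrt(self.concordance_coef ** 2 * latent_var + self.noise_sd ** 2)


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort."""

    labels: dict[str, str]               # patient_id -> "1A" | "1B" | "2"
    latent: dict[str, np.ndarray]
    tempo: dict[str, float]

    def group_labels(self, ids: list[str]) -> list[int]:
        """Magnitude-level truth: group 2 vs the rest (1 = group 1, 2 = group 2)."""
        return [2 if self.labels[pid] == "2" else 1 for pid in ids]

    def subgroup_labels(self, ids: list[str]) -> list[str]:
        return [self.labels[pid] for pid in ids]


def simulate_latent_activity(
    n_visits: int,
    tempo: float,
    rng: np.random.Generator,
    amplitude: float = 1.2,
    period: float = 8.0,
    noise_sd: float = 0.15,
    phase: float | None = None,
) -> np.ndarray:
    """Smooth fluctuating latent disease-activity trajectory.

    A low-frequency sinusoid (visit index scaled by the patient's tempo;
    phase drawn uniformly unless supplied) plus a small random walk. In the
    ``noise_sd -> 0`` limit the trajectory is exactly the deterministic
    waveform; doubling ``tempo`` traverses the same waveform at double speed.
    """
    if n_visits < 3:
        raise ValueError("a trajectory needs at least 3 visits")
    if tempo <= 0:
        raise ValueError("tempo must be positive")
    if phase is None:
        phase = rng.uniform(0, 2 * np.pi)
    i = np.arange(n_visits, dtype=float)
    deterministic = amplitude * np.sin(2 * np.pi * tempo * i / period + phase)
    walk = np.cumsum(rng.normal(0.0, 1.0, n_visits)) * noise_sd
    return deterministic + walk


def _map_sledai(signal: np.ndarray, rng: np.random.Generator,
                center: float, scale: float, noise_sd: float) -> np.ndarray:
    raw = center + scale * signal + rng.normal(0.0, noise_sd, len(signal))
    return np.round(np.clip(raw, 0.0, None))


def simulate_cohort(config: SimConfig) -> tuple[Cohort, SimTruth]:
    """Draw a full cohort plus its ground truth, reproducibly from the seed."""
    rng = np.random.default_rng(config.seed)
    patients: list[PatientSeries] = []
    labels: dict[str, str] = {}
    latents: dict[str, np.ndarray] = {}
    tempos: dict[str, float] = {}
    characteristics: dict[str, dict[str, int]] = {}

    groups = (["1A"] * config.n_group1A + ["1B"] * config.n_group1B
              + ["2"] * config.n_group2)
    width = max(3, len(str(len(groups))))

    base_sd = config.marginal_param_sd

    for idx, group in enumerate(groups):
        pid = f"P{idx + 1:0{width}d}"
        n = int(rng.integers(config.visits_min, config.visits_max + 1))
        tempo = float(rng.uniform(*config.tempo_range))
        # concordant patients enter at a shared disease state (small phase
        # jitter); discordant ones at an arbitrary point of their own cycle
        phase = (float(rng.normal(0.0, config.concordant_phase_sd))
                 if group == "1A" else None)
        latent = simulate_latent_activity(
            n, tempo, rng,
            amplitude=config.latent_amplitude,
            period=config.latent_period,
            noise_sd=config.latent_walk_sd,
            phase=phase,
        )
        if group == "1A":
            # parameters track the fluctuation of activity around the
            # patient's own set-point, so concordance is a property of the
            # dynamics and leaves the magnitude profile uninformative
            latent_c = latent - latent.mean()
            z = (config.concordance_coef * latent_c[:, None]
                 + rng.normal(0.0, config.noise_sd, (n, N_PARAMETERS)))
            signal = latent.copy()
            signal[1:] += z[:-1] @ config.lag_coef
        elif group == "1B":
            z = rng.normal(0.0, 1.0, (n, N_PARAMETERS)) * base_sd
            signal = latent
        else:  # group 2: shifted cytokines, inflated spread, activity-independent
            z = (rng.normal(0.0, 1.0, (n, N_PARAMETERS))
                 * base_sd * config.group2_sd_inflation)
            z[:, _CYTOKINE_IDX] += config.cytokine_shift
            signal = latent
        sledai = _map_sledai(signal, rng, config.sledai_center,
                             config.sledai_scale, config.sledai_noise_sd)
        gaps = rng.integers(30, 91, n)
        days = np.concatenate([[0], np.cumsum(gaps[1:])])
        patients.append(PatientSeries(
            patient_id=pid, days=days,
            values=_RAW_MEAN + _RAW_SD * z, sledai=sledai,
        ))
        labels[pid] = group
        latents[pid] = latent
        tempos[pid] = tempo

        flags: dict[str, int] = {}
        for name, base in config.baseline_outcome_prob.items():
            p = config.exposed_prob(name) if group == "1B" else base
            flags[name] = int(rng.uniform() < p)
        characteristics[pid] = flags

    cohort = Cohort(patients=patients, characteristics=characteristics,
                    normalized=False)
    return cohort, SimTruth(labels=labels, latent=latents, tempo=tempos)


def truth_alignment_score(
    labels_pred: ClusterLabels, truth: SimTruth, level: str = "group"
) -> float:
    """Chance-adjusted agreement (adjusted Rand index) of predicted labels
    with the planted partition.

    ``level="group"`` compares against group 2 vs group 1; ``"subgroup"``
    against the three-way 1A/1B/2 truth.
    """
    missing = [pid for pid in labels_pred.ids if pid not in truth.labels]
    if missing:
        raise ValueError(
            f"predicted labels cover patients absent from the truth: {missing[:5]}"
        )
    if level == "group":
        true = truth.group_labels(labels_pred.ids)
    elif level == "subgroup":
        true = truth.subgroup_labels(labels_pred.ids)
    else:
        raise ValueError(f"level must be 'group' or 'subgroup', got {level!r}")
    return float(adjusted_rand_score(true, labels_pred.labels))
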
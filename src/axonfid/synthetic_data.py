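"""Synthetic recordings with the statistical structure the analysis assumes.

Every input the pipeline consumes can be generated here under an explicit
seed: paired soma/axon spike trains, step-current sessions, behaviour
cohorts, and time-lapse swelling-formation experiments.

The generative model, in brief:

* Somatic spiking is a gamma renewal process (shape ``1 / CV^2``), so the
  target firing rate and interval CV are both free parameters.  A CV of 0
  degenerates to a perfectly periodic train.
* Axonal propagation is per-spike Bernoulli thinning at a fixed failure
  probability (spontaneous regime) or at a probability that increases
  logistically with the driven firing frequency (step-current regime).
* The axonal spike is the somatic spike shifted by the axosomatic delay
  plus Gaussian jitter.  The delay may be negative (spikes initiate in the
  axon initial segment).  Jitter large enough to reorder spikes is allowed
  but flagged in the ground truth.
* Behavioural learning is linearly coupled to swelling density with
  additive Gaussian noise, and raw per-day task tables are constructed so
  that recomputing the learning score reproduces the generated value.
* Time-lapse swelling counts are gamma-Poisson (negative-binomial-like)
  around a per-timepoint mean rate curve.

Default numerical parameters follow the empirical recordings this
generator emulates: ~45 Hz spontaneous firing and a control-axon failure
probability of 6.07 per 1000 spikes (1.12 per 1000 for axons with
swellings).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Sequence

import numpy as np

from .behavior import BehaviorRecord
from .exceptions import InvalidParameterError
from .morphometry import TimelapseRecord
from .spike_metrics import PairedRecording, SpikeTrain, StepRecord, StepSession

__all__ = [
    "GeneratorConfig",
    "FrequencyFailureProfile",
    "BehaviorGenSpec",
    "gen_soma_train",
    "gen_paired_recording",
    "gen_paired_recording_set",
    "gen_step_protocol_session",
    "gen_behavior_cohort",
    "gen_timelapse_experiment",
    "TIMELAPSE_PRESETS",
]

#: Per-spike failure probability of control axons (6.07 per 1000 spikes).
CONTROL_FAILURE_PROB = 0.00607
#: Per-spike failure probability of axons bearing a swelling (1.12 per 1000).
SWELLING_FAILURE_PROB = 0.00112
#: Spontaneous Purkinje-cell firing rate, Hz (control axons).
CONTROL_RATE_HZ = 45.2
#: Spontaneous firing rate of cells whose axon bears a swelling, Hz.
SWELLING_RATE_HZ = 44.3


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the paired-recording generator.

    ``isi_cv`` is the interval coefficient of variation of the gamma
    renewal process; ``delay_ms`` may be negative.  The default interval
    CV of 0.5 is a placeholder for the (unreported) regularity of the
    recordings and is freely configurable.
    """

    firing_rate_hz: float = CONTROL_RATE_HZ
    isi_cv: float = 0.5
    duration_s: float = 60.0
    failure_prob: float = CONTROL_FAILURE_PROB
    delay_ms: float = 0.2
    delay_jitter_ms: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not self.firing_rate_hz > 0:
            raise InvalidParameterError("firing_rate_hz must be positive")
        if self.isi_cv < 0:
            raise InvalidParameterError("isi_cv must be non-negative")
        if not self.duration_s > 0:
            raise InvalidParameterError("duration_s must be positive")
        if not 0.0 <= self.failure_prob <= 1.0:
            raise InvalidParameterError("failure_prob must be in [0, 1]")
        if self.delay_jitter_ms < 0:
            raise InvalidParameterError("delay_jitter_ms must be non-negative")


@dataclass(frozen=True)
class FrequencyFailureProfile:
    """Failure probability as a logistic function of firing frequency.

    ``p(f) = baseline + (ceiling - baseline) * logistic(steepness * (f - midpoint))``

    Monotone non-decreasing in f; flat when baseline == ceiling.  The
    default midpoints (130 Hz control, 170 Hz swelling) and ceilings are
    calibration knobs chosen so that simulated cells driven to their
    maximal frequencies show success fractions on the scale of the
    recordings (roughly 84% control vs 97% swelling at the maximal driven
    frequency); they are not measured values.
    """

    baseline_prob: float = CONTROL_FAILURE_PROB
    midpoint_hz: float = 130.0
    steepness_per_hz: float = 0.05
    ceiling_prob: float = 0.33

    def __post_init__(self):
        if not 0.0 <= self.baseline_prob <= 1.0 or not 0.0 <= self.ceiling_prob <= 1.0:
            raise InvalidParameterError("probabilities must be in [0, 1]")
        if self.ceiling_prob < self.baseline_prob:
            raise InvalidParameterError("ceiling_prob must be >= baseline_prob")
        if not self.midpoint_hz > 0:
            raise InvalidParameterError("midpoint_hz must be positive")
        if not self.steepness_per_hz > 0:
            raise InvalidParameterError("steepness_per_hz must be positive")

    def failure_prob(self, freq_hz: float) -> float:
        z = self.steepness_per_hz * (np.asarray(freq_hz, dtype=float) - self.midpoint_hz)
        p = self.baseline_prob + (self.ceiling_prob - self.baseline_prob) / (1.0 + np.exp(-z))
        return p if np.ndim(freq_hz) else float(p)

    @classmethod
    def control_default(cls) -> "FrequencyFailureProfile":
        return cls(baseline_prob=CONTROL_FAILURE_PROB, midpoint_hz=130.0,
                   steepness_per_hz=0.05, ceiling_prob=0.33)

    @classmethod
    def swelling_default(cls) -> "FrequencyFailureProfile":
        return cls(baseline_prob=SWELLING_FAILURE_PROB, midpoint_hz=170.0,
                   steepness_per_hz=0.05, ceiling_prob=0.075)


@dataclass(frozen=True)
class BehaviorGenSpec:
    """Parameters of the behaviour-cohort generator.

    Learning is ``intercept + slope * density + N(0, noise_sd)`` with the
    swelling density (percent of axons bearing swellings) drawn from a
    normal clipped to [0, 100].  Defaults place the cohort at a population
    learning-density correlation of about 0.5-0.8, the regime the analysis
    operates in.
    """

    n_animals: int = 21
    density_mean: float = 35.0
    density_sd: float = 8.0
    slope: float = 2.0
    intercept: float = 30.0
    noise_sd: float = 20.0
    seed: int = 0

    def __post_init__(self):
        if self.n_animals < 3:
            raise InvalidParameterError("n_animals must be at least 3")
        if self.density_sd < 0 or self.noise_sd < 0:
            raise InvalidParameterError("spreads must be non-negative")

    @property
    def population_correlation(self) -> float:
        """Learning-density correlation implied by the linear model.

        Ignores the [0, 100] density clipping, which is negligible for the
        default mean +/- SD.
        """
        signal = abs(self.slope) * self.density_sd
        denom = np.hypot(signal, self.noise_sd)
        if denom == 0:
            return 0.0
        return float(np.sign(self.slope) * signal / denom)

    @classmethod
    def for_population_correlation(cls, r: float, **kwargs) -> "BehaviorGenSpec":
        """Spec whose noise SD yields population correlation ``r``."""
        if not 0.0 < abs(r) <= 1.0:
            raise InvalidParameterError("target correlation must be in (0, 1]")
        base = cls(noise_sd=0.0, **kwargs)
        signal = abs(base.slope) * base.density_sd
        noise_sd = signal * np.sqrt(1.0 / r**2 - 1.0)
        return replace(base, noise_sd=float(noise_sd))


# ---------------------------------------------------------------------------
# spike trains


def gen_soma_train(cfg: GeneratorConfig, cell_id: str = "cell", rng: Optional[np.random.Generator] = None) -> SpikeTrain:
    """Generate a somatic spike train as a gamma renewal process.

    Gamma shape is ``1 / isi_cv^2`` with the scale set so the mean interval
    is ``1 / firing_rate_hz``; a CV of 0 yields an exactly periodic train.
    The process starts at time 0 (first spike after the first interval).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    mean_isi = 1.0 / cfg.firing_rate_hz
    n_target = int(np.ceil(cfg.duration_s / mean_isi * 1.5)) + 25
    times = np.empty(0)
    t_end = 0.0
    while t_end <= cfg.duration_s:
        if cfg.isi_cv == 0:
            isis = np.full(n_target, mean_isi)
        else:
            shape = 1.0 / cfg.isi_cv**2
            isis = rng.gamma(shape, scale=mean_isi / shape, size=n_target)
        block = (t_end + np.cumsum(isis))
        times = np.concatenate([times, block])
        t_end = times[-1]
    times = times[times <= cfg.duration_s * (1.0 + 1e-12)]
    times = np.minimum(times, cfg.duration_s)
    return SpikeTrain(cell_id=cell_id, compartment="soma", times_s=times, duration_s=cfg.duration_s)


def gen_paired_recording(
    soma: SpikeTrain,
    cfg: GeneratorConfig,
    has_swelling: bool = False,
    axon_distance_um: float = 100.0,
    rng: Optional[np.random.Generator] = None,
) -> PairedRecording:
    """Thin, delay and jitter a somatic train into a paired recording.

    Each somatic spike is deleted with probability ``cfg.failure_prob``
    (independent Bernoulli); survivors are shifted by ``delay_ms`` plus
    Gaussian jitter.  Jitter-induced reordering is permitted (the axonal
    train is re-sorted) but flagged in the ground truth, as are spikes that
    fall outside the recording window after the shift.
    """
    if soma.n_spikes == 0:
        raise InvalidParameterError("soma train must be non-empty")
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    n = soma.n_spikes
    deleted = rng.random(n) < cfg.failure_prob
    jitter = rng.normal(0.0, cfg.delay_jitter_ms / 1000.0, size=n)
    shifted = soma.times_s + cfg.delay_ms / 1000.0 + jitter
    axon_times = shifted[~deleted]
    reordered = bool(np.any(np.diff(axon_times) <= 0))
    if reordered:
        axon_times = np.sort(axon_times)
    in_range = (axon_times >= 0.0) & (axon_times <= soma.duration_s)
    n_edge_dropped = int(np.count_nonzero(~in_range))
    axon_times = axon_times[in_range]
    # guard against exact duplicates after sorting (measure-zero but possible)
    if axon_times.size > 1:
        keep = np.concatenate([[True], np.diff(axon_times) > 0])
        axon_times = axon_times[keep]
    axon = SpikeTrain(
        cell_id=soma.cell_id, compartment="axon", times_s=axon_times, duration_s=soma.duration_s
    )
    return PairedRecording(
        soma=soma,
        axon=axon,
        has_swelling=has_swelling,
        axon_distance_um=axon_distance_um,
        ground_truth={
            "deletion_mask": deleted,
            "failure_prob": cfg.failure_prob,
            "delay_ms": cfg.delay_ms,
            "delay_jitter_ms": cfg.delay_jitter_ms,
            "reordered": reordered,
            "n_edge_dropped": n_edge_dropped,
        },
    )


def gen_paired_recording_set(
    cfg: GeneratorConfig,
    n_cells: int,
    has_swelling: bool = False,
    cell_prefix: str = "cell",
) -> List[PairedRecording]:
    """Generate ``n_cells`` independent paired recordings under one seed."""
    if n_cells < 1:
        raise InvalidParameterError("n_cells must be at least 1")
    children = np.random.SeedSequence(cfg.seed).spawn(n_cells)
    out = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        soma = gen_soma_train(cfg, cell_id=f"{cell_prefix}_{i:03d}", rng=rng)
        out.append(gen_paired_recording(soma, cfg, has_swelling=has_swelling, rng=rng))
    return out


# ---------------------------------------------------------------------------
# step-current protocol


#: Step amplitudes of the current-injection protocol: 0.05 nA increments
#: up to 1.8 nA (36 steps), each step lasting 500 ms.
STEP_AMPLITUDES_NA = np.round(np.arange(1, 37) * 0.05, 2)
STEP_DURATION_S = 0.5


def gen_step_protocol_session(
    cfg: GeneratorConfig,
    profile: FrequencyFailureProfile,
    cell_id: str = "cell",
    fi_gain_hz_per_na: float = 80.0,
    fi_intercept_hz: float = 10.0,
    collapse_na: Optional[float] = None,
    has_swelling: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> StepSession:
    """Simulate a step-current session for one synthetic cell.

    Current steps of 500 ms run from 0.05 nA in 0.05 nA increments up to
    1.8 nA, or stop early at ``collapse_na`` (the amplitude at which the
    cell ceases to fire).  The synthetic f-I curve is linear
    (``fi_intercept_hz + fi_gain_hz_per_na * amplitude``), hence monotone
    up to collapse.  Each step's per-spike failure probability is the
    profile evaluated at the step's realised mean somatic frequency.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if fi_gain_hz_per_na <= 0:
        raise InvalidParameterError("fi_gain_hz_per_na must be positive")
    records = []
    for amp in STEP_AMPLITUDES_NA:
        if collapse_na is not None and amp > collapse_na:
            break
        target_hz = fi_intercept_hz + fi_gain_hz_per_na * amp
        if target_hz <= 0:
            continue
        step_cfg = replace(
            cfg, firing_rate_hz=target_hz, duration_s=STEP_DURATION_S, failure_prob=0.0
        )
        soma = gen_soma_train(step_cfg, cell_id=cell_id, rng=rng)
        if soma.n_spikes == 0:
            continue
        mean_freq = soma.n_spikes / STEP_DURATION_S
        p_fail = float(profile.failure_prob(mean_freq))
        thin_cfg = replace(step_cfg, failure_prob=p_fail)
        pair = gen_paired_recording(soma, thin_cfg, has_swelling=has_swelling, rng=rng)
        records.append(
            StepRecord(
                amplitude_na=float(amp),
                soma=soma,
                axon=pair.axon,
                failure_prob=p_fail,
                deletion_mask=pair.ground_truth["deletion_mask"],
            )
        )
    return StepSession(
        cell_id=cell_id,
        records=tuple(records),
        step_duration_s=STEP_DURATION_S,
        has_swelling=has_swelling,
        ground_truth={
            "profile": profile,
            "fi_gain_hz_per_na": fi_gain_hz_per_na,
            "fi_intercept_hz": fi_intercept_hz,
            "collapse_na": collapse_na,
        },
    )


# ---------------------------------------------------------------------------
# behaviour cohorts


def gen_behavior_cohort(spec: BehaviorGenSpec, task: str = "rotarod") -> List[BehaviorRecord]:
    """Generate a behaviour cohort with density-coupled learning.

    Per animal, swelling density is drawn from a normal clipped to
    [0, 100] and the latent learning score from the linear model.  Raw
    per-day task tables are then constructed so that the standard scoring
    rule (final-day minus first-day performance) recovers the generated
    score: the realised score implied by the table is stored in the ground
    truth alongside the latent one (they differ only by floating-point
    rounding for the rotarod and by integer rounding of step counts for
    the ladder).
    """
    rng = np.random.default_rng(spec.seed)
    densities = np.clip(
        rng.normal(spec.density_mean, spec.density_sd, size=spec.n_animals), 0.0, 100.0
    )
    latent = spec.intercept + spec.slope * densities + rng.normal(0.0, spec.noise_sd, size=spec.n_animals)

    records = []
    for i in range(spec.n_animals):
        if task == "rotarod":
            base = rng.normal(60.0, 10.0)  # day-1 latency scale, s
            n_days, n_trials = 7, 4
            table = np.empty((n_days, n_trials))
            for d in range(n_days):
                day_mean = base + latent[i] * d / (n_days - 1)
                table[d, :2] = day_mean + rng.normal(0.0, 5.0, size=2)
                table[d, 2:] = day_mean  # scored trials: exact day mean
            realized = float(np.mean(table[-1, -2:]) - np.mean(table[0, -2:]))
        elif task == "erasmus":
            base = rng.normal(20.0, 4.0)  # day-1 short-step count scale
            n_days = 4
            counts = np.rint(base + latent[i] * np.arange(n_days) / (n_days - 1))
            table = counts[:, None]
            realized = float(counts[-1] - counts[0])
        elif task == "vor":
            table = np.empty((0, 0))
            realized = float(latent[i])
        else:
            raise InvalidParameterError(f"unknown task {task!r}")
        records.append(
            BehaviorRecord(
                animal_id=f"animal_{i:03d}",
                task=task,
                per_day_scores=table if table.size else np.zeros((1, 1)),
                swelling_density_pct=float(densities[i]),
                precomputed_score=realized if task == "vor" else None,
                ground_truth={
                    "latent_learning": float(latent[i]),
                    "realized_learning": realized,
                    "density_pct": float(densities[i]),
                    "spec": spec,
                },
            )
        )
    return records


# ---------------------------------------------------------------------------
# time-lapse swelling formation


#: Mean new-swelling rate curves (per 100 Purkinje cells) over hourly
#: timepoints, matching the reported endpoints of the three pharmacology
#: conditions, with field counts as in the recordings.
TIMELAPSE_PRESETS = {
    "low_ttx": {"rate_curve": (0.0, 2.4, 4.8, 7.11), "n_fields": 38},
    "no_ttx": {"rate_curve": (0.0, 0.5, 1.0, 1.45), "n_fields": 6},
    "high_ttx": {"rate_curve": (0.0, 0.8, 1.5, 2.26), "n_fields": 6},
}


def gen_timelapse_experiment(
    condition_name: str,
    n_fields: int,
    rate_curve: Sequence[float],
    dispersion: float = 0.3,
    seed: int = 0,
    n_cells_mean: float = 100.0,
) -> List[TimelapseRecord]:
    """Generate per-field new-swelling counts over hourly timepoints.

    Counts are gamma-Poisson mixed around ``rate_curve`` (per 100 cells),
    so the per-100-cell normalisation downstream recovers the curve in
    expectation; ``dispersion`` 0 gives plain Poisson counts.  Each field
    observes a Poisson-distributed number of Purkinje cells around
    ``n_cells_mean``.
    """
    rates = np.asarray(rate_curve, dtype=float)
    if np.any(rates < 0):
        raise InvalidParameterError("rate_curve must be non-negative")
    if n_fields < 1:
        raise InvalidParameterError("n_fields must be at least 1")
    if dispersion < 0:
        raise InvalidParameterError("dispersion must be non-negative")
    rng = np.random.default_rng(seed)
    records = []
    for f in range(n_fields):
        n_cells = max(1, int(rng.poisson(n_cells_mean)))
        mean_counts = rates * n_cells / 100.0
        if dispersion > 0:
            lam = mean_counts * rng.gamma(1.0 / dispersion, dispersion, size=rates.size)
        else:
            lam = mean_counts
        counts = rng.poisson(lam)
        records.append(
            TimelapseRecord(
                condition=condition_name,
                field_id=f"{condition_name}_field_{f:03d}",
                timepoints_h=np.arange(rates.size, dtype=float),
                new_swellings=counts,
                n_cells=n_cells,
            )
        )
    return records
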
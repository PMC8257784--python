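"""Per-cell action-potential propagation fidelity metrics.

The unit of analysis is a pair of simultaneously recorded spike trains from
the soma and the axon of the same Purkinje cell.  A somatic spike with no
corresponding axonal spike is a *propagation failure*.  This module matches
soma and axon spikes, counts failures, estimates the axosomatic conduction
delay (which may be negative, because spikes initiate in the axon initial
segment), summarises firing rate and regularity, and bins step-current
sessions into frequency-resolved propagation-reliability curves.

Spike times are in seconds throughout; delays and matching windows are in
milliseconds; firing frequencies in Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .exceptions import (
    InsufficientDataError,
    InvalidInputError,
    InvalidParameterError,
)

__all__ = [
    "SpikeTrain",
    "PairedRecording",
    "StepRecord",
    "StepSession",
    "SpikeMatching",
    "FiringStats",
    "ReliabilityCurve",
    "match_spikes",
    "failure_rate_per_1000",
    "classify_fidelity",
    "axosomatic_delay_ms",
    "firing_stats",
    "normalize_frequency",
    "reliability_by_frequency",
    "success_at_max_frequency",
]

#: Default half-width of the soma->axon matching window, in ms.  The window
#: is centred on the estimated axosomatic delay; an axonal spike more than
#: this far from the expected arrival time is not accepted as the partner
#: of a somatic spike.  Reported in every output manifest.
DEFAULT_WINDOW_MS = 2.0

_TIME_RTOL = 1e-9


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike times for one compartment of one cell.

    Parameters
    ----------
    cell_id : str
        Identifier of the cell.
    compartment : {"soma", "axon"}
        Recording site.
    times_s : ndarray
        Strictly increasing spike times in seconds, within ``[0, duration_s]``.
    duration_s : float
        Recording duration in seconds (> 0).
    """

    cell_id: str
    compartment: str
    times_s: np.ndarray
    duration_s: float

    def __post_init__(self):
        if self.compartment not in ("soma", "axon"):
            raise InvalidParameterError(
                f"compartment must be 'soma' or 'axon', got {self.compartment!r}"
            )
        if not self.duration_s > 0:
            raise InvalidParameterError("duration_s must be positive")
        t = np.asarray(self.times_s, dtype=float)
        object.__setattr__(self, "times_s", t)
        if t.size:
            if np.any(np.diff(t) <= 0):
                raise InvalidInputError("spike times must be strictly increasing")
            tol = _TIME_RTOL * max(self.duration_s, 1.0)
            if t[0] < -tol or t[-1] > self.duration_s + tol:
                raise InvalidInputError(
                    "spike times must lie within [0, duration_s]"
                )

    @property
    def n_spikes(self) -> int:
        return int(self.times_s.size)

    @property
    def isis_s(self) -> np.ndarray:
        """Interspike intervals in seconds."""
        return np.diff(self.times_s)


@dataclass(frozen=True)
class PairedRecording:
    """Simultaneous soma + axon spike trains from one cell.

    ``ground_truth`` is populated by the synthetic generator (per-spike
    deletion mask, generating parameters); it is ``None`` for real data.
    """

    soma: SpikeTrain
    axon: SpikeTrain
    has_swelling: bool = False
    axon_distance_um: float = 100.0
    ground_truth: Optional[dict] = None

    def __post_init__(self):
        if abs(self.soma.duration_s - self.axon.duration_s) > 1e-9:
            raise InvalidInputError("soma and axon durations must be equal")
        if not self.axon_distance_um > 0:
            raise InvalidParameterError("axon_distance_um must be positive")


@dataclass(frozen=True)
class StepRecord:
    """One current step of a step-protocol session."""

    amplitude_na: float
    soma: SpikeTrain
    axon: SpikeTrain
    failure_prob: Optional[float] = None  # generating value, if synthetic
    deletion_mask: Optional[np.ndarray] = None


@dataclass(frozen=True)
class StepSession:
    """A family of current steps applied to one cell.

    Steps of 500 ms are applied at increasing amplitudes; each step carries
    the evoked somatic train and the axonal train recorded downstream.
    """

    cell_id: str
    records: tuple
    step_duration_s: float = 0.5
    has_swelling: bool = False
    ground_truth: Optional[dict] = None


@dataclass(frozen=True)
class SpikeMatching:
    """Soma->axon spike assignment for one paired recording.

    ``axon_times_s`` holds, for each somatic spike, the matched axonal spike
    time or NaN when the spike failed to propagate.
    """

    soma_times_s: np.ndarray
    axon_times_s: np.ndarray
    window_ms: float
    delay_estimate_ms: float

    @property
    def n_soma(self) -> int:
        return int(self.soma_times_s.size)

    @property
    def matched(self) -> np.ndarray:
        return ~np.isnan(self.axon_times_s)

    @property
    def n_matched(self) -> int:
        return int(np.count_nonzero(self.matched))

    @property
    def n_failures(self) -> int:
        return self.n_soma - self.n_matched


@dataclass(frozen=True)
class FiringStats:
    """Rate and regularity summary of a single spike train.

    ``cv`` is the global coefficient of variation of the interspike
    intervals; ``cv2`` is the local variant, robust to slow rate drift.
    Both are NaN when fewer than 3 spikes are available.
    """

    rate_hz: float
    cv: float
    cv2: float
    n_spikes: int

    @property
    def regularity_defined(self) -> bool:
        return self.n_spikes >= 3


@dataclass(frozen=True)
class ReliabilityCurve:
    """Propagation success fraction per firing-frequency bin.

    Bins are half-open ``[lo, hi)`` with origin 0 Hz.  ``success_fraction``
    is NaN in bins with no spikes.  The spike-weighted mean of the occupied
    bins equals the pooled success fraction exactly.
    """

    bin_edges_hz: np.ndarray
    success_fraction: np.ndarray
    n_spikes_per_bin: np.ndarray
    n_matched_per_bin: np.ndarray
    f_max_hz: float
    success_at_max: float
    window_ms: float = DEFAULT_WINDOW_MS

    @property
    def pooled_success(self) -> float:
        tot = int(self.n_spikes_per_bin.sum())
        return float(self.n_matched_per_bin.sum()) / tot if tot else float("nan")


# ---------------------------------------------------------------------------
# matching


def _estimate_delay_s(soma: np.ndarray, axon: np.ndarray) -> float:
    """Median offset of each somatic spike to its nearest axonal spike."""
    if axon.size == 0 or soma.size == 0:
        return 0.0
    idx = np.searchsorted(axon, soma)
    lo = np.clip(idx - 1, 0, axon.size - 1)
    hi = np.clip(idx, 0, axon.size - 1)
    d_lo = axon[lo] - soma
    d_hi = axon[hi] - soma
    nearest = np.where(np.abs(d_lo) <= np.abs(d_hi), d_lo, d_hi)
    return float(np.median(nearest))


def match_spikes(rec: PairedRecording, window_ms: float = DEFAULT_WINDOW_MS) -> SpikeMatching:
    """Assign axonal spikes to somatic spikes.

    A first pass estimates the axosomatic delay as the median of each
    somatic spike's offset to its nearest axonal spike (robust to the
    small fraction of failures).  A second, greedy pass walks the somatic
    spikes in time order and matches each to the closest unused axonal
    spike within ``window_ms`` of the expected arrival time.

    Raises
    ------
    InsufficientDataError
        If the somatic train is empty (no reference spikes to match).
    """
    if not window_ms > 0:
        raise InvalidParameterError("window_ms must be positive")
    soma = rec.soma.times_s
    axon = rec.axon.times_s
    if soma.size == 0:
        raise InsufficientDataError("cannot match against an empty soma train")

    delay_s = _estimate_delay_s(soma, axon)
    window_s = window_ms / 1000.0
    expected = soma + delay_s

    matched = np.full(soma.size, np.nan)
    used = np.zeros(axon.size, dtype=bool)
    # candidate windows via sorted search; greedy in time order
    left = np.searchsorted(axon, expected - window_s, side="left")
    right = np.searchsorted(axon, expected + window_s, side="right")
    for i in range(soma.size):
        lo, hi = left[i], right[i]
        if lo >= hi:
            continue
        cand = np.arange(lo, hi)
        cand = cand[~used[cand]]
        if cand.size == 0:
            continue
        j = cand[np.argmin(np.abs(axon[cand] - expected[i]))]
        used[j] = True
        matched[i] = axon[j]
    return SpikeMatching(
        soma_times_s=soma,
        axon_times_s=matched,
        window_ms=float(window_ms),
        delay_estimate_ms=delay_s * 1000.0,
    )


def failure_rate_per_1000(m: SpikeMatching) -> float:
    """Propagation failures per 1000 somatic spikes."""
    if m.n_soma < 1:
        raise InsufficientDataError("failure rate undefined for zero soma spikes")
    return 1000.0 * m.n_failures / m.n_soma


def classify_fidelity(rate_per_1000: float) -> str:
    """Classify an axon as a high- or low-fidelity transmitter.

    High fidelity: fewer than 1 in 1000 somatic spikes fail to propagate.
    A rate of exactly 1.0 is assigned to the low-fidelity class.
    """
    if rate_per_1000 < 0:
        raise InvalidParameterError("failure rate cannot be negative")
    return "high" if rate_per_1000 < 1.0 else "low"


def axosomatic_delay_ms(m: SpikeMatching) -> float:
    """Mean axon-minus-soma spike-time difference over matched pairs, ms.

    Negative values are meaningful: the action potential initiates in the
    axon initial segment and can reach the axonal electrode first.
    """
    if m.n_matched == 0:
        raise InsufficientDataError("delay undefined without matched pairs")
    diffs = m.axon_times_s[m.matched] - m.soma_times_s[m.matched]
    return float(np.mean(diffs)) * 1000.0


# ---------------------------------------------------------------------------
# rate and regularity


def firing_stats(train: SpikeTrain, cv2_method: str = "median") -> FiringStats:
    """Firing rate plus ISI regularity (CV and CV2).

    CV2 for consecutive intervals is ``2|I(i+1) - I(i)| / (I(i+1) + I(i))``;
    the median across the train is reported by default (robust to bimodal
    ISI mixtures), the mean on request.
    """
    if cv2_method not in ("median", "mean"):
        raise InvalidParameterError("cv2_method must be 'median' or 'mean'")
    n = train.n_spikes
    rate = n / train.duration_s
    if n < 3:
        return FiringStats(rate_hz=rate, cv=float("nan"), cv2=float("nan"), n_spikes=n)
    isi = train.isis_s
    cv = float(np.std(isi) / np.mean(isi))
    pair_sum = isi[1:] + isi[:-1]
    cv2_vals = 2.0 * np.abs(np.diff(isi)) / pair_sum
    agg = np.median if cv2_method == "median" else np.mean
    return FiringStats(rate_hz=rate, cv=cv, cv2=float(agg(cv2_vals)), n_spikes=n)


def normalize_frequency(series, baseline: float) -> np.ndarray:
    """Divide a per-timepoint rate series by its pre-treatment baseline."""
    if not baseline > 0:
        raise InvalidParameterError("baseline must be positive")
    return np.asarray(series, dtype=float) / baseline


# ---------------------------------------------------------------------------
# step-protocol reliability


def reliability_by_frequency(
    session: StepSession,
    bin_hz: float = 20.0,
    window_ms: float = DEFAULT_WINDOW_MS,
) -> ReliabilityCurve:
    """Propagation success by 20-Hz firing-frequency bin for one session.

    Each current step is assigned to a bin by its mean somatic firing
    frequency (spike count / step duration).  Within a bin, matched axonal
    spikes and somatic spikes are pooled over the steps falling in that bin.
    ``f_max_hz`` is the highest step frequency attained; its success is
    pooled across all steps tied at that frequency.
    """
    if not bin_hz > 0:
        raise InvalidParameterError("bin_hz must be positive")
    steps = [r for r in session.records if r.soma.n_spikes >= 1]
    if not steps:
        raise InsufficientDataError("session contains no step with somatic spikes")

    freqs, n_soma, n_match = [], [], []
    for r in steps:
        pair = PairedRecording(soma=r.soma, axon=r.axon)
        m = match_spikes(pair, window_ms=window_ms)
        freqs.append(r.soma.n_spikes / session.step_duration_s)
        n_soma.append(m.n_soma)
        n_match.append(m.n_matched)
    freqs = np.asarray(freqs)
    n_soma = np.asarray(n_soma)
    n_match = np.asarray(n_match)

    n_bins = int(np.floor(freqs.max() / bin_hz)) + 1
    edges = np.arange(n_bins + 1) * bin_hz
    which = np.minimum((freqs // bin_hz).astype(int), n_bins - 1)
    spikes_per_bin = np.bincount(which, weights=n_soma, minlength=n_bins)
    matched_per_bin = np.bincount(which, weights=n_match, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        success = matched_per_bin / spikes_per_bin

    f_max = float(freqs.max())
    at_max = np.isclose(freqs, f_max)
    success_max = float(n_match[at_max].sum() / n_soma[at_max].sum())
    return ReliabilityCurve(
        bin_edges_hz=edges,
        success_fraction=success,
        n_spikes_per_bin=spikes_per_bin.astype(int),
        n_matched_per_bin=matched_per_bin.astype(int),
        f_max_hz=f_max,
        success_at_max=success_max,
        window_ms=float(window_ms),
    )


def success_at_max_frequency(curve: ReliabilityCurve) -> tuple:
    """(highest attained step frequency, propagation success at it)."""
    if curve.n_spikes_per_bin.sum() == 0:
        raise InsufficientDataError("empty reliability curve")
    return curve.f_max_hz, curve.success_at_max
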
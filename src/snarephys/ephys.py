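"""Stimulus-locked synaptic metrics and mEPSC analysis.

Conventions: EPSC amplitudes and mEPSC amplitudes are positive magnitudes of
inward currents (nA); charges are positive magnitudes (nC).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "TrainRecording",
    "MiniStats",
    "HillFit",
    "detect_minis",
    "paired_pulse_ratio",
    "stp_ratio",
    "back_extrapolate_rrp",
    "recovery_fraction",
    "vesicular_release_probability",
    "hill_fit",
]


@dataclass
class TrainRecording:
    """EPSC amplitudes/charges locked to a stimulus train."""

    stim_times: np.ndarray  # s
    amplitudes: np.ndarray  # nA, magnitudes
    charges: np.ndarray  # nC, magnitudes
    frequency: float  # Hz
    recovery: Dict[str, Tuple[float, float]] = field(default_factory=dict)  # label -> (time s, amplitude nA)

    def __post_init__(self) -> None:
        self.stim_times = np.asarray(self.stim_times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.charges = np.asarray(self.charges, dtype=float)
        if np.any(np.diff(self.stim_times) <= 0):
            raise ValueError("stimulus times must be strictly increasing")
        if np.any(self.amplitudes < 0) or np.any(self.charges < 0):
            raise ValueError("amplitudes and charges are magnitudes, must be >= 0")


@dataclass
class MiniStats:
    """Summary of detected miniature EPSCs."""

    frequency: float  # Hz
    mean_amplitude: float  # nA
    mean_charge: float  # nC
    event_times: np.ndarray  # s


def detect_minis(
    trace: np.ndarray,
    sample_rate: float,
    threshold_mads: float = 4.0,
    min_interval_s: float = 5.0e-3,
    baseline_window_s: float = 1.0,
    min_width_s: float = 1.0e-3,
) -> MiniStats:
    """Detect spontaneous inward events on a current trace (nA, inward negative).

    Baseline is a piecewise running median (block medians interpolated over
    ``baseline_window_s`` blocks); events are negative-going excursions beyond
    ``threshold_mads`` x MAD that stay below threshold for at least
    ``min_width_s`` (rejects single-sample noise spikes), separated by at
    least ``min_interval_s``.  Amplitude is baseline-to-peak; charge
    integrates the event until the trace re-crosses half the detection
    threshold.
    """
    from scipy.ndimage import uniform_filter1d

    trace = np.asarray(trace, dtype=float)
    if len(trace) == 0:
        raise ValueError("empty trace")
    if threshold_mads <= 0:
        raise ValueError("threshold_mads must be > 0")
    n = len(trace)
    block = max(int(baseline_window_s * sample_rate), 1)
    edges = np.arange(0, n, block)
    centers = np.minimum(edges + block // 2, n - 1)
    block_medians = np.array([np.median(trace[i : i + block]) for i in edges])
    baseline = np.interp(np.arange(n), centers, block_medians)
    # brief pre-smoothing suppresses single-sample noise excursions
    resid = uniform_filter1d(trace - baseline, size=max(int(5e-4 * sample_rate), 1), mode="nearest")
    mad = np.median(np.abs(resid - np.median(resid))) * 1.4826
    if mad == 0:
        mad = np.std(resid) or 1e-12
    thr = threshold_mads * mad

    below = resid < -thr
    starts = np.flatnonzero(below & ~np.roll(below, 1))
    ends = np.flatnonzero(below & ~np.roll(below, -1))
    if below[0]:
        starts = np.concatenate([[0], starts[starts != 0]])
    if below[-1]:
        ends = np.concatenate([ends[ends != n - 1], [n - 1]])
    duration = n / sample_rate
    if len(starts) == 0:
        return MiniStats(0.0, np.nan, np.nan, np.array([]))

    # merge regions separated by less than the minimum inter-event interval,
    # tracking the widest contiguous sub-threshold run of each merged event
    gap = max(int(min_interval_s * sample_rate), 1)
    merged = [[starts[0], ends[0], ends[0] - starts[0] + 1]]
    for s, e in zip(starts[1:], ends[1:]):
        if s - merged[-1][1] < gap:
            merged[-1][1] = e
            merged[-1][2] = max(merged[-1][2], e - s + 1)
        else:
            merged.append([s, e, e - s + 1])
    min_width = max(int(min_width_s * sample_rate), 1)
    merged = [[s, e] for s, e, w in merged if w >= min_width]
    if not merged:
        return MiniStats(0.0, np.nan, np.nan, np.array([]))

    dt = 1.0 / sample_rate
    peaks, amps, charges = [], [], []
    for s, e in merged:
        seg = resid[s : e + 1]
        p = s + int(np.argmin(seg))
        peaks.append(p)
        amps.append(-resid[p])
        # integrate to half-threshold re-crossing on either side
        half = thr / 2
        i, j = s, e
        while i > 0 and -resid[i - 1] > half:
            i -= 1
        while j < n - 1 and -resid[j + 1] > half:
            j += 1
        charges.append(float(np.sum(-resid[i : j + 1]) * dt))
    peaks = np.array(peaks)
    return MiniStats(
        frequency=len(peaks) / duration,
        mean_amplitude=float(np.mean(amps)),
        mean_charge=float(np.mean(charges)),
        event_times=peaks / sample_rate,
    )


def paired_pulse_ratio(a1: float, a2: float) -> float:
    """PPR = A2/A1 of two EPSC amplitudes."""
    if a1 <= 0:
        raise ValueError(f"first amplitude must be > 0, got {a1}")
    return a2 / a1


def stp_ratio(train: TrainRecording) -> Tuple[float, np.ndarray]:
    """Short-term plasticity ratio A5/A1 and the A_i/A1 normalized train."""
    if len(train.amplitudes) < 5:
        raise ValueError("train must contain at least 5 stimuli")
    a1 = train.amplitudes[0]
    if a1 <= 0:
        raise ValueError("first amplitude must be > 0")
    normalized = train.amplitudes / a1
    return float(normalized[4]), normalized


def back_extrapolate_rrp(train: TrainRecording, tail_points: int = 20) -> Dict[str, float]:
    """RRP charge by back-extrapolating cumulative released charge to t = 0.

    Ordinary least squares of cumulative charge on time over the final
    ``tail_points`` stimuli; the intercept estimates the pool present before
    the train, the slope the steady refill rate.
    """
    n = len(train.charges)
    if not (n > tail_points >= 3):
        raise ValueError(f"need train length > tail_points >= 3, got {n} and {tail_points}")
    cum = np.cumsum(train.charges)
    t = train.stim_times
    ts, cs = t[-tail_points:], cum[-tail_points:]
    if np.var(ts) == 0:
        raise ValueError("degenerate tail: stimulus times have zero variance")
    slope, intercept = np.polyfit(ts, cs, 1)
    ss_res = float(np.sum((cs - (intercept + slope * ts)) ** 2))
    ss_tot = float(np.sum((cs - cs.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0  # flat tail: exact fit
    return {
        "rrp_charge": float(intercept),
        "refill_rate": float(slope),
        "r2": r2,
    }


def recovery_fraction(a_recovery: float, a_first: float) -> float:
    """Recovered fraction = recovery-pulse amplitude over first train amplitude."""
    if a_first <= 0:
        raise ValueError(f"first amplitude must be > 0, got {a_first}")
    return a_recovery / a_first


def vesicular_release_probability(epsc_charge: float, rrp_charge: float) -> float:
    """P_ves = EPSC charge / RRP charge (clamped to 1 with a warning if above)."""
    if rrp_charge <= 0:
        raise ValueError(f"rrp_charge must be > 0, got {rrp_charge}")
    if epsc_charge <= 0:
        raise ValueError(f"epsc_charge must be > 0, got {epsc_charge}")
    p = epsc_charge / rrp_charge
    if p > 1:
        import warnings

        warnings.warn(f"P_ves {p:.3g} > 1; reporting clamped value", stacklevel=2)
        return 1.0
    return p


@dataclass
class HillFit:
    """Hill-equation fit of normalized response vs calcium concentration."""

    amax: float
    kd: float  # mM
    hill_n: float
    se_amax: float
    se_kd: float
    se_hill_n: float
    converged: bool


def _hill(c: np.ndarray, amax: float, kd: float, n: float) -> np.ndarray:
    return amax * c**n / (kd**n + c**n)


def hill_fit(
    concentrations: Sequence[float],
    responses: Sequence[float],
    init: Tuple[float, float, float] = (1.0, 2.0, 2.0),
) -> HillFit:
    """Least-squares Hill fit A*c^n/(Kd^n + c^n); SEs from the fit covariance."""
    c = np.asarray(concentrations, dtype=float)
    r = np.asarray(responses, dtype=float)
    if len(np.unique(c)) < 4:
        raise ValueError("need at least 4 distinct concentrations")
    try:
        popt, pcov = curve_fit(
            _hill, c, r, p0=init, bounds=([1e-6, 1e-6, 1e-6], [np.inf, np.inf, 20.0]), maxfev=10000
        )
        ses = np.sqrt(np.diag(pcov))
        converged = bool(np.all(np.isfinite(ses)))
    except RuntimeError:
        popt, ses, converged = np.array(init, dtype=float), np.full(3, np.nan), False
    return HillFit(
        amax=float(popt[0]),
        kd=float(popt[1]),
        hill_n=float(popt[2]),
        se_amax=float(ses[0]),
        se_kd=float(ses[1]),
        se_hill_n=float(ses[2]),
        converged=converged,
    )
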
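"""Hidden-Markov segmentation of extension-time trajectories.

Constant-force (or constant-trap-separation) recordings of the dumbbell show
hopping between a few extension levels.  A Gaussian-emission HMM fitted by
Baum-Welch assigns each sample to a folding state; the Viterbi path is then
reduced to dwell times, occupancies and transition rates.  Rates are taken
from transition counts over occupancy time (k_ij = N_ij / T_i), which is
robust when rates are far below the sampling rate; the first and last
(censored) dwells are excluded from lifetime means.

Baum-Welch/Viterbi themselves are delegated to ``hmmlearn``; this module owns
initialization, degeneracy restarts, the sorted-state convention and the
dwell/rate estimators.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from hmmlearn.hmm import GaussianHMM
from hmmlearn.base import ConvergenceMonitor

from .landscape import ForceDependentSeries

__all__ = [
    "Trajectory",
    "HMMFit",
    "DwellStats",
    "mean_filter",
    "fit_hmm",
    "idealize",
    "dwell_statistics",
    "select_n_states",
    "detect_rips",
    "assemble_force_series",
]


@dataclass
class Trajectory:
    """Uniformly sampled extension-time series with optional force channel."""

    time: np.ndarray  # s
    extension: np.ndarray  # nm
    sample_rate: float  # Hz
    force: Optional[np.ndarray] = None  # pN (may be a constant array)
    metadata: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.extension = np.asarray(self.extension, dtype=float)
        if self.force is not None:
            self.force = np.asarray(self.force, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")
        if len(self.time) != len(self.extension):
            raise ValueError("time and extension must have equal length")
        if len(self.time) > 1:
            dt = np.diff(self.time)
            if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
                raise ValueError("time grid must be uniform")
        if not (np.isfinite(self.extension).all() and np.isfinite(self.time).all()):
            raise ValueError("trajectory contains non-finite values")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def duration(self) -> float:
        return len(self) / self.sample_rate

    @property
    def mean_force(self) -> Optional[float]:
        return None if self.force is None else float(np.mean(self.force))


def mean_filter(traj: Trajectory, target_rate: float) -> Trajectory:
    """Decimate by non-overlapping block averaging to ``target_rate`` (Hz)."""
    ratio = traj.sample_rate / target_rate
    block = int(round(ratio))
    if abs(ratio - block) > 1e-9 or block < 1:
        raise ValueError(
            f"target rate {target_rate} Hz must divide sample rate {traj.sample_rate} Hz"
        )
    if block == 1:
        return traj
    n = (len(traj) // block) * block
    ext = traj.extension[:n].reshape(-1, block).mean(axis=1)
    t = traj.time[:n].reshape(-1, block).mean(axis=1)
    force = None
    if traj.force is not None:
        force = traj.force[:n].reshape(-1, block).mean(axis=1)
    meta = dict(traj.metadata)
    meta["mean_filtered_from_Hz"] = traj.sample_rate
    return Trajectory(time=t, extension=ext, sample_rate=target_rate, force=force, metadata=meta)


@dataclass
class HMMFit:
    """Converged Gaussian-emission HMM with states sorted by extension mean."""

    n_states: int
    means: np.ndarray  # nm, ascending
    sds: np.ndarray  # nm
    transmat: np.ndarray  # per-sample-interval, row stochastic
    stationary: np.ndarray
    log_likelihood: float
    log_likelihood_history: List[float]
    viterbi_path: np.ndarray  # state index per sample
    converged: bool
    seed: int
    sample_rate: float

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.means) >= 0):
            raise ValueError("means must be sorted ascending")
        if not np.allclose(self.transmat.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition matrix rows must sum to 1")
        if not np.all(self.sds > 0):
            raise ValueError("emission sds must be > 0")

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_states": self.n_states,
                "means": self.means.tolist(),
                "sds": self.sds.tolist(),
                "transmat": self.transmat.tolist(),
                "stationary": self.stationary.tolist(),
                "log_likelihood": self.log_likelihood,
                "converged": self.converged,
                "seed": self.seed,
                "sample_rate": self.sample_rate,
            },
            indent=2,
        )


class _FullHistoryMonitor(ConvergenceMonitor):
    """Convergence monitor that records the full log-likelihood trace."""

    def __init__(self, tol, n_iter, verbose=False):
        super().__init__(tol, n_iter, verbose)
        self.full_history: List[float] = []

    def report(self, log_prob):
        self.full_history.append(float(log_prob))
        super().report(log_prob)

    def _reset(self):
        self.full_history = []
        super()._reset()


def _quantile_init(x: np.ndarray, n_states: int) -> np.ndarray:
    """Spread initial means between robust extremes of the data.

    An even spread between the 0.1 and 99.9 percentiles places a component
    near rare extreme states that quantile-of-mass initialization would miss.
    """
    lo, hi = np.percentile(x, [0.1, 99.9])
    if hi <= lo:
        hi = lo + 1e-6
    return np.linspace(lo, hi, n_states)


def fit_hmm(
    traj: Trajectory,
    n_states: int,
    init_means: Optional[Sequence[float]] = None,
    seed: int = 0,
    n_iter: int = 500,
    tol: float = 1e-8,
    max_restarts: int = 3,
    em_max_samples: int = 1_200_000,
) -> HMMFit:
    """Fit a Gaussian-emission HMM by Baum-Welch and Viterbi-decode the trace.

    Deterministic given ``seed`` and ``init_means``; the seed is used only to
    jitter restarts after a degenerate EM solution (vanishing emission sd or
    an empty state).  For traces longer than ``em_max_samples`` the EM step
    runs on the leading window of that length and the full trace is decoded
    with the estimated parameters.
    """
    if len(traj) < 100 * n_states:
        raise ValueError(f"trajectory of {len(traj)} samples too short for {n_states} states")
    x = traj.extension.reshape(-1, 1)
    x_train = x[:em_max_samples]
    rng = np.random.default_rng(seed)
    sd0 = max(float(np.std(x_train)) / max(n_states, 2), 1e-3)
    means0 = (
        np.asarray(init_means, dtype=float)
        if init_means is not None
        else _quantile_init(x_train.ravel(), n_states)
    )
    if len(means0) != n_states:
        raise ValueError("init means length must equal n_states")

    last_exc: Optional[str] = None
    for attempt in range(max_restarts + 1):
        jitter = 0.0 if attempt == 0 else rng.normal(0.0, sd0, size=n_states)
        model = GaussianHMM(
            n_components=n_states,
            covariance_type="diag",
            init_params="",
            params="stmc",
            n_iter=n_iter,
            tol=tol,
        )
        model.monitor_ = _FullHistoryMonitor(tol, n_iter)
        model.startprob_ = np.full(n_states, 1.0 / n_states)
        transmat0 = np.full((n_states, n_states), 0.01 / max(n_states - 1, 1))
        np.fill_diagonal(transmat0, 0.99)
        model.transmat_ = transmat0 / transmat0.sum(axis=1, keepdims=True)
        model.means_ = (np.sort(means0 + jitter)).reshape(-1, 1)
        model.covars_ = np.full((n_states, 1), sd0**2)
        hmmlearn_log = logging.getLogger("hmmlearn.base")
        prev_level = hmmlearn_log.level
        hmmlearn_log.setLevel(logging.ERROR)  # tiny negative EM deltas are numerical noise
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(x_train)
        finally:
            hmmlearn_log.setLevel(prev_level)
        sds = np.sqrt(np.asarray(model.covars_).reshape(n_states, -1)[:, 0])
        log_likelihood, path = model.decode(x, algorithm="viterbi")
        counts = np.bincount(path, minlength=n_states)
        if np.any(sds < 1e-6) or (n_states > 1 and np.any(counts == 0)):
            last_exc = f"degenerate EM solution on attempt {attempt} (sds={sds}, counts={counts})"
            continue
        order = np.argsort(model.means_.ravel())
        means = model.means_.ravel()[order]
        sds = sds[order]
        transmat = model.transmat_[np.ix_(order, order)]
        remap = np.empty(n_states, dtype=int)
        remap[order] = np.arange(n_states)
        path = remap[path]
        evals, evecs = np.linalg.eig(transmat.T)
        k = int(np.argmin(np.abs(evals - 1.0)))
        stat = np.real(evecs[:, k])
        stat = np.abs(stat) / np.abs(stat).sum()
        history = list(model.monitor_.full_history)
        converged = bool(model.monitor_.converged)
        return HMMFit(
            n_states=n_states,
            means=means,
            sds=sds,
            transmat=transmat,
            stationary=stat,
            log_likelihood=float(log_likelihood),
            log_likelihood_history=history,
            viterbi_path=path.astype(np.int32),
            converged=converged,
            seed=seed,
            sample_rate=traj.sample_rate,
        )
    raise RuntimeError(f"HMM fit failed after {max_restarts + 1} attempts: {last_exc}")


def idealize(traj: Trajectory, fit: HMMFit) -> np.ndarray:
    """Maximum-probability (Viterbi) state path for the trajectory."""
    if not fit.converged:
        raise ValueError("HMM fit did not converge; refuse to idealize")
    if len(fit.viterbi_path) == len(traj):
        return fit.viterbi_path
    model = GaussianHMM(n_components=fit.n_states, covariance_type="diag", init_params="", params="")
    model.startprob_ = fit.stationary
    model.transmat_ = fit.transmat
    model.means_ = fit.means.reshape(-1, 1)
    model.covars_ = (fit.sds**2).reshape(-1, 1)
    _, path = model.decode(traj.extension.reshape(-1, 1), algorithm="viterbi")
    return path.astype(np.int32)


@dataclass
class DwellStats:
    """Dwell-time summaries of an idealized state path."""

    n_states: int
    occupancy: np.ndarray  # time fraction per state
    mean_lifetime: np.ndarray  # s, NaN when no completed dwell
    dwell_counts: np.ndarray  # completed dwells per state
    transition_counts: np.ndarray  # N_ij
    rates: np.ndarray  # k_ij = N_ij / T_i (1/s)
    total_time: float  # s


def _run_lengths(path: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """(state, length-in-samples) of each maximal run."""
    change = np.flatnonzero(np.diff(path)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(path)]])
    return path[starts], ends - starts


def dwell_statistics(path: np.ndarray, sample_rate: float, n_states: Optional[int] = None) -> DwellStats:
    """Dwell times, occupancies and rates from a state path.

    Dwells are maximal runs; the first and last dwell are censored and
    excluded from lifetime means.  k_ij = N_ij / T_i with T_i the total time
    spent in state i (censored time included).
    """
    path = np.asarray(path)
    if len(path) == 0:
        raise ValueError("empty state path")
    K = int(n_states if n_states is not None else path.max() + 1)
    states, lengths = _run_lengths(path)
    dt = 1.0 / sample_rate

    T = np.zeros(K)
    for k in range(K):
        T[k] = lengths[states == k].sum() * dt
    occupancy = T / T.sum()

    N = np.zeros((K, K))
    for a, b in zip(states[:-1], states[1:]):
        N[a, b] += 1

    mean_lt = np.full(K, np.nan)
    counts = np.zeros(K, dtype=int)
    if len(states) > 2:
        inner_states = states[1:-1]
        inner_lengths = lengths[1:-1]
        for k in range(K):
            sel = inner_states == k
            counts[k] = int(sel.sum())
            if counts[k] > 0:
                mean_lt[k] = inner_lengths[sel].mean() * dt

    with np.errstate(divide="ignore", invalid="ignore"):
        rates = np.where(T[:, None] > 0, N / T[:, None], 0.0)
    np.fill_diagonal(rates, 0.0)

    return DwellStats(
        n_states=K,
        occupancy=occupancy,
        mean_lifetime=mean_lt,
        dwell_counts=counts,
        transition_counts=N,
        rates=rates,
        total_time=len(path) * dt,
    )


def select_n_states(
    traj: Trajectory,
    candidates: Sequence[int] = (1, 2, 3),
    seed: int = 0,
    **fit_kwargs,
) -> int:
    """Pick the state count by BIC over candidate HMM fits (ties -> smaller n)."""
    if not candidates:
        raise ValueError("candidates must be non-empty")
    n_obs = min(len(traj), fit_kwargs.get("em_max_samples", 1_200_000))
    best_n, best_bic = None, np.inf
    failures = []
    for n in sorted(candidates):
        try:
            fit = fit_hmm(traj, n, seed=seed, **fit_kwargs)
        except Exception as exc:  # noqa: BLE001 - collected into diagnostics
            failures.append(f"n={n}: {exc}")
            continue
        n_params = 2 * n + n * (n - 1) + (n - 1)
        ll = fit.log_likelihood_history[-1]
        bic = -2.0 * ll + n_params * np.log(n_obs)
        if bic < best_bic - 1e-9:
            best_n, best_bic = n, bic
    if best_n is None:
        raise RuntimeError("all candidate HMM fits failed: " + "; ".join(failures))
    return best_n


def detect_rips(
    fec: Trajectory,
    threshold_mads: float = 6.0,
    window: int = 5,
    min_separation: int = 5,
    min_jump_nm: float = 2.0,
) -> List[Dict[str, float]]:
    """Detect unfolding rips (abrupt extension jumps) in a pulling curve.

    The curve is boxcar-smoothed over ``window`` samples and differenced at a
    lag of ``window``; excursions above ``threshold_mads`` x 1.4826 x MAD of
    that difference (over the slow-ramp baseline) and above ``min_jump_nm``
    are rips.  Crossings closer than ``min_separation`` samples merge into
    one rip, reported with the force immediately before the jump, ordered by
    occurrence.
    """
    from scipy.ndimage import uniform_filter1d

    n = len(fec.extension)
    if n < 3 * window:
        return []
    smooth = uniform_filter1d(fec.extension, size=window, mode="nearest")
    d = smooth[window:] - smooth[:-window]
    baseline = np.median(d)
    mad = np.median(np.abs(d - baseline))
    thr = max(threshold_mads * 1.4826 * mad, min_jump_nm * 0.5)
    idx = np.flatnonzero(d - baseline > thr)
    rips: List[Dict[str, float]] = []
    if len(idx) == 0:
        return rips
    groups = np.split(idx, np.flatnonzero(np.diff(idx) > min_separation) + 1)
    for g in groups:
        start = int(g[0])
        end = int(min(g[-1] + window, n - 1))
        delta = float(smooth[end] - smooth[start])
        if delta < min_jump_nm:
            continue
        force = float(fec.force[max(start - 1, 0)]) if fec.force is not None else np.nan
        rips.append({"force": force, "delta_extension": delta, "index": start})
    return rips


def assemble_force_series(
    fits: Sequence[Tuple[HMMFit, DwellStats, float]],
    labels: Optional[Sequence[str]] = None,
) -> ForceDependentSeries:
    """Combine per-force HMM results into a force-dependent series.

    Each entry is (HMMFit, DwellStats, mean force pN).  State counts must
    agree across forces; rows are sorted by force and occupancies
    renormalized.
    """
    if not fits:
        raise ValueError("need at least one per-force result")
    K = fits[0][0].n_states
    if any(f.n_states != K for f, _, _ in fits):
        raise ValueError("inconsistent state counts across forces")
    labels = list(labels) if labels is not None else [f"state_{k}" for k in range(K)]
    rows = []
    for fit, dw, force in sorted(fits, key=lambda t: t[2]):
        row = {"force_pN": float(force)}
        occ = dw.occupancy / dw.occupancy.sum()
        for k, lb in enumerate(labels):
            row[f"prob_{lb}"] = float(occ[k])
            row[f"ext_{lb}"] = float(fit.means[k])
            row[f"lifetime_{lb}"] = float(dw.mean_lifetime[k])
        for i in range(K):
            for j in range(K):
                if i != j:
                    row[f"rate_{i}__{j}"] = float(dw.rates[i, j])
        rows.append(row)
    return ForceDependentSeries(labels=labels, table=pd.DataFrame(rows))
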
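"""Synthetic-data generators for every input the analysis pipeline consumes.

Each generator draws from a named substream of a single seed so that adding
or reordering generators does not perturb the others.  Trajectory generators
emulate the acquisition chain of a dual-trap instrument: state dynamics as an
exact continuous-time Markov chain, rendered through the dumbbell elastic
model at 20 kHz with white Gaussian noise, then mean-filtered to 10 kHz.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .hmm import Trajectory, mean_filter
from .landscape import StateEnsemble, rate_matrix
from .polymer import DumbbellConfig, ThermalContext, tether_extension
from .vesicle import SucroseProtocol, VesicleParams, simulate_release

__all__ = [
    "SimulationRecipe",
    "substream",
    "simulate_ctmc",
    "render_trajectory",
    "simulate_fec",
    "generate_sucrose_pair",
    "generate_train",
    "generate_minis",
    "generate_calcium_series",
]

#: Acquisition defaults of the emulated instrument.
ACQUISITION_RATE = 20_000.0  # Hz
FILTERED_RATE = 10_000.0  # Hz
NOISE_SD_NM = 1.2  # nm at the acquisition rate


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent, reproducible random stream named by purpose."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])


@dataclass(frozen=True)
class SimulationRecipe:
    """Serializable description of one synthetic scenario.

    ``truth`` holds the generating parameters (state energies, vesicle rates,
    train model, Hill parameters ... as plain JSON-able values); the same
    recipe and seed always produce bit-identical output because every
    generator draws from ``substream(seed, scenario)``.
    """

    seed: int
    scenario: str
    truth: Dict
    noise: Dict
    duration_s: float = 0.0
    sample_rate_hz: float = ACQUISITION_RATE

    def rng(self) -> np.random.Generator:
        return substream(self.seed, self.scenario)

    def to_json(self) -> str:
        import json

        return json.dumps(vars(self), indent=2, default=str)

    @classmethod
    def from_json(cls, text: str) -> "SimulationRecipe":
        import json

        return cls(**json.loads(text))


def simulate_ctmc(
    rate_matrix_Q: np.ndarray,
    initial_state: int,
    duration: float,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray]:
    """Exact (event-driven) simulation of a continuous-time Markov chain.

    ``rate_matrix_Q`` holds off-diagonal transition rates in 1/s (the
    diagonal is ignored).  Returns ``(states, entry_times)``; the last dwell
    is truncated at ``duration``.  An absorbing state simply holds to the end.
    """
    Q = np.asarray(rate_matrix_Q, dtype=float)
    K = Q.shape[0]
    off = Q.copy()
    np.fill_diagonal(off, 0.0)
    if np.any(off < 0):
        raise ValueError("off-diagonal rates must be >= 0")
    exit_rates = off.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        jump_probs = np.where(exit_rates[:, None] > 0, off / exit_rates[:, None], 0.0)

    states = [int(initial_state)]
    times = [0.0]
    t, s = 0.0, int(initial_state)
    while True:
        if exit_rates[s] == 0:
            break
        t += rng.exponential(1.0 / exit_rates[s])
        if t >= duration:
            break
        s = int(rng.choice(K, p=jump_probs[s]))
        states.append(s)
        times.append(t)
    return np.array(states, dtype=np.int32), np.array(times)


def render_trajectory(
    states: np.ndarray,
    entry_times: np.ndarray,
    ensemble: StateEnsemble,
    force: float,
    cfg: DumbbellConfig,
    th: ThermalContext,
    duration: float,
    noise_sd: float = NOISE_SD_NM,
    sample_rate: float = ACQUISITION_RATE,
    filter_to: Optional[float] = FILTERED_RATE,
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
) -> Trajectory:
    """Render a CTMC state path into a noisy extension-time trajectory.

    Extension per sample is the tether extension of the occupied state at the
    holding force plus white Gaussian noise, then (optionally) mean-filtered
    to ``filter_to``.  Metadata records the generating recipe.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    levels = np.array(
        [
            tether_extension(force, s.unfolded_contour, cfg, th, core_offset=s.core_offset)
            for s in ensemble.states
        ]
    )
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    idx = np.searchsorted(entry_times, t, side="right") - 1
    ext = levels[states[idx]]
    if noise_sd > 0:
        ext = ext + rng.normal(0.0, noise_sd, size=n)
    traj = Trajectory(
        time=t,
        extension=ext,
        sample_rate=sample_rate,
        force=np.full(n, float(force)),
        metadata={
            "force_pN": float(force),
            "noise_sd_nm": float(noise_sd),
            "state_levels_nm": levels.tolist(),
            "labels": ensemble.labels,
        },
    )
    if filter_to is not None and filter_to != sample_rate:
        traj = mean_filter(traj, filter_to)
    return traj


def simulate_fec(
    ensemble: StateEnsemble,
    cfg: DumbbellConfig,
    th: ThermalContext,
    force_range: Tuple[float, float],
    pull_speed: float = 10.0,  # nm/s of trap separation
    sample_rate: float = 1000.0,
    noise_sd: float = 0.5,
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
    initial_state: Optional[int] = None,
) -> Trajectory:
    """Quasi-static force-extension curve with stochastic state hopping.

    The trap separation ramps at ``pull_speed``; at each sample the occupied
    state may hop with probability k*dt, where k is the instantaneous Kramers
    rate.  A decreasing ramp (relaxation) is requested by passing
    ``force_range`` high-to-low.  Unfolding rips appear as extension jumps.
    """
    if pull_speed <= 0:
        raise ValueError("pull_speed must be > 0")
    rng = rng if rng is not None else np.random.default_rng(seed)
    f_lo, f_hi = force_range
    pulling = f_hi >= f_lo
    K = ensemble.n_states

    # precompute per-separation grids of force, extension and rates per state
    ref = ensemble.states[ensemble.reference_index]
    grid_F = np.linspace(min(f_lo, f_hi), max(f_lo, f_hi), 400)
    sep = {}
    ext = {}
    for k, s in enumerate(ensemble.states):
        x = np.array([tether_extension(F, s.unfolded_contour, cfg, th, core_offset=s.core_offset) for F in grid_F])
        sep[k] = x + grid_F * cfg.trap_stiffness_sum_inverse
        ext[k] = x
    rates_grid = np.zeros((len(grid_F), K, K))
    for gi, F in enumerate(grid_F):
        rates_grid[gi] = np.clip(rate_matrix(ensemble, F, cfg, th), 0.0, None)
        np.fill_diagonal(rates_grid[gi], 0.0)

    # separation ramp covering the requested force range in the current state
    state = (
        initial_state
        if initial_state is not None
        else (0 if pulling else ensemble.reference_index)
    )
    D_start = float(np.interp(f_lo, grid_F, sep[state]))
    D_end_hint = float(np.interp(f_hi, grid_F, sep[ensemble.reference_index if pulling else 0]))
    dt = 1.0 / sample_rate
    n = max(int(abs(D_end_hint - D_start) / pull_speed * sample_rate), 2)
    D = np.linspace(D_start, D_end_hint, n)

    out_ext = np.empty(n)
    out_force = np.empty(n)
    u = rng.random(n)
    for i in range(n):
        F_i = float(np.interp(D[i], sep[state], grid_F))
        out_force[i] = F_i
        out_ext[i] = float(np.interp(F_i, grid_F, ext[state]))
        k_row = rates_grid[int(np.searchsorted(grid_F, F_i).clip(0, len(grid_F) - 1))][state]
        total = k_row.sum()
        if total > 0 and u[i] < -np.expm1(-total * dt):
            state = int(rng.choice(K, p=k_row / total))
    if noise_sd > 0:
        out_ext += rng.normal(0.0, noise_sd, size=n)
    return Trajectory(
        time=np.arange(n) * dt,
        extension=out_ext,
        sample_rate=sample_rate,
        force=out_force,
        metadata={"pull_speed_nm_s": pull_speed, "pulling": pulling},
    )


def generate_sucrose_pair(
    params_control: VesicleParams,
    params_test: VesicleParams,
    protocol: SucroseProtocol,
    duration: float = 10.0,
    dt: float = 1.0e-3,
    snr: float = 20.0,
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
) -> Dict[str, np.ndarray]:
    """Paired noisy sucrose responses (e.g. control vs tomosyn-deficient).

    Gaussian current noise with standard deviation peak/snr is added to each
    trace.  Returns time, both traces, and the noiseless truths.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    t, clean_c = simulate_release(params_control, protocol, duration, dt)
    _, clean_t = simulate_release(params_test, protocol, duration, dt)
    sd_c = float(np.max(clean_c)) / snr
    sd_t = float(np.max(clean_t)) / snr
    return {
        "time": t,
        "control": clean_c + rng.normal(0.0, sd_c, len(t)),
        "test": clean_t + rng.normal(0.0, sd_t, len(t)),
        "control_clean": clean_c,
        "test_clean": clean_t,
        "noise_sd": np.array([sd_c, sd_t]),
    }


def generate_train(
    pool0: float,
    release_fraction: float,
    refill_rate: float,
    n_stim: int,
    freq: float,
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
    noise_cv: float = 0.0,
    refill_tau: Optional[float] = None,
    recovery_times: Sequence[float] = (),
    amp_per_charge: float = 10.0,  # nA per nC; fixed EPSC shape factor
):
    """Depletion-model EPSC train: A_i = p * pool_i, pool refilled between stimuli.

    Refill is linear at ``refill_rate`` (nC/s, capped at ``pool0``) unless
    ``refill_tau`` is given, in which case the pool relaxes exponentially
    toward ``pool0`` with that time constant.  Optional multiplicative
    log-normal noise with coefficient of variation ``noise_cv``.
    """
    from .ephys import TrainRecording

    if not (0 < release_fraction <= 1):
        raise ValueError("release fraction must be in (0, 1]")
    rng = rng if rng is not None else np.random.default_rng(seed)
    dt = 1.0 / freq

    def refill(pool: float, interval: float) -> float:
        if refill_tau is not None:
            return pool0 - (pool0 - pool) * np.exp(-interval / refill_tau)
        return min(pool + refill_rate * interval, pool0)

    pool = pool0
    charges = np.empty(n_stim)
    times = np.arange(n_stim) * dt
    for i in range(n_stim):
        q = release_fraction * pool
        if noise_cv > 0:
            q *= rng.lognormal(-0.5 * np.log(1 + noise_cv**2), np.sqrt(np.log(1 + noise_cv**2)))
        charges[i] = q
        pool = refill(pool - release_fraction * pool, dt)
    recovery = {}
    for rt in recovery_times:
        pr = refill(pool, rt - dt)  # pool state at the recovery pulse
        recovery[f"R@{rt:g}s"] = (times[-1] + rt, release_fraction * pr * amp_per_charge)
    return TrainRecording(
        stim_times=times,
        amplitudes=charges * amp_per_charge,
        charges=charges,
        frequency=freq,
        recovery=recovery,
    )


def generate_minis(
    rate_hz: float,
    duration: float,
    sample_rate: float = 10_000.0,
    amplitude_nA: float = 0.030,
    tau_rise: float = 5.0e-4,
    tau_decay: float = 3.0e-3,
    noise_sd: float = 0.004,
    amplitude_cv: float = 0.3,
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Poisson train of miniature EPSCs on Gaussian noise (inward = negative nA)."""
    rng = rng if rng is not None else np.random.default_rng(seed)
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    trace = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else np.zeros(n)
    n_events = rng.poisson(rate_hz * duration)
    event_times = np.sort(rng.uniform(0, duration, n_events))
    kernel_t = np.arange(0, 8 * tau_decay, 1 / sample_rate)
    kernel = np.exp(-kernel_t / tau_decay) - np.exp(-kernel_t / tau_rise)
    kernel /= kernel.max()
    for et in event_times:
        i0 = int(et * sample_rate)
        amp = amplitude_nA * rng.lognormal(
            -0.5 * np.log(1 + amplitude_cv**2), np.sqrt(np.log(1 + amplitude_cv**2))
        )
        seg = min(len(kernel), n - i0)
        if seg > 0:
            trace[i0 : i0 + seg] -= amp * kernel[:seg]
    return t, trace


def generate_calcium_series(
    kd: float,
    hill_n: float,
    concentrations: Sequence[float] = (0.5, 1.0, 2.0, 4.0, 8.0),
    noise_sd: float = 0.05,
    norm_conc: float = 2.0,
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Hill-law calcium-dependence table, normalized to the response at ``norm_conc``."""
    rng = rng if rng is not None else np.random.default_rng(seed)
    c = np.asarray(concentrations, dtype=float)
    resp_raw = c**hill_n / (kd**hill_n + c**hill_n)
    norm = norm_conc**hill_n / (kd**hill_n + norm_conc**hill_n)
    resp = resp_raw / norm
    noisy = resp + rng.normal(0.0, noise_sd, len(c))
    return pd.DataFrame({"calcium_mM": c, "response": noisy, "response_true": resp})
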
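"""Folding-state ensemble model and zero-force energy extrapolation.

A folding trajectory visits a small set of discrete states, each defined by
the contour length of its unfolded polypeptide (``l_n``), its folding free
energy at zero force relative to the fully unfolded reference (``G_n``, in
kBT), and a rigid core offset.  At a given force the total energy of the
dumbbell in state ``n`` (force ensemble) is

    V_n(F) = G_n + [E_handle(F) + E_peptide(F; l_n) - F * x_n(F)] / kBT

where ``x_n`` is the tether extension and E are WLC stretching energies.
State occupancies follow the Boltzmann distribution over V_n; transition
rates follow Kramers' equation k = A * exp(-(V_barrier - V_from)), with a
transition state parameterized like a folding state.  Fitting the predicted
extensions, occupancies and rates to their measured force dependence and
evaluating the fitted G_n at zero force yields folding energies free of the
instrument's mechanical bias.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Tuple, Union

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares
from scipy.special import logsumexp

from .polymer import (
    DumbbellConfig,
    ThermalContext,
    tether_extension,
    wlc_extension,
    wlc_stretch_energy,
)

__all__ = [
    "FoldingState",
    "StateEnsemble",
    "ForceDependentSeries",
    "LandscapeFit",
    "dumbbell_energy",
    "state_probabilities",
    "kramers_rate",
    "rate_matrix",
    "equilibrium_force",
    "predicted_extension_change",
    "fit_landscape",
    "initial_ensemble_from_series",
]

Control = Union[float, Tuple[str, float]]


@dataclass(frozen=True)
class FoldingState:
    """One folding state: unfolded contour l_n (nm), zero-force energy G_n (kBT)."""

    label: str
    unfolded_contour: float  # nm
    zero_force_energy: float  # kBT, relative to the fully unfolded reference
    core_offset: float = 2.0  # nm

    def __post_init__(self) -> None:
        if self.unfolded_contour < 0:
            raise ValueError(f"unfolded_contour must be >= 0, got {self.unfolded_contour}")


@dataclass
class StateEnsemble:
    """Sequential chain of folding states with transition-state barriers.

    ``states`` are ordered by unfolded contour length ascending (most folded
    first); allowed transitions are between adjacent states only.  ``barriers``
    maps an adjacent index pair ``(i, i+1)`` to a transition state; the shared
    ``rate_prefactor`` is the Kramers attempt frequency in 1/s.
    """

    states: List[FoldingState]
    barriers: Dict[Tuple[int, int], FoldingState] = field(default_factory=dict)
    rate_prefactor: float = 1.0e4  # s^-1

    def __post_init__(self) -> None:
        contours = [s.unfolded_contour for s in self.states]
        if any(b > a for a, b in zip(contours[1:], contours[:-1])):
            raise ValueError("states must be ordered by unfolded contour ascending")
        for (i, j), b in self.barriers.items():
            if j != i + 1:
                raise ValueError(f"barrier {(i, j)} is not between adjacent states (sequential chain)")
            lo = min(contours[i], contours[j])
            hi = max(contours[i], contours[j])
            if not (lo <= b.unfolded_contour <= hi):
                raise ValueError(
                    f"barrier contour {b.unfolded_contour} nm outside [{lo}, {hi}] of pair {(i, j)}"
                )

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def labels(self) -> List[str]:
        return [s.label for s in self.states]

    @property
    def reference_index(self) -> int:
        """Index of the fully unfolded reference (largest contour)."""
        return int(np.argmax([s.unfolded_contour for s in self.states]))

    def to_json(self) -> str:
        doc = {
            "states": [vars(s) for s in self.states],
            "barriers": {f"{i},{j}": vars(b) for (i, j), b in self.barriers.items()},
            "rate_prefactor": self.rate_prefactor,
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "StateEnsemble":
        doc = json.loads(text)
        states = [FoldingState(**s) for s in doc["states"]]
        barriers = {
            tuple(int(k) for k in key.split(",")): FoldingState(**b)
            for key, b in doc.get("barriers", {}).items()
        }
        return cls(states=states, barriers=barriers, rate_prefactor=doc.get("rate_prefactor", 1.0e4))


def _resolve_force(state: FoldingState, control: Control, cfg: DumbbellConfig, th: ThermalContext) -> float:
    """Force on the tether for the given control variable in the given state."""
    if isinstance(control, tuple):
        mode, value = control
    else:
        mode, value = "force", float(control)
    if mode == "force":
        return value
    if mode == "separation":
        D = value

        def g(F: float) -> float:
            return (
                tether_extension(F, state.unfolded_contour, cfg, th, core_offset=state.core_offset)
                + F * cfg.trap_stiffness_sum_inverse
                - D
            )

        hi = 1.0
        while g(hi) < 0:
            hi *= 2.0
            if hi > 1e4:
                raise ValueError(f"separation {D} nm unreachable")
        if g(0.0) > 0:
            raise ValueError(f"separation {D} nm below slack tether length")
        return brentq(g, 0.0, hi, xtol=1e-10, maxiter=200)
    raise ValueError(f"unknown control mode {mode!r}")


def dumbbell_energy(
    state: FoldingState,
    control: Control,
    cfg: DumbbellConfig,
    th: ThermalContext,
) -> float:
    """Total dumbbell energy of ``state`` (kBT) at fixed force or separation.

    Fixed-force mode uses the force-ensemble energy
    G_n + E_stretch(x(F)) - F*x(F); fixed-separation mode adds the trap
    potential instead of the -F*x term.
    """
    F = _resolve_force(state, control, cfg, th)
    kBT = th.kBT
    xh = wlc_extension(F, cfg.dna_handle, th)
    Eh = wlc_stretch_energy(xh, cfg.dna_handle, th)
    if state.unfolded_contour > 0:
        pep = cfg.peptide_wlc(state.unfolded_contour)
        xp = wlc_extension(F, pep, th)
        Ep = wlc_stretch_energy(xp, pep, th)
    else:
        xp, Ep = 0.0, 0.0
    x_tot = xh + xp + state.core_offset
    if isinstance(control, tuple) and control[0] == "separation":
        return state.zero_force_energy + (Eh + Ep + 0.5 * F * F * cfg.trap_stiffness_sum_inverse) / kBT
    return state.zero_force_energy + (Eh + Ep - F * x_tot) / kBT


def state_probabilities(
    ens: StateEnsemble,
    control: Control,
    cfg: DumbbellConfig,
    th: ThermalContext,
) -> np.ndarray:
    """Boltzmann occupancy of each state (simplex vector, order of ``ens.states``)."""
    if ens.n_states < 1:
        raise ValueError("ensemble must contain at least one state")
    energies = np.array([dumbbell_energy(s, control, cfg, th) for s in ens.states])
    log_p = -energies - logsumexp(-energies)
    return np.exp(log_p)


def kramers_rate(
    ens: StateEnsemble,
    from_state: int,
    to_state: int,
    control: Control,
    cfg: DumbbellConfig,
    th: ThermalContext,
) -> float:
    """Kramers transition rate (1/s) between adjacent states: A*exp(-(V‡ - V_from))."""
    pair = (min(from_state, to_state), max(from_state, to_state))
    if abs(from_state - to_state) != 1:
        raise ValueError(f"transition {from_state}->{to_state} not allowed in sequential chain")
    if pair not in ens.barriers:
        raise KeyError(f"no barrier defined for state pair {pair}")
    barrier = ens.barriers[pair]
    v_from = dumbbell_energy(ens.states[from_state], control, cfg, th)
    v_barrier = dumbbell_energy(barrier, control, cfg, th)
    return ens.rate_prefactor * float(np.exp(-(v_barrier - v_from)))


def rate_matrix(
    ens: StateEnsemble,
    control: Control,
    cfg: DumbbellConfig,
    th: ThermalContext,
) -> np.ndarray:
    """Generator matrix Q (1/s) over the sequential chain at the given control."""
    K = ens.n_states
    Q = np.zeros((K, K))
    for (i, j) in ens.barriers:
        Q[i, j] = kramers_rate(ens, i, j, control, cfg, th)
        Q[j, i] = kramers_rate(ens, j, i, control, cfg, th)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def equilibrium_force(delta_G: float, delta_x: float, th: ThermalContext) -> float:
    """Closed-form equilibrium-force estimate F = dG*kBT/dx (pN).

    ``delta_G`` in kBT, ``delta_x`` in nm.  Assumes the extension change is
    force independent; used as a consistency check, not a fit.
    """
    if delta_x <= 0:
        raise ValueError(f"delta_x must be > 0, got {delta_x}")
    return delta_G * th.kBT / delta_x


def predicted_extension_change(
    ens: StateEnsemble,
    state_m: int,
    state_n: int,
    F: float,
    cfg: DumbbellConfig,
    th: ThermalContext,
) -> float:
    """Extension difference x_m - x_n (nm) between two states at force F."""
    sm, sn = ens.states[state_m], ens.states[state_n]
    xm = tether_extension(F, sm.unfolded_contour, cfg, th, core_offset=sm.core_offset)
    xn = tether_extension(F, sn.unfolded_contour, cfg, th, core_offset=sn.core_offset)
    return xm - xn


# ---------------------------------------------------------------------------
# Force-dependent series and the nonlinear least-squares extrapolation
# ---------------------------------------------------------------------------


@dataclass
class ForceDependentSeries:
    """Measured per-force state summaries: occupancies, extensions, rates, lifetimes.

    ``table`` columns: ``force_pN``; ``prob_<label>``, ``ext_<label>`` and
    optionally ``lifetime_<label>`` per state; ``rate_<i>__<j>`` per ordered
    adjacent state-index pair.
    """

    labels: List[str]
    table: pd.DataFrame

    def __post_init__(self) -> None:
        if "force_pN" not in self.table.columns:
            raise ValueError("series table needs a force_pN column")
        if (self.table["force_pN"] <= 0).any():
            raise ValueError("forces must be strictly positive")
        probs = self.prob_matrix()
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("state probabilities must sum to 1 per row")

    def prob_matrix(self) -> np.ndarray:
        return self.table[[f"prob_{lb}" for lb in self.labels]].to_numpy()

    def ext_matrix(self) -> np.ndarray:
        return self.table[[f"ext_{lb}" for lb in self.labels]].to_numpy()

    def rate_columns(self) -> List[Tuple[int, int]]:
        pairs = []
        for col in self.table.columns:
            if col.startswith("rate_"):
                i, j = col[len("rate_"):].split("__")
                pairs.append((int(i), int(j)))
        return sorted(pairs)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# states: {','.join(self.labels)}\n")
            self.table.to_csv(fh, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def from_tsv(cls, path) -> "ForceDependentSeries":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("# states:"):
                raise ValueError(f"{path}: missing '# states:' header line")
            labels = header.split(":", 1)[1].strip().split(",")
            table = pd.read_csv(fh, sep="\t")
        return cls(labels=labels, table=table)


@dataclass
class LandscapeFit:
    """Result of the zero-force extrapolation fit."""

    ensemble: StateEnsemble
    unfolding_energies: Dict[str, float]  # label -> G_ref - G_n (kBT), per state
    standard_errors: Dict[str, float]
    residual_norm: float
    converged: bool
    bootstrap_n: int
    condition_number: float
    message: str = ""

    def to_json(self) -> str:
        return json.dumps(
            {
                "ensemble": json.loads(self.ensemble.to_json()),
                "unfolding_energies": self.unfolding_energies,
                "standard_errors": self.standard_errors,
                "residual_norm": self.residual_norm,
                "converged": self.converged,
                "bootstrap_n": self.bootstrap_n,
                "condition_number": self.condition_number,
                "message": self.message,
            },
            indent=2,
        )


def _handle_terms(forces: np.ndarray, cfg: DumbbellConfig, th: ThermalContext):
    """Precompute per-force DNA-handle extension and stretching energy."""
    xh = np.array([wlc_extension(F, cfg.dna_handle, th) for F in forces])
    Eh = np.array([wlc_stretch_energy(x, cfg.dna_handle, th) for x in xh])
    return xh, Eh


def _peptide_terms(F: float, contour: float, cfg: DumbbellConfig, th: ThermalContext):
    if contour <= 0:
        return 0.0, 0.0
    pep = cfg.peptide_wlc(contour)
    xp = wlc_extension(F, pep, th)
    return xp, wlc_stretch_energy(xp, pep, th)


def _model_series(
    params: np.ndarray,
    forces: np.ndarray,
    n_states: int,
    ref: int,
    core_offsets: np.ndarray,
    xh: np.ndarray,
    Eh: np.ndarray,
    cfg: DumbbellConfig,
    th: ThermalContext,
):
    """Predicted occupancies and extensions from a packed parameter vector."""
    G = np.zeros(n_states)
    G[[i for i in range(n_states) if i != ref]] = params[: n_states - 1]
    L = params[n_states - 1 : 2 * n_states - 1]
    kBT = th.kBT
    P = np.zeros((len(forces), n_states))
    X = np.zeros((len(forces), n_states))
    for r, F in enumerate(forces):
        V = np.zeros(n_states)
        for n in range(n_states):
            xp, Ep = _peptide_terms(F, L[n], cfg, th)
            x_tot = xh[r] + xp + core_offsets[n]
            V[n] = G[n] + (Eh[r] + Ep - F * x_tot) / kBT
            X[r, n] = x_tot
        lp = -V - logsumexp(-V)
        P[r] = np.exp(lp)
    return P, X, G, L


def _model_rates(
    G: np.ndarray,
    L: np.ndarray,
    barrier_G: np.ndarray,
    log_A: float,
    barrier_pairs: List[Tuple[int, int]],
    barrier_contours: np.ndarray,
    forces: np.ndarray,
    core_offsets: np.ndarray,
    xh: np.ndarray,
    Eh: np.ndarray,
    cfg: DumbbellConfig,
    th: ThermalContext,
) -> Dict[Tuple[int, int], np.ndarray]:
    """Kramers rates per ordered adjacent pair at each force row."""
    kBT = th.kBT

    def total_energy(r: int, F: float, contour: float, G_state: float, c: float) -> float:
        xp, Ep = _peptide_terms(F, contour, cfg, th)
        return G_state + (Eh[r] + Ep - F * (xh[r] + xp + c)) / kBT

    out: Dict[Tuple[int, int], np.ndarray] = {}
    for b, (i, j) in enumerate(barrier_pairs):
        k_fwd = np.empty(len(forces))
        k_rev = np.empty(len(forces))
        for r, F in enumerate(forces):
            v_b = total_energy(r, F, barrier_contours[b], barrier_G[b], core_offsets[i])
            v_i = total_energy(r, F, L[i], G[i], core_offsets[i])
            v_j = total_energy(r, F, L[j], G[j], core_offsets[j])
            k_fwd[r] = np.exp(log_A - (v_b - v_i))
            k_rev[r] = np.exp(log_A - (v_b - v_j))
        out[(i, j)] = k_fwd
        out[(j, i)] = k_rev
    return out


def fit_landscape(
    series: ForceDependentSeries,
    ens0: StateEnsemble,
    cfg: DumbbellConfig,
    th: ThermalContext,
    seed: int = 0,
    bootstrap_n: int = 0,
    sigma_ext: float = 0.2,
    sigma_logit: float = 0.3,
    sigma_lograte: float = 0.3,
    include_rates: str = "auto",
) -> LandscapeFit:
    """Fit zero-force energies and contours to a force-dependent series.

    Weighted nonlinear least squares over state extensions (nm, weight
    1/``sigma_ext``), occupancies on the logit scale (weight
    1/``sigma_logit``) and, when ``include_rates`` is true-ish, measured
    transition rates on the log scale (weight 1/``sigma_lograte``).  Free
    parameters are G_n for non-reference states and l_n for all states; with
    rates also the barrier energies and a shared log attempt frequency
    (barrier contours stay at their ``ens0`` positions).  ``include_rates=
    "auto"`` turns the rate terms on when the series carries rate columns and
    ``ens0`` defines barriers; rates constrain barriers, not state energies,
    so the occupancy/extension route alone already determines every G_n.
    Core offsets are taken from ``ens0``.  Non-convergence is flagged in the
    result, never raised.  Bootstrap (row resampling with replacement,
    seeded) supplies standard errors for the unfolding energies.
    """
    if ens0.labels != series.labels:
        raise ValueError("initial ensemble state labels must match series labels in order")
    tab = series.table
    forces = tab["force_pN"].to_numpy()
    if len(np.unique(forces)) < 3:
        raise ValueError("series must cover at least 3 distinct forces")
    n_states = len(series.labels)
    ref = ens0.reference_index
    core_offsets = np.array([s.core_offset for s in ens0.states])
    p_obs = series.prob_matrix()
    x_obs = series.ext_matrix()
    xh, Eh = _handle_terms(forces, cfg, th)

    rate_pairs = [(i, j) for (i, j) in series.rate_columns() if (min(i, j), max(i, j)) in ens0.barriers]
    if include_rates == "auto":
        use_rates = bool(rate_pairs)
    else:
        use_rates = bool(include_rates) and bool(rate_pairs)
    barrier_pairs = sorted(ens0.barriers) if use_rates else []
    barrier_contours = np.array([ens0.barriers[p].unfolded_contour for p in barrier_pairs])
    n_barriers = len(barrier_pairs)
    if use_rates:
        lograte_obs = {}
        for (i, j) in rate_pairs:
            k = tab[f"rate_{i}__{j}"].to_numpy()
            lograte_obs[(i, j)] = np.log(np.clip(k, 1e-12, None))

    eps = 1e-6
    logit_obs = np.log(np.clip(p_obs, eps, 1 - eps) / np.clip(1 - p_obs, eps, 1 - eps))

    def residuals(params: np.ndarray, rows: np.ndarray) -> np.ndarray:
        core = params[: 2 * n_states - 1]
        P, X, G, L = _model_series(
            core, forces[rows], n_states, ref, core_offsets, xh[rows], Eh[rows], cfg, th
        )
        logit_mod = np.log(np.clip(P, eps, 1 - eps) / np.clip(1 - P, eps, 1 - eps))
        r_ext = ((X - x_obs[rows]) / sigma_ext).ravel()
        r_prob = ((logit_mod - logit_obs[rows]) / sigma_logit).ravel()
        parts = [r_ext, r_prob]
        if use_rates:
            barrier_G = params[2 * n_states - 1 : 2 * n_states - 1 + n_barriers]
            log_A = params[-1]
            k_mod = _model_rates(
                G, L, barrier_G, log_A, barrier_pairs, barrier_contours,
                forces[rows], core_offsets, xh[rows], Eh[rows], cfg, th,
            )
            for (i, j) in rate_pairs:
                r_rate = (np.log(np.clip(k_mod[(i, j)], 1e-12, None)) - lograte_obs[(i, j)][rows]) / sigma_lograte
                parts.append(r_rate)
        return np.concatenate(parts)

    p0 = np.concatenate(
        [
            [ens0.states[i].zero_force_energy for i in range(n_states) if i != ref],
            [s.unfolded_contour for s in ens0.states],
            [ens0.barriers[p].zero_force_energy for p in barrier_pairs],
            [np.log(ens0.rate_prefactor)] if use_rates else [],
        ]
    )
    lower = np.concatenate(
        [
            np.full(n_states - 1, -200.0),
            np.full(n_states, 1e-3),
            np.full(n_barriers, -200.0),
            [-5.0] if use_rates else [],
        ]
    )
    upper = np.concatenate(
        [
            np.full(n_states - 1, 200.0),
            np.full(n_states, 500.0),
            np.full(n_barriers, 300.0),
            [40.0] if use_rates else [],
        ]
    )
    all_rows = np.arange(len(forces))

    def run(rows: np.ndarray, start: np.ndarray):
        return least_squares(
            residuals, start, args=(rows,), bounds=(lower, upper), xtol=1e-10, ftol=1e-10, gtol=1e-10
        )

    sol = run(all_rows, p0)
    _, _, G_fit, L_fit = _model_series(
        sol.x[: 2 * n_states - 1], forces, n_states, ref, core_offsets, xh, Eh, cfg, th
    )
    fitted_states = [
        replace(ens0.states[n], unfolded_contour=float(L_fit[n]), zero_force_energy=float(G_fit[n]))
        for n in range(n_states)
    ]
    fitted_barriers = dict(ens0.barriers)
    prefactor = ens0.rate_prefactor
    if use_rates:
        barrier_G_fit = sol.x[2 * n_states - 1 : 2 * n_states - 1 + n_barriers]
        prefactor = float(np.exp(sol.x[-1]))
        fitted_barriers = {
            p: replace(ens0.barriers[p], zero_force_energy=float(barrier_G_fit[b]))
            for b, p in enumerate(barrier_pairs)
        }
    fitted = StateEnsemble(
        states=fitted_states, barriers=fitted_barriers, rate_prefactor=prefactor
    )
    unfolding = {
        s.label: float(G_fit[ref] - G_fit[n]) for n, s in enumerate(fitted_states) if n != ref
    }

    J = sol.jac
    sv = np.linalg.svd(J, compute_uv=False)
    cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf
    if cond > 1e8:
        warnings.warn(f"ill-conditioned landscape fit (condition number {cond:.3g})", stacklevel=2)

    ses: Dict[str, float] = {}
    if bootstrap_n > 0:
        rng = np.random.default_rng(seed)
        reps = {lb: [] for lb in unfolding}
        for _ in range(bootstrap_n):
            for _attempt in range(50):
                rows = rng.integers(0, len(forces), size=len(forces))
                if len(np.unique(forces[rows])) >= 3:
                    break
            try:
                bsol = run(rows, sol.x)
            except Exception:
                continue
            Gb = np.zeros(n_states)
            Gb[[i for i in range(n_states) if i != ref]] = bsol.x[: n_states - 1]
            for n, s in enumerate(fitted_states):
                if n != ref:
                    reps[s.label].append(Gb[ref] - Gb[n])
        ses = {lb: float(np.std(v, ddof=1)) if len(v) > 1 else np.nan for lb, v in reps.items()}

    return LandscapeFit(
        ensemble=fitted,
        unfolding_energies=unfolding,
        standard_errors=ses,
        residual_norm=float(np.sqrt(2 * sol.cost)),
        converged=bool(sol.success),
        bootstrap_n=bootstrap_n,
        condition_number=cond,
        message=sol.message,
    )


def initial_ensemble_from_series(
    series: ForceDependentSeries,
    cfg: DumbbellConfig,
    th: ThermalContext,
    core_offset: float = 2.0,
) -> StateEnsemble:
    """Data-driven starting ensemble: contours from extensions, energies from occupancies.

    Contours are inverted from the per-state extensions at the median-force
    row; zero-force energies follow from the observed occupancy ratios minus
    the model stretch terms at that force.  No barriers are attached.
    """
    tab = series.table
    mid = int(np.argsort(tab["force_pN"].to_numpy())[len(tab) // 2])
    F = float(tab["force_pN"].iloc[mid])
    kBT = th.kBT
    xh = wlc_extension(F, cfg.dna_handle, th)
    Eh = wlc_stretch_energy(xh, cfg.dna_handle, th)

    contours = []
    for lb in series.labels:
        x_target = float(tab[f"ext_{lb}"].iloc[mid]) - xh - core_offset
        if x_target <= 0:
            contours.append(1e-3)
            continue

        def g(Lc: float) -> float:
            return wlc_extension(F, cfg.peptide_wlc(Lc), th) - x_target

        hi = max(2 * x_target, 1.0)
        while g(hi) < 0:
            hi *= 2.0
        contours.append(brentq(g, 1e-6, hi, xtol=1e-9))

    ref = int(np.argmax(contours))
    p_row = np.clip(
        tab[[f"prob_{lb}" for lb in series.labels]].iloc[mid].to_numpy(), 1e-6, 1.0
    )
    stretch = np.zeros(len(contours))
    for n, Lc in enumerate(contours):
        xp, Ep = _peptide_terms(F, Lc, cfg, th)
        stretch[n] = (Eh + Ep - F * (xh + xp + core_offset)) / kBT
    # V_n - V_ref = ln(p_ref / p_n); G_n = V_n - stretch_n with G_ref = 0
    dV = np.log(p_row[ref] / p_row)
    G = dV - (stretch - stretch[ref])
    G -= G[ref]

    states = [
        FoldingState(
            label=series.labels[n],
            unfolded_contour=float(contours[n]),
            zero_force_energy=float(G[n]),
            core_offset=core_offset,
        )
        for n in range(len(contours))
    ]
    return StateEnsemble(states=states)
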
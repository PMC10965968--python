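"""Minimal vesicle-state model for hypertonic-sucrose release traces.

A single primed pool R (carried in charge units, nC) obeys

    dR/dt = k_prime - k_deprime * R - k2(t) * R

with constant priming flux ``k_prime`` (nC/s), de-priming rate ``k_deprime``
(1/s) and a fusion rate ``k2(t)`` that rises during sucrose application:

    k2(t) = k2_rest * exp(beta * c(t))

where c(t) saturates as 1 - exp(-(t - onset)/drive_tau) while sucrose is
applied and decays exponentially with the same time constant afterwards.
``beta`` (dimensionless, RT units) is the reduction of the fusion energy
barrier at full drive, so the maximal fusion rate is k2_max = k2_rest*e^beta.
The recorded inward current is the release charge rate k2(t)*R(t) (nA).

Fitting a measured trace yields the readily releasable pool (RRP) corrected
for ongoing priming, the priming/de-priming rates and k2_max; barrier shifts
between conditions follow from the Arrhenius relation
dEa = -ln(k2_max / k2_reference) in RT units.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Tuple

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

__all__ = [
    "VesicleParams",
    "SucroseProtocol",
    "SucroseFit",
    "simulate_release",
    "fit_sucrose",
    "resting_fusion_rate",
    "arrhenius_delta",
]


@dataclass(frozen=True)
class VesicleParams:
    """Kinetic parameters of the single-pool vesicle-state model."""

    k_prime: float = 0.02  # nC/s, priming flux
    k_deprime: float = 0.04  # 1/s
    k2_rest: float = 6.0e-4  # 1/s, spontaneous fusion rate
    beta: float = 8.0  # RT, barrier reduction at full sucrose drive
    drive_tau: float = 0.4  # s, sucrose arrival/washout time constant

    def __post_init__(self) -> None:
        if min(self.k_prime, self.k_deprime, self.k2_rest, self.drive_tau) < 0:
            raise ValueError("all rates and time constants must be >= 0")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.k_deprime + self.k2_rest <= 0:
            raise ValueError("resting pool undefined: k_deprime + k2_rest must be > 0")

    @property
    def rrp_rest(self) -> float:
        """Resting steady-state pool charge (nC)."""
        return self.k_prime / (self.k_deprime + self.k2_rest)

    @property
    def k2_max(self) -> float:
        return self.k2_rest * math.exp(self.beta)


@dataclass(frozen=True)
class SucroseProtocol:
    """Timing and label of one sucrose application."""

    onset: float = 1.0  # s
    duration: float = 7.0  # s
    concentration_mM: int = 500

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.onset < 0:
            raise ValueError("onset must be >= 0")


def _drive(t: np.ndarray, protocol: SucroseProtocol, tau: float) -> np.ndarray:
    """Normalized sucrose drive c(t) in [0, 1)."""
    t = np.asarray(t, dtype=float)
    c = np.zeros_like(t)
    on, off = protocol.onset, protocol.onset + protocol.duration
    rising = (t >= on) & (t < off)
    c[rising] = 1.0 - np.exp(-(t[rising] - on) / tau)
    c_end = 1.0 - math.exp(-protocol.duration / tau)
    after = t >= off
    c[after] = c_end * np.exp(-(t[after] - off) / tau)
    return c


def simulate_release(
    params: VesicleParams,
    protocol: SucroseProtocol,
    duration: float = 10.0,
    dt: float = 1.0e-3,
    r0: Optional[float] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Simulate the sucrose-evoked release current.

    Returns ``(time_s, current_nA)`` on a uniform grid; current is the charge
    release rate k2(t)*R(t).  The pool starts at its resting steady state
    (or ``r0`` nC if given) and the integration uses an adaptive stiff solver
    (LSODA, atol 1e-9 nC).
    """
    if dt > 1.0e-3 + 1e-12:
        raise ValueError("dt must be <= 1 ms")
    if duration < protocol.onset + protocol.duration:
        raise ValueError("duration must cover the sucrose application")
    t = np.arange(0.0, duration + dt / 2, dt)

    def k2_of(tt: float) -> float:
        return params.k2_rest * math.exp(params.beta * float(_drive(np.array([tt]), protocol, params.drive_tau)[0]))

    def rhs(tt: float, y):
        return [params.k_prime - (params.k_deprime + k2_of(tt)) * y[0]]

    sol = solve_ivp(
        rhs,
        (t[0], t[-1]),
        [params.rrp_rest if r0 is None else r0],
        t_eval=t,
        method="LSODA",
        rtol=1e-8,
        atol=1e-9,
        max_step=params.drive_tau / 4 if params.drive_tau > 0 else np.inf,
    )
    if not sol.success:
        raise RuntimeError(f"release ODE failed: {sol.message}; params={params}")
    R = sol.y[0]
    k2 = params.k2_rest * np.exp(params.beta * _drive(t, protocol, params.drive_tau))
    return t, k2 * R


@dataclass
class SucroseFit:
    """Fitted vesicle-state model for one sucrose trace."""

    params: VesicleParams
    rrp_charge: float  # nC, resting pool of the fitted model
    k2_max: float  # 1/s
    residual_norm: float
    converged: bool
    delta_Ea: Optional[float] = None  # RT, filled against a reference rate
    message: str = ""

    def with_reference(self, k2_reference: float) -> "SucroseFit":
        out = SucroseFit(**{**vars(self)})
        out.delta_Ea = arrhenius_delta(self.k2_max, k2_reference)
        return out

    def to_json(self) -> str:
        doc = {k: (vars(v) if isinstance(v, VesicleParams) else v) for k, v in vars(self).items()}
        return json.dumps(doc, indent=2)


_FREE_DEFAULT = ("k_prime", "beta", "drive_tau")


def initial_sucrose_params(
    time: np.ndarray,
    current: np.ndarray,
    protocol: SucroseProtocol,
    template: Optional[VesicleParams] = None,
) -> VesicleParams:
    """Heuristic starting point: pool from early released charge, beta from peak rate."""
    template = template or VesicleParams()
    dt = float(np.median(np.diff(time)))
    early = (time >= protocol.onset) & (time <= protocol.onset + 4.0)
    q4 = max(float(np.sum(current[early]) * dt), 1e-4)
    k_prime0 = q4 * (template.k_deprime + template.k2_rest)
    peak = max(float(np.max(current)), 1e-6)
    beta0 = max(math.log(peak / (template.k2_rest * q4)), 0.5)
    return replace(template, k_prime=k_prime0, beta=beta0)


def fit_sucrose(
    time: np.ndarray,
    current: np.ndarray,
    protocol: SucroseProtocol,
    init: Optional[VesicleParams] = None,
    fixed: Iterable[str] = ("k_deprime", "k2_rest"),
) -> SucroseFit:
    """Least-squares fit of the vesicle-state model to a sucrose trace.

    ``fixed`` names parameters held at their ``init`` values (by default the
    de-priming and spontaneous fusion rates, which a single trace does not
    constrain).  Positive parameters are fitted in log space.  On
    non-convergence the best point is returned with ``converged=False``.
    """
    time = np.asarray(time, dtype=float)
    current = np.asarray(current, dtype=float)
    if time[-1] < protocol.onset + protocol.duration:
        raise ValueError("trace must cover the sucrose application")
    init = init or initial_sucrose_params(time, current, protocol)
    fixed = set(fixed)
    free = [name for name in ("k_prime", "k_deprime", "k2_rest", "beta", "drive_tau") if name not in fixed]
    if not free:
        raise ValueError("at least one parameter must be free")
    dt = float(np.median(np.diff(time)))

    def unpack(theta: np.ndarray) -> VesicleParams:
        values = dict(vars(init))
        for name, v in zip(free, theta):
            values[name] = math.exp(v)
        return VesicleParams(**values)

    def residuals(theta: np.ndarray) -> np.ndarray:
        p = unpack(theta)
        try:
            _, model = simulate_release(p, protocol, duration=float(time[-1]), dt=dt)
        except RuntimeError:
            return np.full(len(current), 1e3)
        return model[: len(current)] - current

    theta0 = np.array([math.log(max(getattr(init, name), 1e-8)) for name in free])
    sol = least_squares(residuals, theta0, xtol=1e-10, ftol=1e-10, max_nfev=400)
    p_fit = unpack(sol.x)
    return SucroseFit(
        params=p_fit,
        rrp_charge=p_fit.rrp_rest,
        k2_max=p_fit.k2_max,
        residual_norm=float(np.sqrt(2 * sol.cost)),
        converged=bool(sol.success),
        message=sol.message,
    )


def resting_fusion_rate(mini_freq: float, mini_charge: float, rrp_charge: float) -> float:
    """Spontaneous fusion rate k2 at rest: (mini frequency x mini charge) / RRP charge."""
    if mini_freq <= 0 or mini_charge <= 0:
        raise ValueError("mini frequency and charge must be > 0")
    if rrp_charge <= 0:
        raise ValueError(f"rrp_charge must be > 0, got {rrp_charge}")
    return mini_freq * mini_charge / rrp_charge


def arrhenius_delta(k2: float, k2_ref: float) -> float:
    """Fusion-barrier change dEa = -ln(k2/k2_ref) in RT units."""
    if k2 <= 0 or k2_ref <= 0:
        raise ValueError("rates must be > 0")
    return -math.log(k2 / k2_ref)
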
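"""Worm-like-chain mechanics and the tethered-dumbbell forward model.

The experimental construct is a dumbbell: bead -- DNA handle -- (unfolded
polypeptide + folded protein core) -- bead, held in two optical traps.  Every
downstream quantity (state extensions, Boltzmann occupancies, Kramers rates)
is computed from the elastic response of this series arrangement.

Forces are in pN, lengths in nm, energies in pN·nm unless a docstring says
kBT.  The entropic elasticity of both the DNA handle and the unfolded
polypeptide is described by the Marko–Siggia interpolation formula

    F(x) = (kBT / P) * [ 1/4 (1 - x/L)^-2 - 1/4 + x/L ]

with persistence length ``P`` and contour length ``L``.  For the DNA handle an
extensible correction is applied by substituting x/L -> x/L - F/S, with
stretch modulus ``S``; unfolded polypeptide is treated as inextensible, the
standard choice for kbp-scale handles and short peptides.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import brentq

#: Boltzmann constant in pN·nm/K.
KB = 0.0138065

__all__ = [
    "KB",
    "WLCParams",
    "ThermalContext",
    "DumbbellConfig",
    "wlc_force",
    "wlc_extension",
    "wlc_stretch_energy",
    "peptide_contour",
    "tether_extension",
    "contour_for_step",
]


@dataclass(frozen=True)
class WLCParams:
    """Elastic parameters of one worm-like chain.

    ``stretch_modulus`` (pN) is optional; when absent the chain is treated as
    inextensible.
    """

    persistence_length: float  # nm
    contour_length: float  # nm
    stretch_modulus: Optional[float] = None  # pN

    def __post_init__(self) -> None:
        if not self.persistence_length > 0:
            raise ValueError(f"persistence_length must be > 0, got {self.persistence_length}")
        if not self.contour_length > 0:
            raise ValueError(f"contour_length must be > 0, got {self.contour_length}")
        if self.stretch_modulus is not None and not self.stretch_modulus > 0:
            raise ValueError(f"stretch_modulus must be > 0, got {self.stretch_modulus}")

    def replace_contour(self, contour_length: float) -> "WLCParams":
        return WLCParams(self.persistence_length, contour_length, self.stretch_modulus)


@dataclass(frozen=True)
class ThermalContext:
    """Temperature and the derived thermal energy kBT (pN·nm)."""

    temperature: float = 296.0  # K; room temperature, 23 °C

    def __post_init__(self) -> None:
        if not (273.0 <= self.temperature <= 320.0):
            raise ValueError(f"temperature {self.temperature} K outside [273, 320]")

    @property
    def kBT(self) -> float:
        return KB * self.temperature


@dataclass(frozen=True)
class DumbbellConfig:
    """Geometry and elasticity of the whole tethered dumbbell.

    ``residue_contour`` is the contour length released per unfolded amino
    acid; ``trap_stiffness_sum_inverse`` is 1/k1 + 1/k2 of the two traps and
    only enters the constant-trap-separation ensemble; ``core_offset`` is the
    small rigid extension contributed by a folded core along the pulling axis.
    """

    dna_handle: WLCParams = field(
        default_factory=lambda: WLCParams(persistence_length=50.0, contour_length=770.0, stretch_modulus=1000.0)
    )
    peptide_persistence: float = 0.6  # nm
    residue_contour: float = 0.365  # nm per amino acid
    trap_stiffness_sum_inverse: float = 10.0  # nm/pN (two ~0.2 pN/nm traps)
    core_offset: float = 2.0  # nm

    def __post_init__(self) -> None:
        if not (0.3 < self.residue_contour < 0.42):
            raise ValueError(f"residue_contour {self.residue_contour} outside (0.3, 0.42) nm/aa")
        if self.trap_stiffness_sum_inverse < 0:
            raise ValueError("trap_stiffness_sum_inverse must be >= 0")

    def peptide_wlc(self, contour_length: float) -> WLCParams:
        """WLC parameters of an unfolded polypeptide of given contour length."""
        return WLCParams(self.peptide_persistence, contour_length)


def _ms_force_inextensible(x: float, p: WLCParams, kBT: float) -> float:
    u = x / p.contour_length
    return (kBT / p.persistence_length) * (0.25 / (1.0 - u) ** 2 - 0.25 + u)


def wlc_force(x: float, p: WLCParams, th: ThermalContext) -> float:
    """Tension (pN) of a worm-like chain at end-to-end extension ``x`` (nm).

    Marko–Siggia interpolation; for an extensible chain the implicit equation
    F = (kBT/P) f(x/L - F/S) is solved by bracketed root finding.
    """
    if x < 0:
        raise ValueError(f"extension must be >= 0, got {x}")
    if x == 0:
        return 0.0
    if p.stretch_modulus is None:
        if x >= p.contour_length:
            raise ValueError(
                f"extension {x} nm >= contour length {p.contour_length} nm of inextensible chain"
            )
        return _ms_force_inextensible(x, p, th.kBT)

    S = p.stretch_modulus

    def g(F: float) -> float:
        u = x / p.contour_length - F / S
        if u >= 1.0:
            return np.inf
        return (th.kBT / p.persistence_length) * (0.25 / (1.0 - u) ** 2 - 0.25 + u) - F

    # F = 0 gives g >= 0 iff x/L >= ... bracket upward until sign change
    lo, hi = 0.0, max(1.0, th.kBT / p.persistence_length)
    it = 0
    while g(hi) > 0:
        hi *= 2.0
        it += 1
        if it > 60:
            raise ValueError(f"no force bracket found for extension {x} nm")
    if g(lo) <= 0:
        return 0.0
    return brentq(g, lo, hi, xtol=1e-12, rtol=1e-14, maxiter=200)


def wlc_extension(F: float, p: WLCParams, th: ThermalContext) -> float:
    """Extension (nm) of a worm-like chain at tension ``F`` (pN).

    Numeric inverse of :func:`wlc_force` by bracketed bisection (Brent), with
    1e-9 nm tolerance.  The extensible case reduces to the inextensible
    entropic extension plus the enthalpic term F·L/S.
    """
    if F < 0:
        raise ValueError(f"force must be >= 0, got {F}")
    if F == 0:
        return 0.0
    L = p.contour_length

    def g(x: float) -> float:
        return _ms_force_inextensible(x, p, th.kBT) - F

    x_ent = brentq(g, 0.0, L * (1.0 - 1e-12), xtol=1e-9, maxiter=200)
    if p.stretch_modulus is None:
        return x_ent
    return x_ent + F * L / p.stretch_modulus


def wlc_stretch_energy(x: float, p: WLCParams, th: ThermalContext) -> float:
    """Stretching free energy (pN·nm) stored in the chain at extension ``x``.

    Inextensible chains use the closed-form integral of the Marko–Siggia
    force; extensible chains integrate the root-solved force with fixed-order
    Gauss–Legendre quadrature (exact to ~1e-10 relative for smooth F).
    """
    if x < 0:
        raise ValueError(f"extension must be >= 0, got {x}")
    if x == 0:
        return 0.0
    if p.stretch_modulus is None:
        if x >= p.contour_length:
            raise ValueError(
                f"extension {x} nm >= contour length {p.contour_length} nm of inextensible chain"
            )
        u = x / p.contour_length
        # integral of (kBT/P)[1/4 (1-u)^-2 - 1/4 + u] dx, x = L u
        return (th.kBT * p.contour_length / p.persistence_length) * (
            0.25 / (1.0 - u) - 0.25 - 0.25 * u + 0.5 * u * u
        )
    nodes, weights = np.polynomial.legendre.leggauss(48)
    t = 0.5 * x * (nodes + 1.0)
    vals = np.array([wlc_force(ti, p, th) for ti in t])
    return float(0.5 * x * np.dot(weights, vals))


def peptide_contour(n_residues: float, cfg: DumbbellConfig) -> float:
    """Contour length (nm) of ``n_residues`` unfolded amino acids."""
    if n_residues < 0:
        raise ValueError(f"residue count must be >= 0, got {n_residues}")
    return n_residues * cfg.residue_contour


def tether_extension(
    F: float,
    unfolded_contour: float,
    cfg: DumbbellConfig,
    th: ThermalContext,
    core_offset: Optional[float] = None,
) -> float:
    """Extension (nm) of the whole tether at force ``F``.

    Sum of the DNA-handle WLC extension, the unfolded-polypeptide WLC
    extension at contour length ``unfolded_contour``, and the rigid core
    offset.  Trap displacement is not part of the tether.
    """
    if F < 0:
        raise ValueError(f"force must be >= 0, got {F}")
    c = cfg.core_offset if core_offset is None else core_offset
    x = wlc_extension(F, cfg.dna_handle, th) + c
    if unfolded_contour > 0:
        x += wlc_extension(F, cfg.peptide_wlc(unfolded_contour), th)
    return x


def contour_for_step(
    step_nm: float,
    force_pN: float,
    cfg: DumbbellConfig,
    th: ThermalContext,
) -> float:
    """Unfolded-contour difference (nm) that produces a given extension step.

    Solves for dL such that a polypeptide of contour dL extends by
    ``step_nm`` at ``force_pN``; used to translate measured extension changes
    between folding states into released contour length.
    """
    if step_nm <= 0 or force_pN <= 0:
        raise ValueError("step and force must be > 0")

    def g(dL: float) -> float:
        return wlc_extension(force_pN, cfg.peptide_wlc(dL), th) - step_nm

    hi = step_nm * 2.0
    while g(hi) < 0:
        hi *= 2.0
        if hi > 1e5:
            raise ValueError("no contour solution found")
    return brentq(g, 1e-9, hi, xtol=1e-9, maxiter=200)
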
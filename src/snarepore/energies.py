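"""Free-energy contributions of a single fusion-pore state.

A state is a pore shape (r_po, h) together with a SNARE configuration
(Nz zippered of N available).  All energies are returned in kT.  Functions
come in two flavours: vectorised kernels operating on broadcastable arrays
of (r_po, h) — used by the partition sum in :mod:`snarepore.profile` — and a
scalar API operating on :class:`~snarepore.geometry.PoreShape` /
:class:`SnareState` objects.

Components
----------
bending
    Curvature elasticity of the midplane surface, ``kappa ∫ C² dA`` with
    ``C`` the mean curvature, evaluated in closed form over the (possibly
    truncated) torus.
tension
    ``gamma · ΔA`` where ΔA is the change in total midplane area caused by
    forming the pore (pore wall area minus the flat area it replaces).
hydration
    Short-ranged steric-hydration repulsion between the apposed membranes,
    evaluated for fully toroidal shapes only (it is negligible at the large
    separations where truncation occurs).
scaffold (ApoE)
    ``tau · pi D · phi`` work done twisting the disc's rim proteins.
SNAREs
    Translational/orientational entropy and zippering energy of the ring of
    zippered TMDs at the pore waist plus the freely roaming partially
    zippered SNAREs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .geometry import PoreShape, twist_angle_grid
from .params import ModelParams

__all__ = [
    "SnareState",
    "bending_energy",
    "tension_energy",
    "membrane_energy",
    "hydration_energy",
    "apoe_energy",
    "snare_energy",
    "state_energy",
    "membrane_energy_grid",
]


@dataclass(frozen=True)
class SnareState:
    """SNARE bookkeeping: N available per disc face, Nz fully zippered."""

    N: int
    Nz: int

    def __post_init__(self) -> None:
        if not 0 <= self.Nz <= self.N:
            raise ValueError("need 0 <= Nz <= N")

    @property
    def Nuz(self) -> int:
        return self.N - self.Nz


# ---------------------------------------------------------------------------
# membrane elasticity: closed forms over the midplane torus
# ---------------------------------------------------------------------------

def _bend_toroidal(R, H, kappa):
    at = np.arctan(np.sqrt((R + 2 * H) / R))
    return np.pi * kappa * (
        2 * (R + H) ** 2 * at / (H * np.sqrt(R * (R + 2 * H))) - 4
    )


def _bend_partial_correction(R, H, phi, kappa):
    s = np.sqrt(R / (R + 2 * H))
    # difference of arctans stays finite as phi -> pi/2 (cot -> 0)
    with np.errstate(divide="ignore"):
        ata = np.arctan(s / np.tan((np.pi - 2 * phi) / 4)) - np.arctan(s)
    return np.pi * kappa * (
        2 * (1 - np.cos(phi)) - (R + H) ** 2 * ata / (H * np.sqrt(R * (R + 2 * H)))
    )


def _area_change_toroidal(R, H):
    return np.pi * H * ((2 * np.pi - 4) * H + 2 * np.pi * R) - 2 * np.pi * (H + R) ** 2


def _area_change_partial(R, H, phi, D):
    # truncated torus wall minus the flat disc face and the hole in the
    # planar membrane; reduces to the toroidal expression at phi = 0 where
    # R + H = D/2
    wall = 2 * np.pi * H * ((R + H) * (np.pi - phi) - H * (1 + np.cos(phi)))
    return wall - np.pi * (R + H) ** 2 - np.pi * (D / 2) ** 2


def membrane_energy_grid(r_po, h, params: ModelParams):
    """Vectorised bending and tension energies (kT) with regime masks.

    Returns ``(U_bend, U_tension, phi, partial, valid)`` broadcast over the
    inputs.  Entries where ``valid`` is False are meaningless and must be
    excluded by the caller.
    """
    r = np.asarray(r_po, dtype=float)
    hh = np.asarray(h, dtype=float)
    R = r + params.delta / 2
    H = hh / 2 + params.delta / 2
    phi, partial, valid = twist_angle_grid(r, hh, params)

    U_bend = _bend_toroidal(R, H, params.kappa)
    U_bend = U_bend + np.where(
        partial, _bend_partial_correction(R, H, phi, params.kappa), 0.0
    )
    dA = np.where(
        partial,
        _area_change_partial(R, H, phi, params.D),
        _area_change_toroidal(R, H),
    )
    U_tension = params.gamma_kT_nm2 * dA
    return U_bend, U_tension, phi, partial, valid


def bending_energy(shape: PoreShape, params: ModelParams) -> float:
    """Curvature energy of the pore midplane, kT."""
    U = _bend_toroidal(shape.R, shape.H, params.kappa)
    if shape.partial:
        U = U + _bend_partial_correction(shape.R, shape.H, shape.phi, params.kappa)
    return float(U)


def tension_energy(shape: PoreShape, params: ModelParams) -> float:
    """Tension energy ``gamma ΔA`` of the pore, kT."""
    if shape.partial:
        dA = _area_change_partial(shape.R, shape.H, shape.phi, params.D)
    else:
        dA = _area_change_toroidal(shape.R, shape.H)
    return float(params.gamma_kT_nm2 * dA)


def membrane_energy(shape: PoreShape, params: ModelParams) -> tuple[float, float]:
    """(bending, tension) energies of the membrane, kT."""
    return bending_energy(shape, params), tension_energy(shape, params)


# ---------------------------------------------------------------------------
# steric-hydration repulsion
# ---------------------------------------------------------------------------

def hydration_energy_grid(r_po, h, params: ModelParams):
    """Vectorised steric-hydration energy for toroidal shapes, kT."""
    r = np.asarray(r_po, dtype=float)
    hh = np.asarray(h, dtype=float)
    lam = params.lam_hyd
    P0 = params.P0_kT_nm3
    # effective pore height over which the lumen stays within lam of 2 r_po
    l_eff = 2 * np.sqrt(lam * (hh / 2 + params.delta))
    flat = P0 * lam * (np.pi * params.D ** 2 / 4) * np.exp(-hh / lam)
    rim = (
        P0
        * (2 * np.pi * l_eff)
        * np.exp(-2 * r / lam)
        * (lam * r / 2 + (lam / 2) ** 2)
    )
    return flat + rim


def hydration_energy(shape: PoreShape, params: ModelParams) -> float:
    """Steric-hydration energy of a toroidal pore, kT.

    Only fully toroidal shapes carry a hydration term: the repulsion decays
    over ~0.1 nm, far shorter than the separations at which the shape
    becomes truncated.
    """
    if shape.partial:
        raise ValueError("hydration energy is defined for toroidal shapes only")
    return float(hydration_energy_grid(shape.r_po, shape.h, params))


# ---------------------------------------------------------------------------
# scaffold twisting
# ---------------------------------------------------------------------------

def apoe_energy(shape: PoreShape, params: ModelParams) -> float:
    """Work done against the rim scaffold torque, ``tau pi D phi``, kT."""
    return float(params.tau_kT_nm * np.pi * params.D * shape.phi)


# ---------------------------------------------------------------------------
# SNARE free energy
# ---------------------------------------------------------------------------

def snare_ring_capacity(r_po: float, params: ModelParams) -> int:
    """Maximum number of zippered TMDs that fit on the waist ring."""
    circ = 2 * np.pi * (r_po + params.b_snare / 2)
    return int(np.floor(circ / params.b_snare))


def _zippered_energy(r_po, Nz, params: ModelParams):
    """Free energy of Nz zippered SNAREs (vectorised over r_po), kT.

    The TMD bundles (diameter b) pack on the ring of their centres, of
    circumference ``2 pi (r_po + b/2)``; states where they do not fit get
    infinite energy (zero Boltzmann weight).  Includes the
    indistinguishability factor ln Nz! unless the parameter set opts out.
    """
    if Nz == 0:
        return np.zeros_like(np.asarray(r_po, dtype=float))
    b = params.b_snare
    free_len = 2 * np.pi * (np.asarray(r_po, dtype=float) + b / 2) - Nz * b
    ok = free_len > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        U = np.where(
            ok,
            -Nz * (np.log(np.where(ok, free_len, 1.0) / b) + 1.0)
            - Nz * params.eps_zip
            - Nz * np.log(params.omega_z),
            np.inf,
        )
    if not params.distinguishable_snares:
        U = U + gammaln(Nz + 1)
    return U


def _unzippered_energy(Nuz, params: ModelParams) -> float:
    """Free energy of Nuz partially zippered, freely roaming SNAREs, kT."""
    if Nuz == 0:
        return 0.0
    return -Nuz * (np.log(2 * np.pi * params.D / params.b_snare)
                   + np.log(params.omega_uz))


def snare_energy(r_po: float, state: SnareState, params: ModelParams) -> float:
    """Total SNARE free energy for a given configuration, kT.

    Returns ``+inf`` for excluded configurations (ring over-filled), which
    the partition sum treats as zero Boltzmann weight.
    """
    Uz = _zippered_energy(r_po, state.Nz, params)
    return float(Uz + _unzippered_energy(state.Nuz, params))


def state_energy(shape: PoreShape, state: SnareState, params: ModelParams) -> float:
    """Total free energy of one pore state, kT.

    Membrane bending + tension + SNAREs + hydration (toroidal only) +
    scaffold twisting.
    """
    Ub, Ut = membrane_energy(shape, params)
    U = Ub + Ut + snare_energy(shape.r_po, state, params)
    if not shape.partial:
        U += hydration_energy(shape, params)
    U += apoe_energy(shape, params)
    return float(U)
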
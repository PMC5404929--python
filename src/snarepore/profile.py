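"""Equilibrium free energy of the pore versus radius.

For each lumen radius the pore is in equilibrium over its remaining degrees
of freedom — the membrane separation h and the number of zippered SNAREs
Nz — so the observable free energy is obtained from the restricted
partition sum

    exp(−U(r, N)) = Σ_{Nz=0..N} ∫_b^{h_max} exp(−U_tot(r, h, Nz, N)) dh

evaluated by deterministic composite-Simpson quadrature on a fixed h grid.  The
lower integration limit is the zippered-bundle thickness b (the membranes
cannot approach closer with a ring of zippered TMDs between them).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import simpson

from . import units
from .energies import (
    _unzippered_energy,
    _zippered_energy,
    hydration_energy_grid,
    membrane_energy_grid,
)
from .params import ModelParams

__all__ = [
    "FreeEnergyProfile",
    "free_energy",
    "free_energy_profile",
    "mean_zippered",
    "net_inward_force",
    "boltzmann_mean_radius",
    "expansion_work",
    "default_grid",
]

DEFAULT_H_MAX = 20.0
DEFAULT_N_H = 400
DEFAULT_GRID_STEP = 0.025


def default_grid(params: ModelParams, step: float = DEFAULT_GRID_STEP) -> np.ndarray:
    """Default radius grid: 0.25 nm up to the largest admissible radius."""
    return np.arange(0.25, params.r_max + step / 2, step)


def _base_energy(r_grid: np.ndarray, h: np.ndarray, params: ModelParams):
    """SNARE-independent state energy on the (r, h) grid, +inf where invalid."""
    r = r_grid[:, None]
    hh = h[None, :]
    Ub, Ut, phi, partial, valid = membrane_energy_grid(r, hh, params)
    Uh = np.where(partial, 0.0, hydration_energy_grid(r, hh, params))
    Ua = params.tau_kT_nm * np.pi * params.D * phi
    base = Ub + Ut + Uh + Ua
    return np.where(valid, base, np.inf)


def _partition_terms(
    r_grid: np.ndarray,
    N: int,
    params: ModelParams,
    h_max: float,
    n_h: int,
):
    """Boltzmann weights w(r, Nz) integrated over h, for Nz = 0..N.

    Each radius row is shifted by its minimum state energy before
    exponentiating (log-sum-exp), so deep and shallow parts of the
    landscape are handled with uniform relative accuracy.  Returns
    ``(weights, E0, h, base)`` where the true integrated weight is
    ``weights * exp(-E0)``.
    """
    h = np.linspace(params.b_snare, h_max, n_h)
    base = _base_energy(r_grid, h, params)
    E = np.empty((N + 1, len(r_grid), n_h))
    for Nz in range(N + 1):
        Us = _zippered_energy(r_grid, Nz, params) + _unzippered_energy(N - Nz, params)
        E[Nz] = base + Us[:, None]
    E0 = np.min(E, axis=(0, 2))  # per-radius shift; may be +inf if no state
    finite = np.isfinite(E0)
    shift = np.where(finite, E0, 0.0)
    with np.errstate(invalid="ignore"):
        rel = np.where(np.isfinite(E), np.exp(-np.clip(E - shift[None, :, None],
                                                       -700.0, 700.0)), 0.0)
    weights = simpson(rel, x=h, axis=2)
    return weights, E0, h, base


def free_energy(
    r_po: float,
    N: int,
    params: ModelParams,
    h_max: float = DEFAULT_H_MAX,
    n_h: int = DEFAULT_N_H,
    tail_tol: float = 1e-9,
) -> float:
    """Free energy U(r_po, N) in kT (up to an additive constant).

    Warns if the integrand has not decayed at ``h_max`` (truncated tail).
    """
    r_grid = np.atleast_1d(float(r_po))
    weights, E0, h, base = _partition_terms(r_grid, N, params, h_max, n_h)
    Z = weights.sum(axis=0)[0]
    if not (Z > 0 and np.isfinite(E0[0])):
        return np.inf
    shifted = base[0] - base[0].min()
    tail = np.exp(-shifted[-1]) if np.isfinite(shifted[-1]) else 0.0
    if tail > tail_tol:
        warnings.warn(
            f"h integration tail not converged at h_max={h_max} "
            f"(relative weight {tail:.2e}); increase h_max",
            RuntimeWarning,
        )
    return float(E0[0] - np.log(Z))


@dataclass(frozen=True)
class FreeEnergyProfile:
    """U(r) on a radius grid for a given available SNARE number.

    ``U`` is shifted so its minimum is exactly zero; all derived quantities
    (forces, Boltzmann averages, argmin) are invariant to that shift.
    """

    grid: np.ndarray
    U: np.ndarray
    N: int
    params: ModelParams
    mean_Nz: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        if g.ndim != 1 or len(g) < 2 or not np.all(np.diff(g) > 0):
            raise ValueError("grid must be a strictly increasing 1-D array")
        if len(self.U) != len(g):
            raise ValueError("U and grid must have matching lengths")

    @property
    def argmin_radius(self) -> float:
        """Continuous argmin via local quadratic interpolation, nm."""
        i = int(np.argmin(self.U))
        if i == 0 or i == len(self.grid) - 1:
            return float(self.grid[i])
        x = self.grid[i - 1 : i + 2]
        y = self.U[i - 1 : i + 2]
        denom = (y[0] - 2 * y[1] + y[2])
        if denom <= 0:
            return float(self.grid[i])
        step = 0.5 * (y[0] - y[2]) / denom
        return float(x[1] + step * (x[1] - x[0]))

    def shifted(self, offset: float) -> "FreeEnergyProfile":
        return FreeEnergyProfile(self.grid, self.U + offset, self.N, self.params,
                                 self.mean_Nz)


def free_energy_profile(
    grid: np.ndarray | None,
    N: int,
    params: ModelParams,
    h_max: float = DEFAULT_H_MAX,
    n_h: int = DEFAULT_N_H,
) -> FreeEnergyProfile:
    """Compute the free-energy profile U(r) − min U for N available SNAREs."""
    if grid is None:
        grid = default_grid(params)
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or not np.all(np.diff(grid) > 0):
        raise ValueError("grid must be strictly increasing")
    if grid[0] <= 0 or grid[-1] > params.D / 2:
        raise ValueError("grid must lie within (0, D/2]")
    weights, E0, _, _ = _partition_terms(grid, N, params, h_max, n_h)
    Z = weights.sum(axis=0)
    with np.errstate(divide="ignore"):
        U = E0 - np.log(Z)
    if not np.all(np.isfinite(U)):
        raise ValueError(
            "free energy diverged on part of the grid; restrict the grid to "
            f"radii <= {params.r_max} nm"
        )
    nz = np.arange(N + 1)[:, None]
    mean_Nz = (nz * weights).sum(axis=0) / Z
    return FreeEnergyProfile(grid, U - U.min(), N, params, mean_Nz)


def mean_zippered(
    r_po: float,
    N: int,
    params: ModelParams,
    h_max: float = DEFAULT_H_MAX,
    n_h: int = DEFAULT_N_H,
) -> float:
    """Boltzmann-average number of zippered SNAREs at radius ``r_po``."""
    weights, _, _, _ = _partition_terms(np.atleast_1d(float(r_po)), N, params,
                                        h_max, n_h)
    Z = weights.sum(axis=0)[0]
    if not Z > 0:
        raise ValueError("no admissible state at this radius")
    return float((np.arange(N + 1) * weights[:, 0]).sum() / Z)


def net_inward_force(
    profile: FreeEnergyProfile,
    r_min: float = 1.5,
    r_max: float | None = None,
) -> float:
    """Mean inward force over pore radii above ``r_min``, in pN.

    The force is the Boltzmann-weighted average of dU/dr over the window
    [r_min, r_max] with weights exp(−U/kT): the force felt by a pore
    sampling its own equilibrium size distribution.  Positive values resist
    expansion.
    """
    g = profile.grid
    if r_max is None:
        r_max = g[-1]
    if r_min < g[0] or r_max > g[-1] or not r_min < r_max:
        raise ValueError("force window must lie within the profile grid")
    dU = np.gradient(profile.U, g)
    m = (g >= r_min) & (g <= r_max)
    w = np.exp(-(profile.U[m] - profile.U[m].min()))
    f_kT_nm = float(np.sum(dU[m] * w) / np.sum(w))
    return units.kT_per_nm_to_pN(f_kT_nm, profile.params.T)


def boltzmann_mean_radius(profile: FreeEnergyProfile) -> float:
    """Thermal-average pore radius ⟨r⟩ on the profile grid, nm."""
    U = profile.U - profile.U.min()
    if U[0] < 10 or U[-1] < 10:
        warnings.warn(
            "profile may not cover the thermally accessible range "
            "(U < min + 10 kT at a grid end)",
            RuntimeWarning,
        )
    w = np.exp(-U)
    return float(np.sum(profile.grid * w) / np.sum(w))


def expansion_work(
    params: ModelParams,
    dr: float = 1.0,
    h_max: float = DEFAULT_H_MAX,
    n_h: int = DEFAULT_N_H,
    grid: np.ndarray | None = None,
) -> dict:
    """Tension and bending work over a ``dr`` expansion from the minimum.

    For the SNARE-free pore, finds the minimum-energy radius r*, the
    conditionally optimal separation h*(r) (the h minimising the state
    energy at fixed r), and returns the changes of the tension and bending
    terms between (r*, h*(r*)) and (r*+dr, h*(r*+dr)), in kT.
    """
    prof = free_energy_profile(grid, 0, params, h_max=h_max, n_h=n_h)
    r0 = prof.grid[int(np.argmin(prof.U))]
    r1 = r0 + dr
    h = np.linspace(params.b_snare, h_max, n_h)
    out = {}
    for tag, r in (("min", r0), ("expanded", r1)):
        Ub, Ut, phi, partial, valid = membrane_energy_grid(r, h, params)
        Uh = np.where(partial, 0.0, hydration_energy_grid(r, h, params))
        Ua = params.tau_kT_nm * np.pi * params.D * phi
        tot = np.where(valid, Ub + Ut + Uh + Ua, np.inf)
        i = int(np.argmin(tot))
        out[tag] = {"r": float(r), "h_opt": float(h[i]),
                    "U_bend": float(Ub[i]), "U_tension": float(Ut[i])}
    return {
        "r_min": float(r0),
        "tension_work_kT": out["expanded"]["U_tension"] - out["min"]["U_tension"],
        "bending_work_kT": out["expanded"]["U_bend"] - out["min"]["U_bend"],
        "detail": out,
    }
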
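"""Staged fitting of model parameters to reference free-energy curves.

The membrane and SNARE parameters that are not known independently are
obtained sequentially from free-energy curves, each stage pinning one
parameter from the feature of the curve it dominates:

1. hydration decay length ``lam_hyd`` — position of the free-energy minimum
   of the SNARE-free curve;
2. membrane tension ``gamma`` — slope just beyond the minimum
   (0.5–1.0 nm), SNARE-free;
3. zippering energy ``eps_zip`` — slope over 0.5–2.5 nm with the full
   SNARE load (N = 15 per face);
4. scaffold torque ``tau`` — slope in the truncated-shape region
   (4.0–4.5 nm), N = 4.

All stages are 1-D root finds / minimisations on slopes or minimum
positions, so they are invariant to the arbitrary additive constant of a
reference curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import simpson
from scipy.optimize import brentq, minimize_scalar

from .params import ModelParams
from .profile import (
    FreeEnergyProfile,
    boltzmann_mean_radius,
    free_energy_profile,
)

__all__ = [
    "FitResult",
    "fit_hydration_and_tension",
    "fit_zippering",
    "fit_torque",
    "fit_all_stages",
    "lipid_anchor_delta",
]


@dataclass(frozen=True)
class FitResult:
    name: str
    value: float
    units: str
    window: tuple[float, float]
    residual: float
    reference: str = ""

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValueError(f"fitted {self.name} must be positive")


def _mean_slope(profile: FreeEnergyProfile, lo: float, hi: float) -> float:
    g, U = profile.grid, profile.U
    m = (g >= lo) & (g <= hi)
    if m.sum() < 2:
        raise ValueError(f"window [{lo}, {hi}] contains fewer than 2 grid points")
    return float(np.polyfit(g[m], U[m], 1)[0])


def _first_branch_root(f, lo: float, hi: float, n_scan: int = 12,
                       xtol: float = 1e-3) -> float:
    """Root of ``f`` on the first sign-changing sub-interval of [lo, hi].

    The slope responses are monotone over the physical parameter range but
    can turn over at extreme values; scanning and keeping the first
    bracket selects the physical branch.  Falls back to the scanned point
    with the smallest |f| when no sign change exists.
    """
    xs = np.geomspace(lo, hi, n_scan)
    vals = [f(x) for x in xs]
    for (x0, f0), (x1, f1) in zip(zip(xs, vals), zip(xs[1:], vals[1:])):
        if f0 == 0:
            return float(x0)
        if f0 * f1 < 0:
            return float(brentq(f, x0, x1, xtol=xtol))
    return float(xs[int(np.argmin(np.abs(vals)))])


def _interior_argmin(profile: FreeEnergyProfile) -> float:
    i = int(np.argmin(profile.U))
    if i == 0 or i == len(profile.grid) - 1:
        raise ValueError("reference curve has no interior minimum")
    return profile.argmin_radius


def fit_hydration_and_tension(
    reference: FreeEnergyProfile,
    params0: ModelParams,
    lam_bounds: tuple[float, float] = (0.02, 0.3),
    gamma_bounds: tuple[float, float] = (0.05, 5.0),
    slope_window: tuple[float, float] = (0.5, 1.0),
) -> tuple[FitResult, FitResult]:
    """Fit ``lam_hyd`` to the minimum position, then ``gamma`` to the slope.

    The reference must be comparable to a SNARE-free curve with a single
    interior minimum.  The bending modulus is held fixed.
    """
    target_min = _interior_argmin(reference)
    grid = reference.grid

    def argmin_mismatch(lam: float) -> float:
        prof = free_energy_profile(grid, 0, params0.replace(lam_hyd=lam))
        return prof.argmin_radius - target_min

    lo, hi = lam_bounds
    if argmin_mismatch(lo) * argmin_mismatch(hi) < 0:
        lam = brentq(argmin_mismatch, lo, hi, xtol=1e-3)
    else:  # no bracketing: fall back to |mismatch| minimisation
        res = minimize_scalar(
            lambda x: abs(argmin_mismatch(x)), bounds=lam_bounds, method="bounded",
            options={"xatol": 1e-3},
        )
        lam = float(res.x)
    lam_res = abs(argmin_mismatch(lam))
    p1 = params0.replace(lam_hyd=float(lam))

    target_slope = _mean_slope(reference, *slope_window)

    def slope_mismatch(gamma: float) -> float:
        prof = free_energy_profile(grid, 0, p1.replace(gamma=gamma))
        return _mean_slope(prof, *slope_window) - target_slope

    gamma = _first_branch_root(slope_mismatch, *gamma_bounds)
    gam_res = abs(slope_mismatch(gamma))
    return (
        FitResult("lam_hyd", float(lam), "nm", (grid[0], grid[-1]), lam_res),
        FitResult("gamma", float(gamma), "pN/nm", slope_window, gam_res),
    )


def fit_zippering(
    reference: FreeEnergyProfile,
    N: int,
    params: ModelParams,
    window: tuple[float, float] = (0.5, 2.5),
    bounds: tuple[float, float] = (0.0, 30.0),
) -> FitResult:
    """Fit ``eps_zip`` so the model slope over ``window`` matches the
    reference at the given SNARE load.  Membrane parameters must already be
    fixed."""
    if N == 0:
        raise ValueError("zippering energy has no effect at N = 0")
    target = _mean_slope(reference, *window)
    grid = reference.grid

    def mismatch(eps: float) -> float:
        prof = free_energy_profile(grid, N, params.replace(eps_zip=max(eps, 1e-9)))
        return _mean_slope(prof, *window) - target

    lo, hi = bounds
    eps = brentq(mismatch, max(lo, 1e-6), hi, xtol=1e-3)
    return FitResult("eps_zip", float(np.clip(eps, *bounds)), "kT", window,
                     abs(mismatch(eps)))


def fit_torque(
    reference: FreeEnergyProfile,
    N: int,
    params: ModelParams,
    window: tuple[float, float] = (4.0, 4.5),
    bounds: tuple[float, float] = (0.05, 60.0),
) -> FitResult:
    """Fit the scaffold torque ``tau`` to the slope in the truncated-shape
    window (default 4.0–4.5 nm)."""
    r_partial_onset = params.D / 2 - params.delta - params.b_snare / 2
    if window[0] >= params.r_max or window[1] <= 0:
        raise ValueError("torque window lies outside the admissible radii")
    if window[1] < r_partial_onset - 2.0:
        raise ValueError(
            "torque window is entirely in the fully toroidal regime; "
            "the slope there carries no torque information"
        )
    target = _mean_slope(reference, *window)
    grid = reference.grid

    def mismatch(tau: float) -> float:
        prof = free_energy_profile(grid, N, params.replace(tau=tau))
        return _mean_slope(prof, *window) - target

    lo, hi = bounds
    flo, fhi = mismatch(lo), mismatch(hi)
    if flo * fhi < 0:
        tau = brentq(mismatch, lo, hi, xtol=1e-3)
    else:
        # slope target below the tau->0 limit: report the boundary
        tau = lo if abs(flo) < abs(fhi) else hi
    return FitResult("tau", float(tau), "pN", window, abs(mismatch(tau)))


def fit_all_stages(
    ref_snarefree: FreeEnergyProfile,
    ref_loaded: FreeEnergyProfile,
    ref_torque: FreeEnergyProfile,
    params0: ModelParams,
    N_loaded: int = 15,
    N_torque: int = 4,
) -> dict[str, FitResult]:
    """Run the staged recipe in order and return all four fits."""
    lam_fit, gamma_fit = fit_hydration_and_tension(ref_snarefree, params0)
    p = params0.replace(lam_hyd=lam_fit.value, gamma=gamma_fit.value)
    eps_fit = fit_zippering(ref_loaded, N_loaded, p)
    p = p.replace(eps_zip=eps_fit.value)
    tau_fit = fit_torque(ref_torque, N_torque, p)
    return {
        "lam_hyd": lam_fit,
        "gamma": gamma_fit,
        "eps_zip": eps_fit,
        "tau": tau_fit,
    }


def lipid_anchor_delta(
    params: ModelParams,
    N: int = 7,
    reduction: float = 0.5,
    tol: float = 0.01,
) -> float:
    """Zippering-energy decrease compensating a smaller zippered footprint.

    Lipid-anchored v-SNAREs lack the v-TMD, shrinking the membrane
    footprint of the zippered bundle by up to ``reduction`` (default 50%).
    A smaller footprint weakens crowding, which alone would shrink the
    equilibrium pore; this function returns the decrease in ``eps_zip``
    (kT, positive) that keeps the Boltzmann-mean pore radius unchanged.
    The reduced footprint enters the ring packing only; the entropy
    reference length is unchanged.

    Default N = 7 per face matches discs loaded with ~15 lipid-anchored
    copies in total.
    """
    if N < 1:
        raise ValueError("need at least one SNARE")
    if not 0 <= reduction < 1:
        raise ValueError("reduction must be in [0, 1)")
    if reduction == 0:
        return 0.0
    target = boltzmann_mean_radius(free_energy_profile(None, N, params))

    b_small = params.b_snare * (1 - reduction)

    def mismatch(d_eps: float) -> float:
        p = params.replace(eps_zip=params.eps_zip - d_eps)
        prof = _reduced_footprint_profile(p, N, b_small, params.b_snare)
        return boltzmann_mean_radius(prof) - target

    lo, hi = -1.0, 5.0
    if mismatch(lo) * mismatch(hi) > 0:
        raise ValueError("no compensating zippering-energy shift in [-1, 5] kT")
    return float(brentq(mismatch, lo, hi, xtol=tol))


def _reduced_footprint_profile(
    params: ModelParams, N: int, b_pack: float, b_ref: float
) -> FreeEnergyProfile:
    """Profile with zippered footprint ``b_pack`` but entropy reference
    length ``b_ref`` (used by the lipid-anchor calculation)."""
    from scipy.special import gammaln

    from .profile import _base_energy, DEFAULT_H_MAX, DEFAULT_N_H, default_grid

    grid = default_grid(params)
    h = np.linspace(params.b_snare, DEFAULT_H_MAX, DEFAULT_N_H)
    base = _base_energy(grid, h, params)
    Z = np.zeros(len(grid))
    for Nz in range(N + 1):
        free_len = 2 * np.pi * (grid + b_pack / 2) - Nz * b_pack
        ok = free_len > 0
        if Nz == 0:
            Us = np.zeros(len(grid))
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                Us = np.where(
                    ok,
                    -Nz * (np.log(np.where(ok, free_len, 1.0) / b_ref) + 1.0)
                    - Nz * params.eps_zip
                    - Nz * np.log(params.omega_z),
                    np.inf,
                )
            if not params.distinguishable_snares:
                Us = Us + gammaln(Nz + 1)
        Us = Us + (-(N - Nz) * (np.log(2 * np.pi * params.D / params.b_snare)
                                + np.log(params.omega_uz)))
        E = base + Us[:, None]
        Z += simpson(
            np.where(np.isfinite(E), np.exp(-np.clip(E, -700, 700)), 0.0), x=h, axis=1
        )
    U = -np.log(Z)
    return FreeEnergyProfile(grid, U - U.min(), N, params)
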
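"""Synthetic cell-attached patch recordings with known ground truth.

The generator emulates the statistical structure of single fusion-pore
recordings: a flat noisy baseline, rare current bursts arriving as a
renewal process (~0.2/min), open/closed flickering within each burst with
a geometrically distributed number of open periods, negative-going open
currents equal to −G·V, and white Gaussian instrument noise whose
amplitude leaves ≲0.2 pA rms after the standard filtering chain.

Burst anatomy
-------------
A burst has ``K`` open periods, ``K = 1 + n`` with ``n`` geometric on
n = 0, 1, 2, … (parameter ``flicker_p``); open dwells are exponential with
mean ``flicker_p · open_fraction · burst_lifetime_s`` so that the total
open time — and hence the burst lifetime — is itself approximately
exponential with the requested mean.  Intra-burst closures are short
exponential dwells, clipped below the burst-merging gap of the detector so
that one generated burst is one detected burst.

Every stochastic output is a pure function of the spec (including its
mandatory seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .profile import FreeEnergyProfile
from .traces import CurrentTrace, conductance_from_radius

__all__ = ["SynthSpec", "GroundTruthBurst", "GroundTruth", "synth_trace",
           "render_trace", "synth_cohort", "synth_profile_curves"]


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic recording.  ``seed`` is mandatory."""

    seed: int
    duration_s: float = 600.0
    rate: float = 20000.0
    burst_rate_per_min: float = 0.2
    flicker_p: float = 0.0573
    burst_lifetime_s: float = 10.3
    open_fraction: float = 0.85
    conductance_mode: Literal["fixed", "mixture", "boltzmann"] = "fixed"
    conductance_ps: float = 450.0
    mixture_means: tuple[float, ...] = (300.0, 7210.0)
    mixture_sds: tuple[float, ...] = (150.0, 3000.0)
    mixture_weights: tuple[float, ...] = (0.71, 0.29)
    profile: FreeEnergyProfile | None = None
    conductance_dwell_s: float = 0.04
    driving_mv: float = 16.0
    resistivity: float = 0.60
    noise_sd_pa: float = 2.0
    min_open_s: float = 0.08
    min_closed_s: float = 0.016
    max_closed_s: float = 0.4
    min_burst_sep_s: float = 2.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("duration_s", "rate", "burst_rate_per_min",
                     "burst_lifetime_s"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.flicker_p <= 1:
            raise ValueError("flicker_p must be in (0, 1]")
        if abs(sum(self.mixture_weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if self.conductance_mode == "boltzmann" and self.profile is None:
            raise ValueError("boltzmann conductance mode needs a profile")


@dataclass
class GroundTruthBurst:
    start_s: float
    end_s: float
    open_periods: list[tuple[float, float]]
    conductances_ps: list[np.ndarray]   # per open period, per conductance dwell
    n_flickers: int

    @property
    def lifetime_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def open_time_s(self) -> float:
        return sum(e - s for s, e in self.open_periods)


@dataclass
class GroundTruth:
    bursts: list[GroundTruthBurst]
    spec: SynthSpec

    @property
    def n_bursts(self) -> int:
        return len(self.bursts)


def _sample_radius(rng: np.random.Generator, profile: FreeEnergyProfile) -> float:
    w = np.exp(-(profile.U - profile.U.min()))
    return float(rng.choice(profile.grid, p=w / w.sum()))


def _draw_conductance(rng: np.random.Generator, spec: SynthSpec) -> float:
    if spec.conductance_mode == "fixed":
        return spec.conductance_ps
    if spec.conductance_mode == "mixture":
        i = rng.choice(len(spec.mixture_weights), p=spec.mixture_weights)
        return float(abs(rng.normal(spec.mixture_means[i], spec.mixture_sds[i])))
    r = _sample_radius(rng, spec.profile)
    return float(conductance_from_radius(r, spec.resistivity))


def _make_burst(rng: np.random.Generator, start: float, spec: SynthSpec,
                fixed_g: float | None) -> GroundTruthBurst:
    n_extra = int(rng.geometric(spec.flicker_p)) - 1  # geometric on 0,1,2,...
    k_open = n_extra + 1
    mu_open = spec.flicker_p * spec.open_fraction * spec.burst_lifetime_s
    mu_closed = (
        spec.flicker_p * (1 - spec.open_fraction) * spec.burst_lifetime_s
        / max(1 - spec.flicker_p, 1e-9)
    )
    t = start
    opens: list[tuple[float, float]] = []
    conds: list[np.ndarray] = []
    for i in range(k_open):
        if i > 0:
            gap = np.clip(rng.exponential(mu_closed),
                          spec.min_closed_s, spec.max_closed_s)
            t += gap
        dwell = max(rng.exponential(mu_open), spec.min_open_s)
        opens.append((t, t + dwell))
        n_seg = max(1, int(np.ceil(dwell / spec.conductance_dwell_s)))
        if fixed_g is not None:
            g = np.full(n_seg, fixed_g)
        else:
            g = np.array([_draw_conductance(rng, spec) for _ in range(n_seg)])
        conds.append(g)
        t += dwell
    # guarantee the burst satisfies the 250 ms acceptance criterion of the
    # detector (with margin), so generated and detected bursts correspond 1:1
    min_span = 0.30
    if t - start < min_span:
        s0, _ = opens[-1]
        extend = min_span - (t - start)
        opens[-1] = (s0, opens[-1][1] + extend)
        t += extend
        n_seg = max(1, int(np.ceil((opens[-1][1] - s0) / spec.conductance_dwell_s)))
        if len(conds[-1]) < n_seg:
            conds[-1] = np.concatenate(
                [conds[-1], np.repeat(conds[-1][-1:], n_seg - len(conds[-1]))]
            )
    return GroundTruthBurst(
        start_s=start,
        end_s=t,
        open_periods=opens,
        conductances_ps=conds,
        n_flickers=k_open,
    )


def render_trace(bursts: list[GroundTruthBurst], spec: SynthSpec,
                 rng: np.random.Generator | None = None) -> CurrentTrace:
    """Render burst events into a raw-rate current trace (noise from rng)."""
    n = int(round(spec.duration_s * spec.rate))
    current = np.zeros(n)
    for b in bursts:
        for (s, e), g in zip(b.open_periods, b.conductances_ps):
            i0, i1 = int(round(s * spec.rate)), min(int(round(e * spec.rate)), n)
            if i1 <= i0:
                continue
            seg_len = int(np.ceil((i1 - i0) / len(g)))
            amp = -np.repeat(g, seg_len)[: i1 - i0] * spec.driving_mv * 1e-3
            current[i0:i1] = amp
    if rng is not None and spec.noise_sd_pa > 0:
        current = current + rng.normal(0.0, spec.noise_sd_pa, size=n)
    return CurrentTrace(
        samples=current,
        rate=spec.rate,
        driving_mv=spec.driving_mv,
        resistivity=spec.resistivity,
        meta={"synthetic": True, "seed": spec.seed},
    )


def synth_trace(spec: SynthSpec) -> tuple[CurrentTrace, GroundTruth]:
    """Generate one synthetic recording and its ground truth.

    Bursts arrive as a renewal process at ``burst_rate_per_min`` with a
    minimum separation; a burst that would not finish at least 1 s before
    the end of the recording is not placed.
    """
    rng = np.random.default_rng(spec.seed)
    mean_wait = 60.0 / spec.burst_rate_per_min
    bursts: list[GroundTruthBurst] = []
    # one conductance level per burst unless sampling point-by-point
    t = 0.0
    while True:
        wait = max(rng.exponential(mean_wait), spec.min_burst_sep_s)
        start = t + wait
        if start >= spec.duration_s - 1.0:
            break
        fixed_g = (
            _draw_conductance(rng, spec)
            if spec.conductance_mode in ("fixed", "mixture")
            else None
        )
        burst = _make_burst(rng, start, spec, fixed_g)
        if burst.end_s >= spec.duration_s - 1.0:
            break
        bursts.append(burst)
        t = burst.end_s
    trace = render_trace(bursts, spec, rng)
    return trace, GroundTruth(bursts=bursts, spec=spec)


def synth_cohort(conditions: list[dict], seed: int) -> pd.DataFrame:
    """Per-pore mean conductances for a multi-condition cohort.

    Each condition is a mapping with keys ``label``, ``n_per_face``,
    ``n_pores`` and optionally ``mixture`` as ``(means, sds, weights)``.
    Returns a tidy DataFrame with one row per pore.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for cond in conditions:
        if cond["n_pores"] < 1:
            raise ValueError("each condition needs at least one pore")
        means, sds, weights = cond.get(
            "mixture", ((300.0, 7210.0), (150.0, 3000.0), (0.71, 0.29))
        )
        weights = np.asarray(weights, dtype=float)
        if abs(weights.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        comp = rng.choice(len(weights), size=cond["n_pores"], p=weights)
        g = np.abs(rng.normal(np.take(means, comp), np.take(sds, comp)))
        for gi, ci in zip(g, comp):
            rows.append(
                {
                    "condition": cond["label"],
                    "n_per_face": cond["n_per_face"],
                    "g_po_ps": float(gi),
                    "true_component": int(ci),
                }
            )
    return pd.DataFrame(rows)


def synth_profile_curves(
    params,
    N_values: tuple[int, ...] = (0, 15, 4),
    noise_sd_kT: float = 0.0,
    offset_kT: float = 0.0,
    seed: int = 0,
    grid=None,
) -> dict[int, FreeEnergyProfile]:
    """Model-generated reference curves, optionally noisy and offset.

    Used to exercise the staged parameter-fitting recipe with known ground
    truth.  Noise is i.i.d. Gaussian per grid point; the offset emulates
    the arbitrary additive constant of an empirical free energy.
    """
    from .profile import free_energy_profile

    rng = np.random.default_rng(seed)
    out = {}
    for N in N_values:
        prof = free_energy_profile(grid, N, params)
        U = prof.U + offset_kT
        if noise_sd_kT > 0:
            U = U + rng.normal(0.0, noise_sd_kT, size=len(U))
        out[N] = FreeEnergyProfile(prof.grid, U, N, params, prof.mean_Nz)
    return out
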
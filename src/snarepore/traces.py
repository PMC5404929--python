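"""Idealization of single fusion-pore patch-clamp current traces.

The pipeline mirrors standard single-channel practice for cell-attached
fusion-pore recordings: zero-phase low-pass (and optional notch) filtering,
block-average decimation to 125 Hz, amplitude/duration thresholding into
current *bursts* (one burst = one pore), open/closed idealization of the
flickering within each burst, and conversion of open-state currents to
conductances and pore radii.

Conventions
-----------
* Driving force ``V`` is the voltage across the patch (mV); open currents
  are negative-going, so conductance samples are ``|I|/V`` (pA/mV = nS).
* A burst is a maximal episode of above-threshold current ``|I| > 2 pA``
  lasting at least 250 ms; sub-threshold gaps shorter than ``merge_gap_s``
  are treated as intra-burst closures (flickers), not burst boundaries,
  and count toward the burst lifetime T0.
* Open sub-periods are maximal runs with ``I < −0.25 pA`` lasting at least
  15 decimated points (60 ms); the flicker count of a burst is the number
  of open sub-periods.
* A pore of radius r is modelled as a cylindrical channel of length 15 nm,
  giving ``r = sqrt(rho * L * G / pi)``.

All intervals are half-open ``[start, end)`` in seconds at the decimated
rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "CurrentTrace",
    "ProcessedTrace",
    "PoreRecord",
    "preprocess",
    "detect_bursts",
    "detect_flickers",
    "pore_record",
    "analyze_trace",
    "radius_from_conductance",
    "conductance_from_radius",
    "averaged_pdf",
    "energy_from_pdf",
    "fit_flicker_geometric",
    "geometric_mean_flickers",
    "fit_burst_exponential",
    "nucleation_rate",
]

DEFAULT_RATE = 20000.0
DEFAULT_DRIVING_MV = 16.0
DEFAULT_RESISTIVITY = 0.60  # Ohm*m (NaCl pipette solution); 0.88 for NMDG
CHANNEL_LENGTH_NM = 15.0


@dataclass
class CurrentTrace:
    """Raw patch current. ``samples`` in pA at ``rate`` samples/s."""

    samples: np.ndarray
    rate: float = DEFAULT_RATE
    driving_mv: float = DEFAULT_DRIVING_MV
    resistivity: float = DEFAULT_RESISTIVITY
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0 or self.resistivity <= 0:
            raise ValueError("rate and resistivity must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite samples")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.rate


@dataclass
class ProcessedTrace:
    """Filtered, block-decimated current ready for idealization."""

    samples: np.ndarray
    rate: float
    driving_mv: float
    resistivity: float
    provenance: dict = field(default_factory=dict)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.rate

    @property
    def dt(self) -> float:
        return 1.0 / self.rate


def preprocess(
    trace: CurrentTrace,
    cutoff_hz: float = 280.0,
    block: int = 80,
    notch_hz: tuple[float, ...] = (),
    notch_q: float = 30.0,
    order: int = 8,
) -> ProcessedTrace:
    """Zero-phase low-pass (+ optional notch) filter, then block-average.

    The low-pass is an ``order``-th Butterworth applied forward-backward
    (zero phase shift); each notch is a biquad at the given line frequency.
    Decimation averages non-overlapping blocks of ``block`` samples,
    bringing 20 kHz data to a 125 Hz final bandwidth.
    """
    if trace.rate < 2 * cutoff_hz:
        raise ValueError("sampling rate must be at least twice the cutoff")
    if len(trace.samples) < block:
        raise ValueError("trace shorter than one decimation block")
    sos = signal.butter(order, cutoff_hz, fs=trace.rate, output="sos")
    x = signal.sosfiltfilt(sos, trace.samples)
    for f0 in notch_hz:
        b, a = signal.iirnotch(f0, notch_q, fs=trace.rate)
        x = signal.filtfilt(b, a, x)
    n = (len(x) // block) * block
    decimated = x[:n].reshape(-1, block).mean(axis=1)
    return ProcessedTrace(
        samples=decimated,
        rate=trace.rate / block,
        driving_mv=trace.driving_mv,
        resistivity=trace.resistivity,
        provenance={
            "cutoff_hz": cutoff_hz,
            "block": block,
            "notch_hz": list(notch_hz),
            "filter_order": order,
            "raw_rate": trace.rate,
        },
    )


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open index runs where ``mask`` is True."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    return list(zip(starts, ends))


def detect_bursts(
    p: ProcessedTrace,
    amp_thresh_pa: float = 2.0,
    min_dur_s: float = 0.25,
    merge_gap_s: float = 0.5,
) -> list[tuple[float, float]]:
    """Detect fusion-pore current bursts.

    A burst is a maximal episode with ``|I| > amp_thresh_pa`` lasting at
    least ``min_dur_s``; sub-threshold gaps shorter than ``merge_gap_s``
    are flickers within the burst and do not end it.  Returns disjoint,
    ordered ``(start_s, end_s)`` pairs; the burst lifetime is
    ``end − start`` including intra-burst closures.
    """
    above = np.abs(p.samples) > amp_thresh_pa
    runs = _runs(above)
    if not runs:
        return []
    max_gap = int(round(merge_gap_s * p.rate))
    merged = [list(runs[0])]
    for s, e in runs[1:]:
        if s - merged[-1][1] <= max_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    min_pts = int(round(min_dur_s * p.rate))
    return [
        (s * p.dt, e * p.dt) for s, e in merged if e - s >= min_pts
    ]


def detect_flickers(
    p: ProcessedTrace,
    burst: tuple[float, float],
    open_thresh_pa: float = -0.25,
    min_pts: int = 15,
) -> list[tuple[float, float]]:
    """Open sub-periods within a burst: maximal runs with I < threshold
    lasting at least ``min_pts`` decimated points."""
    i0, i1 = int(round(burst[0] * p.rate)), int(round(burst[1] * p.rate))
    if i0 < 0 or i1 > len(p.samples) or i0 >= i1:
        raise ValueError("burst bounds outside the trace")
    seg = p.samples[i0:i1]
    opens = [
        ((i0 + s) * p.dt, (i0 + e) * p.dt)
        for s, e in _runs(seg < open_thresh_pa)
        if e - s >= min_pts
    ]
    return opens


@dataclass
class PoreRecord:
    """Per-burst summary of one fusion pore."""

    start_s: float
    end_s: float
    open_periods: list[tuple[float, float]]
    open_samples_pa: np.ndarray
    g_po_ps: float            # mean open conductance, pS (nan if never open)
    p_open: float
    n_flickers: int
    driving_mv: float = DEFAULT_DRIVING_MV
    resistivity: float = DEFAULT_RESISTIVITY
    condition: str = ""

    @property
    def lifetime_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def g_samples_ps(self) -> np.ndarray:
        """Point-by-point open conductance samples, pS."""
        return np.abs(self.open_samples_pa) / self.driving_mv * 1e3

    @property
    def r_samples_nm(self) -> np.ndarray:
        """Point-by-point open pore radii, nm."""
        return radius_from_conductance(self.g_samples_ps, self.resistivity)


def pore_record(
    p: ProcessedTrace,
    burst: tuple[float, float],
    opens: list[tuple[float, float]] | None = None,
    condition: str = "",
) -> PoreRecord:
    """Assemble the per-pore record for one detected burst."""
    if opens is None:
        opens = detect_flickers(p, burst)
    pieces = []
    for s, e in opens:
        i0, i1 = int(round(s * p.rate)), int(round(e * p.rate))
        pieces.append(p.samples[i0:i1])
    open_samples = np.concatenate(pieces) if pieces else np.empty(0)
    t_open = sum(e - s for s, e in opens)
    lifetime = burst[1] - burst[0]
    g_po = (
        float(np.mean(np.abs(open_samples)) / p.driving_mv * 1e3)
        if len(open_samples)
        else float("nan")
    )
    return PoreRecord(
        start_s=burst[0],
        end_s=burst[1],
        open_periods=list(opens),
        open_samples_pa=open_samples,
        g_po_ps=g_po,
        p_open=t_open / lifetime if lifetime > 0 else 0.0,
        n_flickers=len(opens),
        driving_mv=p.driving_mv,
        resistivity=p.resistivity,
        condition=condition,
    )


def analyze_trace(
    trace: CurrentTrace,
    condition: str = "",
    cutoff_hz: float = 280.0,
    block: int = 80,
    notch_hz: tuple[float, ...] = (),
    **detect_kwargs,
) -> tuple[ProcessedTrace, list[PoreRecord]]:
    """Full per-trace pipeline: preprocess, detect bursts, build records."""
    p = preprocess(trace, cutoff_hz=cutoff_hz, block=block, notch_hz=notch_hz)
    records = [
        pore_record(p, burst, condition=condition)
        for burst in detect_bursts(p, **detect_kwargs)
    ]
    return p, records


# ---------------------------------------------------------------------------
# conductance <-> radius
# ---------------------------------------------------------------------------

def radius_from_conductance(
    g_ps,
    resistivity: float = DEFAULT_RESISTIVITY,
    length_nm: float = CHANNEL_LENGTH_NM,
):
    """Pore radius (nm) of a cylindrical channel with conductance ``g_ps``.

    ``r = sqrt(rho * L * G / pi)`` with rho in Ω·m, L in nm, G in pS.
    """
    g = np.asarray(g_ps, dtype=float)
    if np.any(g < 0):
        raise ValueError("conductance must be non-negative")
    r_m = np.sqrt(resistivity * (length_nm * 1e-9) * (g * 1e-12) / np.pi)
    out = r_m * 1e9
    return float(out) if np.isscalar(g_ps) else out


def conductance_from_radius(
    r_nm,
    resistivity: float = DEFAULT_RESISTIVITY,
    length_nm: float = CHANNEL_LENGTH_NM,
):
    """Inverse of :func:`radius_from_conductance`; returns pS."""
    r = np.asarray(r_nm, dtype=float)
    g_s = np.pi * (r * 1e-9) ** 2 / (resistivity * (length_nm * 1e-9))
    out = g_s * 1e12
    return float(out) if np.isscalar(r_nm) else out


# ---------------------------------------------------------------------------
# cohort statistics
# ---------------------------------------------------------------------------

def averaged_pdf(
    samples_per_pore: list[np.ndarray],
    bin_width: float,
    lo: float | None = None,
    hi: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Equal-weight average of per-pore probability densities.

    Each pore's samples are histogrammed with the shared fixed-width
    binning and normalized to unit integral *individually*; the cohort
    density is the unweighted mean of the per-pore densities, so every pore
    contributes equally regardless of how long it stayed open.

    Returns ``(bin_edges, density)``.
    """
    pools = [np.asarray(s, dtype=float) for s in samples_per_pore if len(s)]
    if not pools:
        raise ValueError("need at least one pore with open-state samples")
    if lo is None:
        lo = min(s.min() for s in pools)
    if hi is None:
        hi = max(s.max() for s in pools)
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    densities = [np.histogram(s, bins=edges, density=True)[0] for s in pools]
    return edges, np.mean(densities, axis=0)


def energy_from_pdf(density: np.ndarray, bin_width: float) -> np.ndarray:
    """Boltzmann inversion ``U/kT = −ln(P) + A`` of a binned density.

    ``P`` is the probability mass per bin (density × bin width).  Bins with
    zero mass are returned as NaN (unvisited, energy undefined); the
    constant A is chosen so the minimum over visited bins is exactly 0.
    """
    d = np.asarray(density, dtype=float)
    if np.any(d < 0):
        raise ValueError("density must be non-negative")
    mass = d * bin_width
    if not np.any(mass > 0):
        raise ValueError("all-zero density")
    with np.errstate(divide="ignore"):
        U = np.where(mass > 0, -np.log(np.where(mass > 0, mass, 1.0)), np.nan)
    return U - np.nanmin(U)


# ---------------------------------------------------------------------------
# dwell statistics
# ---------------------------------------------------------------------------

def geometric_mean_flickers(p: float) -> float:
    """Mean of the geometric flicker-count law ``P(n) = p (1−p)^n``, n≥0."""
    if not 0 < p <= 1:
        raise ValueError("p must be in (0, 1]")
    return (1 - p) / p


def fit_flicker_geometric(
    n_flickers, confidence: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Maximum-likelihood geometric fit of per-burst flicker counts.

    For counts on support n = 0, 1, 2, … the MLE is
    ``p = 1 / (1 + mean(n))``.  The confidence interval is the normal
    approximation with the Fisher standard error
    ``se = sqrt(p² (1−p) / n_obs)``.
    """
    counts = np.asarray(n_flickers, dtype=float)
    if len(counts) == 0 or np.any(counts < 0):
        raise ValueError("need non-negative flicker counts")
    mean = counts.mean()
    p = 1.0 / (1.0 + mean)
    if mean == 0:
        return 1.0, (1.0, 1.0)
    from scipy.stats import norm

    z = norm.ppf(0.5 + confidence / 2)
    se = np.sqrt(p ** 2 * (1 - p) / len(counts))
    return float(p), (float(max(p - z * se, 0.0)), float(min(p + z * se, 1.0)))


def fit_burst_exponential(lifetimes_s) -> tuple[float, float]:
    """MLE of the exponential burst-lifetime law: (mean, standard error)."""
    t = np.asarray(lifetimes_s, dtype=float)
    if len(t) == 0 or np.any(t <= 0):
        raise ValueError("lifetimes must be positive")
    mean = float(t.mean())
    return mean, mean / np.sqrt(len(t))


def nucleation_rate(
    burst_counts,
    durations_min,
    excluded_min=None,
) -> tuple[float, np.ndarray]:
    """Pore nucleation rate, bursts/min.

    Per recording: bursts (outside excluded intervals) divided by usable
    duration; the condition-level rate is the unweighted mean over
    recordings.  Recordings with zero usable duration are dropped with a
    warning.  Returns ``(mean_rate, per_recording_rates)``.
    """
    import warnings

    counts = np.asarray(burst_counts, dtype=float)
    durations = np.asarray(durations_min, dtype=float)
    excluded = (
        np.zeros_like(durations)
        if excluded_min is None
        else np.asarray(excluded_min, dtype=float)
    )
    if counts.shape != durations.shape:
        raise ValueError("burst_counts and durations must align")
    usable = durations - excluded
    keep = usable > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} recording(s) with no usable duration",
            RuntimeWarning,
        )
    if not keep.any():
        raise ValueError("no recording with usable duration")
    rates = counts[keep] / usable[keep]
    return float(rates.mean()), rates
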
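"""Conductance-state classification and the dilation-probability curve.

Mean open-pore conductances cluster into a small-pore population
(~300 pS) and a dilated population (several nS), separated near 1 nS.
Pores are classified by that cutoff, the fraction of dilated pores per
SNARE copy number gives the dilation probability, and a two-parameter
logistic in copy number describes the transition:

    P_dil(N) = exp((N − N0)/b) / (1 + exp((N − N0)/b))

with ``N0`` the copy number at half-maximal dilation and ``b`` the
transition width.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, curve_fit
from sklearn.mixture import GaussianMixture
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "MixtureFit",
    "DilationCurve",
    "fit_conductance_mixture",
    "classify_pores",
    "dilation_probability",
    "fit_dilation_sigmoid",
    "eval_sigmoid",
    "fluctuation_ratio",
]

DEFAULT_THRESHOLD_PS = 1000.0


@dataclass(frozen=True)
class MixtureFit:
    """Two-component Gaussian mixture of mean open conductances (pS)."""

    means: tuple[float, float]        # ordered ascending
    sds: tuple[float, float]
    weights: tuple[float, float]
    boundary_ps: float | None         # responsibility crossover; None if degenerate
    responsibilities: np.ndarray      # P(component 2 | G), per input point
    log_scale: bool = False


def fit_conductance_mixture(
    g_means_ps,
    n_components: int = 2,
    log_scale: bool = False,
    seed: int = 0,
    n_init: int = 10,
) -> MixtureFit:
    """EM fit of a Gaussian mixture to per-pore mean conductances.

    Deterministic for a given ``seed`` (multi-start k-means init).  The
    small/large boundary is the conductance where the posterior
    responsibility of the upper component crosses 0.5; it is ``None`` when
    the components coincide.
    """
    g = np.asarray(g_means_ps, dtype=float)
    if len(g) < 10:
        raise ValueError("need at least 10 conductance values")
    x = np.log10(g) if log_scale else g
    gm = GaussianMixture(
        n_components=n_components,
        n_init=n_init,
        random_state=seed,
        covariance_type="full",
        reg_covar=1e-6,
    ).fit(x.reshape(-1, 1))
    order = np.argsort(gm.means_.ravel())
    means = gm.means_.ravel()[order]
    sds = np.sqrt(gm.covariances_.ravel()[order])
    weights = gm.weights_[order]
    resp = gm.predict_proba(x.reshape(-1, 1))[:, order][:, -1]

    boundary = None
    lo, hi = means[0], means[-1]
    if hi - lo > 1e-9 * max(abs(hi), 1.0):
        def diff(v):
            return gm.predict_proba(np.array([[v]]))[0, order][-1] - 0.5

        try:
            boundary = brentq(diff, lo, hi)
        except ValueError:
            boundary = None
    to_ps = (lambda v: 10 ** v) if log_scale else (lambda v: v)
    return MixtureFit(
        means=(to_ps(means[0]), to_ps(means[-1])),
        sds=(float(sds[0]), float(sds[-1])),
        weights=(float(weights[0]), float(weights[-1])),
        boundary_ps=None if boundary is None else float(to_ps(boundary)),
        responsibilities=resp,
        log_scale=log_scale,
    )


def classify_pores(g_means_ps, threshold_ps: float = DEFAULT_THRESHOLD_PS):
    """Label pores as dilated (True) iff mean conductance exceeds the
    threshold (strict inequality: exactly 1 nS is a small pore)."""
    g = np.asarray(g_means_ps, dtype=float)
    return g > threshold_ps


@dataclass(frozen=True)
class DilationCurve:
    """Dilation fractions vs SNARE copies per face, with the logistic fit."""

    n_per_face: np.ndarray
    k_large: np.ndarray
    n_total: np.ndarray
    p_dilation: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    N0: float | None = None
    b_dil: float | None = None
    r_squared: float | None = None


def dilation_probability(
    labels_by_condition: dict[float, np.ndarray],
    confidence: float = 0.95,
) -> DilationCurve:
    """Fraction of dilated pores per copy number, with Wilson intervals.

    ``labels_by_condition`` maps SNARE copies per disc face to the boolean
    dilation labels of that cohort.
    """
    n_face, k, n = [], [], []
    for copies in sorted(labels_by_condition):
        labels = np.asarray(labels_by_condition[copies], dtype=bool)
        if len(labels) == 0:
            raise ValueError(f"condition {copies} has no pores")
        n_face.append(float(copies))
        k.append(int(labels.sum()))
        n.append(len(labels))
    k = np.array(k)
    n = np.array(n)
    lo, hi = proportion_confint(k, n, alpha=1 - confidence, method="wilson")
    return DilationCurve(
        n_per_face=np.array(n_face),
        k_large=k,
        n_total=n,
        p_dilation=k / n,
        ci_low=np.asarray(lo, dtype=float),
        ci_high=np.asarray(hi, dtype=float),
    )


def eval_sigmoid(n, N0: float, b_dil: float):
    """Logistic dilation probability at copy number ``n``."""
    if b_dil <= 0:
        raise ValueError("width b_dil must be positive")
    z = (np.asarray(n, dtype=float) - N0) / b_dil
    out = 1.0 / (1.0 + np.exp(-z))
    return float(out) if np.isscalar(n) else out


def fit_dilation_sigmoid(curve: DilationCurve) -> DilationCurve:
    """Unweighted least-squares logistic fit of the dilation fractions.

    Returns a copy of the curve with ``N0``, ``b_dil`` and ``R²`` filled
    in.  Requires at least three copy-number points.
    """
    x, y = curve.n_per_face, curve.p_dilation
    if len(x) < 3:
        raise ValueError("need at least 3 copy-number points")
    span = x.max() - x.min()
    p0 = (np.interp(0.5, np.clip(y, 1e-6, 1 - 1e-6), x), max(span / 4, 1.0))
    popt, _ = curve_fit(
        lambda n, N0, b: eval_sigmoid(n, N0, b),
        x,
        y,
        p0=p0,
        bounds=([x.min() - 10 * span - 1, 1e-3], [x.max() + 10 * span + 1, 1e3]),
        maxfev=20000,
    )
    resid = y - eval_sigmoid(x, *popt)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid ** 2) / ss_tot if ss_tot > 0 else float("nan")
    return DilationCurve(
        n_per_face=curve.n_per_face,
        k_large=curve.k_large,
        n_total=curve.n_total,
        p_dilation=curve.p_dilation,
        ci_low=curve.ci_low,
        ci_high=curve.ci_high,
        N0=float(popt[0]),
        b_dil=float(popt[1]),
        r_squared=float(r2),
    )


def fluctuation_ratio(open_samples, mode: str = "rms") -> float:
    """Open-state conductance fluctuation relative to the mean.

    ``mode='rms'`` (default): rms deviation about the mean divided by the
    mean — scale-invariant, 0 for a constant conductance.
    ``mode='second_moment'``: ⟨G²⟩/⟨G⟩ (has units of conductance).
    """
    g = np.asarray(open_samples, dtype=float)
    if len(g) < 2:
        raise ValueError("need at least two open-state samples")
    mean = g.mean()
    if mode == "rms":
        return float(np.sqrt(np.mean((g - mean) ** 2)) / mean)
    if mode == "second_moment":
        return float(np.mean(g ** 2) / mean)
    raise ValueError("mode must be 'rms' or 'second_moment'")
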
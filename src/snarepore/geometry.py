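"""Toroidal fusion-pore geometry.

The pore connecting the disc to the planar membrane is an inner half-torus
parametrised by the lumen radius ``r_po`` and the membrane separation ``h``
at the disc edge.  Working on the bilayer midplane, the torus has waist
radius ``R = r_po + delta/2`` and meridional (semicircle) radius
``H = h/2 + delta/2``.

Small pores are fully toroidal.  When ``r_po + h/2 + delta >= D/2`` the
torus no longer fits inside the disc: the shape is truncated at the disc
boundary and the scaffold proteins lining the rim are twisted through an
angle ``phi``, with ``sin(phi) = (r_po + h/2 + delta − D/2)/(h/2)``.
Shapes whose arcsine argument exceeds 1 do not exist.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ModelParams


class InvalidShapeError(ValueError):
    """The requested (r_po, h) pair does not correspond to a realizable pore."""


_ARG_TOL = 1e-9  # forgiveness for round-off at the existence boundary


def twist_arg(r_po, h, params: ModelParams):
    """Argument of the arcsine defining the scaffold twist angle."""
    return (np.asarray(r_po) + np.asarray(h) / 2 + params.delta - params.D / 2) / (
        np.asarray(h) / 2
    )


def twist_angle(r_po: float, h: float, params: ModelParams) -> float:
    """Twist angle ``phi`` (rad) of the scaffold proteins at the disc rim.

    Zero in the fully toroidal regime; in the partially toroidal regime
    ``phi = arcsin((r_po + h/2 + delta − D/2)/(h/2))``.

    Raises
    ------
    InvalidShapeError
        If the arcsine argument exceeds 1 (no such shape exists).
    """
    if not r_po > 0:
        raise ValueError("r_po must be positive")
    if h < 0:
        raise ValueError("h must be non-negative")
    x = twist_arg(r_po, h, params)
    if x > 1 + _ARG_TOL:
        raise InvalidShapeError(
            f"no pore shape exists for r_po={r_po}, h={h}: arcsin argument {x:.3f} > 1"
        )
    return float(np.arcsin(min(x, 1.0))) if x > 0 else 0.0


def twist_angle_grid(r_po, h, params: ModelParams):
    """Vectorised twist angle with validity masks.

    Returns
    -------
    phi : ndarray
        Twist angle, 0 where toroidal.
    partial : ndarray of bool
        True where the shape is partially toroidal.
    valid : ndarray of bool
        False where no shape exists (arcsine argument > 1).
    """
    x = twist_arg(r_po, h, params)
    valid = x <= 1.0 + _ARG_TOL
    partial = (x > 0.0) & valid
    phi = np.where(partial, np.arcsin(np.clip(x, 0.0, 1.0)), 0.0)
    return phi, partial, valid


@dataclass(frozen=True)
class PoreShape:
    """A single realizable pore shape with derived midplane quantities."""

    r_po: float
    h: float
    phi: float
    partial: bool
    H: float
    R: float
    h_po: float

    @classmethod
    def from_rh(cls, r_po: float, h: float, params: ModelParams) -> "PoreShape":
        phi = twist_angle(r_po, h, params)
        partial = phi > 0.0
        # membrane separation at the disc edge; equals h while toroidal
        h_po = h / 2 * (1 + np.cos(phi)) if partial else h
        return cls(
            r_po=r_po,
            h=h,
            phi=phi,
            partial=partial,
            H=h / 2 + params.delta / 2,
            R=r_po + params.delta / 2,
            h_po=float(h_po),
        )

    @property
    def regime(self) -> str:
        return "partial" if self.partial else "toroidal"
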
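"""Model parameters for the nanodisc–membrane fusion pore.

:class:`ModelParams` is the single source of truth for the physical
constants of the equilibrium pore model: membrane elasticity, inter-membrane
hydration repulsion, the scaffold (ApoE) twisting torque, and the SNARE
zippering thermodynamics.  Defaults are the best-fit / measured values for a
~24 nm ApoE-scaffolded nanolipoprotein disc fusing with a planar plasma
membrane.

Parameters may be loaded from / saved to a YAML mapping that uses the same
field names.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import units


@dataclass(frozen=True)
class ModelParams:
    """Physical parameters of the fusion-pore free-energy model.

    Attributes
    ----------
    b_snare:
        Thickness (diameter) of the zippered SNARE transmembrane bundle, nm.
    eps_zip:
        Free energy released when a partially zippered SNARE complex
        completes zippering of its linkers and TMDs, kT.
    delta:
        Bilayer thickness, nm.
    D:
        Nanodisc diameter, nm.
    lam_hyd:
        Decay length of the inter-membrane steric-hydration repulsion, nm.
    P0:
        Hydration pressure prefactor, dyn/cm² (converted internally).
    tau:
        Torque per unit length resisting twisting of the ApoE scaffold
        proteins at the disc rim, pN.
    kappa:
        Membrane bending modulus, kT.
    gamma:
        Membrane tension, pN/nm.
    omega_z:
        Solid angle explored by the stiff zippered SNARE rods, steradian.
    omega_uz:
        Orientational freedom of partially zippered (Y-shaped) SNAREs,
        steradian.  Default 2π: all orientations in the half-space that do
        not intersect the membrane.
    T:
        Absolute temperature for kT↔pN conversions, K.
    distinguishable_snares:
        If True, drop the 1/Nz! indistinguishability factor from the
        zippered-ring positional entropy (the expansion force −∂U/∂r is
        identical either way; the relative weight of high-Nz states is not).
    """

    b_snare: float = 2.0
    eps_zip: float = 9.6
    delta: float = 5.0
    D: float = 24.0
    lam_hyd: float = 0.10
    P0: float = 5.0e11
    tau: float = 8.43
    kappa: float = 20.0
    gamma: float = 0.66
    omega_z: float = 0.05
    omega_uz: float = 2.0 * math.pi
    T: float = units.DEFAULT_TEMPERATURE_K
    distinguishable_snares: bool = False

    def __post_init__(self) -> None:
        positive = (
            "b_snare eps_zip delta D lam_hyd P0 tau kappa gamma "
            "omega_z omega_uz T"
        ).split()
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if not self.delta < self.D:
            raise ValueError("bilayer thickness delta must be < disc diameter D")
        if not self.lam_hyd < self.delta / 10:
            raise ValueError("hydration decay length must satisfy lam_hyd << delta")

    # -- derived, cached conversions -------------------------------------

    @property
    def kT_pN_nm(self) -> float:
        """Thermal energy in pN·nm at the configured temperature."""
        return units.kT_pN_nm(self.T)

    @property
    def P0_kT_nm3(self) -> float:
        """Hydration prefactor converted to kT/nm³."""
        return units.dyn_cm2_to_kT_nm3(self.P0, self.T)

    @property
    def gamma_kT_nm2(self) -> float:
        """Membrane tension in kT/nm²."""
        return self.gamma / self.kT_pN_nm

    @property
    def tau_kT_nm(self) -> float:
        """Scaffold torque per unit length in kT/nm."""
        return self.tau / self.kT_pN_nm

    @property
    def r_max(self) -> float:
        """Largest pore radius with any admissible shape, D/2 − delta (nm)."""
        return self.D / 2 - self.delta

    # -- serialization ----------------------------------------------------

    def replace(self, **changes) -> "ModelParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelParams":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def digest(self) -> str:
        """Short stable hash of the parameter set, for provenance blocks."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
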
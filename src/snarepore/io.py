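"""Plain-text input/output for traces, profiles and pore records."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .params import ModelParams
from .profile import FreeEnergyProfile
from .traces import CurrentTrace, PoreRecord

__all__ = [
    "read_trace_csv",
    "write_trace_csv",
    "read_profile",
    "write_profile",
    "records_to_frame",
    "write_records_csv",
]


def write_trace_csv(trace: CurrentTrace, path: str | Path) -> None:
    """Write a trace as two-column delimited text with a metadata header."""
    path = Path(path)
    t = np.arange(len(trace.samples)) / trace.rate
    header = (
        f"# rate_hz={trace.rate}\n"
        f"# driving_mv={trace.driving_mv}\n"
        f"# resistivity_ohm_m={trace.resistivity}\n"
        "time_s,current_pa"
    )
    np.savetxt(
        path,
        np.column_stack([t, trace.samples]),
        delimiter=",",
        header=header,
        comments="",
        fmt=["%.6f", "%.5f"],
    )


def read_trace_csv(path: str | Path) -> CurrentTrace:
    """Read a trace written by :func:`write_trace_csv` (or any two-column
    time/current file; the rate is inferred from the time column if no
    metadata header is present)."""
    path = Path(path)
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                key, val = line.lstrip("# ").strip().split("=", 1)
                meta[key] = float(val)
    data = np.loadtxt(path, delimiter=",", comments="#", skiprows=_n_header(path))
    t, current = data[:, 0], data[:, 1]
    rate = meta.get("rate_hz")
    if rate is None:
        rate = 1.0 / np.median(np.diff(t))
    return CurrentTrace(
        samples=current,
        rate=float(rate),
        driving_mv=float(meta.get("driving_mv", 16.0)),
        resistivity=float(meta.get("resistivity_ohm_m", 0.60)),
        meta={"path": str(path)},
    )


def _n_header(path: Path) -> int:
    n = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.strip().startswith("time"):
                n += 1
            else:
                break
    return n


def write_profile(profile: FreeEnergyProfile, path: str | Path,
                  extra: dict | None = None) -> None:
    """Write a profile as 2-column text plus a JSON metadata sidecar."""
    path = Path(path)
    np.savetxt(
        path,
        np.column_stack([profile.grid, profile.U]),
        delimiter="\t",
        header="r_po_nm\tU_kT",
        fmt="%.6f",
    )
    from .profile import net_inward_force

    meta = {
        "N": profile.N,
        "params_digest": profile.params.digest(),
        "argmin_nm": profile.argmin_radius,
        "net_inward_force_pN": net_inward_force(profile),
    }
    if extra:
        meta.update(extra)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def read_profile(path: str | Path, N: int = 0,
                 params: ModelParams | None = None) -> FreeEnergyProfile:
    """Read a 2-column (r_po_nm, U_kT) delimited text profile."""
    data = np.loadtxt(path, comments="#", delimiter=None)
    return FreeEnergyProfile(
        grid=data[:, 0],
        U=data[:, 1],
        N=N,
        params=params or ModelParams(),
    )


def records_to_frame(records: list[PoreRecord]) -> pd.DataFrame:
    """Tidy per-pore summary table (one row per burst)."""
    return pd.DataFrame(
        [
            {
                "condition": r.condition,
                "start_s": r.start_s,
                "end_s": r.end_s,
                "lifetime_s": r.lifetime_s,
                "n_flickers": r.n_flickers,
                "p_open": r.p_open,
                "g_po_ps": r.g_po_ps,
                "n_open_samples": len(r.open_samples_pa),
            }
            for r in records
        ]
    )


def write_records_csv(records: list[PoreRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)
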
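"""Readers and writers for the package's file dialects.

Sweeps travel as RFC-4180 CSV with columns ``time_ms``, ``current`` and
``voltage_mV`` plus an optional JSON annotation sidecar (same stem,
``.json`` extension).  Coordinate trajectories travel as multi-model PDB
(MODEL/ENDMDL records), parsed and written through biotite.
"""

from __future__ import annotations

import json
from pathlib import Path

import biotite.structure as struc
import biotite.structure.io.pdb as pdb
import numpy as np
import pandas as pd

from .errors import DataError, FormatError, SchemaError
from .md import FrameSeries
from .traces import Sweep

__all__ = [
    "read_sweep_table",
    "write_sweep_table",
    "read_sweep_dir",
    "read_structure_frames",
    "write_structure_frames",
]

SWEEP_COLUMNS = ("time_ms", "current", "voltage_mV")


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def read_sweep_table(path: str | Path) -> Sweep:
    """Read one sweep CSV (+ optional JSON annotation sidecar)."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    for col in SWEEP_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"sweep table {path.name} missing column '{col}'")
    t = df["time_ms"].to_numpy(dtype=float)
    if np.any(~np.isfinite(t)) or np.any(np.diff(t) <= 0):
        raise DataError(f"time_ms in {path.name} must be finite and strictly increasing")
    annotations = {}
    if _sidecar(path).exists():
        annotations = json.loads(_sidecar(path).read_text())
    return Sweep(
        times=t,
        current=df["current"].to_numpy(dtype=float),
        voltage=df["voltage_mV"].to_numpy(dtype=float),
        annotations=annotations,
    )


def write_sweep_table(sweep: Sweep, path: str | Path) -> None:
    """Write a sweep CSV plus its JSON annotation sidecar."""
    path = Path(path)
    pd.DataFrame(
        {"time_ms": sweep.times, "current": sweep.current, "voltage_mV": sweep.voltage}
    ).to_csv(path, index=False, float_format="%.17g")  # round-trips float64 exactly
    _sidecar(path).write_text(json.dumps(sweep.annotations, indent=2, default=float))


def read_sweep_dir(directory: str | Path) -> list[Sweep]:
    """Read every ``*.csv`` sweep in a directory, sorted by filename."""
    directory = Path(directory)
    return [read_sweep_table(p) for p in sorted(directory.glob("*.csv"))]


def read_structure_frames(
    path: str | Path, frame_interval_ns: float = 1.0
) -> FrameSeries:
    """Read a multi-model PDB into a :class:`FrameSeries`.

    All models must contain the same atoms in the same order; model
    indices define the frame order.
    """
    path = Path(path)
    pdb_file = pdb.PDBFile.read(str(path))
    try:
        stack = pdb_file.get_structure()
    except Exception as exc:
        raise FormatError(f"inconsistent models in {path.name}: {exc}") from exc
    if isinstance(stack, struc.AtomArray):  # single model
        stack = struc.stack([stack])
    atoms = pd.DataFrame(
        {
            "resid": stack.res_id,
            "name": stack.atom_name,
            "resname": stack.res_name,
            "chain": stack.chain_id,
        }
    )
    return FrameSeries(
        coords=np.asarray(stack.coord, dtype=float),
        atoms=atoms,
        frame_interval_ns=frame_interval_ns,
    )


def write_structure_frames(traj: FrameSeries, path: str | Path) -> None:
    """Write a :class:`FrameSeries` as a multi-model PDB."""
    n = traj.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = traj.coords[0]
    arr.res_id = traj.atoms["resid"].to_numpy(dtype=int)
    arr.atom_name = traj.atoms["name"].to_numpy(dtype="U6")
    arr.res_name = traj.atoms.get("resname", pd.Series(["UNK"] * n)).to_numpy(dtype="U5")
    arr.chain_id = traj.atoms.get("chain", pd.Series(["A"] * n)).to_numpy(dtype="U4")
    arr.element = np.array([name[0] for name in traj.atoms["name"]], dtype="U2")
    stack = struc.stack([arr] * traj.n_frames)
    stack.coord = traj.coords
    out = pdb.PDBFile()
    out.set_structure(stack)
    out.write(str(Path(path)))
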
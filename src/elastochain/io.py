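"""File formats: Cα-trace PDB trajectories and the pipeline's CSV schemas.

PDB files are multi-model Cα traces (one ``CA`` atom per residue, chain A,
1-based residue numbers, occupancy 1.00, B-factor 0.00) written and read via
biotite; coordinates round-trip at the format's 3-decimal precision. CSV
schemas:

* scalar series (per trajectory): ``frame, time_ps, L_A, rmsd_A``
* per-force summary: ``force_pN, mean_L_A, sd_L_A, n_frames_equilibrated, seed``
* replicate table: ``trajectory, mean_L_A, sd_L_A`` plus a summary row

Frame indices in CSV are 0-based; PDB model numbers are 1-based.
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Optional, Union

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .simulate import Conformation, Trajectory
from .trajectory import EquilibriumSummary, ScalarSeries

__all__ = [
    "write_trajectory_pdb",
    "write_conformation_pdb",
    "read_trajectory_pdb",
    "read_conformation_pdb",
    "write_series_csv",
    "read_series_csv",
    "write_summary_csv",
    "read_summary_csv",
    "write_replicate_table_csv",
]

PathLike = Union[str, Path]

SERIES_COLUMNS = ["frame", "time_ps", "L_A", "rmsd_A"]
SUMMARY_COLUMNS = ["force_pN", "mean_L_A", "sd_L_A", "n_frames_equilibrated", "seed"]


def _stack_from_frames(frames: np.ndarray) -> struc.AtomArrayStack:
    n_frames, n_beads, _ = frames.shape
    stack = struc.AtomArrayStack(n_frames, n_beads)
    stack.coord = np.asarray(frames, dtype=np.float32)
    stack.chain_id = np.full(n_beads, "A")
    stack.res_id = np.arange(1, n_beads + 1)
    stack.res_name = np.full(n_beads, "GLY")
    stack.atom_name = np.full(n_beads, "CA")
    stack.element = np.full(n_beads, "C")
    stack.hetero = np.full(n_beads, False)
    stack.occupancy = np.ones(n_beads, dtype=np.float32)
    stack.b_factor = np.zeros(n_beads, dtype=np.float32)
    return stack


def write_trajectory_pdb(traj: Trajectory, path: PathLike) -> None:
    """Write a trajectory as a multi-model (MODEL/ENDMDL) Cα-trace PDB."""
    pdb = PDBFile()
    pdb.set_structure(_stack_from_frames(traj.frames))
    pdb.write(str(path))


def write_conformation_pdb(conf: Conformation, path: PathLike) -> None:
    """Write a single conformation as a one-model Cα-trace PDB."""
    pdb = PDBFile()
    pdb.set_structure(_stack_from_frames(conf.coordinates[None, :, :]))
    pdb.write(str(path))


def read_trajectory_pdb(path: PathLike, frame_times: Optional[np.ndarray] = None) -> np.ndarray:
    """Read all models of a Cα-trace PDB as a coordinate array (n_frames, n_beads, 3).

    PDB carries no time axis; pair with the scalar-series CSV for frame times.
    """
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)
    ca = stack[:, stack.atom_name == "CA"] if "CA" in stack.atom_name else stack
    return np.asarray(ca.coord, dtype=float)


def read_conformation_pdb(path: PathLike, model: int = 1) -> Conformation:
    """Read one model of a Cα-trace PDB as a :class:`Conformation`."""
    pdb = PDBFile.read(str(path))
    arr = pdb.get_structure(model=model)
    arr = arr[arr.atom_name == "CA"] if "CA" in arr.atom_name else arr
    return Conformation(np.asarray(arr.coord, dtype=float))


def write_series_csv(
    path: PathLike, l_series: ScalarSeries, rmsd: Optional[ScalarSeries] = None
) -> None:
    """Write per-frame scalars as ``frame, time_ps, L_A, rmsd_A`` (rmsd blank if absent)."""
    df = pd.DataFrame(
        {
            "frame": l_series.frames,
            "time_ps": l_series.frame_times,
            "L_A": l_series.values,
            "rmsd_A": rmsd.values if rmsd is not None else np.nan,
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")


def read_series_csv(path: PathLike) -> pd.DataFrame:
    """Read a scalar-series CSV, validating its schema."""
    df = pd.read_csv(path)
    missing = [c for c in SERIES_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing scalar-series columns {missing}")
    return df


def series_from_frame(df: pd.DataFrame, column: str = "L_A") -> ScalarSeries:
    """Build a :class:`ScalarSeries` from a scalar-series DataFrame column."""
    values = df[column].to_numpy(dtype=float)
    keep = np.isfinite(values)
    return ScalarSeries(
        values=values[keep],
        frame_times=df["time_ps"].to_numpy(dtype=float)[keep],
        frames=df["frame"].to_numpy(dtype=int)[keep],
    )


def write_summary_csv(path: PathLike, rows: pd.DataFrame) -> None:
    """Write the per-force summary CSV (schema ``SUMMARY_COLUMNS``)."""
    missing = [c for c in SUMMARY_COLUMNS if c not in rows.columns]
    if missing:
        raise ValueError(f"summary rows missing columns {missing}")
    rows[SUMMARY_COLUMNS].to_csv(path, index=False, float_format="%.6f")


def read_summary_csv(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing per-force summary columns {missing}")
    return df


def write_replicate_table_csv(path: PathLike, summary: EquilibriumSummary) -> None:
    """Write the replicate table: one row per trajectory plus a mean ± SEM row."""
    rows: List[dict] = [
        {"trajectory": f"Trajectory {i + 1}", "mean_L_A": m, "sd_L_A": s}
        for i, (m, s, _) in enumerate(summary.per_trajectory)
    ]
    rows.append(
        {
            "trajectory": "Mean",
            "mean_L_A": summary.grand_mean,
            "sd_L_A": summary.grand_spread if summary.grand_spread is not None else "",
        }
    )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6f")
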
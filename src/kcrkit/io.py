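"""Readers, writers, configuration and run manifests.

Tabular data travel as UTF-8 CSV with '.' decimal separators and unit-bearing
column headers (time_s, v_-96_mV, wavelength_nm ...). Trajectory topology is
standard fixed-column PDB (parsed with biotite); coordinate frames are
concatenated XYZ (parsed with MDAnalysis). Every run can write a manifest of
output checksums so re-runs are verifiable.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

import biotite.structure as bstruct
import biotite.structure.io.pdb as bpdb

from .constants import DEFAULT_TEMPERATURE_K
from .iontransport import IVRecording, SolutionPair
from .photocycle import GROUND, PhotocycleScheme, TransientAbsorptionCube
from .traj import ATOM_COLUMNS, TrajectoryBundle

__all__ = [
    "TableSchemaError", "read_csv_table", "write_csv_table",
    "read_iv_recording", "write_iv_recording",
    "read_cube", "write_cube", "read_scheme", "write_scheme",
    "read_pdb_topology", "read_xyz_frames", "write_pdb_topology",
    "write_xyz_frames", "read_trajectory",
    "RunConfig", "load_config", "write_manifest", "verify_manifest",
]

FLOAT_FORMAT = "%.12g"


class TableSchemaError(ValueError):
    """CSV content does not match the expected schema."""


# ---------------------------------------------------------------------------
# generic CSV tables
# ---------------------------------------------------------------------------

def read_csv_table(path, schema: list[str] | None = None) -> pd.DataFrame:
    """Read a numeric CSV table, validating header and cell types.

    Missing schema columns and non-numeric cells raise
    :class:`TableSchemaError` citing the offending row/column (rows are
    1-based data rows, excluding the header).
    """
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    if schema is not None:
        missing = [c for c in schema if c not in df.columns]
        if missing:
            raise TableSchemaError(
                f"{path}: missing column(s) {missing}; found {list(df.columns)}")
    out = {}
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise TableSchemaError(
                f"{path}: non-numeric cell at row {row}, column {col!r}: "
                f"{df[col].iloc[row - 1]!r}")
        out[col] = converted.astype(float)
    return pd.DataFrame(out)


def write_csv_table(path, df: pd.DataFrame) -> None:
    """Write CSV with 12 significant digits (read o write = identity)."""
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# I-V recordings
# ---------------------------------------------------------------------------

_VCOL = re.compile(r"^v_(-?\d+(?:\.\d+)?)_mV$")


def write_iv_recording(csv_path, rec: IVRecording,
                       sidecar_path=None, solutions: SolutionPair | None = None) -> None:
    """CSV with `time_s, v_<mV>_mV...` columns plus a metadata sidecar JSON."""
    data = {"time_s": rec.time_s}
    for v, trace in zip(rec.voltages_mV, rec.currents_pA):
        data[f"v_{v:g}_mV"] = trace
    write_csv_table(csv_path, pd.DataFrame(data))
    if sidecar_path is None:
        sidecar_path = str(csv_path) + ".json"
    meta = {
        "light_on_s": rec.light_on_s, "light_off_s": rec.light_off_s,
        "sampling_rate_hz": rec.sampling_rate_hz,
        "junction_corrected": rec.junction_corrected,
    }
    if solutions is not None:
        meta["solutions"] = {"outer_mM": solutions.outer,
                             "inner_mM": solutions.inner,
                             "temperature_K": solutions.temperature}
    Path(sidecar_path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def read_iv_recording(csv_path, sidecar_path=None
                      ) -> tuple[IVRecording, SolutionPair | None]:
    df = read_csv_table(csv_path)
    if "time_s" not in df.columns:
        raise TableSchemaError(f"{csv_path}: missing 'time_s' column")
    volts, traces = [], []
    for col in df.columns:
        m = _VCOL.match(col)
        if m:
            volts.append(float(m.group(1)))
            traces.append(df[col].to_numpy())
    if not volts:
        raise TableSchemaError(f"{csv_path}: no v_<mV>_mV step columns found")
    order = np.argsort(volts)
    if sidecar_path is None:
        sidecar_path = str(csv_path) + ".json"
    meta = json.loads(Path(sidecar_path).read_text())
    rec = IVRecording(
        df["time_s"].to_numpy(), np.asarray(volts)[order],
        np.asarray(traces)[order], meta["light_on_s"], meta["light_off_s"],
        meta["sampling_rate_hz"], meta.get("junction_corrected", False))
    sol = None
    if "solutions" in meta:
        s = meta["solutions"]
        sol = SolutionPair(s["outer_mM"], s["inner_mM"],
                           s.get("temperature_K", DEFAULT_TEMPERATURE_K))
    return rec, sol


# ---------------------------------------------------------------------------
# transient-absorption cubes and schemes
# ---------------------------------------------------------------------------

def write_cube(path, cube: TransientAbsorptionCube) -> None:
    """First column wavelength_nm; remaining columns named by time (s)."""
    data = {"wavelength_nm": cube.wavelengths_nm}
    for j, t in enumerate(cube.times_s):
        data[f"{t:.9g}"] = cube.delta_A[:, j]
    write_csv_table(path, pd.DataFrame(data))


def read_cube(path) -> TransientAbsorptionCube:
    df = read_csv_table(path)
    if df.columns[0] != "wavelength_nm":
        raise TableSchemaError(f"{path}: first column must be wavelength_nm")
    times = np.array([float(c) for c in df.columns[1:]])
    return TransientAbsorptionCube(
        df["wavelength_nm"].to_numpy(), times,
        df.iloc[:, 1:].to_numpy())


def write_scheme(path, scheme: PhotocycleScheme) -> None:
    doc = {
        "species": [s for s in scheme.species if s != scheme.ground],
        "ground": scheme.ground,
        "edges": [{"from": a, "to": b, "rate_s-1": k}
                  for (a, b), k in scheme.rates.items()],
        "initial": scheme.initial,
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_scheme(path) -> PhotocycleScheme:
    doc = json.loads(Path(path).read_text())
    rates = {(e["from"], e["to"]): e.get("rate_s-1") for e in doc["edges"]}
    return PhotocycleScheme(list(doc["species"]), rates, dict(doc["initial"]),
                            doc.get("ground", GROUND))


# ---------------------------------------------------------------------------
# structures and trajectories
# ---------------------------------------------------------------------------

def read_pdb_topology(path) -> pd.DataFrame:
    """Atom table from fixed-column PDB ATOM/HETATM records (biotite)."""
    pdb = bpdb.PDBFile.read(str(path))
    arr = pdb.get_structure(model=1)
    return pd.DataFrame({
        "index": np.arange(arr.array_length()),
        "name": arr.atom_name,
        "resname": arr.res_name,
        "resnum": arr.res_id,
        "chain": arr.chain_id,
        "element": arr.element,
    }, columns=list(ATOM_COLUMNS))


def write_pdb_topology(path, atoms: pd.DataFrame,
                       coords: np.ndarray | None = None) -> None:
    n = len(atoms)
    arr = bstruct.AtomArray(n)
    arr.coord = np.zeros((n, 3)) if coords is None else np.asarray(coords, float)
    arr.atom_name = atoms["name"].to_numpy(dtype="U6")
    arr.res_name = atoms["resname"].to_numpy(dtype="U5")
    arr.res_id = atoms["resnum"].to_numpy(dtype=int)
    arr.chain_id = atoms["chain"].to_numpy(dtype="U4")
    arr.element = atoms["element"].to_numpy(dtype="U2")
    arr.hetero = ~np.isin(arr.res_name, ("ALA", "ARG", "ASN", "ASP", "CYS",
                                         "GLN", "GLU", "GLY", "HIS", "ILE",
                                         "LEU", "LYS", "MET", "PHE", "PRO",
                                         "SER", "THR", "TRP", "TYR", "VAL"))
    f = bpdb.PDBFile()
    f.set_structure(arr)
    f.write(str(path))


def write_xyz_frames(path, atoms: pd.DataFrame, coords: np.ndarray) -> None:
    """Concatenated XYZ frames with fixed numeric formatting."""
    names = atoms["element"].tolist()
    with open(path, "w") as fh:
        for f in range(coords.shape[0]):
            fh.write(f"{len(names)}\nframe {f}\n")
            for name, (x, y, z) in zip(names, coords[f]):
                fh.write(f"{name:<2s} {x:15.6f} {y:15.6f} {z:15.6f}\n")


def read_xyz_frames(path, n_atoms: int | None = None) -> np.ndarray:
    """Coordinate frames (n_frames, n_atoms, 3) from concatenated XYZ."""
    from MDAnalysis.coordinates.XYZ import XYZReader

    # structural check first: a truncated trailing frame must be an error,
    # not a silently shorter trajectory
    with open(path) as fh:
        n_lines = sum(1 for line in fh if line.strip())
        fh.seek(0)
        declared = int(fh.readline().split()[0])
    if n_lines % (declared + 2):
        raise ValueError(
            f"{path}: {n_lines} non-blank lines is not a whole number of "
            f"frames of {declared} atoms (truncated file?)")

    reader = XYZReader(str(path))
    frames = np.array([ts.positions.copy() for ts in reader], dtype=float)
    reader.close()
    if n_atoms is not None and frames.shape[1] != n_atoms:
        raise ValueError(
            f"{path}: XYZ frames have {frames.shape[1]} atoms but the "
            f"topology defines {n_atoms}")
    return frames


def read_trajectory(pdb_path, xyz_path,
                    frame_interval_ps: float | None = None) -> TrajectoryBundle:
    atoms = read_pdb_topology(pdb_path)
    coords = read_xyz_frames(xyz_path, n_atoms=len(atoms))
    return TrajectoryBundle(atoms, coords, frame_interval_ps)


# ---------------------------------------------------------------------------
# run configuration and manifests
# ---------------------------------------------------------------------------

class RunConfig(BaseModel):
    """Schema-validated run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    inputs: dict[str, str] = Field(default_factory=dict)
    params: dict = Field(default_factory=dict)
    output_dir: str = "."
    log_level: str = "INFO"
    seed: int = 20230830


def load_config(path) -> RunConfig:
    return RunConfig.model_validate(json.loads(Path(path).read_text()))


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class Manifest:
    files: dict[str, str]
    tool_version: str
    timestamp: str
    truth: str | None = None


def write_manifest(directory, files: list[str], *, truth: str | None = None,
                   timestamp: str = "") -> Path:
    from . import __version__

    directory = Path(directory)
    doc = {
        "files": {name: _sha256(directory / name) for name in sorted(files)},
        "tool_version": __version__,
        "timestamp": timestamp,
        "truth": truth,
    }
    out = directory / "manifest.json"
    out.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    return out


def verify_manifest(directory) -> bool:
    directory = Path(directory)
    doc = json.loads((directory / "manifest.json").read_text())
    return all(_sha256(directory / name) == digest
               for name, digest in doc["files"].items())
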
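"""Structure and table I/O plus run configuration.

PDB files carry coordinates in Å; everything inside the package is in nm, so
coordinates are multiplied by 0.1 on ingestion and by 10 on export.  Each
MODEL of a multi-model PDB is treated as one trajectory frame.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "RunConfig",
    "StructureFrames",
    "read_structure",
    "write_structure",
    "trace_to_csv",
    "axis_points_to_csv",
    "axis_points_to_pdb",
    "write_descriptors_csv",
    "write_profiles_csv",
    "write_selection",
    "write_sidecar",
]

ANGSTROM_PER_NM = 10.0


@dataclass
class RunConfig:
    """Resolved configuration of one run; written into output metadata."""

    degree: int = 2
    contact_cutoff_nm: float = 1.4
    stability_cutoff: float = 0.5
    quadrature_points: int = 100
    moving_average_window: int = 51
    orientation_policy: str = "auto"
    torsion_derivative_convention: str = "corrected"
    seed: Optional[int] = None

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = open(path).read()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            payload = yaml.safe_load(text)
        else:
            payload = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class StructureFrames:
    """Per-frame Cα coordinates (nm) with residue labels."""

    coords: np.ndarray  # (F, N, 3), nm
    residue_ids: np.ndarray  # (N,)
    chain_ids: np.ndarray  # (N,)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return self.coords.shape[1]

    def trace(self, frame: int = 0):
        from .synthetic import HelixTrace

        return HelixTrace(self.coords[frame], residue_ids=self.residue_ids)

    def traces(self):
        return [self.trace(f) for f in range(self.n_frames)]


def _parse_residue_range(spec: Optional[str]) -> Optional[Tuple[int, int]]:
    if spec is None:
        return None
    lo, _, hi = spec.partition(":")
    return int(lo), int(hi)


def read_structure(
    path,
    chain: Optional[str] = None,
    residue_range: Optional[str] = None,
) -> StructureFrames:
    """Read Cα coordinates from a single- or multi-model PDB.

    ``residue_range`` is an inclusive "first:last" selection on 1-based PDB
    residue numbers.  Residues of the selection missing a Cα atom are
    reported explicitly.
    """
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)
    mask = stack.atom_name == "CA"
    if chain is not None:
        mask &= stack.chain_id == chain
    rng = _parse_residue_range(residue_range)
    if rng is not None:
        mask &= (stack.res_id >= rng[0]) & (stack.res_id <= rng[1])
    if not mask.any():
        raise InputError(f"no Cα atoms match the selection in {path}")
    coords = stack.coord[:, mask, :] / ANGSTROM_PER_NM
    res_ids = stack.res_id[mask]
    chain_ids = stack.chain_id[mask]
    if rng is not None:
        missing = sorted(set(range(rng[0], rng[1] + 1)) - set(res_ids.tolist()))
        if missing:
            raise InputError(
                f"selection {rng[0]}:{rng[1]} is missing Cα atoms for residues {missing}"
            )
    return StructureFrames(coords=coords, residue_ids=res_ids, chain_ids=chain_ids)


def write_structure(
    path,
    coords_nm: np.ndarray,
    residue_ids: Optional[np.ndarray] = None,
    chain_id: str = "A",
    res_name: str = "ALA",
    atom_name: str = "CA",
) -> None:
    """Write (F, N, 3) nm coordinates as a Cα-only (multi-)model PDB."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    coords = np.asarray(coords_nm, dtype=float)
    if coords.ndim == 2:
        coords = coords[None, :, :]
    F, N, _ = coords.shape
    if residue_ids is None:
        residue_ids = np.arange(1, N + 1)

    template = struc.AtomArray(N)
    template.coord = coords[0] * ANGSTROM_PER_NM
    template.chain_id = np.full(N, chain_id)
    template.res_id = np.asarray(residue_ids, dtype=int)
    template.res_name = np.full(N, res_name)
    template.atom_name = np.full(N, atom_name)
    template.element = np.full(N, "C")
    template.hetero = np.zeros(N, dtype=bool)
    template.set_annotation("occupancy", np.ones(N))
    template.set_annotation("b_factor", np.zeros(N))

    arrays = []
    for f in range(F):
        arr = template.copy()
        arr.coord = coords[f] * ANGSTROM_PER_NM
        arrays.append(arr)
    stack = struc.stack(arrays)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def trace_to_csv(trace, path) -> None:
    """Plain CSV export (k, x, y, z) of a helix trace, nm."""
    df = pd.DataFrame(trace.coords, columns=["x", "y", "z"])
    df.insert(0, "k", np.arange(1, trace.n_atoms + 1))
    df.to_csv(path, index=False)


def axis_points_to_csv(axis, path) -> None:
    """CSV export (u, x, y, z) of fragment-fitted axis points, nm."""
    df = pd.DataFrame(axis.points, columns=["x", "y", "z"])
    df.insert(0, "u", axis.u_values)
    df.to_csv(path, index=False)


def axis_points_to_pdb(axis, path) -> None:
    """Axis points as pseudo-atoms for visualization."""
    write_structure(path, axis.points[None, :, :], res_name="AXI")


def write_descriptors_csv(series, path) -> None:
    """One CSV row of groove descriptors per successfully analysed frame."""
    series.to_dataframe().to_csv(path, index=False)


def write_profiles_csv(series, path) -> None:
    """Long-format distance/torsion profiles per frame."""
    series.profiles_dataframe().to_csv(path, index=False)


def write_selection(profile, result, csv_path, segments_path=None) -> None:
    """Stability selection as CSV plus an optional segment-list JSON."""
    selected = np.isin(profile.residue_ids, result.selected_residues)
    profile.to_dataframe(selected=selected).to_csv(csv_path, index=False)
    if segments_path is not None:
        payload = {
            "segments": [list(seg) for seg in result.segments],
            "warnings": result.warnings,
        }
        with open(segments_path, "w") as fh:
            json.dump(payload, fh, indent=2)


def write_sidecar(path, config: RunConfig, extra: Optional[dict] = None) -> None:
    """Resolved run configuration + package version, next to the outputs."""
    from . import __version__

    payload = {"config": config.to_dict(), "helixgeom_version": __version__}
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
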
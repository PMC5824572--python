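"""Structure file formats: tabular xyz and pseudo-atom PDB export.

``xyz_tsv`` is a 4-column table (original_bin_index, x, y, z) that round-trips
coordinates to 6 decimals.  The PDB export writes one HETATM pseudo-atom per
bead for molecular viewers, isotropically rescaled into a 100-unit bounding
box so coordinates fit the fixed-width PDB fields, with CONECT records
linking genomically consecutive beads; a filtered (gap) bin breaks the chain.
"""

from __future__ import annotations

import json

import numpy as np

from .model import Structure3D

__all__ = ["write_structure", "read_structure", "probe_distance", "write_manifest"]

_PDB_BOX = 100.0


def write_structure(s: Structure3D, path, format: str = "xyz_tsv") -> None:
    """Write a structure as ``xyz_tsv`` or ``pdb``."""
    if format == "xyz_tsv":
        with open(path, "w") as fh:
            for b, (x, y, z) in zip(s.bin_map, s.coords):
                fh.write(f"{b}\t{x:.6f}\t{y:.6f}\t{z:.6f}\n")
        return
    if format == "pdb":
        coords = s.coords - s.coords.mean(axis=0)
        span = np.ptp(coords, axis=0).max()
        if span > 0:
            coords = coords * (_PDB_BOX / span)
        with open(path, "w") as fh:
            for k, (b, (x, y, z)) in enumerate(zip(s.bin_map, coords), start=1):
                fh.write(
                    f"HETATM{k:5d}  CA  BED A{int(b) + 1:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
                )
            for k in range(s.n_beads - 1):
                if s.bin_map[k + 1] - s.bin_map[k] == 1:
                    fh.write(f"CONECT{k + 1:5d}{k + 2:5d}\n")
            fh.write("END\n")
        return
    raise ValueError(f"unknown structure format {format!r}")


def read_structure(path) -> Structure3D:
    """Read an ``xyz_tsv`` structure file."""
    data = np.loadtxt(path, dtype=float, ndmin=2)
    if data.shape[1] != 4:
        raise ValueError(f"{path}: expected 4 columns (bin, x, y, z)")
    return Structure3D(data[:, 1:4], bin_map=data[:, 0].astype(int))


def probe_distance(s: Structure3D, bin_a: int, bin_b: int) -> float:
    """Euclidean distance between two original bins' beads (model units).

    Supports FISH-style closer/farther queries on a reconstructed model.
    Raises if either bin was filtered out of the model.
    """
    positions = {int(b): k for k, b in enumerate(s.bin_map)}
    try:
        ka, kb = positions[int(bin_a)], positions[int(bin_b)]
    except KeyError as exc:
        raise ValueError(
            f"bin {exc.args[0]} is not part of the model (filtered or out of range)"
        ) from None
    return float(np.linalg.norm(s.coords[ka] - s.coords[kb]))


def write_manifest(params: dict, path) -> None:
    """Record all effective parameters/seeds of a run for reproducibility."""
    with open(path, "w") as fh:
        json.dump(params, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
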
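"""Atomic model container, PDB input/output and structural deviation.

The model of choice throughout the package is a coarse-grained chain of
Cα beads (one bead per residue), but the container holds arbitrary named
atoms so that all-atom PDB entries can be read and reduced.

Coordinates are in Å.  Masses default to one reduced mass unit per bead,
consistent with the reduced-unit structure-based force field in
:mod:`nmmdfit.go_model`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

logger = logging.getLogger(__name__)

__all__ = [
    "AtomicModel",
    "PDBParseError",
    "read_pdb",
    "write_pdb",
    "write_trajectory_pdb",
    "extract_ca",
    "rmsd",
]


class PDBParseError(ValueError):
    """Raised when a PDB file cannot be parsed into a usable model."""


@dataclass
class AtomicModel:
    """A set of named atoms with coordinates.

    Parameters
    ----------
    atom_name:
        Per-atom PDB atom name (e.g. ``"CA"``).
    residue_index:
        1-based residue number, strictly increasing within a chain.
    chain_id:
        Per-atom chain identifier.
    coords:
        ``(N, 3)`` float array, Å.
    mass:
        Per-atom mass in reduced units (default 1 per bead).
    """

    atom_name: np.ndarray
    residue_index: np.ndarray
    chain_id: np.ndarray
    coords: np.ndarray
    mass: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.atom_name = np.asarray(self.atom_name, dtype=object)
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        self.chain_id = np.asarray(self.chain_id, dtype=object)
        self.coords = np.array(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (N, 3) array")
        if self.n_atoms < 1:
            raise ValueError("model must contain at least one atom")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates in model")
        if self.mass is None:
            self.mass = np.ones(self.n_atoms)
        self.mass = np.asarray(self.mass, dtype=float)
        for arr, name in [
            (self.atom_name, "atom_name"),
            (self.residue_index, "residue_index"),
            (self.chain_id, "chain_id"),
            (self.mass, "mass"),
        ]:
            if len(arr) != self.n_atoms:
                raise ValueError(f"{name} length does not match coords")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def copy(self) -> "AtomicModel":
        return AtomicModel(
            self.atom_name.copy(),
            self.residue_index.copy(),
            self.chain_id.copy(),
            self.coords.copy(),
            self.mass.copy(),
        )

    def with_coords(self, coords: np.ndarray) -> "AtomicModel":
        """Return a copy of the model with replaced coordinates."""
        out = self.copy()
        coords = np.asarray(coords, dtype=float).reshape(self.n_atoms, 3)
        out.coords = coords.copy()
        return out


def _to_atom_array(model: AtomicModel) -> struc.AtomArray:
    arr = struc.AtomArray(model.n_atoms)
    arr.coord = np.asarray(model.coords, dtype=np.float32)
    arr.atom_name = np.asarray([str(a) for a in model.atom_name])
    arr.res_id = model.residue_index
    arr.chain_id = np.asarray([str(c) for c in model.chain_id])
    arr.res_name = np.full(model.n_atoms, "ALA")
    arr.element = np.asarray(
        [str(a)[:1] if len(str(a)) > 0 else "C" for a in model.atom_name]
    )
    return arr


def _from_atom_array(arr: struc.AtomArray) -> AtomicModel:
    return AtomicModel(
        atom_name=arr.atom_name.astype(object),
        residue_index=arr.res_id.astype(int),
        chain_id=arr.chain_id.astype(object),
        coords=np.asarray(arr.coord, dtype=float),
    )


def read_pdb(path: str | Path) -> AtomicModel:
    """Read an atomic model from a PDB file.

    Only the first MODEL of a multi-model file is read.  Alternate
    locations other than blank/"A" are discarded.  Raises
    :class:`PDBParseError` when the file contains no ATOM/HETATM records
    or a record cannot be parsed.
    """
    path = Path(path)
    try:
        pdb = PDBFile.read(str(path))
        arr = pdb.get_structure(model=1, altloc="first")
    except Exception as exc:  # biotite raises a mix of exception types
        if "0 models" in str(exc):
            raise PDBParseError(
                f"empty model: no ATOM/HETATM records in {path}") from exc
        raise PDBParseError(f"cannot parse PDB file {path}: {exc}") from exc
    if arr.array_length() == 0:
        raise PDBParseError(f"empty model: no ATOM/HETATM records in {path}")
    return _from_atom_array(arr)


def write_pdb(model: AtomicModel, path: str | Path) -> None:
    """Write a model as a single-model PDB file (fixed-column format)."""
    pdb = PDBFile()
    pdb.set_structure(_to_atom_array(model))
    pdb.write(str(Path(path)))


def write_trajectory_pdb(models: list[AtomicModel], path: str | Path) -> None:
    """Write a conformational series as a multi-MODEL PDB file."""
    if not models:
        raise ValueError("no models to write")
    template = _to_atom_array(models[0])
    stack = struc.stack([_to_atom_array(m) for m in models])
    stack.atom_name = template.atom_name
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(Path(path)))


def extract_ca(model: AtomicModel) -> AtomicModel:
    """Reduce a model to its Cα trace, order preserved.

    Residues lacking a CA atom are dropped with a logged warning; each
    residue contributes at most one bead.  Raises ``ValueError`` when no
    CA atom is present.
    """
    keep = []
    seen: set[tuple[str, int]] = set()
    residues: set[tuple[str, int]] = set()
    for i in range(model.n_atoms):
        key = (str(model.chain_id[i]), int(model.residue_index[i]))
        residues.add(key)
        if str(model.atom_name[i]).strip() == "CA" and key not in seen:
            seen.add(key)
            keep.append(i)
    if not keep:
        raise ValueError("no CA atoms in model")
    missing = residues - seen
    if missing:
        logger.warning(
            "%d residue(s) lack a CA atom and were dropped: %s",
            len(missing),
            sorted(missing)[:10],
        )
    idx = np.asarray(keep, dtype=int)
    return AtomicModel(
        model.atom_name[idx],
        model.residue_index[idx],
        model.chain_id[idx],
        model.coords[idx],
        model.mass[idx],
    )


def rmsd(a: AtomicModel | np.ndarray, b: AtomicModel | np.ndarray) -> float:
    """Root-mean-square deviation between two equally sized models, Å.

    No superposition is performed; atoms are compared in order.
    """
    xa = a.coords if isinstance(a, AtomicModel) else np.asarray(a, dtype=float)
    xb = b.coords if isinstance(b, AtomicModel) else np.asarray(b, dtype=float)
    if xa.shape != xb.shape:
        raise ValueError(f"model sizes differ: {xa.shape} vs {xb.shape}")
    return float(np.sqrt(np.mean(np.sum((xa - xb) ** 2, axis=1))))
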
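"""Coordinate data model and PDB-format I/O shared by all pipeline stages.

Coordinates are in Angstrom throughout; the filament axis is +Z by
convention.  Residue numbering is 1-based and preserved on round trips.
Only C-alpha coordinates are carried as the primary representation;
backbone N-H orientations, when present, are stored as per-residue unit
vectors.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from biotite.sequence import ProteinSequence

__all__ = [
    "ProtomerStructure",
    "StructureEnsemble",
    "read_structure",
    "write_structure",
    "CHAIN_ID_ALPHABET",
]

#: Chain identifiers usable in fixed-width PDB files (62 symbols).
CHAIN_ID_ALPHABET = string.ascii_uppercase + string.ascii_lowercase + string.digits

_UNK_RESNAME = "UNK"


def _three_letter(one: str) -> str:
    try:
        return ProteinSequence.convert_letter_1to3(one).upper()
    except KeyError:
        return _UNK_RESNAME


def _one_letter(three: str) -> str:
    try:
        return ProteinSequence.convert_letter_3to1(three.upper())
    except KeyError:
        return "X"


@dataclass
class ProtomerStructure:
    """A single-chain C-alpha structure with optional N-H orientations.

    Parameters
    ----------
    residue_ids : ndarray of int
        1-based, strictly increasing residue numbers.
    sequence : str
        One-letter amino-acid string, one letter per residue.
    ca_coords : ndarray, shape (n, 3)
        C-alpha coordinates in Angstrom.
    nh_vectors : ndarray, shape (n, 3), optional
        Unit vectors giving the backbone N-H orientation per residue.
    chain_id : str
        Single-character chain identifier.
    """

    residue_ids: np.ndarray
    sequence: str
    ca_coords: np.ndarray
    nh_vectors: Optional[np.ndarray] = None
    chain_id: str = "A"

    def __post_init__(self):
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.ca_coords = np.asarray(self.ca_coords, dtype=float)
        if self.ca_coords.ndim != 2 or self.ca_coords.shape[1] != 3:
            raise ValueError("ca_coords must have shape (n, 3)")
        n = len(self.residue_ids)
        if self.ca_coords.shape[0] != n:
            raise ValueError("one C-alpha required per residue")
        if len(self.sequence) != n:
            raise ValueError("sequence length must match residue count")
        if n > 1 and not np.all(np.diff(self.residue_ids) > 0):
            raise ValueError("residue_ids must be strictly increasing")
        if self.nh_vectors is not None:
            self.nh_vectors = np.asarray(self.nh_vectors, dtype=float)
            if self.nh_vectors.shape != (n, 3):
                raise ValueError("nh_vectors must have shape (n, 3)")
            norms = np.linalg.norm(self.nh_vectors, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-6):
                raise ValueError("nh_vectors must be unit vectors (norm 1 +/- 1e-6)")

    @property
    def n_residues(self) -> int:
        return len(self.residue_ids)

    def copy(self) -> "ProtomerStructure":
        return ProtomerStructure(
            residue_ids=self.residue_ids.copy(),
            sequence=self.sequence,
            ca_coords=self.ca_coords.copy(),
            nh_vectors=None if self.nh_vectors is None else self.nh_vectors.copy(),
            chain_id=self.chain_id,
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ProtomerStructure":
        """Return a copy with ``R @ x + t`` applied to all coordinates."""
        out = self.copy()
        out.ca_coords = self.ca_coords @ np.asarray(rotation).T + np.asarray(translation)
        if out.nh_vectors is not None:
            out.nh_vectors = self.nh_vectors @ np.asarray(rotation).T
        return out

    def select_residues(self, residue_ids: Sequence[int]) -> np.ndarray:
        """Boolean mask over this structure's residues for the given ids."""
        return np.isin(self.residue_ids, np.asarray(residue_ids, dtype=int))


@dataclass
class StructureEnsemble:
    """A set of coordinate models sharing topology (numbering and length)."""

    models: list
    label: str = ""

    def __post_init__(self):
        if not self.models:
            raise ValueError("ensemble must contain at least one model")
        n0 = _model_coords(self.models[0]).shape[0]
        for m in self.models[1:]:
            if _model_coords(m).shape[0] != n0:
                raise ValueError("all ensemble models must have the same atom count")

    @property
    def n_models(self) -> int:
        return len(self.models)

    def coords_stack(self) -> np.ndarray:
        """Stacked coordinates, shape (n_models, n_atoms, 3)."""
        return np.stack([_model_coords(m) for m in self.models])

    @property
    def residue_ids(self) -> np.ndarray:
        return _model_residue_ids(self.models[0])


def _model_coords(model) -> np.ndarray:
    """C-alpha coordinates of either a protomer or a filament, (n, 3)."""
    if isinstance(model, ProtomerStructure):
        return model.ca_coords
    return model.all_coords()  # FilamentModel


def _model_residue_ids(model) -> np.ndarray:
    if isinstance(model, ProtomerStructure):
        return model.residue_ids
    return model.all_residue_ids()


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def read_structure(path: Union[str, Path], ca_only: bool = True):
    """Read a PDB file into a :class:`ProtomerStructure` or FilamentModel.

    A single-chain file yields a ``ProtomerStructure``; a multi-chain file
    with chains of identical length yields a ``FilamentModel`` whose subunit
    order follows the order of chains in the file.  If backbone N and
    amide-H atoms are present, per-residue N-H unit vectors are derived.

    Raises
    ------
    ValueError
        If a residue lacks a CA atom, insertion codes are present, or
        chains differ in length.
    """
    pdb = PDBFile.read(str(path))
    atoms = pdb.get_structure(model=1, altloc="all")
    if atoms.array_length() == 0:
        raise ValueError(f"no atoms in {path}")

    if np.any(atoms.ins_code != ""):
        raise ValueError("insertion codes are not supported")

    # keep first altloc of each (chain, residue, atom name); warn on duplicates
    keys = list(zip(atoms.chain_id, atoms.res_id, atoms.atom_name))
    seen = set()
    keep = np.ones(atoms.array_length(), dtype=bool)
    for i, k in enumerate(keys):
        if k in seen:
            keep[i] = False
        else:
            seen.add(k)
    if not keep.all():
        warnings.warn("duplicate altloc atoms found; keeping first occurrence")
        atoms = atoms[keep]

    chain_order = []
    for cid in atoms.chain_id:
        if cid not in chain_order:
            chain_order.append(cid)

    protomers = []
    for cid in chain_order:
        chain = atoms[atoms.chain_id == cid]
        res_ids = []
        for rid in chain.res_id:
            if rid not in res_ids:
                res_ids.append(rid)
        ca = chain[chain.atom_name == "CA"]
        ca_by_res = {r: c for r, c in zip(ca.res_id, ca.coord)}
        for rid in res_ids:
            if rid not in ca_by_res:
                raise ValueError(f"residue {rid} in chain {cid} lacks a CA atom")
        coords = np.array([ca_by_res[r] for r in res_ids], dtype=float)
        resname_by_res = {r: n for r, n in zip(ca.res_id, ca.res_name)}
        seq = "".join(_one_letter(resname_by_res[r]) for r in res_ids)

        nh = None
        n_at = chain[chain.atom_name == "N"]
        h_at = chain[np.isin(chain.atom_name, ("H", "HN"))]
        if n_at.array_length() and h_at.array_length():
            n_by_res = {r: c for r, c in zip(n_at.res_id, n_at.coord)}
            h_by_res = {r: c for r, c in zip(h_at.res_id, h_at.coord)}
            vecs = np.full((len(res_ids), 3), np.nan)
            ok = True
            for i, rid in enumerate(res_ids):
                if rid in n_by_res and rid in h_by_res:
                    v = np.asarray(h_by_res[rid], float) - np.asarray(n_by_res[rid], float)
                    nrm = np.linalg.norm(v)
                    if nrm == 0:
                        ok = False
                        break
                    vecs[i] = v / nrm
                else:
                    ok = False
                    break
            if ok:
                nh = vecs

        protomers.append(
            ProtomerStructure(
                residue_ids=np.array(res_ids, dtype=int),
                sequence=seq,
                ca_coords=coords,
                nh_vectors=nh,
                chain_id=str(cid),
            )
        )

    if len(protomers) == 1:
        return protomers[0]

    n0 = protomers[0].n_residues
    for p in protomers[1:]:
        if p.n_residues != n0:
            raise ValueError("chains differ in length; cannot map to filament subunits")

    from .filament import FilamentModel  # deferred to avoid import cycle

    return FilamentModel(
        protomer=protomers[0],
        params=None,
        n_subunits=len(protomers),
        subunit_coords=np.stack([p.ca_coords for p in protomers]),
    )


def write_structure(model, path: Union[str, Path]) -> None:
    """Write a protomer or filament as a fixed-width PDB file.

    N-H orientations, if present on a protomer, are encoded as an ``N``
    atom at the C-alpha position and an ``H`` atom displaced by 1.02 A
    along the stored vector, so that read/write round trips preserve them.
    """
    if isinstance(model, ProtomerStructure):
        blocks = [model.ca_coords]
        protomer = model
    else:
        if model.n_subunits == 0:
            raise ValueError("cannot write an empty model")
        blocks = list(model.subunit_coords)
        protomer = model.protomer
    if len(blocks) == 0 or protomer.n_residues == 0:
        raise ValueError("cannot write an empty model")
    if len(blocks) > len(CHAIN_ID_ALPHABET):
        raise ValueError(
            f"{len(blocks)} subunits exceed the {len(CHAIN_ID_ALPHABET)} "
            "available PDB chain identifiers"
        )

    write_nh = isinstance(model, ProtomerStructure) and model.nh_vectors is not None
    atoms_per_res = 3 if write_nh else 1
    n_atoms = len(blocks) * protomer.n_residues * atoms_per_res
    arr = struc.AtomArray(n_atoms)

    coords = np.empty((n_atoms, 3))
    chain_ids, res_ids, res_names, atom_names, elements = [], [], [], [], []
    i = 0
    for b, block in enumerate(blocks):
        cid = CHAIN_ID_ALPHABET[b]
        for r in range(protomer.n_residues):
            rname = _three_letter(protomer.sequence[r])
            entries = [("CA", "C", block[r])]
            if write_nh:
                entries.append(("N", "N", block[r]))
                entries.append(("H", "H", block[r] + 1.02 * model.nh_vectors[r]))
            for aname, elem, xyz in entries:
                coords[i] = xyz
                chain_ids.append(cid)
                res_ids.append(int(protomer.residue_ids[r]))
                res_names.append(rname)
                atom_names.append(aname)
                elements.append(elem)
                i += 1

    arr.coord = coords
    arr.chain_id = np.array(chain_ids)
    arr.res_id = np.array(res_ids)
    arr.res_name = np.array(res_names)
    arr.atom_name = np.array(atom_names)
    arr.element = np.array(elements)
    arr.hetero = np.zeros(n_atoms, dtype=bool)

    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))
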
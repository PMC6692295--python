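"""Helical filament assembly and Z-axis slice selection.

A filament is generated from one protomer by repeated application of a
screw operator about the +Z axis: subunit ``k`` is the protomer rotated
by ``k * twist`` degrees and translated by ``k * rise`` Angstrom along Z.
Positive twist is counter-clockwise when viewed from +Z looking down;
with positive rise this yields a right-handed 1-start helix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .structures import ProtomerStructure

__all__ = [
    "HelicalParams",
    "FilamentModel",
    "FilamentSlice",
    "build_filament",
    "slice_filament",
    "consecutive_interface_rmsd",
]


@dataclass(frozen=True)
class HelicalParams:
    """Helical symmetry: axial rise (A) and rotation (deg) per subunit."""

    rise: float
    twist: float

    def __post_init__(self):
        if self.rise <= 0:
            raise ValueError("rise must be positive")
        if abs(self.twist) > 360:
            raise ValueError("|twist| must be <= 360 degrees")

    @property
    def handedness(self) -> str:
        return "right" if self.twist > 0 else ("left" if self.twist < 0 else "none")

    def operator(self, k: int = 1):
        """Rotation matrix and translation for ``k`` screw applications."""
        ang = np.deg2rad(self.twist * k)
        c, s = np.cos(ang), np.sin(ang)
        R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        t = np.array([0.0, 0.0, self.rise * k])
        return R, t


@dataclass
class FilamentModel:
    """Ordered subunits generated from one protomer by helical symmetry.

    ``params`` may be None for filaments read back from a file (whose
    subunits need not obey an exact symmetry).
    """

    protomer: ProtomerStructure
    params: Optional[HelicalParams]
    n_subunits: int
    subunit_coords: np.ndarray  # (n_subunits, n_residues, 3)

    def __post_init__(self):
        self.subunit_coords = np.asarray(self.subunit_coords, dtype=float)
        if self.subunit_coords.shape != (self.n_subunits, self.protomer.n_residues, 3):
            raise ValueError("subunit_coords shape mismatch")

    @property
    def n_atoms(self) -> int:
        return self.n_subunits * self.protomer.n_residues

    def all_coords(self) -> np.ndarray:
        """All C-alpha coordinates in subunit order, shape (n_atoms, 3)."""
        return self.subunit_coords.reshape(-1, 3)

    def all_residue_ids(self) -> np.ndarray:
        return np.tile(self.protomer.residue_ids, self.n_subunits)

    def subunit_index(self) -> np.ndarray:
        """Per-atom subunit index, shape (n_atoms,)."""
        return np.repeat(np.arange(self.n_subunits), self.protomer.n_residues)

    def subunit(self, k: int) -> ProtomerStructure:
        out = self.protomer.copy()
        out.ca_coords = self.subunit_coords[k].copy()
        if self.params is not None and out.nh_vectors is not None:
            R, _ = self.params.operator(k)
            out.nh_vectors = out.nh_vectors @ R.T
        return out


@dataclass
class FilamentSlice:
    """Atom subset of a filament selected by a Z-window around one subunit."""

    coords: np.ndarray          # (m, 3)
    atom_indices: np.ndarray    # indices into filament.all_coords()
    residue_ids: np.ndarray     # per selected atom
    subunit_index: np.ndarray   # per selected atom
    central_index: int
    z_range: tuple


def build_filament(
    protomer: ProtomerStructure, params: HelicalParams, n_subunits: int
) -> FilamentModel:
    """Assemble ``n_subunits`` copies of the protomer along the +Z screw axis.

    Subunit 0 is the input protomer unchanged; subunit k is rotated by
    ``k * twist`` about +Z and shifted by ``k * rise`` along Z.
    """
    if protomer.n_residues == 0:
        raise ValueError("protomer is empty")
    if n_subunits < 1:
        raise ValueError("n_subunits must be >= 1")
    blocks = np.empty((n_subunits, protomer.n_residues, 3))
    for k in range(n_subunits):
        R, t = params.operator(k)
        blocks[k] = protomer.ca_coords @ R.T + t
    return FilamentModel(
        protomer=protomer.copy(),
        params=params,
        n_subunits=n_subunits,
        subunit_coords=blocks,
    )


def slice_filament(
    filament: FilamentModel, central_index: int, margin_z: float = 15.0
) -> FilamentSlice:
    """Select all atoms within ``margin_z`` of the central subunit's Z-extent.

    The selection is the axial box ``[zmin(central) - margin, zmax(central)
    + margin]``; every atom of the central subunit is always included.
    """
    if not 0 <= central_index < filament.n_subunits:
        raise ValueError("central_index out of range")
    if margin_z < 0:
        raise ValueError("margin_z must be >= 0")
    z_central = filament.subunit_coords[central_index][:, 2]
    lo, hi = z_central.min() - margin_z, z_central.max() + margin_z
    coords = filament.all_coords()
    mask = (coords[:, 2] >= lo) & (coords[:, 2] <= hi)
    idx = np.nonzero(mask)[0]
    return FilamentSlice(
        coords=coords[idx],
        atom_indices=idx,
        residue_ids=filament.all_residue_ids()[idx],
        subunit_index=filament.subunit_index()[idx],
        central_index=central_index,
        z_range=(float(lo), float(hi)),
    )


def consecutive_interface_rmsd(filament: FilamentModel) -> np.ndarray:
    """C-alpha RMSD of each consecutive dimer to dimer (0, 1) after superposition.

    A symmetry-built filament gives values at numerical zero for every
    dimer; deviations localise construction or perturbation errors.
    """
    from .compare import kabsch_superpose

    if filament.n_subunits < 3:
        raise ValueError("need at least 3 subunits")
    ref = np.concatenate([filament.subunit_coords[0], filament.subunit_coords[1]])
    out = np.empty(filament.n_subunits - 1)
    for k in range(filament.n_subunits - 1):
        dim = np.concatenate([filament.subunit_coords[k], filament.subunit_coords[k + 1]])
        _, _, rmsd = kabsch_superpose(dim, ref)
        out[k] = rmsd
    return out
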
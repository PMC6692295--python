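"""Anisotropic network model: Hessian, modes, fluctuations, mode characters.

C-alpha nodes within a distance cutoff (15 A default) are coupled by
uniform Hookean springs; normal modes are eigenpairs of the resulting
3N x 3N Hessian.  Mean square fluctuations are reported in relative
units (kBT/gamma = 1).  Mode character (bend / twist / stretch) is
assigned by overlap with analytic deformation fields built from the
coordinates, and fluctuation differences between two ensembles are
tested with the per-position t-test + effect-size + run-length rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import eigsh
from scipy.spatial import cKDTree

from ._stats import RegionCriterion, SignificantRegion, scan_regions
from .filament import FilamentModel, FilamentSlice

__all__ = [
    "ElasticNetworkParams",
    "NormalModeSet",
    "FluctuationProfile",
    "build_hessian",
    "compute_modes",
    "mode_msf",
    "subunit_average_msf",
    "classify_mode",
    "significant_fluct_regions",
]

#: Dense eigensolver is used at or below this many atoms.
_DENSE_LIMIT_ATOMS = 400


@dataclass(frozen=True)
class ElasticNetworkParams:
    """Uniform-spring network parameters: distance cutoff (A) and gamma."""

    cutoff: float = 15.0
    gamma: float = 1.0

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")


@dataclass
class NormalModeSet:
    """Low-frequency eigenpairs of an elastic-network Hessian.

    Eigenvalues are ascending; eigenvectors are unit-norm columns of
    ``vectors`` (shape 3N x k).  The ``n_trivial`` lowest modes are the
    rigid-body zero modes and are excluded from non-trivial indexing:
    ``nontrivial_index(1)`` is the first elastic mode.
    """

    eigenvalues: np.ndarray
    vectors: np.ndarray
    n_trivial: int
    n_atoms: int
    residue_ids: Optional[np.ndarray] = None
    subunit_index: Optional[np.ndarray] = None

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)

    def nontrivial_index(self, k: int) -> int:
        """Global index of the k-th (1-based) non-trivial mode."""
        if k < 1:
            raise ValueError("non-trivial mode numbering is 1-based")
        idx = self.n_trivial + k - 1
        if idx >= self.n_modes:
            raise IndexError(f"mode {k}: only {self.n_modes - self.n_trivial} non-trivial modes computed")
        return idx

    def mode_vector(self, index: int) -> np.ndarray:
        """Eigenvector as per-atom displacements, shape (N, 3)."""
        return self.vectors[:, index].reshape(self.n_atoms, 3)


@dataclass
class FluctuationProfile:
    """Per-atom mean square fluctuations for a set of modes (relative units)."""

    per_atom_msf: np.ndarray
    mode_indices: np.ndarray
    residue_ids: Optional[np.ndarray] = None
    subunit_index: Optional[np.ndarray] = None


def build_hessian(
    coords: np.ndarray, params: Optional[ElasticNetworkParams] = None
) -> sparse.csr_matrix:
    """Anisotropic-network Hessian for C-alpha coordinates.

    For each pair (i, j) within the cutoff, the off-diagonal 3x3 block is
    ``-(gamma / d_ij^2) * r_ij r_ij^T``; diagonal blocks make every block
    row sum to zero.  The network must be connected under the cutoff.
    """
    if params is None:
        params = ElasticNetworkParams()
    X = np.asarray(coords, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("coords must have shape (n, 3)")
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 atoms")

    tree = cKDTree(X)
    pairs = tree.query_pairs(params.cutoff, output_type="ndarray")
    if len(pairs) == 0:
        raise ValueError("no contacts under cutoff; network disconnected")

    adj = sparse.coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels)
        raise ValueError(
            f"network is disconnected under cutoff {params.cutoff} A: "
            f"{n_comp} components of sizes {sizes.tolist()}"
        )

    i, j = pairs[:, 0], pairs[:, 1]
    rij = X[j] - X[i]                      # (m, 3)
    d2 = np.sum(rij**2, axis=1)
    # super-element for each pair: -(gamma/d^2) * outer(rij, rij)
    blocks = -(params.gamma / d2)[:, None, None] * (rij[:, :, None] * rij[:, None, :])

    m = len(i)
    rows = np.empty(m * 9, dtype=np.int64)
    cols = np.empty(m * 9, dtype=np.int64)
    vals = np.empty(m * 9)
    k = 0
    for a in range(3):
        for b in range(3):
            rows[k * m : (k + 1) * m] = 3 * i + a
            cols[k * m : (k + 1) * m] = 3 * j + b
            vals[k * m : (k + 1) * m] = blocks[:, a, b]
            k += 1

    H = sparse.coo_matrix((vals, (rows, cols)), shape=(3 * n, 3 * n))
    H = H + H.T
    # diagonal super-elements: negative sum of off-diagonal blocks in the row
    diag_blocks = np.zeros((n, 3, 3))
    np.add.at(diag_blocks, i, -blocks)
    np.add.at(diag_blocks, j, -blocks)
    drows = np.repeat(3 * np.arange(n), 9) + np.tile(np.repeat(np.arange(3), 3), n)
    dcols = np.repeat(3 * np.arange(n), 9) + np.tile(np.tile(np.arange(3), 3), n)
    D = sparse.coo_matrix((diag_blocks.reshape(-1), (drows, dcols)), shape=(3 * n, 3 * n))
    return (H + D).tocsr()


def compute_modes(
    hessian: sparse.spmatrix, n_modes: int = 26, method: str = "auto"
) -> NormalModeSet:
    """Lowest-frequency eigenpairs with rigid-body modes flagged trivial.

    Small systems are solved densely; larger ones by shift-invert Lanczos
    (``method`` forces one route).  Zero modes are those with eigenvalue
    below ``1e-8 * lambda_max_bound``.
    """
    H = sparse.csr_matrix(hessian)
    dim = H.shape[0]
    if H.shape[0] != H.shape[1]:
        raise ValueError("hessian must be square")
    n_atoms = dim // 3
    n_modes = min(n_modes, dim)
    if method not in ("auto", "dense", "sparse"):
        raise ValueError("method must be auto, dense or sparse")
    use_dense = (n_atoms <= _DENSE_LIMIT_ATOMS) if method == "auto" else (method == "dense")

    if use_dense:
        w, v = np.linalg.eigh(H.toarray())
        w, v = w[:n_modes], v[:, :n_modes]
        lam_max = float(np.max(np.abs(w))) if n_modes == dim else _spectral_bound(H)
    else:
        # fixed start vector keeps the Lanczos iteration (and hence every
        # output byte) deterministic across runs
        v0 = np.random.default_rng(1905).standard_normal(dim)
        try:
            w, v = eigsh(H, k=n_modes, sigma=-1e-6, which="LM", mode="normal", v0=v0)
        except Exception as exc:  # pragma: no cover - solver failure path
            raise RuntimeError(
                f"sparse eigensolver failed on {dim}-dim Hessian: {exc}"
            ) from exc
        order = np.argsort(w)
        w, v = w[order], v[:, order]
        lam_max = _spectral_bound(H)

    zero_tol = 1e-8 * lam_max
    n_trivial = int(np.sum(w < zero_tol))
    w = np.clip(w, 0.0, None)
    # canonical sign: largest-magnitude component of each mode is positive
    for k in range(v.shape[1]):
        j = int(np.argmax(np.abs(v[:, k])))
        if v[j, k] < 0:
            v[:, k] *= -1
    return NormalModeSet(
        eigenvalues=w, vectors=v, n_trivial=n_trivial, n_atoms=n_atoms
    )


def _spectral_bound(H: sparse.spmatrix) -> float:
    """Cheap upper bound on the largest eigenvalue (max abs row sum)."""
    return float(np.max(np.abs(H).sum(axis=1)))


def attach_topology(modes: NormalModeSet, filament_or_slice) -> NormalModeSet:
    """Record residue / subunit indices on a mode set for aggregation."""
    if isinstance(filament_or_slice, FilamentModel):
        modes.residue_ids = filament_or_slice.all_residue_ids()
        modes.subunit_index = filament_or_slice.subunit_index()
    elif isinstance(filament_or_slice, FilamentSlice):
        modes.residue_ids = filament_or_slice.residue_ids
        modes.subunit_index = filament_or_slice.subunit_index
    else:
        modes.residue_ids = filament_or_slice.residue_ids
        modes.subunit_index = np.zeros(modes.n_atoms, dtype=int)
    return modes


def mode_msf(modes: NormalModeSet, mode_indices: Sequence[int]) -> FluctuationProfile:
    """Per-atom mean square fluctuations from the given non-trivial modes.

    ``msf_i = sum_k (1/lambda_k) |u_k,i|^2`` with kBT/gamma = 1.
    Requesting a trivial mode is an error (its eigenvalue is ~0).
    """
    mode_indices = np.asarray(list(mode_indices), dtype=int)
    if np.any(mode_indices < modes.n_trivial):
        bad = mode_indices[mode_indices < modes.n_trivial]
        raise ValueError(f"trivial modes requested: {bad.tolist()}")
    if np.any(mode_indices >= modes.n_modes):
        raise IndexError("mode index out of range")
    msf = np.zeros(modes.n_atoms)
    for k in mode_indices:
        u = modes.mode_vector(k)
        msf += np.sum(u**2, axis=1) / modes.eigenvalues[k]
    return FluctuationProfile(
        per_atom_msf=msf,
        mode_indices=mode_indices,
        residue_ids=modes.residue_ids,
        subunit_index=modes.subunit_index,
    )


def subunit_average_msf(
    filament: FilamentModel,
    profile: FluctuationProfile,
    exclude_first_n: int = 24,
) -> np.ndarray:
    """Average MSF per subunit over residues with id > ``exclude_first_n``."""
    res_ids = filament.all_residue_ids()
    sub_idx = filament.subunit_index()
    if len(profile.per_atom_msf) != len(res_ids):
        raise ValueError("profile does not match filament atom count")
    keep = res_ids > exclude_first_n
    if not keep.any():
        raise ValueError("exclusion removes all residues")
    out = np.empty(filament.n_subunits)
    for k in range(filament.n_subunits):
        m = keep & (sub_idx == k)
        out[k] = profile.per_atom_msf[m].mean()
    return out


# ---------------------------------------------------------------------------
# Mode character
# ---------------------------------------------------------------------------

def _rigid_body_basis(coords: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the 6 rigid-body displacement fields, (3N, 6)."""
    n = coords.shape[0]
    c = coords - coords.mean(axis=0)
    fields = []
    for ax in np.eye(3):
        fields.append(np.tile(ax, (n, 1)))           # translations
    for ax in np.eye(3):
        fields.append(np.cross(ax, c))               # rotations
    B = np.stack([f.ravel() for f in fields], axis=1)
    Q, _ = np.linalg.qr(B)
    return Q


def _deformation_fields(coords: np.ndarray) -> dict:
    """Analytic bend / twist / stretch displacement fields from coordinates.

    Axial profiles are cosine shapes in the normalized axial coordinate
    ``s in [0, 1]``; the bend family spans both the symmetric
    (``cos 2*pi*s``, first free-free bending shape) and antisymmetric
    (``cos pi*s``) forms in each lateral direction.  All fields are
    orthogonalized against the rigid-body space, so overlaps measure
    elastic deformation only.
    """
    n = coords.shape[0]
    c = coords - coords.mean(axis=0)
    z = c[:, 2]
    span = z.max() - z.min()
    if span <= 0:
        raise ValueError("degenerate geometry: no axial extent")
    s = (z - z.min()) / span
    r_perp = np.column_stack([c[:, 0], c[:, 1], np.zeros(n)])
    if np.max(np.linalg.norm(r_perp, axis=1)) < 1e-9:
        raise ValueError("degenerate geometry: all atoms on the axis")
    zhat = np.array([0.0, 0.0, 1.0])
    tangential = np.cross(np.tile(zhat, (n, 1)), r_perp)

    half = np.cos(np.pi * s)
    full = np.cos(2 * np.pi * s)
    xhat = np.array([1.0, 0.0, 0.0])
    yhat = np.array([0.0, 1.0, 0.0])
    fields = {
        "twist": [ (z - z.mean())[:, None] * tangential / span ],
        "stretch": [ (z - z.mean())[:, None] * np.tile(zhat, (n, 1)) / span ],
        "bend": [
            half[:, None] * np.tile(xhat, (n, 1)),
            half[:, None] * np.tile(yhat, (n, 1)),
            full[:, None] * np.tile(xhat, (n, 1)),
            full[:, None] * np.tile(yhat, (n, 1)),
        ],
    }
    Q = _rigid_body_basis(coords)
    out = {}
    for name, fam in fields.items():
        vecs = []
        for f in fam:
            v = f.ravel().astype(float)
            v = v - Q @ (Q.T @ v)
            nrm = np.linalg.norm(v)
            if nrm > 1e-12:
                vecs.append(v / nrm)
        if not vecs:
            raise ValueError(f"degenerate geometry for {name} field")
        # orthonormalize the family so the subspace projection is well defined
        F = np.stack(vecs, axis=1)
        Qf, _ = np.linalg.qr(F)
        out[name] = Qf
    return out


def classify_mode(
    mode: Union[np.ndarray, NormalModeSet],
    coords_or_filament,
    mode_index: Optional[int] = None,
    threshold: float = 0.5,
):
    """Label a non-trivial mode as bend / twist / stretch / other.

    The normalized mode vector is projected onto analytic deformation
    subspaces (lateral cosine shapes for bend, tangential field for
    twist, axial field for stretch); the score per character is the norm
    of the projection, quadrature-combined over each family.  The label
    is the argmax, or ``"other"`` when the best score is below the
    threshold.

    Returns ``(label, scores)`` with ``scores`` a dict.
    """
    if isinstance(mode, NormalModeSet):
        if mode_index is None:
            raise ValueError("mode_index required when passing a NormalModeSet")
        if mode_index < mode.n_trivial:
            raise ValueError("cannot classify a trivial mode")
        u = mode.vectors[:, mode_index]
    else:
        u = np.asarray(mode, float).ravel()
    if isinstance(coords_or_filament, FilamentModel):
        coords = coords_or_filament.all_coords()
    elif isinstance(coords_or_filament, FilamentSlice):
        coords = coords_or_filament.coords
    else:
        coords = np.asarray(coords_or_filament, float)
    u = u / np.linalg.norm(u)
    fields = _deformation_fields(coords)
    scores = {}
    for name, Qf in fields.items():
        proj = Qf.T @ u
        scores[name] = float(np.sqrt(np.sum(proj**2)))
    label = max(scores, key=scores.get)
    if scores[label] < threshold:
        label = "other"
    return label, scores


def significant_fluct_regions(
    profiles_a: np.ndarray,
    profiles_b: np.ndarray,
    criterion: Optional[RegionCriterion] = None,
    residue_ids: Optional[np.ndarray] = None,
) -> list:
    """Residue runs where two ensembles' MSF profiles differ significantly.

    ``profiles_a`` / ``profiles_b`` are (n_models, n_positions) MSF arrays.
    A position qualifies when the t-test p-value is below the threshold
    and the absolute mean MSF difference exceeds sigma, where sigma is the
    mean over positions and both ensembles of the per-position standard
    deviation (pooled rule, configurable via ``criterion.effect_threshold``).
    """
    if criterion is None:
        criterion = RegionCriterion()
    A = np.asarray(profiles_a, float)
    B = np.asarray(profiles_b, float)
    if A.ndim != 2 or B.ndim != 2 or A.shape[1] != B.shape[1]:
        raise ValueError("profiles must be 2D with matching positions")
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise ValueError("both ensembles need at least 2 models")
    if residue_ids is None:
        residue_ids = np.arange(1, A.shape[1] + 1)
    effect = criterion.effect_threshold
    if effect is None:
        sigma = 0.5 * (
            A.std(axis=0, ddof=1).mean() + B.std(axis=0, ddof=1).mean()
        )
        effect = sigma
    return scan_regions(A, B, residue_ids, criterion, effect)
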
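"""Superposition and per-residue ensemble RMSD statistics.

Implements least-squares (Kabsch) superposition, per-residue deviation
profiles of a model ensemble against a reference (or the iterative
ensemble mean), and the region test flagging residue stretches where two
ensembles differ significantly in their deviation from a common
reference: per-position Welch t-test, effect threshold 0.5 A, and a
minimum run length of 3 consecutive qualifying positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple, Union

import numpy as np

from ._stats import RegionCriterion, SignificantRegion, scan_regions
from .structures import ProtomerStructure, StructureEnsemble, _model_coords, _model_residue_ids

__all__ = [
    "kabsch_superpose",
    "ensemble_rmsd_profile",
    "delta_rmsd_regions",
    "RMSDProfile",
]


def _as_coords(obj) -> np.ndarray:
    if isinstance(obj, np.ndarray):
        return np.asarray(obj, dtype=float)
    return _model_coords(obj)


def kabsch_superpose(
    mobile,
    reference,
    selection: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Least-squares superposition of ``mobile`` onto ``reference``.

    Parameters
    ----------
    mobile, reference : array (n, 3) or structure
        Coordinate sets with matching atom counts.
    selection : bool or int array, optional
        Atoms used to determine the transform (all by default).

    Returns
    -------
    rotation : (3, 3) proper rotation matrix (det = +1)
    translation : (3,) vector
    rmsd : float
        RMSD over the selection after applying ``R @ x + t``.
    """
    X = _as_coords(mobile)
    Y = _as_coords(reference)
    if X.shape != Y.shape:
        raise ValueError("mobile and reference must have the same shape")
    if selection is None:
        Xs, Ys = X, Y
    else:
        Xs, Ys = X[selection], Y[selection]
    if Xs.shape[0] < 3:
        raise ValueError("need at least 3 selected atoms for superposition")

    xc = Xs.mean(axis=0)
    yc = Ys.mean(axis=0)
    H = (Xs - xc).T @ (Ys - yc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = yc - R @ xc
    diff = (Xs @ R.T + t) - Ys
    rmsd = float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))
    return R, t, rmsd


@dataclass
class RMSDProfile:
    """Per-residue deviation statistics of an ensemble from a reference."""

    residue_ids: np.ndarray
    mean: np.ndarray                  # A, per residue, averaged over models
    std: np.ndarray                   # A, across models
    per_model: np.ndarray             # (n_models, n_residues), A
    reference_label: str = ""
    selection: Optional[np.ndarray] = None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "residue": self.residue_ids,
                "rmsd_mean": self.mean,
                "rmsd_std": self.std,
            }
        )


def _iterative_mean(coords: np.ndarray, selection, n_iter: int = 2) -> np.ndarray:
    """Coordinate average after iteratively superposing models on the mean."""
    work = coords.copy()
    mean = work[0].copy()
    for _ in range(n_iter):
        for m in range(work.shape[0]):
            R, t, _ = kabsch_superpose(work[m], mean, selection)
            work[m] = work[m] @ R.T + t
        mean = work.mean(axis=0)
    return mean


def ensemble_rmsd_profile(
    ensemble: StructureEnsemble,
    reference="mean",
    superpose_selection: Optional[np.ndarray] = None,
    n_mean_iterations: int = 2,
) -> RMSDProfile:
    """Per-residue C-alpha deviations of each model from a reference.

    Each model is independently superposed onto the reference over
    ``superpose_selection`` and the per-residue distance recorded; the
    profile reports mean and standard deviation across models.  With
    ``reference="mean"`` the reference is the coordinate average after
    iterative superposition (2 iterations by default).
    """
    if ensemble.n_models < 1:
        raise ValueError("ensemble must contain at least one model")
    coords = ensemble.coords_stack()
    res_ids = ensemble.residue_ids

    if isinstance(reference, str) and reference == "mean":
        ref_coords = _iterative_mean(coords, superpose_selection, n_mean_iterations)
        ref_label = "ensemble mean"
    else:
        ref_coords = _as_coords(reference)
        ref_label = "external reference"
    if ref_coords.shape != coords[0].shape:
        raise ValueError("reference does not match ensemble topology")

    per_model = np.empty((ensemble.n_models, coords.shape[1]))
    for m in range(ensemble.n_models):
        R, t, _ = kabsch_superpose(coords[m], ref_coords, superpose_selection)
        moved = coords[m] @ R.T + t
        per_model[m] = np.linalg.norm(moved - ref_coords, axis=1)

    return RMSDProfile(
        residue_ids=res_ids,
        mean=per_model.mean(axis=0),
        std=per_model.std(axis=0, ddof=1) if ensemble.n_models > 1 else np.zeros(coords.shape[1]),
        per_model=per_model,
        reference_label=ref_label,
        selection=superpose_selection,
    )


def delta_rmsd_regions(
    profiles_a: Union[RMSDProfile, np.ndarray],
    profiles_b: Union[RMSDProfile, np.ndarray],
    criterion: Optional[RegionCriterion] = None,
    residue_ids: Optional[np.ndarray] = None,
) -> list:
    """Residue intervals where two ensembles' deviations differ significantly.

    Per position, a t-test (Welch by default) compares per-model deviations
    of ensemble A against ensemble B; a position qualifies when
    ``p < p_threshold`` and ``|mean_A - mean_B| > effect_threshold``
    (0.5 A default).  Maximal runs of at least ``min_run_length``
    consecutive qualifying positions are reported with the sign of the
    difference (positive: B deviates more than A).
    """
    if criterion is None:
        criterion = RegionCriterion(effect_threshold=0.5)
    A = profiles_a.per_model if isinstance(profiles_a, RMSDProfile) else np.asarray(profiles_a, float)
    B = profiles_b.per_model if isinstance(profiles_b, RMSDProfile) else np.asarray(profiles_b, float)
    if residue_ids is None:
        if isinstance(profiles_a, RMSDProfile):
            residue_ids = profiles_a.residue_ids
        else:
            residue_ids = np.arange(1, A.shape[1] + 1)
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise ValueError("both ensembles need at least 2 models")
    if A.shape[1] != B.shape[1]:
        raise ValueError("ensembles cover different residue sets")
    effect = criterion.effect_threshold
    if effect is None:
        raise ValueError("delta_rmsd_regions requires an explicit effect threshold")
    return scan_regions(A, B, residue_ids, criterion, effect)
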
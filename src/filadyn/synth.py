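"""Deterministic generators for every input the pipeline consumes.

The default protomer is a pilin-like C-alpha trace: a long N-terminal
alpha-helix (residues 1-54) aligned with +Z and a compact four-segment
helical head packed against its upper half, offset from the filament
axis.  The protomer geometry is analytic (seed-independent); seeds only
control noise draws (ensemble perturbations, relaxation and HDX noise,
N-H vector jitter).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np

from .filament import HelicalParams
from .structures import ProtomerStructure, StructureEnsemble

__all__ = [
    "SyntheticConfig",
    "make_protomer",
    "make_ensemble",
    "make_nh_vectors",
    "make_relaxation_dataset",
    "make_peptide_map",
    "make_hdx_tables",
    "DEFAULT_TIME_POINTS_MIN",
]

#: Default HDX labeling time course (minutes).
DEFAULT_TIME_POINTS_MIN = (0.16, 1.0, 10.0, 30.0, 60.0, 120.0, 180.0)

_AA = "ACDEFGHIKLMNQRSTVWY"  # no proline; prolines are placed explicitly


@dataclass
class SyntheticConfig:
    """All knobs of the synthetic generators, with pipeline defaults."""

    seed: int = 0
    protomer_length: int = 134
    helix_rise: float = 10.0          # A per subunit
    helix_twist: float = 85.0         # deg per subunit
    n_subunits: int = 30
    ensemble_size: int = 11
    coordinate_noise_sd: float = 0.3  # A per axis
    relaxation_noise_frac: float = 0.02
    hdx_noise_sd: float = 0.05        # Da
    hdx_replicates: int = 3
    time_points_min: Sequence[float] = DEFAULT_TIME_POINTS_MIN
    sample_volume_ul: float = 15.0
    buffer_volume_ul: float = 55.0

    @property
    def helix_params(self) -> HelicalParams:
        return HelicalParams(rise=self.helix_rise, twist=self.helix_twist)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**data)


def _default_sequence(length: int, rng: np.random.Generator) -> str:
    seq = [_AA[int(rng.integers(len(_AA)))] for _ in range(length)]
    # sprinkle a few prolines in the head so HDX proline handling is exercised
    for pos in (70, 95, 120):
        if pos < length:
            seq[pos] = "P"
    return "".join(seq)


def _ideal_helix(n: int, rise: float = 1.5, radius: float = 2.3,
                 twist_deg: float = 100.0) -> np.ndarray:
    """C-alpha trace of an ideal alpha-helix along +Z starting at z=0."""
    i = np.arange(n)
    ang = np.deg2rad(twist_deg) * i
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang), rise * i])


def make_protomer(config: Optional[SyntheticConfig] = None) -> ProtomerStructure:
    """Pilin-like C-alpha protomer: long N-terminal helix plus compact head.

    Residues 1-54 form an ideal helix along +Z (1.5 A rise per residue,
    2.3 A radius, 100 deg per residue).  The remaining residues form a
    four-segment antiparallel helical bundle whose center is offset from
    the Z axis, packed against the upper half of the long helix; the head
    fits inside a 25 A sphere.  Geometry is analytic and identical for
    every seed; only N-H vector jitter is seeded.
    """
    if config is None:
        config = SyntheticConfig()
    length = config.protomer_length
    if length < 60:
        raise ValueError("protomer length must be >= 60")
    n_helix = min(54, length - 6)
    helix = _ideal_helix(n_helix)

    n_head = length - n_helix
    n_seg = 4
    seg_sizes = [n_head // n_seg + (1 if r < n_head % n_seg else 0) for r in range(n_seg)]
    # bundle of short helices parallel to Z, centers on a square around
    # (offset, 0); alternate up/down so segment ends stay adjacent
    offset = 18.0
    spread = 5.0
    corners = [(-spread, -spread), (spread, -spread), (spread, spread), (-spread, spread)]
    z_top = helix[-1, 2]
    head_pts = []
    for si, size in enumerate(seg_sizes):
        seg = _ideal_helix(size)
        if si % 2 == 1:
            seg = seg[::-1].copy()
            seg[:, 2] -= seg[-1, 2] - seg[0, 2]  # keep z starting near the same base
            seg[:, 2] -= seg[:, 2].min()
        cx, cy = corners[si]
        seg[:, 0] += offset + cx
        seg[:, 1] += cy
        seg[:, 2] += z_top - 38.0  # pack the head against the helix upper half
        head_pts.append(seg)
    coords = np.vstack([helix] + head_pts)

    rng = np.random.default_rng(config.seed)
    sequence = _default_sequence(length, np.random.default_rng(12345))  # fixed sequence
    nh = make_nh_vectors(coords, seed=config.seed)
    return ProtomerStructure(
        residue_ids=np.arange(1, length + 1),
        sequence=sequence,
        ca_coords=coords,
        nh_vectors=nh,
        chain_id="A",
    )


def make_nh_vectors(coords: np.ndarray, seed: int = 0,
                    cone_half_angle_deg: float = 20.0) -> np.ndarray:
    """Unit N-H vectors roughly perpendicular to the local chain direction.

    For each residue, a vector perpendicular to the local C-alpha chain
    tangent is jittered inside a cone of the given half-angle (seeded,
    deterministic) and normalized.
    """
    X = np.asarray(coords, float)
    n = len(X)
    rng = np.random.default_rng(seed)
    tangents = np.empty_like(X)
    tangents[1:-1] = X[2:] - X[:-2]
    tangents[0] = X[1] - X[0]
    tangents[-1] = X[-1] - X[-2]
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    ref = np.array([0.0, 0.0, 1.0])
    out = np.empty_like(X)
    for i in range(n):
        t = tangents[i]
        perp = np.cross(t, ref)
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(t, np.array([1.0, 0.0, 0.0]))
        perp /= np.linalg.norm(perp)
        # jitter inside the cone around `perp`
        ang = np.deg2rad(cone_half_angle_deg) * np.sqrt(rng.uniform())
        phi = rng.uniform(0, 2 * np.pi)
        b1 = np.cross(perp, t)
        b1 /= np.linalg.norm(b1)
        b2 = np.cross(perp, b1)
        v = (
            np.cos(ang) * perp
            + np.sin(ang) * (np.cos(phi) * b1 + np.sin(phi) * b2)
        )
        out[i] = v / np.linalg.norm(v)
    return out


def make_ensemble(
    model, n: int, noise_sd: float, seed: int = 0, label: str = ""
) -> StructureEnsemble:
    """The model plus ``n - 1`` Gaussian-perturbed copies.

    Noise is i.i.d. per coordinate with standard deviation ``noise_sd``
    (A); the expected C-alpha RMSD of a perturbed copy to the original is
    ``noise_sd * sqrt(3)``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    models = [model.copy() if hasattr(model, "copy") else model]
    for _ in range(n - 1):
        if isinstance(model, ProtomerStructure):
            pert = model.copy()
            pert.ca_coords = pert.ca_coords + rng.normal(0.0, noise_sd, pert.ca_coords.shape)
            models.append(pert)
        else:  # FilamentModel
            from .filament import FilamentModel

            blocks = model.subunit_coords + rng.normal(
                0.0, noise_sd, model.subunit_coords.shape
            )
            models.append(
                FilamentModel(
                    protomer=model.protomer.copy(),
                    params=None,
                    n_subunits=model.n_subunits,
                    subunit_coords=blocks,
                )
            )
    return StructureEnsemble(models=models, label=label)


def make_relaxation_dataset(
    truth: Dict[str, np.ndarray],
    tensor,
    constants=None,
    noise_frac: float = 0.02,
    seed: int = 0,
    nh_vectors: Optional[np.ndarray] = None,
    residue_ids: Optional[np.ndarray] = None,
):
    """Forward-model T1/T2/NOE from known (S2, tau_e, Rex) and add noise.

    ``truth`` maps "S2", "tau_e", "Rex" to per-residue arrays.  Observables
    are multiplied by ``(1 + eps)`` with ``eps ~ N(0, noise_frac^2)``;
    quoted errors are ``noise_frac * value`` (a 1e-6 floor at zero noise).
    """
    from .relax import RelaxationDataset, SpinConstants, predict_relaxation

    if constants is None:
        constants = SpinConstants()
    S2 = np.asarray(truth["S2"], float)
    tau_e = np.asarray(truth["tau_e"], float)
    Rex = np.asarray(truth["Rex"], float)
    n = len(S2)
    if nh_vectors is None:
        rng_v = np.random.default_rng(seed + 777)
        v = rng_v.normal(size=(n, 3))
        nh_vectors = v / np.linalg.norm(v, axis=1, keepdims=True)
    if residue_ids is None:
        residue_ids = np.arange(1, n + 1)

    rng = np.random.default_rng(seed)
    T1 = np.empty(n)
    T2 = np.empty(n)
    noe = np.empty(n)
    for i in range(n):
        T1[i], T2[i], noe[i] = predict_relaxation(
            S2[i], tau_e[i], Rex[i], tensor, nh_vectors[i], constants
        )
    if noise_frac > 0:
        T1 *= 1 + rng.normal(0, noise_frac, n)
        T2 *= 1 + rng.normal(0, noise_frac, n)
        noe *= 1 + rng.normal(0, noise_frac, n)
    err_floor = 1e-6
    frac = max(noise_frac, err_floor)
    return RelaxationDataset(
        residue_ids=np.asarray(residue_ids, int),
        T1=T1,
        T1_err=np.abs(T1) * frac,
        T2=T2,
        T2_err=np.abs(T2) * frac,
        noe=noe,
        noe_err=np.maximum(np.abs(noe) * frac, err_floor),
        nh_vectors=np.asarray(nh_vectors, float),
    )


def make_peptide_map(sequence: str, min_len: int = 5, max_len: int = 15,
                     seed: int = 0) -> list:
    """Overlapping peptides (length 5-15) with 100% sequence coverage.

    Deterministic given the seed; every peptide has at least one
    exchangeable amide.  Returns a list of :class:`filadyn.hdx.HDXPeptide`.
    """
    from .hdx import HDXPeptide, count_exchangeable

    n = len(sequence)
    if n < min_len:
        raise ValueError("sequence shorter than the minimum peptide length")
    rng = np.random.default_rng(seed)
    peptides = []
    start = 1
    covered_to = 0
    while covered_to < n:
        length = int(rng.integers(min_len, max_len + 1))
        end = min(start + length - 1, n)
        if end - start + 1 < min_len:
            start = max(1, n - min_len + 1)
            end = n
        seq = sequence[start - 1 : end]
        # grow the window if proline placement leaves nothing exchangeable
        while count_exchangeable(seq) < 1 and end < n:
            end += 1
            seq = sequence[start - 1 : end]
        while count_exchangeable(seq) < 1 and start > 1:
            start -= 1
            seq = sequence[start - 1 : end]
        peptides.append(HDXPeptide(start=start, end=end, sequence=seq))
        covered_to = max(covered_to, end)
        if end >= n:
            break
        # overlap roughly half a peptide
        start = end - int(rng.integers(2, max(3, (end - start) // 2 + 1))) + 1
        start = max(start, 1)
        start = max(start, covered_to - max_len + 2)
        start = min(start, covered_to + 1)
    return peptides


def make_hdx_tables(
    truth_rates_per_state: Dict[str, np.ndarray],
    peptide_map: list,
    conditions=None,
    noise_sd: float = 0.05,
    n_replicates: int = 3,
    seed: int = 0,
) -> Dict[str, "object"]:
    """Replicate uptake tables per state from per-residue exchange rates.

    ``truth_rates_per_state`` maps state label to a per-residue array of
    observed exchange rates (min^-1, indexed by residue id 1..n).  Uptake
    is the closed-form forward model plus Gaussian noise truncated at 0.
    """
    from .hdx import LabelingConditions, UptakeTable, peptide_uptake_model

    if conditions is None:
        conditions = LabelingConditions()
    rng = np.random.default_rng(seed)
    out = {}
    for state, rates in truth_rates_per_state.items():
        rates = np.asarray(rates, float)
        if np.any(rates < 0):
            raise ValueError("exchange rates must be >= 0")
        n_res = len(rates)
        for pep in peptide_map:
            if pep.end > n_res:
                raise ValueError(f"peptide {pep.start}-{pep.end} outside sequence")
        records = []
        for pep in peptide_map:
            for t in conditions.time_points:
                clean = peptide_uptake_model(pep, rates, conditions, t)
                for rep in range(1, n_replicates + 1):
                    val = clean + rng.normal(0.0, noise_sd) if noise_sd > 0 else clean
                    records.append(
                        {
                            "start": pep.start,
                            "end": pep.end,
                            "sequence": pep.sequence,
                            "time_min": t,
                            "replicate": rep,
                            "uptake_Da": max(val, 0.0),
                        }
                    )
        out[state] = UptakeTable.from_records(records, state=state)
    return out
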
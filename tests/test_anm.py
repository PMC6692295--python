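import numpy as np
import pytest

from filadyn import anm
from filadyn._stats import RegionCriterion
from filadyn.anm import (
    ElasticNetworkParams,
    build_hessian,
    classify_mode,
    compute_modes,
    mode_msf,
    significant_fluct_regions,
    subunit_average_msf,
)
from filadyn.filament import HelicalParams, build_filament, slice_filament


def _random_connected_cloud(n, seed=0, scale=6.0):
    rng = np.random.default_rng(seed)
    return rng.uniform(0, scale, (n, 3)) * [1, 1, n / 10]


class TestBuildHessian:
    def test_two_atom_analytic(self):
        # pair along x at 3 A: blocks +/- diag(1,0,0); one nonzero eigenvalue 2
        coords = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        H = build_hessian(coords, ElasticNetworkParams(cutoff=15, gamma=1)).toarray()
        assert np.allclose(H[0:3, 3:6], -np.diag([1.0, 0, 0]))
        w = np.linalg.eigvalsh(H)
        assert np.sum(w > 1e-10) == 1
        assert np.isclose(w[-1], 2.0)

    def test_disconnected_errors(self):
        coords = np.array([[0.0, 0, 0], [20.0, 0, 0]])
        with pytest.raises(ValueError, match="disconnected"):
            build_hessian(coords, ElasticNetworkParams(cutoff=15))

    def test_symmetry_and_psd(self):
        coords = _random_connected_cloud(40, seed=3)
        H = build_hessian(coords).toarray()
        assert np.max(np.abs(H - H.T)) < 1e-12
        assert np.linalg.eigvalsh(H).min() >= -1e-10

    def test_block_row_sums_zero(self):
        coords = _random_connected_cloud(25, seed=4)
        H = build_hessian(coords).toarray()
        n = len(coords)
        rowsum = sum(H[:, 3 * j : 3 * j + 3] for j in range(n))
        assert np.max(np.abs(rowsum)) < 1e-10

    def test_gamma_scales_linearly(self):
        coords = _random_connected_cloud(15, seed=5)
        H1 = build_hessian(coords, ElasticNetworkParams(gamma=1.0)).toarray()
        H2 = build_hessian(coords, ElasticNetworkParams(gamma=2.0)).toarray()
        assert np.allclose(H2, 2 * H1)


class TestComputeModes:
    def test_dumbbell_five_trivial(self):
        coords = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        modes = compute_modes(build_hessian(coords), n_modes=6)
        assert modes.n_trivial == 5
        assert np.sum(modes.eigenvalues > 1e-10) == 1

    def test_six_trivial_noncollinear(self):
        coords = _random_connected_cloud(10, seed=1)
        modes = compute_modes(build_hessian(coords), n_modes=12)
        assert modes.n_trivial == 6

    def test_orthonormal(self):
        coords = _random_connected_cloud(20, seed=2)
        modes = compute_modes(build_hessian(coords), n_modes=15)
        G = modes.vectors.T @ modes.vectors
        assert np.allclose(G, np.eye(15), atol=1e-8)
        assert np.allclose(np.diff(modes.eigenvalues) >= -1e-12, True)

    def test_sparse_matches_dense_oracle(self):
        # 50-atom cloud: shift-invert route vs full dense eigendecomposition
        coords = _random_connected_cloud(50, seed=7)
        H = build_hessian(coords)
        sparse_modes = compute_modes(H, n_modes=20, method="sparse")
        w_dense, v_dense = np.linalg.eigh(H.toarray())
        # trivial modes: both numerically zero; elastic modes: 1e-8 relative
        assert np.all(sparse_modes.eigenvalues[:6] < 1e-10)
        assert np.all(np.abs(w_dense[:6]) < 1e-10)
        rel = np.abs(sparse_modes.eigenvalues[6:] - w_dense[6:20]) / w_dense[6:20]
        assert np.max(rel) < 1e-8
        # subspace overlap of the non-trivial block
        U = sparse_modes.vectors[:, 6:20]
        V = v_dense[:, 6:20]
        s = np.linalg.svd(U.T @ V, compute_uv=False)
        assert np.min(s) > 1 - 1e-8


class TestModeMSF:
    def test_concentrated_mode(self):
        # eigenvalue 2, eigenvector entirely on atom 0 -> msf_0 = 0.5
        vecs = np.zeros((6, 2))
        vecs[0, 1] = 1.0
        vecs[3, 0] = 1.0
        modes = anm.NormalModeSet(
            eigenvalues=np.array([0.0, 2.0]), vectors=vecs, n_trivial=1, n_atoms=2
        )
        prof = mode_msf(modes, [1])
        assert np.allclose(prof.per_atom_msf, [0.5, 0.0])

    def test_trivial_mode_rejected(self):
        coords = _random_connected_cloud(10, seed=1)
        modes = compute_modes(build_hessian(coords), n_modes=10)
        with pytest.raises(ValueError, match="trivial"):
            mode_msf(modes, [0])

    def test_gamma_doubling_halves_msf(self):
        coords = _random_connected_cloud(12, seed=9)
        m1 = compute_modes(build_hessian(coords, ElasticNetworkParams(gamma=1.0)), 10)
        m2 = compute_modes(build_hessian(coords, ElasticNetworkParams(gamma=2.0)), 10)
        p1 = mode_msf(m1, range(6, 10)).per_atom_msf
        p2 = mode_msf(m2, range(6, 10)).per_atom_msf
        assert np.allclose(p2, p1 / 2, rtol=1e-8)

    def test_pseudoinverse_oracle_chain(self):
        # 10-atom chain: msf over all non-trivial modes equals the diagonal
        # blocks of the Moore-Penrose pseudo-inverse of H  [oracle]
        coords = np.column_stack([np.zeros(10), np.zeros(10), 3.8 * np.arange(10.0)])
        coords += np.random.default_rng(0).normal(0, 0.3, coords.shape)  # break collinearity
        H = build_hessian(coords, ElasticNetworkParams(cutoff=9))
        modes = compute_modes(H, n_modes=30)
        sel = list(range(modes.n_trivial, 30))
        prof = mode_msf(modes, sel)
        Hinv = np.linalg.pinv(H.toarray(), rcond=1e-10)
        oracle = np.array([np.trace(Hinv[3 * i : 3 * i + 3, 3 * i : 3 * i + 3]) for i in range(10)])
        assert np.allclose(prof.per_atom_msf, oracle, rtol=1e-6)

    def test_rigid_transform_invariance(self):
        from conftest import random_rotation

        coords = _random_connected_cloud(30, seed=11)
        R = random_rotation(5)
        moved = coords @ R.T + np.array([3.0, -2.0, 7.0])
        m1 = compute_modes(build_hessian(coords), 12)
        m2 = compute_modes(build_hessian(moved), 12)
        p1 = mode_msf(m1, range(6, 12)).per_atom_msf
        p2 = mode_msf(m2, range(6, 12)).per_atom_msf
        assert np.allclose(p1, p2, rtol=1e-8)


class TestSubunitAverage:
    def test_uniform_profile(self, default_filament):
        n = default_filament.n_atoms
        prof = anm.FluctuationProfile(per_atom_msf=np.full(n, 3.14), mode_indices=np.array([6]))
        avg = subunit_average_msf(default_filament, prof)
        assert np.allclose(avg, 3.14)

    def test_exclude_zero_uses_all(self, default_filament):
        rng = np.random.default_rng(0)
        vals = rng.uniform(size=default_filament.n_atoms)
        prof = anm.FluctuationProfile(per_atom_msf=vals, mode_indices=np.array([6]))
        avg = subunit_average_msf(default_filament, prof, exclude_first_n=0)
        oracle = vals.reshape(30, -1).mean(axis=1)
        assert np.allclose(avg, oracle)

    def test_exclusion_removing_everything_errors(self, default_filament):
        n = default_filament.n_atoms
        prof = anm.FluctuationProfile(per_atom_msf=np.ones(n), mode_indices=np.array([6]))
        with pytest.raises(ValueError):
            subunit_average_msf(default_filament, prof, exclude_first_n=200)

    def test_terminal_amplification(self, default_filament, filament_modes):
        # bending modes: extremities fluctuate more than the center
        idx = [filament_modes.nontrivial_index(1), filament_modes.nontrivial_index(2)]
        prof = mode_msf(filament_modes, idx)
        avg = subunit_average_msf(default_filament, prof, exclude_first_n=24)
        central = avg[12:18].mean()
        assert avg[0] > central and avg[-1] > central


class TestClassifyMode:
    def test_self_overlap_twist(self, default_filament):
        from filadyn.anm import _deformation_fields

        coords = default_filament.all_coords()
        fields = _deformation_fields(coords)
        u = fields["twist"][:, 0]
        label, scores = classify_mode(u, coords)
        assert label == "twist"
        assert scores["twist"] > 0.999

    def test_orthogonal_vector_is_other(self, default_filament):
        coords = default_filament.all_coords()
        rng = np.random.default_rng(0)
        u = rng.normal(size=coords.size)
        u /= np.linalg.norm(u)  # random high-dim vector: near-orthogonal to all fields
        label, scores = classify_mode(u, coords)
        assert label == "other"

    def test_degenerate_axis_geometry(self):
        coords = np.column_stack([np.zeros(10), np.zeros(10), np.arange(10.0)])
        with pytest.raises(ValueError, match="degenerate"):
            classify_mode(np.ones(30) / np.sqrt(30), coords)

    def test_filament_mode_characters(self, default_filament, filament_modes):
        labels = []
        for k in (1, 2, 3):
            gi = filament_modes.nontrivial_index(k)
            lab, _ = classify_mode(filament_modes, default_filament, gi)
            labels.append(lab)
        assert labels == ["bend", "bend", "twist"]
        e1 = filament_modes.eigenvalues[filament_modes.nontrivial_index(1)]
        e2 = filament_modes.eigenvalues[filament_modes.nontrivial_index(2)]
        assert abs(e2 - e1) / e1 < 0.10  # near-degenerate bend pair

    def test_slice_twist_is_lowest(self, default_filament):
        sl = slice_filament(default_filament, 15, 15.0)
        modes = compute_modes(build_hessian(sl.coords), n_modes=10)
        lab, _ = classify_mode(modes, sl, modes.nontrivial_index(1))
        assert lab == "twist"


class TestSignificantFluctRegions:
    def test_identical_ensembles_no_regions(self):
        rng = np.random.default_rng(0)
        A = rng.uniform(1, 2, (5, 50))
        assert significant_fluct_regions(A, A.copy()) == []

    def test_run_length_rule(self):
        # qualifying positions exactly {10,11,12,40,41} -> single region [10,12]
        rng = np.random.default_rng(1)
        n_pos, n_models = 60, 12
        A = rng.normal(10.0, 0.1, (n_models, n_pos))
        B = rng.normal(10.0, 0.1, (n_models, n_pos))
        for pos in (10, 11, 12, 40, 41):
            B[:, pos] += 5.0
        regions = significant_fluct_regions(A, B, RegionCriterion(min_run_length=3))
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (11, 13)  # 1-based residue ids
        assert regions[0].sign == 1

    def test_injected_offset_detected(self):
        # +3 sigma offset at residues 60-70, noise sigma/5, 11 models each
        rng = np.random.default_rng(42)
        n_pos = 134
        base = 10.0
        sigma = 1.0
        A = rng.normal(base, sigma / 5, (11, n_pos))
        B = rng.normal(base, sigma / 5, (11, n_pos))
        B[:, 59:70] += 3 * sigma  # residues 60..70
        regions = significant_fluct_regions(A, B)
        assert len(regions) == 1
        r = regions[0]
        assert r.start >= 58 and r.end <= 72
        assert r.start <= 61 and r.end >= 69

    def test_too_few_models(self):
        A = np.ones((1, 10))
        with pytest.raises(ValueError):
            significant_fluct_regions(A, A)

    def test_swap_flips_sign(self):
        rng = np.random.default_rng(3)
        A = rng.normal(10, 0.2, (8, 40))
        B = A + 0.0
        B = rng.normal(10, 0.2, (8, 40))
        B[:, 10:16] += 4.0
        r1 = significant_fluct_regions(A, B)
        r2 = significant_fluct_regions(B, A)
        assert [(r.start, r.end, r.sign) for r in r1] == [
            (r.start, r.end, -r.sign) for r in r2
        ]
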
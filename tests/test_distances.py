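"""Distance-matrix mathematics: worked examples, oracles, and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import caflex
from caflex import (
    ConformerEnsemble,
    difference_matrix,
    distance_matrix,
    drmsd,
    fluctuation_matrix,
    flexibility_matrix,
    matrix_correlation,
    mean_abs_difference_matrix,
    overall_fluctuation,
    superposed_rmsd,
)
from caflex.distances import cross_submatrix, pair_distance_vectors

from conftest import (
    collinear_conformer,
    drmsd_bruteforce,
    pairwise_dist,
    random_conformer,
    random_ensemble,
)


def rigid_copy(conf, seed=0):
    rng = np.random.default_rng(seed)
    # random proper rotation via QR
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    shifted = conf.coords @ q.T + rng.normal(0, 10, size=3)
    return caflex.CalphaConformer(conf.residue_labels, shifted, "rigid")


class TestDistanceMatrix:
    def test_collinear_points(self):
        dm = distance_matrix(collinear_conformer([0, 1, 2]))
        np.testing.assert_allclose(dm.values, [[0, 1, 2], [1, 0, 1], [2, 1, 0]])

    def test_symmetric_zero_diagonal(self):
        dm = distance_matrix(random_conformer(1))
        np.testing.assert_allclose(dm.values, dm.values.T)
        np.testing.assert_allclose(np.diag(dm.values), 0)

    def test_rigid_invariance(self):
        conf = random_conformer(2)
        dm1 = distance_matrix(conf)
        dm2 = distance_matrix(rigid_copy(conf, 3))
        np.testing.assert_allclose(dm1.values, dm2.values, atol=1e-9)


class TestDifferenceMatrix:
    def test_collinear_example(self):
        a = distance_matrix(collinear_conformer([0, 1, 2]))
        b = distance_matrix(collinear_conformer([0, 1, 3]))
        d = difference_matrix(a, b)
        assert d.values[0, 1] == 0
        assert d.values[0, 2] == -1
        assert d.values[1, 2] == -1

    def test_self_difference_zero(self):
        a = distance_matrix(random_conformer(4))
        np.testing.assert_allclose(difference_matrix(a, a).values, 0)

    def test_antisymmetry_under_swap(self):
        a = distance_matrix(random_conformer(5))
        b = distance_matrix(random_conformer(6))
        np.testing.assert_allclose(
            difference_matrix(a, b).values + difference_matrix(b, a).values, 0,
            atol=1e-12,
        )


class TestDrmsd:
    def test_identity_is_zero(self):
        a = distance_matrix(random_conformer(7))
        assert drmsd(a, a) == 0

    def test_collinear_hand_value(self):
        a = distance_matrix(collinear_conformer([0, 1, 2]))
        b = distance_matrix(collinear_conformer([0, 1, 3]))
        # squared differences 0, 1, 1 over three unordered pairs
        assert drmsd(a, b) == pytest.approx(np.sqrt(2 / 3), abs=1e-12)

    def test_matches_bruteforce(self):
        a = distance_matrix(random_conformer(8))
        b = distance_matrix(random_conformer(9))
        assert drmsd(a, b) == pytest.approx(
            drmsd_bruteforce(a.values, b.values), abs=1e-12
        )

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_pseudometric_triangle_inequality(self, seed):
        rng = np.random.default_rng(seed)
        confs = [random_conformer(int(rng.integers(2**31)), n=6) for _ in range(3)]
        da, db, dc = (distance_matrix(c) for c in confs)
        assert drmsd(da, db) >= 0
        assert drmsd(da, db) == pytest.approx(drmsd(db, da), abs=1e-12)
        assert drmsd(da, dc) <= drmsd(da, db) + drmsd(db, dc) + 1e-12

    def test_shape_mismatch_rejected(self):
        a = distance_matrix(random_conformer(1, n=5))
        b = distance_matrix(random_conformer(1, n=6))
        with pytest.raises(ValueError):
            drmsd(a, b)


class TestPairStatMatrices:
    def test_fluctuation_two_frame_hand_value(self):
        ens = ConformerEnsemble(
            frames=[collinear_conformer([0, 2]), collinear_conformer([0, 3])]
        )
        F = fluctuation_matrix(ens)
        # population variance of {2, 3}: ((2-2.5)^2 + (3-2.5)^2)/2
        assert F.values[0, 1] == pytest.approx(0.25, abs=1e-12)

    def test_identical_frames_zero(self):
        conf = random_conformer(10)
        ens = ConformerEnsemble(frames=[conf, conf, conf])
        assert np.all(fluctuation_matrix(ens).values <= 1e-24)
        assert np.all(flexibility_matrix(ens).values == 0)

    def test_fluctuation_matches_bruteforce(self):
        ens = random_ensemble(11, k=50, n=8)
        F = fluctuation_matrix(ens)
        dists = np.stack([pairwise_dist(f.coords) for f in ens.frames])
        for i in range(8):
            for j in range(8):
                expected = np.mean((dists[:, i, j] - dists[:, i, j].mean()) ** 2)
                assert F.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_flexibility_two_frame_hand_value(self):
        ens = ConformerEnsemble(
            frames=[collinear_conformer([0, 2]), collinear_conformer([0, 3])]
        )
        assert flexibility_matrix(ens).values[0, 1] == pytest.approx(1.0)

    def test_variance_range_bound(self):
        # population variance of a bounded variable is at most (range/2)^2
        for seed in range(5):
            ens = random_ensemble(seed, k=30, n=6)
            F = fluctuation_matrix(ens).values
            X = flexibility_matrix(ens).values
            assert np.all(F <= X**2 / 4 + 1e-12)

    def test_requires_two_frames(self):
        ens = ConformerEnsemble(frames=[random_conformer(0)])
        with pytest.raises(ValueError):
            fluctuation_matrix(ens)


class TestOverallFluctuation:
    def test_two_frame_hand_value(self):
        ens = ConformerEnsemble(
            frames=[collinear_conformer([0, 1, 2]), collinear_conformer([0, 1, 3])]
        )
        th = overall_fluctuation(ens)
        # off-diagonal F entries: 0, 0.25, 0.25 -> mean 1/6
        assert th.theta == pytest.approx(np.sqrt(1 / 6), abs=1e-12)

    def test_identical_frames_zero(self):
        conf = random_conformer(12)
        ens = ConformerEnsemble(frames=[conf] * 4)
        assert overall_fluctuation(ens).theta == 0

    def test_equals_rms_drmsd_to_mean(self):
        ens = random_ensemble(13, k=100, n=10)
        th = overall_fluctuation(ens)
        F = fluctuation_matrix(ens).values
        iu = np.triu_indices(10, k=1)
        assert abs(th.theta**2 - F[iu].mean()) < 1e-12
        vecs = pair_distance_vectors(ens)
        mean_vec = vecs.mean(axis=0)
        p = vecs.shape[1]
        d_to_mean = np.linalg.norm(vecs - mean_vec, axis=1) / np.sqrt(p)
        assert th.theta == pytest.approx(
            np.sqrt(np.mean(d_to_mean**2)), abs=1e-12
        )

    def test_cross_block_scope(self, pocket, pocket_sel):
        from caflex import generate_harmonic

        ens = generate_harmonic(pocket, 0.1, 50, seed=3).ensemble
        th = overall_fluctuation(ens, pocket_sel, pair_scope="cross_block")
        F = fluctuation_matrix(ens, pocket_sel).values
        sub, _, _ = cross_submatrix(F, pocket_sel, "strand", "helix")
        assert th.theta == pytest.approx(np.sqrt(sub.mean()), abs=1e-12)


class TestMeanAbsDifference:
    def test_reference_itself_zero(self):
        conf = random_conformer(14)
        ens = ConformerEnsemble(frames=[conf])
        ref = distance_matrix(conf)
        assert np.allclose(mean_abs_difference_matrix(ens, ref).values, 0)

    def test_two_frame_hand_value(self):
        ens = ConformerEnsemble(
            frames=[collinear_conformer([0, 2]), collinear_conformer([0, 4])]
        )
        ref = distance_matrix(collinear_conformer([0, 3]))
        assert mean_abs_difference_matrix(ens, ref).values[0, 1] == pytest.approx(1.0)

    def test_matches_bruteforce(self):
        ens = random_ensemble(15, k=20, n=7)
        ref = distance_matrix(random_conformer(16, n=7))
        delta = mean_abs_difference_matrix(ens, ref).values
        dists = np.stack([pairwise_dist(f.coords) for f in ens.frames])
        for i in range(7):
            for j in range(7):
                expected = np.mean(np.abs(dists[:, i, j] - ref.values[i, j]))
                assert delta[i, j] == pytest.approx(expected, abs=1e-12)


class TestCrossSubmatrix:
    def test_pocket_shape_and_entries(self, pocket, pocket_sel):
        from caflex import generate_harmonic

        ens = generate_harmonic(pocket, 0.1, 20, seed=5).ensemble
        F = fluctuation_matrix(ens, pocket_sel).values
        sub, ia, ib = cross_submatrix(F, pocket_sel, "strand", "helix")
        assert sub.shape == (5, 10)
        for r, i in enumerate(ia):
            for c, j in enumerate(ib):
                assert sub[r, c] == F[i, j]

    def test_same_block_rejected(self, pocket_sel):
        with pytest.raises(ValueError, match="overlap"):
            cross_submatrix(np.zeros((15, 15)), pocket_sel, "strand", "strand")


class TestMatrixCorrelation:
    def test_self_correlation_one(self):
        rng = np.random.default_rng(17)
        m = rng.random((6, 6))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        assert matrix_correlation(m, m) == pytest.approx(1.0)

    def test_negative_affine_gives_minus_one(self):
        rng = np.random.default_rng(18)
        m = rng.random((6, 6))
        m = (m + m.T) / 2
        assert matrix_correlation(m, -2.0 * m + 5.0) == pytest.approx(-1.0)

    def test_matches_two_pass_pearson(self):
        rng = np.random.default_rng(19)
        m1, m2 = rng.random((5, 10)), rng.random((5, 10))
        x, y = m1.ravel(), m2.ravel()
        xc, yc = x - x.mean(), y - y.mean()
        expected = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
        assert matrix_correlation(m1, m2) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            matrix_correlation(np.ones((4, 4)), np.eye(4))


def grid_rmsd_oracle(pa, pb):
    """Dense Euler-angle grid + local refinement of the superposition RMSD."""
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation

    xa = pa - pa.mean(axis=0)
    xb = pb - pb.mean(axis=0)

    def rmsd_of(angles):
        rot = Rotation.from_euler("zyx", angles).as_matrix()
        diff = xb - xa @ rot.T
        return np.sqrt(np.mean(np.sum(diff**2, axis=1)))

    grid = np.linspace(-np.pi, np.pi, 13)
    best = None
    for a in grid:
        for b in grid[:7]:
            for c in grid:
                v = rmsd_of([a, b, c])
                if best is None or v < best[0]:
                    best = (v, [a, b, c])
    res = minimize(rmsd_of, best[1], method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-14})
    return min(best[0], res.fun)


class TestSuperposedRmsd:
    def test_rigid_copy_is_zero(self):
        conf = random_conformer(20, n=8)
        assert superposed_rmsd(conf, rigid_copy(conf, 21)) < 1e-9

    def test_identical_is_zero(self):
        conf = random_conformer(22, n=5)
        assert superposed_rmsd(conf, conf) < 1e-12

    def test_matches_rotation_grid_oracle(self):
        rng = np.random.default_rng(23)
        pa = rng.normal(0, 3, size=(4, 3))
        pb = pa.copy()
        pb[0, 0] += 0.3  # single perturbed coordinate
        a = collinear_conformer([0, 1, 2, 3])
        a.coords = pa
        b = collinear_conformer([0, 1, 2, 3])
        b.coords = pb
        ours = superposed_rmsd(a, b)
        assert ours == pytest.approx(grid_rmsd_oracle(pa, pb), abs=1e-3)

    def test_matches_mdanalysis(self):
        from MDAnalysis.analysis.rms import rmsd as mda_rmsd

        rng = np.random.default_rng(24)
        pa, pb = rng.normal(0, 4, size=(10, 3)), rng.normal(0, 4, size=(10, 3))
        a = random_conformer(0, n=10)
        a.coords = pa
        b = random_conformer(0, n=10)
        b.coords = pb
        assert superposed_rmsd(a, b) == pytest.approx(
            mda_rmsd(pa, pb, center=True, superposition=True), abs=1e-6
        )

    def test_collinear_rejected(self):
        a = collinear_conformer([0, 1, 2, 3])
        with pytest.raises(ValueError, match="collinear|degenerate"):
            superposed_rmsd(a, a, pairs=[(0, 0), (1, 1), (2, 2), (3, 3)])

    def test_too_few_pairs_rejected(self):
        conf = random_conformer(25, n=5)
        with pytest.raises(ValueError):
            superposed_rmsd(conf, conf, pairs=[(0, 0), (1, 1)])
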
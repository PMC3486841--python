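import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import optimize, stats as sps
from scipy.spatial.transform import Rotation

from bridgeswitch import (
    DistanceSeries,
    Topology,
    Trajectory,
    anticorrelation,
    block_bootstrap_ci,
    cross_rmsd_matrix,
    kabsch_rmsd,
    running_average,
)
from bridgeswitch.errors import (
    AlignmentError,
    DegenerateGeometryError,
    EmptyAnalysisError,
    ParameterError,
    SelectionError,
    UndefinedCorrelationError,
)

from conftest import atom


def _series(values, dt=10.0):
    return DistanceSeries(np.arange(len(values)) * dt, np.asarray(values, float))


class TestRunningAverage:
    def test_constant_unchanged(self):
        s = _series([4.2] * 9)
        np.testing.assert_allclose(running_average(s, 100.0).values_A, s.values_A, atol=1e-12)

    def test_three_frame_window_with_edge_truncation(self):
        # dt=10 ps, window 30 ps -> 3-frame centered window, symmetric truncation
        out = running_average(_series([0, 0, 3, 0, 0]), window_ps=30.0)
        np.testing.assert_allclose(out.values_A, [0, 1, 1, 1, 0])
        np.testing.assert_array_equal(out.times_ps, np.arange(5) * 10.0)

    def test_matches_per_point_oracle(self):
        rng = np.random.default_rng(5)
        v = rng.uniform(0, 10, 101)
        s = _series(v)
        out = running_average(s, window_ps=100.0)  # half-width 5 frames
        n = v.size
        for i in range(n):
            h = min(5, i, n - 1 - i)
            assert out.values_A[i] == pytest.approx(v[i - h : i + h + 1].mean(), abs=1e-10)

    def test_empty_errors(self):
        with pytest.raises(EmptyAnalysisError):
            running_average(_series([]), 100.0)

    def test_window_smaller_than_dt_is_identity(self):
        s = _series([1, 5, 2, 8])
        np.testing.assert_array_equal(running_average(s, 5.0).values_A, s.values_A)


class TestAnticorrelation:
    def test_perfect_alternation_is_minus_one(self):
        assert anticorrelation([3, 6, 3, 6, 3], [6, 3, 6, 3, 6]).rho == pytest.approx(-1.0)

    def test_orthogonal_case_is_zero(self):
        assert anticorrelation([3, 3, 6, 6], [3, 6, 3, 6]).rho == pytest.approx(0.0, abs=1e-15)

    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            n = rng.integers(3, 300)
            a, b = rng.uniform(0, 20, n), rng.uniform(0, 20, n)
            assert anticorrelation(a, b).rho == pytest.approx(
                sps.pearsonr(a, b).statistic, abs=1e-12
            )

    def test_constant_input_undefined(self):
        with pytest.raises(UndefinedCorrelationError):
            anticorrelation([3.0, 3.0, 3.0], [1.0, 2.0, 3.0])

    def test_length_mismatch(self):
        with pytest.raises(AlignmentError):
            anticorrelation([1, 2, 3], [1, 2, 3, 4])

    @given(
        st.lists(st.floats(-50, 50), min_size=3, max_size=40),
        st.floats(0.1, 10),
        st.floats(-5, 5),
    )
    def test_symmetry_and_affine_invariance(self, values, scale, shift):
        rng = np.random.default_rng(1)
        a = np.asarray(values) + rng.normal(0, 1, len(values))
        b = rng.normal(0, 1, len(values))
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            return
        r = anticorrelation(a, b).rho
        assert anticorrelation(b, a).rho == pytest.approx(r, abs=1e-12)
        assert anticorrelation(scale * a + shift, b).rho == pytest.approx(r, abs=1e-9)
        assert anticorrelation(-a, b).rho == pytest.approx(-r, abs=1e-12)


def _random_structure(rng, n=12):
    return rng.uniform(-8, 8, size=(n, 3))


class TestKabschRMSD:
    def test_rigid_copy_zero_rmsd(self):
        rng = np.random.default_rng(2)
        x = _random_structure(rng)
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        y = x @ rot.T + np.array([1.0, -2.0, 3.0])
        res = kabsch_rmsd(x, y)
        assert res.rmsd < 1e-8
        # returned transform actually maps y onto x
        np.testing.assert_allclose(y @ res.rotation.T + res.translation, x, atol=1e-8)

    def test_matches_align_vectors_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            x = _random_structure(rng)
            y = x + rng.normal(0, 0.3, x.shape)
            rot = Rotation.random(random_state=rng).as_matrix()
            y = y @ rot.T + rng.uniform(-5, 5, 3)
            _, rssd = Rotation.align_vectors(x - x.mean(0), y - y.mean(0))
            oracle = rssd / np.sqrt(x.shape[0])
            assert kabsch_rmsd(x, y).rmsd == pytest.approx(oracle, abs=1e-6)

    def test_matches_numeric_minimization_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(3):
            x = _random_structure(rng, n=8)
            y = x + rng.normal(0, 0.3, x.shape)

            def objective(rv):
                r = Rotation.from_rotvec(rv).as_matrix()
                yc = (y - y.mean(0)) @ r.T
                return np.sqrt(np.mean(np.sum((x - x.mean(0) - yc) ** 2, axis=1)))

            best = min(
                optimize.minimize(objective, v0, method="Nelder-Mead",
                                  options={"xatol": 1e-10, "fatol": 1e-12}).fun
                for v0 in (np.zeros(3), np.array([0.5, -0.3, 0.2]), np.array([2.0, 1.0, -1.0]))
            )
            assert kabsch_rmsd(x, y).rmsd == pytest.approx(best, abs=1e-6)

    def test_mirror_image_uses_proper_rotation_only(self):
        rng = np.random.default_rng(6)
        x = _random_structure(rng)
        y = x * np.array([1.0, 1.0, -1.0])  # reflection
        res = kabsch_rmsd(x, y)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-10)
        # reflection-allowed optimum would be exactly 0
        assert res.rmsd > 0.1

    def test_collinear_rejected(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(DegenerateGeometryError):
            kabsch_rmsd(line, line)

    def test_too_few_atoms_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            kabsch_rmsd(np.zeros((2, 3)), np.zeros((2, 3)))


def _anchor_traj(frames):
    atoms = (
        atom(1, "CA", "ALA", seq=1),
        atom(2, "CA", "ALA", seq=2),
        atom(3, "CB", "ALA", seq=3),
        atom(4, "NZ", "LYS", seq=9),
    )
    return Trajectory(Topology(atoms), np.asarray(frames, float), dt_ps=10.0)


class TestCrossRMSD:
    def _frames(self, rng, k=4):
        base = rng.uniform(-5, 5, size=(4, 3))
        return np.stack([base + rng.normal(0, 0.4, base.shape) for _ in range(k)])

    def test_identical_frames_zero_matrix(self):
        base = np.array([[0.0, 0, 0], [3, 0, 0], [0, 4, 0], [1, 1, 5]])
        frames = np.tile(base, (3, 1, 1))
        m = cross_rmsd_matrix(_anchor_traj(frames), "CA,CB,NZ")
        np.testing.assert_allclose(m.values, 0.0, atol=1e-12)

    def test_matches_per_pair_oracle_symmetric_zero_diag(self):
        rng = np.random.default_rng(12)
        frames = self._frames(rng, k=3)
        traj = _anchor_traj(frames)
        m = cross_rmsd_matrix(traj, "CA,CB,NZ")
        np.testing.assert_array_equal(m.values, m.values.T)
        np.testing.assert_array_equal(np.diag(m.values), 0.0)
        for i in range(3):
            for j in range(3):
                if i != j:
                    assert m.values[i, j] == pytest.approx(
                        kabsch_rmsd(frames[i], frames[j]).rmsd, abs=1e-12
                    )

    def test_rigid_transform_per_frame_invariance(self):
        rng = np.random.default_rng(13)
        frames = self._frames(rng)
        m0 = cross_rmsd_matrix(_anchor_traj(frames), "CA,CB,NZ").values
        moved = np.stack(
            [
                f @ Rotation.random(random_state=100 + i).as_matrix().T + rng.uniform(-9, 9, 3)
                for i, f in enumerate(frames)
            ]
        )
        m1 = cross_rmsd_matrix(_anchor_traj(moved), "CA,CB,NZ").values
        np.testing.assert_allclose(m1, m0, atol=1e-8)

    def test_empty_selection_error(self):
        rng = np.random.default_rng(1)
        with pytest.raises(SelectionError):
            cross_rmsd_matrix(_anchor_traj(self._frames(rng)), "SG")


class TestBlockBootstrap:
    def test_same_seed_same_ci(self):
        rng = np.random.default_rng(21)
        a, b = rng.normal(5, 1, 400), rng.normal(5, 1, 400)
        r1 = block_bootstrap_ci(a, b, n_boot=200, block_frames=10, seed=7)
        r2 = block_bootstrap_ci(a, b, n_boot=200, block_frames=10, seed=7)
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)

    def test_iid_width_matches_fisher_z(self):
        rng = np.random.default_rng(8)
        n = 2000
        x = rng.normal(0, 1, n)
        a = 5 + x + rng.normal(0, 1, n)
        b = 5 - x + rng.normal(0, 1, n)
        res = block_bootstrap_ci(a, b, n_boot=1000, block_frames=1, seed=0)
        z = np.arctanh(res.rho)
        half = 1.959964 / np.sqrt(n - 3)
        fisher_width = np.tanh(z + half) - np.tanh(z - half)
        width = res.ci_high - res.ci_low
        assert width == pytest.approx(fisher_width, rel=0.25)

    def test_deterministic_alternation_ci_is_point(self):
        a = np.array([3.0, 6.0] * 50)
        b = 9.0 - a
        res = block_bootstrap_ci(a, b, n_boot=100, block_frames=2, seed=1)
        assert res.rho == -1.0
        assert (res.ci_low, res.ci_high) == (-1.0, -1.0)

    def test_block_longer_than_series_rejected(self):
        with pytest.raises(ParameterError):
            block_bootstrap_ci(np.arange(10.0), np.arange(10.0), n_boot=100, block_frames=11)

    def test_too_few_boots_rejected(self):
        with pytest.raises(ParameterError):
            block_bootstrap_ci(np.arange(10.0), np.arange(10.0), n_boot=50, block_frames=2)
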
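"""Superposition, covariance, quasi-harmonic entropy, RMSF, windows, CIs."""
import numpy as np
import pytest

from bpbreathe import fluctuations as fl
from bpbreathe import synthetic
from bpbreathe.constants import AMU_KG, HBAR_SI, KB_SI, R_CAL
from bpbreathe.core import AtomRecord, Trajectory
from bpbreathe.errors import ConsistencyError, GeometryError, StatisticsError

from conftest import random_rotation

T = 298.0


def _alpha_one_eigenvalue(temperature=T):
    """λ (amu·Å²) for which ħω/k_BT is exactly 1."""
    return HBAR_SI**2 / (KB_SI * temperature) / (AMU_KG * 1e-20)


def _toy_traj(coords, masses=None):
    n = coords.shape[1]
    masses = masses if masses is not None else [12.011] * n
    atoms = [AtomRecord(f"C{i}", "C", 1, "TOY", masses[i], i) for i in range(n)]
    return Trajectory(atoms, coords)


class TestSuperpose:
    def test_rigid_copies_collapse(self, wc_template, rng):
        frames = [wc_template.coords[0]]
        for _ in range(4):
            rot = random_rotation(rng)
            frames.append(wc_template.coords[0] @ rot.T + rng.standard_normal(3) * 5)
        traj = wc_template.with_coords(np.stack(frames))
        aligned = fl.superpose(traj, 0)
        for f in range(5):
            rmsd = np.sqrt(((aligned.coords[f] - aligned.coords[0]) ** 2).sum(axis=1).mean())
            assert rmsd < 1e-6

    def test_already_aligned_unchanged(self, wc_template, rng):
        coords = wc_template.coords[0] + rng.standard_normal((3, wc_template.n_atoms, 3)) * 0.01
        traj = wc_template.with_coords(coords)
        aligned = fl.superpose(traj, 0)
        again = fl.superpose(aligned, 0)
        np.testing.assert_allclose(again.coords, aligned.coords, atol=1e-6)

    def test_matches_scipy_kabsch_oracle(self, rng):
        from scipy.spatial.transform import Rotation

        ref = rng.standard_normal((10, 3)) * 3
        mob = rng.standard_normal((10, 3)) * 3
        traj = _toy_traj(np.stack([ref, mob]))
        aligned = fl.superpose(traj, 0)
        my_rmsd = np.sqrt(((aligned.coords[1] - ref) ** 2).sum(axis=1).mean())
        _, oracle_ssd = Rotation.align_vectors(ref - ref.mean(0), mob - mob.mean(0))
        oracle_rmsd = oracle_ssd / np.sqrt(10)
        assert my_rmsd == pytest.approx(oracle_rmsd, rel=1e-6)

    def test_too_few_atoms(self, rng):
        traj = _toy_traj(rng.standard_normal((2, 2, 3)))
        with pytest.raises(GeometryError):
            fl.superpose(traj, 0)


class TestCovariance:
    def test_one_frame_is_error(self, wc_template):
        with pytest.raises(StatisticsError):
            fl.mass_weighted_covariance(wc_template)

    def test_constant_trajectory_zero(self, wc_template):
        traj = wc_template.with_coords(np.repeat(wc_template.coords, 4, axis=0))
        res = fl.mass_weighted_covariance(traj)
        assert np.allclose(res.covariance, 0)
        assert np.allclose(res.mw_eigenvalues, 0)

    def test_two_point_oscillation_variance(self):
        a = 0.7
        coords = np.zeros((2, 1, 3))
        coords[0, 0, 0] = a
        coords[1, 0, 0] = -a
        res = fl.mass_weighted_covariance(_toy_traj(coords, masses=[1.0]))
        assert res.covariance[0, 0] == pytest.approx(a**2, abs=1e-12)
        assert res.mw_eigenvalues[0] == pytest.approx(a**2, abs=1e-12)

    def test_matches_two_pass_brute_force(self, rng):
        coords = rng.standard_normal((7, 3, 3))
        traj = _toy_traj(coords, masses=[1.0, 12.0, 16.0])
        res = fl.mass_weighted_covariance(traj)
        x = coords.reshape(7, 9)
        mu = x.mean(axis=0)
        brute = np.zeros((9, 9))
        for f in range(7):
            d = x[f] - mu
            brute += np.outer(d, d)
        brute /= 7
        np.testing.assert_allclose(res.covariance, brute, atol=1e-10)

    def test_gaussian_spectrum_recovered(self, rng):
        spec = np.array([4.0, 2.5, 1.5, 0.8, 0.4, 0.2])
        q = np.linalg.qr(rng.standard_normal((6, 6)))[0]
        cov = q @ np.diag(spec) @ q.T
        traj = _toy_traj(np.zeros((1, 2, 3)), masses=[1.0, 1.0])
        ens = synthetic.gaussian_ensemble(traj, cov, 50_000, seed=5)
        res = fl.mass_weighted_covariance(ens)
        np.testing.assert_allclose(np.sort(res.mw_eigenvalues), np.sort(spec), rtol=0.05)


class TestEntropy:
    def test_single_mode_alpha_one(self):
        s = fl.entropy_from_eigenvalues(np.array([_alpha_one_eigenvalue()]), T)
        expected = R_CAL * (1 / (np.e - 1) - np.log(1 - np.exp(-1)))
        assert s == pytest.approx(expected, abs=1e-12)
        assert s == pytest.approx(2.068, abs=1e-3)

    def test_stiff_mode_contributes_nothing(self):
        lam = _alpha_one_eigenvalue()
        s1 = fl.entropy_from_eigenvalues(np.array([lam]), T)
        s2 = fl.entropy_from_eigenvalues(np.array([lam, 1e-12]), T)
        assert s2 == pytest.approx(s1, abs=1e-12)

    def test_all_zero_eigenvalues_warn_and_return_zero(self):
        with pytest.warns(UserWarning):
            assert fl.entropy_from_eigenvalues(np.array([1e-12]), T) == 0.0

    def test_monotone_in_eigenvalue_scale(self):
        lam = np.array([2.0, 1.0, 0.5]) * _alpha_one_eigenvalue()
        s1 = fl.entropy_from_eigenvalues(lam, T)
        s2 = fl.entropy_from_eigenvalues(1.7 * lam, T)
        assert s2 > s1

    def test_mass_doubling_consistent_with_direct_reevaluation(self, rng):
        # doubling masses doubles the mass-weighted eigenvalues
        lam = np.abs(rng.standard_normal(5)) * _alpha_one_eigenvalue()
        s_direct = fl.entropy_from_eigenvalues(2.0 * lam, T)
        coords = rng.standard_normal((2000, 2, 3))
        t1 = _toy_traj(coords, masses=[1.0, 1.0])
        t2 = _toy_traj(coords, masses=[2.0, 2.0])
        r1 = fl.mass_weighted_covariance(t1)
        r2 = fl.mass_weighted_covariance(t2)
        np.testing.assert_allclose(r2.mw_eigenvalues, 2 * r1.mw_eigenvalues, rtol=1e-10)
        assert fl.quasiharmonic_entropy(r2, T) == pytest.approx(
            fl.entropy_from_eigenvalues(2 * r1.mw_eigenvalues, T), abs=1e-10
        )
        assert s_direct == pytest.approx(fl.entropy_from_eigenvalues(2 * lam, T))

    def test_entropy_invariant_under_rigid_motion(self, wc_template, rng):
        ens = synthetic.gaussian_ensemble(wc_template, 0.09, 500, seed=9)
        rot = random_rotation(rng)
        moved = ens.with_coords(ens.coords @ rot.T + 5.0)
        s0 = fl.quasiharmonic_entropy(fl.mass_weighted_covariance(ens), T)
        s1 = fl.quasiharmonic_entropy(fl.mass_weighted_covariance(moved), T)
        assert s1 == pytest.approx(s0, rel=1e-8)


class TestRmsf:
    def test_constant_trajectory_zero(self, wc_template):
        traj = wc_template.with_coords(np.repeat(wc_template.coords, 3, axis=0))
        assert np.allclose(fl.rmsf(traj), 0)

    def test_isotropic_jitter_sigma_sqrt3(self, wc_template):
        sigma = 0.5
        ens = synthetic.gaussian_ensemble(wc_template, sigma**2, 20_000, seed=2)
        vals = fl.rmsf(ens)
        np.testing.assert_allclose(vals, sigma * np.sqrt(3), rtol=0.03)

    def test_matches_double_loop_oracle(self, rng):
        coords = rng.standard_normal((9, 4, 3))
        traj = _toy_traj(coords, masses=[1.0] * 4)
        got = fl.rmsf(traj)
        for i in range(4):
            mean = coords[:, i].mean(axis=0)
            acc = 0.0
            for f in range(9):
                acc += ((coords[f, i] - mean) ** 2).sum()
            assert got[i] == pytest.approx(np.sqrt(acc / 9), abs=1e-10)


class TestRmsfRatio:
    def test_identity_and_scaling(self):
        r = np.array([0.5, 1.0, 2.0])
        assert np.allclose(fl.rmsf_ratio(r, r), 1.0)
        assert np.allclose(fl.rmsf_ratio(2 * r, r), 2.0)

    def test_mismatch_raises(self):
        with pytest.raises(ConsistencyError):
            fl.rmsf_ratio(np.ones(3), np.ones(4))

    def test_zero_denominator_flagged_nan(self):
        out = fl.rmsf_ratio(np.array([1.0, 1.0]), np.array([1.0, 0.0]))
        assert np.isnan(out[1]) and out[0] == 1.0

    def test_residue_aggregation(self):
        hg = np.array([1.0, 3.0, 2.0, 2.0])
        wc = np.array([1.0, 1.0, 1.0, 1.0])
        out = fl.rmsf_ratio(hg, wc, aggregation="residue", residue_ids=[1, 1, 2, 2])
        np.testing.assert_allclose(out, [2.0, 2.0])


class TestWindows:
    def _traj_100ns(self):
        n = 101
        coords = np.zeros((n, 1, 3))
        times = np.linspace(0, 100, n)
        return _toy_traj(coords, masses=[1.0]).with_coords(coords, times)

    def test_production_window_scheme(self):
        traj = self._traj_100ns()
        spec = fl.WindowSpec(window_length=50.0, stride=10.0, start=10.0)
        wins = fl.segment_windows(traj, spec)
        assert len(wins) == 5
        spans = [(w.frame_times[0], w.frame_times[-1]) for w in wins]
        assert spans == [(10, 60), (20, 70), (30, 80), (40, 90), (50, 100)]

    def test_full_span_single_window(self):
        traj = self._traj_100ns()
        wins = fl.segment_windows(traj, fl.WindowSpec(100.0, 10.0, 0.0))
        assert len(wins) == 1

    def test_stride_beyond_span_single_window(self):
        traj = self._traj_100ns()
        wins = fl.segment_windows(traj, fl.WindowSpec(60.0, 500.0, 0.0))
        assert len(wins) == 1

    def test_too_short_raises(self):
        traj = self._traj_100ns()
        with pytest.raises(StatisticsError):
            fl.segment_windows(traj, fl.WindowSpec(200.0, 10.0, 0.0))


class TestMeanCI:
    def test_one_to_five(self):
        mean, hw = fl.mean_ci95([1, 2, 3, 4, 5])
        assert mean == 3.0
        # t_{0.975,4} = 2.776..., s = 1.5811, n = 5
        assert hw == pytest.approx(2.7764 * 1.5811 / np.sqrt(5), abs=1e-3)
        assert hw == pytest.approx(1.963, abs=1e-3)

    def test_equal_values_zero_halfwidth(self):
        assert fl.mean_ci95([2.0, 2.0, 2.0])[1] == 0.0

    def test_two_values(self):
        assert fl.mean_ci95([0.0, 2.0])[0] == 1.0

    def test_single_value_raises(self):
        with pytest.raises(StatisticsError):
            fl.mean_ci95([1.0])
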
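"""PMF grids: anchoring, ΔG, watershed paths, reweighting, convergence, I/O."""
import itertools

import numpy as np
import pytest

from bpbreathe import landscape as ls
from bpbreathe.constants import KB_KCAL
from bpbreathe.errors import BpBreatheError, FormatError, NoPathError


def axis(n=4, periodic=False, name="x", lo=0.0, hi=None):
    hi = float(n) if hi is None else hi
    return ls.GridAxis(name, lo, hi, n, periodic=periodic)


def grid2(values, periodic=(False, False)):
    values = np.asarray(values, dtype=float)
    ax1 = axis(values.shape[0], periodic[0], "a")
    ax2 = axis(values.shape[1], periodic[1], "b")
    return ls.PMFGrid((ax1, ax2), values)


def brute_force_barrier(values, start, end, periodic):
    """Exhaustive minimax over all simple 8-neighbour paths (with pruning)."""
    shape = values.shape
    best = [np.inf]

    def neighbors(node):
        out = []
        for di, dj in itertools.product((-1, 0, 1), repeat=2):
            if (di, dj) == (0, 0):
                continue
            i, j = node[0] + di, node[1] + dj
            if periodic[0]:
                i %= shape[0]
            elif not 0 <= i < shape[0]:
                continue
            if periodic[1]:
                j %= shape[1]
            elif not 0 <= j < shape[1]:
                continue
            out.append((i, j))
        return out

    def dfs(node, cur_max, visited):
        if cur_max >= best[0]:
            return
        if node == end:
            best[0] = cur_max
            return
        for nb in neighbors(node):
            if nb not in visited and not np.isnan(values[nb]):
                dfs(nb, max(cur_max, values[nb]), visited | {nb})

    dfs(start, values[start], frozenset({start}))
    return best[0]


class TestAnchorAndDeltaG:
    def test_anchor_shifts_min_to_zero(self):
        g = grid2([[4.2, 5.0], [6.0, 7.0]])
        a = ls.anchor_zero(g)
        assert np.nanmin(a.values) == 0.0
        np.testing.assert_allclose(a.values, g.values - 4.2)
        again = ls.anchor_zero(a)
        np.testing.assert_allclose(again.values, a.values)

    def test_all_equal_grid_anchors_to_zeros(self):
        a = ls.anchor_zero(grid2(np.full((3, 3), 2.5)))
        assert np.all(a.values == 0.0)

    def test_delta_g_constructed_wells(self):
        vals = np.full((10, 10), 5.0)
        vals[2, 2] = 0.0
        vals[7, 7] = 3.0
        g = grid2(vals)
        ba = ((0.0, 4.0), (0.0, 4.0))
        bb = ((5.0, 10.0), (5.0, 10.0))
        assert ls.delta_g(g, ba, bb) == pytest.approx(3.0)
        assert ls.delta_g(g, bb, ba) == pytest.approx(-3.0)

    def test_symmetric_wells_zero(self):
        vals = np.full((8, 8), 4.0)
        vals[1, 1] = vals[6, 6] = 1.0
        g = grid2(vals)
        assert ls.delta_g(g, ((0, 3), (0, 3)), ((4, 8), (4, 8))) == 0.0

    def test_empty_basin_raises(self):
        g = grid2(np.full((4, 4), np.nan))
        with pytest.raises(BpBreatheError):
            ls.anchor_zero(g)


class TestMinFreeEnergyPath:
    def test_low_row_is_followed(self):
        vals = np.full((5, 5), 10.0)
        vals[2, :] = 1.0
        g = grid2(vals)
        mep = ls.min_free_energy_path(g, (2, 0), (2, 4))
        assert all(n[0] == 2 for n in mep.nodes)
        assert mep.barrier == 1.0

    def test_random_grids_match_exhaustive_enumeration(self):
        rng = np.random.default_rng(99)
        for _ in range(25):
            vals = rng.uniform(0, 10, size=(4, 4))
            g = grid2(vals)
            mep = ls.min_free_energy_path(g, (0, 0), (3, 3))
            oracle = brute_force_barrier(vals, (0, 0), (3, 3), (False, False))
            assert mep.barrier == pytest.approx(oracle, abs=1e-12)
            # returned path is simple and achieves its barrier
            assert len(set(mep.nodes)) == len(mep.nodes)
            assert mep.profile.max() == pytest.approx(mep.barrier)

    def test_periodic_channel_wraps(self):
        vals = np.full((6, 6), 8.0)
        vals[0, 0] = vals[0, 5] = 0.5  # low channel across the wrap on axis 2
        vals[0, 1] = 6.0  # non-wrapping detour is expensive
        g = grid2(vals, periodic=(False, True))
        mep = ls.min_free_energy_path(g, (0, 0), (0, 5))
        assert len(mep.nodes) == 2  # stepped straight across the boundary
        g_nowrap = grid2(vals, periodic=(False, False))
        mep_nowrap = ls.min_free_energy_path(g_nowrap, (0, 0), (0, 5))
        assert mep.barrier < mep_nowrap.barrier

    def test_disconnected_regions_raise(self):
        vals = np.full((4, 4), 1.0)
        vals[:, 2] = np.nan
        g = grid2(vals)
        with pytest.raises(NoPathError):
            ls.min_free_energy_path(g, (0, 0), (0, 3))

    def test_barrier_invariant_under_constant_shift(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(0, 5, (5, 5))
        m1 = ls.min_free_energy_path(grid2(vals), (0, 0), (4, 4))
        m2 = ls.min_free_energy_path(grid2(vals + 7.3), (0, 0), (4, 4))
        assert m2.barrier == pytest.approx(m1.barrier + 7.3, abs=1e-10)

    def test_raising_off_path_node_never_lowers_barrier(self):
        rng = np.random.default_rng(8)
        vals = rng.uniform(0, 5, (4, 4))
        base = ls.min_free_energy_path(grid2(vals), (0, 0), (3, 3))
        off_path = [
            (i, j)
            for i in range(4)
            for j in range(4)
            if (i, j) not in base.nodes
        ]
        for node in off_path[:5]:
            bumped = vals.copy()
            bumped[node] += 3.0
            raised = ls.min_free_energy_path(grid2(bumped), (0, 0), (3, 3))
            assert raised.barrier >= base.barrier - 1e-12


class TestPathProfile:
    def test_single_node(self):
        g = grid2(np.arange(16.0).reshape(4, 4))
        arc, prof = ls.path_profile(g, [(1, 1)])
        assert arc.tolist() == [0.0] and prof.tolist() == [5.0]

    def test_flat_grid_constant_profile(self):
        g = grid2(np.full((4, 4), 2.0))
        arc, prof = ls.path_profile(g, [(0, 0), (1, 1), (2, 2)])
        assert np.all(prof == 2.0)
        assert arc[-1] == pytest.approx(2 * np.sqrt(2))

    def test_linear_ramp(self):
        vals = np.tile(np.arange(5.0), (5, 1))
        g = grid2(vals)
        arc, prof = ls.path_profile(g, [(2, j) for j in range(5)])
        np.testing.assert_allclose(prof, np.arange(5.0))
        np.testing.assert_allclose(np.diff(arc), 1.0)


class TestReweighting:
    def test_zero_bias_reduces_to_boltzmann_inversion(self, rng):
        x = rng.normal(0.0, 1.0, size=20_000)
        ax = ls.GridAxis("x", -4, 4, 16)
        pmf = ls.reweight_to_new_cvs(x[:, None], (ax,), 298.0)
        counts, _ = np.histogram(x, bins=ax.edges())
        kt = KB_KCAL * 298.0
        expected = -kt * np.log(counts / counts.max())
        got = pmf.values[counts > 0]
        np.testing.assert_allclose(got, expected[counts > 0], atol=1e-10)

    def test_duplicating_samples_is_invariant(self, rng):
        x = rng.normal(0.0, 1.0, size=5000)
        b = rng.uniform(0, 2, size=5000)
        ax = ls.GridAxis("x", -4, 4, 16)
        p1 = ls.reweight_to_new_cvs(x[:, None], (ax,), 298.0, bias_free_energy=b)
        p2 = ls.reweight_to_new_cvs(
            np.concatenate([x, x])[:, None], (ax,), 298.0,
            bias_free_energy=np.concatenate([b, b]),
        )
        np.testing.assert_allclose(p1.values, p2.values, atol=1e-10)

    def test_known_biased_density_recovered(self, rng):
        kt = KB_KCAL * 298.0
        n_fine = 3600
        xs = np.linspace(-180, 180, n_fine, endpoint=False) + 0.05
        u = 1.5 * (1 - np.cos(2 * np.radians(xs)))
        b = 1.0 * np.cos(np.radians(xs))
        p = np.exp(-(u + b) / kt)
        p /= p.sum()
        idx = rng.choice(n_fine, size=200_000, p=p)
        x = xs[idx] + rng.uniform(-0.05, 0.05, size=idx.size)
        ax = ls.GridAxis("x", -180, 180, 72, periodic=True)
        pmf = ls.reweight_to_new_cvs(
            x[:, None], (ax,), 298.0,
            bias_free_energy=u[idx], cv_biased=x[:, None], biased_axes=(ax,),
        )
        cen = ax.centers()
        u_ref = 1.5 * (1 - np.cos(2 * np.radians(cen)))
        u_ref -= u_ref.min()
        rms = np.sqrt(np.mean((pmf.values - u_ref) ** 2))
        assert rms < 0.1

    def test_nonfinite_bias_rejected(self):
        ax = ls.GridAxis("x", 0, 1, 4)
        with pytest.raises(BpBreatheError):
            ls.reweight_to_new_cvs(
                np.array([[0.5]]), (ax,), 298.0, bias_free_energy=np.array([np.inf])
            )


class TestConvergence:
    def test_identical_pmfs_zero(self):
        g = grid2(np.arange(16.0).reshape(4, 4))
        assert ls.convergence_series([g, g, g]).tolist() == [0.0, 0.0]

    def test_constant_offset_zero_after_anchoring(self):
        g1 = grid2(np.arange(16.0).reshape(4, 4))
        g2 = grid2(np.arange(16.0).reshape(4, 4) + 3.0)
        assert ls.convergence_series([g1, g2])[0] == pytest.approx(0.0, abs=1e-12)

    def test_constructed_perturbation_rms(self):
        base = np.zeros((4, 4))
        base[0, 0] = 0.0  # anchored already
        pert = base.copy()
        pert[1:, :] += 0.5  # min still 0 at [0,*]? keep [0,:] zero
        g1, g2 = grid2(base), grid2(pert)
        expected = np.sqrt(np.mean((base - pert) ** 2))
        assert ls.convergence_series([g1, g2])[0] == pytest.approx(expected, abs=1e-12)

    def test_shape_mismatch_raises(self):
        from bpbreathe.errors import ConsistencyError

        with pytest.raises(ConsistencyError):
            ls.convergence_series([grid2(np.zeros((4, 4))), grid2(np.zeros((3, 3)))])


class TestGridIO:
    def test_roundtrip_is_exact(self, tmp_path, rng):
        vals = rng.uniform(-3, 9, size=(5, 7))
        vals[2, 3] = np.nan
        ax1 = ls.GridAxis("chi", -180.0, 180.0, 5, periodic=True, units="deg")
        ax2 = ls.GridAxis("d", 0.0, 14.0, 7, periodic=False, units="A")
        g = ls.PMFGrid((ax1, ax2), vals)
        path = tmp_path / "grid.pmf"
        ls.write_pmf(g, path)
        back = ls.read_pmf(path)
        assert back.axes[0].periodic and not back.axes[1].periodic
        assert back.axes[0].lower == -180.0
        np.testing.assert_array_equal(back.values, g.values)  # bit-faithful

    def test_bad_header_raises(self, tmp_path):
        p = tmp_path / "bad.pmf"
        p.write_text("1.0\n2.0\n")
        with pytest.raises(FormatError):
            ls.read_pmf(p)

    def test_wrong_value_count_raises(self, tmp_path):
        p = tmp_path / "short.pmf"
        p.write_text("# 1\n# x 0.0 1.0 4 0\n1.0\n2.0\n")
        with pytest.raises(FormatError):
            ls.read_pmf(p)
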
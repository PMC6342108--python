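import itertools

import numpy as np
import pytest

from microscape.resistance import (
    MODES,
    TransformSpec,
    combine_surfaces,
    commute_distance_matrix,
    raster_graph,
    transform_surface,
)
from microscape.surfaces import GridSurface


def dense_commute_oracle(rs, points):
    """Brute-force commute distances via the dense Laplacian pseudoinverse.

    For a connected graph L+ = (L + J/n)^-1 - J/n exactly, which avoids the
    accuracy loss of an SVD-based pseudoinverse.
    """
    adj, index = raster_graph(rs)
    lap = np.diag(np.asarray(adj.sum(axis=1)).ravel()) - adj.toarray()
    nv = lap.shape[0]
    lplus = np.linalg.inv(lap + 1.0 / nv) - 1.0 / nv
    vol = float(adj.sum())
    cells = [index[rs.cell_of(x, y)] for x, y in points]
    n = len(points)
    out = np.zeros((n, n))
    for a in range(n):
        for b in range(n):
            i, j = cells[a], cells[b]
            out[a, b] = vol * (lplus[i, i] + lplus[j, j] - 2 * lplus[i, j])
    return out


class TestTransformSpec:
    def test_validation(self):
        with pytest.raises(ValueError):
            TransformSpec(family="gompertz")
        with pytest.raises(ValueError):
            TransformSpec(shape=-1.0)
        with pytest.raises(ValueError):
            TransformSpec(magnitude=1.0)  # must exceed 1
        with pytest.raises(ValueError):
            TransformSpec(magnitude=3000.0)  # above default cap 2500


class TestTransformSurface:
    def test_rescale_endpoints(self, ramp_surface):
        spec = TransformSpec("monomolecular", "plain", shape=0.5, magnitude=50.0)
        rs = transform_surface(ramp_surface, spec)
        vals = rs.unmasked()
        assert vals.min() == pytest.approx(1.0)
        assert vals.max() == pytest.approx(50.0)
        # monomolecular/plain is monotone along the ramp
        row = rs.values[0]
        assert (np.diff(row) >= -1e-9).all()
        # minimum x cell -> 1, maximum x cell -> r
        assert rs.values[0, 0] == pytest.approx(1.0)
        assert rs.values[0, -1] == pytest.approx(50.0)

    def test_ricker_argmax_at_inverse_b(self):
        # dense ramp so the x = 1/b cell exists almost exactly
        vals = np.linspace(0.0, 10.0, 2001).reshape(1, -1)
        s = GridSurface(vals, cell_size=1.0)
        b = 0.5
        spec = TransformSpec("ricker", "plain", shape=b, magnitude=100.0)
        rs = transform_surface(s, spec)
        argmax_x = vals[0, np.argmax(rs.values[0])]
        assert argmax_x == pytest.approx(1.0 / b, abs=0.01)

    def test_flat_surface_rejected(self):
        s = GridSurface(np.full((4, 4), 3.3), cell_size=5.0)
        with pytest.raises(ValueError, match="zero range"):
            transform_surface(s, TransformSpec())

    @pytest.mark.parametrize("family", ["monomolecular", "ricker"])
    @pytest.mark.parametrize("mode", MODES)
    def test_eight_modes_curve_shapes(self, ramp_surface, family, mode):
        spec = TransformSpec(family, mode, shape=0.4, magnitude=10.0)
        rs = transform_surface(ramp_surface, spec)
        row = rs.values[0]
        assert row.min() == pytest.approx(1.0)
        assert row.max() == pytest.approx(10.0)
        diffs = np.diff(row)
        if family == "monomolecular":
            # saturating: monotone, direction flips with reverse/inverse parity
            rising = mode in ("plain", "inverse-reverse")
            assert (diffs >= -1e-9).all() if rising else (diffs <= 1e-9).all()
        else:
            # hump-shaped (or valley for inverse): at most one sign change
            signs = np.sign(diffs[np.abs(diffs) > 1e-12])
            changes = int((np.diff(signs) != 0).sum())
            assert changes <= 1

    def test_inverse_monomolecular_bare_soil_high_resistance(self):
        # NDVI-like ramp: cells below 0.1 (bare soil) get the top resistances
        vals = np.linspace(-0.2, 0.8, 101).reshape(1, -1)
        s = GridSurface(vals, cell_size=5.0)
        spec = TransformSpec("monomolecular", "inverse", shape=1.0,
                             magnitude=100.0)
        rs = transform_surface(s, spec)
        bare = rs.values[0, vals[0] < 0.1]
        vegetated = rs.values[0, vals[0] >= 0.1]
        assert bare.min() > vegetated.mean()
        assert rs.values[0, 0] == pytest.approx(100.0)  # barest cell

    def test_composite_minimum_one(self, ramp_surface):
        t1 = transform_surface(ramp_surface, TransformSpec(magnitude=20.0))
        t2 = transform_surface(
            ramp_surface, TransformSpec("ricker", "inverse", 0.3, 30.0)
        )
        comp = combine_surfaces([t1, t2])
        assert comp.unmasked().min() == pytest.approx(1.0)
        with pytest.raises(ValueError):
            combine_surfaces([t1])


class TestCommuteDistance:
    def test_two_vertex_closed_form(self):
        # 1x2 raster: single edge of conductance c; commute = vol * R_eff
        # = 2c * (1/c) = 2 for any c
        for resistance in (1.0, 5.0, 50.0):
            rs = GridSurface(np.full((1, 2), resistance), cell_size=10.0,
                             origin=(0.0, 10.0))
            pts = np.array([[5.0, 5.0], [15.0, 5.0]])
            m = commute_distance_matrix(rs, pts)
            assert m.values[0, 1] == pytest.approx(2.0, rel=1e-12)

    def test_uniform_3x3_matches_dense_oracle(self):
        rs = GridSurface(np.ones((3, 3)) * 2.0, cell_size=10.0,
                         origin=(0.0, 30.0))
        pts = np.array([[5.0, 25.0], [15.0, 15.0], [25.0, 5.0], [5.0, 5.0]])
        m = commute_distance_matrix(rs, pts)
        oracle = dense_commute_oracle(rs, pts)
        assert np.allclose(m.values, oracle, rtol=1e-8)

    def test_random_raster_matches_oracle(self):
        rng = np.random.default_rng(8)
        rs = GridSurface(rng.uniform(1, 30, (8, 9)), cell_size=5.0,
                         origin=(0.0, 40.0))
        pts = np.array([[2.0, 38.0], [42.0, 3.0], [20.0, 20.0]])
        m = commute_distance_matrix(rs, pts)
        oracle = dense_commute_oracle(rs, pts)
        assert np.allclose(m.values, oracle, rtol=1e-8)

    def test_permutation_symmetry(self):
        rng = np.random.default_rng(3)
        rs = GridSurface(rng.uniform(1, 10, (6, 6)), cell_size=5.0,
                         origin=(0.0, 30.0))
        pts = np.array([[2.0, 28.0], [15.0, 15.0], [28.0, 2.0]])
        m1 = commute_distance_matrix(rs, pts, labels=["a", "b", "c"])
        m2 = commute_distance_matrix(rs, pts[::-1], labels=["c", "b", "a"])
        assert np.allclose(m1.values, m2.values[::-1, ::-1])

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(1, 20, (5, 5))
        pts = np.array([[2.0, 23.0], [22.0, 2.0]])
        m1 = commute_distance_matrix(
            GridSurface(vals, 5.0, origin=(0.0, 25.0)), pts
        )
        m2 = commute_distance_matrix(
            GridSurface(vals * 7.0, 5.0, origin=(0.0, 25.0)), pts
        )
        # vol scales by 1/7, R_eff by 7: commute matrix unchanged
        assert np.allclose(m1.values, m2.values, rtol=1e-10)

    def test_masked_point_and_disconnection_errors(self):
        vals = np.ones((3, 3))
        mask = np.zeros((3, 3), dtype=bool)
        mask[:, 1] = True  # wall disconnects left and right columns
        rs = GridSurface(vals, 10.0, origin=(0.0, 30.0), mask=mask)
        with pytest.raises(ValueError, match="masked"):
            commute_distance_matrix(rs, np.array([[15.0, 15.0], [5.0, 5.0]]))
        with pytest.raises(ValueError, match="disconnected"):
            commute_distance_matrix(rs, np.array([[5.0, 15.0], [25.0, 15.0]]))

    def test_effective_resistance_triangle_inequality(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            rs = GridSurface(rng.uniform(1, 50, (5, 5)), cell_size=10.0,
                             origin=(0.0, 50.0))
            pts = rng.uniform(1, 49, size=(3, 2))
            m = commute_distance_matrix(rs, pts).values
            for i, j, k in itertools.permutations(range(3), 3):
                assert m[i, j] <= m[i, k] + m[k, j] + 1e-9

    def test_corridor_monotonicity(self):
        # raising resistance on the only corridor never lowers commute dist
        base = np.ones((3, 5))
        mask = np.zeros((3, 5), dtype=bool)
        mask[0, 2] = mask[2, 2] = True  # corridor through the middle cell
        pts = np.array([[5.0, 15.0], [45.0, 15.0]])
        prev = 0.0
        for corridor_r in (1.0, 5.0, 25.0):
            vals = base.copy()
            vals[1, 2] = corridor_r
            rs = GridSurface(vals, 10.0, origin=(0.0, 30.0), mask=mask)
            d = commute_distance_matrix(rs, pts).values[0, 1]
            assert d >= prev
            prev = d
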
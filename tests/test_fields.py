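"""Shim-field model: grid geometry, harmonic symmetries, linearity, coupling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from parashim.fields import (
    COIL_NAMES,
    FieldMap,
    build_coupling_matrix,
    build_sample_grid,
    build_sh_basis,
    sample_intrinsic_distortion,
    total_field,
)


class TestSampleGrid:
    def test_axial_three_point_layout(self):
        grid = build_sample_grid(1.0, 8.0, 1, 3)
        assert grid.n_points == 3
        np.testing.assert_allclose(sorted(grid.z), [-4.0, 0.0, 4.0])
        np.testing.assert_allclose(grid.points[:, :2], 0.0)
        np.testing.assert_allclose(grid.weights, 1.0 / 3.0)

    def test_weights_normalized_and_geometry_bounded(self):
        grid = build_sample_grid(1.0, 8.0, 4, 64)
        assert grid.n_points == 256
        assert abs(grid.weights.sum() - 1.0) < 1e-12
        assert np.all(grid.weights >= 0)
        assert np.max(np.abs(grid.z)) <= 4.0
        r = np.hypot(grid.points[:, 0], grid.points[:, 1])
        assert np.max(r) <= 0.5 + 1e-12

    def test_z_symmetry(self):
        grid = build_sample_grid(1.0, 8.0, 4, 64)
        flipped = grid.points.copy()
        flipped[:, 2] *= -1
        orig = {tuple(np.round(p, 12)) for p in grid.points}
        assert {tuple(np.round(p, 12)) for p in flipped} == orig

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            build_sample_grid(-1.0, 8.0, 4, 64)
        with pytest.raises(ValueError):
            build_sample_grid(1.0, 8.0, 4, 2)


class TestShimBasis:
    @pytest.fixture(scope="class")
    def grid(self):
        return build_sample_grid(1.0, 8.0, 4, 64)

    @pytest.fixture(scope="class")
    def basis(self, grid):
        return build_sh_basis(grid, [1.0, 1.0, 1.0, 1.0, 1.0, 1.0])

    def test_parities(self, grid, basis):
        """Z, Z3 odd and Z2, Z4 even under z -> -z; X odd in x; Y odd in y."""
        # map each point to its z-mirror partner
        key = lambda p: tuple(np.round(p, 10))
        index = {key(p): i for i, p in enumerate(grid.points)}
        mirror = [index[key(p * np.array([1, 1, -1]))] for p in grid.points]
        for name, parity in [("Z", -1), ("Z3", -1), ("Z2", +1), ("Z4", +1)]:
            prof = basis.profiles[COIL_NAMES.index(name)]
            np.testing.assert_allclose(prof[mirror], parity * prof, atol=1e-12)
        xmirror = [index.get(key(p * np.array([-1, 1, 1]))) for p in grid.points]
        assert all(i is not None for i in xmirror)
        x_prof = basis.profiles[COIL_NAMES.index("X")]
        np.testing.assert_allclose(x_prof[xmirror], -x_prof, atol=1e-12)

    def test_gain_scaling_at_reference(self):
        grid = build_sample_grid(1.0, 8.0, 1, 3)  # points at z = -4, 0, 4
        basis = build_sh_basis(grid, [1, 1, 5.0, 3.0, 2.0, 1.0])
        z_prof = basis.profiles[COIL_NAMES.index("Z")]
        top = int(np.argmax(grid.z))
        assert z_prof[top] == pytest.approx(5.0)
        assert z_prof[np.argmin(np.abs(grid.z))] == 0.0
        z2 = basis.profiles[COIL_NAMES.index("Z2")]
        assert z2[top] == pytest.approx(3.0)
        assert z2[np.argmin(grid.z)] == pytest.approx(3.0)  # even symmetry

    def test_xyz_orthogonality_decoupled(self, grid, basis):
        """Weighted Gram matrix of {X, Y, Z} is diagonal on the symmetric grid."""
        sub = basis.profiles[:3]
        gram = (sub * grid.weights) @ sub.T
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-10

    def test_wrong_gain_count(self, grid):
        with pytest.raises(ValueError):
            build_sh_basis(grid, [1.0, 2.0])

    def test_coil_subset(self, grid):
        basis = build_sh_basis(grid, [8.0, 6.0], coil_names=("Z", "Z2"))
        assert basis.coil_names == ("Z", "Z2")
        assert basis.profiles.shape == (2, grid.n_points)


class TestIntrinsicDistortion:
    def test_zero_span_is_zero_field(self):
        grid = build_sample_grid(1.0, 8.0, 4, 64)
        fm = sample_intrinsic_distortion(grid, 0.0, 0.0, seed=3)
        np.testing.assert_array_equal(fm.offsets, 0.0)

    def test_axial_span_matches_request(self):
        grid = build_sample_grid(1.0, 8.0, 1, 64)
        fm = sample_intrinsic_distortion(grid, 3000.0, 0.0, seed=5)
        span = fm.offsets.max() - fm.offsets.min()
        assert span == pytest.approx(3000.0, abs=1e-6)

    def test_transverse_span_bounded(self):
        grid = build_sample_grid(1.0, 8.0, 8, 16)
        fm = sample_intrinsic_distortion(grid, 0.0, 500.0, seed=5)
        assert fm.offsets.max() - fm.offsets.min() <= 500.0 + 1e-9

    def test_seeded_reproducibility(self):
        grid = build_sample_grid(1.0, 8.0, 4, 32)
        a = sample_intrinsic_distortion(grid, 1000.0, 200.0, seed=11)
        b = sample_intrinsic_distortion(grid, 1000.0, 200.0, seed=11)
        np.testing.assert_array_equal(a.offsets, b.offsets)


class TestTotalField:
    @pytest.fixture(scope="class")
    def world(self):
        grid = build_sample_grid(1.0, 8.0, 1, 16)
        basis = build_sh_basis(grid, [1, 1, 4.0, 3.0, 2.0, 1.5])
        intr = [
            sample_intrinsic_distortion(grid, 100.0, 0.0, seed=ch, channel_id=ch)
            for ch in range(2)
        ]
        return grid, [basis, basis], intr

    def test_zero_currents_identity_coupling(self, world):
        grid, bases, intr = world
        coup = build_coupling_matrix(2, 6, epsilon=0.0)
        out = total_field(bases, np.zeros((2, 6)), coup, intr)
        for ch in range(2):
            np.testing.assert_array_equal(out[ch].offsets, intr[ch].offsets)

    def test_linearity_in_currents(self, world, rng):
        grid, bases, intr = world
        zero = [FieldMap(np.zeros(grid.n_points), ch) for ch in range(2)]
        coup = build_coupling_matrix(2, 6, epsilon=0.1, seed=4)
        c = rng.normal(size=(2, 6))
        one = total_field(bases, c, coup, zero)
        two = total_field(bases, 2 * c, coup, zero)
        for ch in range(2):
            np.testing.assert_allclose(two[ch].offsets, 2 * one[ch].offsets, rtol=1e-12)

    @settings(deadline=None, max_examples=20)
    @given(st.integers(0, 2**31 - 1))
    def test_superposition(self, seed):
        """total_field is affine: f(a) + f(b) - f(0) == f(a + b)."""
        grid = build_sample_grid(1.0, 8.0, 1, 8)
        basis = build_sh_basis(grid, [1, 1, 4.0, 3.0, 2.0, 1.5])
        bases = [basis, basis]
        intr = [FieldMap(np.ones(grid.n_points) * 3.0, ch) for ch in range(2)]
        coup = build_coupling_matrix(2, 6, epsilon=0.1, seed=1)
        r = np.random.default_rng(seed)
        a, b = r.normal(size=(2, 2, 6))
        fa = total_field(bases, a, coup, intr)
        fb = total_field(bases, b, coup, intr)
        f0 = total_field(bases, np.zeros((2, 6)), coup, intr)
        fab = total_field(bases, a + b, coup, intr)
        for ch in range(2):
            np.testing.assert_allclose(
                fa[ch].offsets + fb[ch].offsets - f0[ch].offsets,
                fab[ch].offsets,
                rtol=1e-9, atol=1e-9,
            )

    def test_cross_channel_coupling_leak(self, world):
        """Unit current on channel-1 Z leaks eps x the Z profile into channel 2."""
        grid, bases, _ = world
        zero = [FieldMap(np.zeros(grid.n_points), ch) for ch in range(2)]
        eps = 0.1
        entries = np.eye(12)
        j = 2  # channel-1 Z coil, channel-major index
        entries[6 + 2, j] = eps  # channel-2 Z amplitude responds to channel-1 Z current
        from parashim.fields import CouplingMatrix

        coup = CouplingMatrix(entries=entries)
        cur = np.zeros((2, 6))
        cur[0, 2] = 1.0
        out = total_field(bases, cur, coup, zero)
        z_profile = bases[1].profiles[2]
        np.testing.assert_allclose(out[1].offsets, eps * z_profile, rtol=1e-12)
        np.testing.assert_allclose(out[0].offsets, z_profile, rtol=1e-12)

    def test_dimension_mismatch_raises(self, world):
        grid, bases, intr = world
        coup = build_coupling_matrix(2, 6, epsilon=0.0)
        with pytest.raises(ValueError):
            total_field(bases, np.zeros((2, 5)), coup, intr)


class TestCouplingMatrix:
    def test_identity_and_bounds(self):
        coup = build_coupling_matrix(2, 6, epsilon=0.1, seed=9)
        e = coup.entries
        np.testing.assert_array_equal(np.diag(e), 1.0)
        off = e - np.diag(np.diag(e))
        assert np.max(np.abs(off)) <= 0.1
        ident = build_coupling_matrix(2, 6, epsilon=0.0)
        np.testing.assert_array_equal(ident.entries, np.eye(12))
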
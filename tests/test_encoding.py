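"""NUFFT accuracy, adjointness, and the block-diagonal/subspace operators."""

import numpy as np
import pytest

from allt1.encoding import (
    EncodingOperator,
    NUFFT,
    SubspaceOperator,
    radial_density_weights,
    spoke_sample_coords,
)
from allt1.signal import SequenceTiming
from allt1.subspace import SubspaceBasis
from allt1.trajectory import golden_angle_directions_2d, make_trajectory, tgm_directions


def direct_dft(image, coords):
    """Brute-force DFT at arbitrary frequencies (cycles/FOV, centered)."""
    shape = image.shape
    centers = [n // 2 for n in shape]
    grids = np.meshgrid(*[np.arange(n) - c for n, c in zip(shape, centers)],
                        indexing="ij")
    out = np.empty(len(coords), dtype=np.complex128)
    for i, k in enumerate(coords):
        phase = sum(k[d] * grids[d] / shape[d] for d in range(len(shape)))
        out[i] = np.sum(image * np.exp(-2j * np.pi * phase))
    return out


@pytest.fixture(scope="module", params=[(16, 16), (8, 8, 8)], ids=["2d", "3d"])
def plan(request):
    shape = request.param
    n = shape[0]
    dirs = (golden_angle_directions_2d(20) if len(shape) == 2
            else tgm_directions(20))
    coords = spoke_sample_coords(dirs, n, n)
    return shape, coords, NUFFT(shape, coords)


class TestNUFFT:
    def test_matches_direct_dft(self, plan, rng):
        shape, coords, op = plan
        x = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
        y = op.forward(x)
        yd = direct_dft(x, coords)
        assert np.linalg.norm(y - yd) / np.linalg.norm(yd) < 1e-5

    def test_centered_impulse_gives_flat_spectrum(self, plan):
        shape, _, op = plan
        imp = np.zeros(shape, dtype=np.complex128)
        imp[tuple(n // 2 for n in shape)] = 1.0
        y = op.forward(imp)
        assert np.max(np.abs(y - 1.0)) < 1e-4

    def test_linearity(self, plan, rng):
        shape, _, op = plan
        x1 = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
        x2 = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
        lhs = op.forward(2.0 * x1 + (1 - 3j) * x2)
        rhs = 2.0 * op.forward(x1) + (1 - 3j) * op.forward(x2)
        assert np.linalg.norm(lhs - rhs) / np.linalg.norm(rhs) < 1e-10

    def test_adjoint_dot_test(self, plan, rng):
        shape, coords, op = plan
        u = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
        v = rng.standard_normal(len(coords)) + 1j * rng.standard_normal(len(coords))
        lhs = np.vdot(v, op.forward(u))
        rhs = np.vdot(op.adjoint(v), u)
        assert abs(lhs - rhs) / abs(lhs) < 1e-6

    def test_zero_samples_give_zero_volume(self, plan):
        shape, coords, op = plan
        out = op.adjoint(np.zeros(len(coords), dtype=np.complex128))
        assert np.all(out == 0)

    def test_density_compensated_adjoint_recovers_smooth_image(self):
        n = 32
        dirs = golden_angle_directions_2d(120)
        coords = spoke_sample_coords(dirs, n, n)
        op = NUFFT((n, n), coords)
        yy, xx = np.meshgrid(*(np.arange(n) - n // 2,) * 2, indexing="ij")
        img = np.exp(-(xx ** 2 + yy ** 2) / (2 * 5.0 ** 2)).astype(np.complex128)
        w = np.tile(radial_density_weights(n, n, 2), 120)
        rec = op.adjoint(w * op.forward(img))
        a, b = rec.real.ravel(), img.real.ravel()
        corr = np.corrcoef(a, b)[0, 1]
        assert corr > 0.99

    def test_out_of_band_coordinates_rejected(self):
        with pytest.raises(ValueError):
            NUFFT((16, 16), np.array([[9.0, 0.0]]))

    def test_shape_mismatch_rejected(self, plan, rng):
        shape, _, op = plan
        with pytest.raises(ValueError):
            op.forward(np.zeros([n + 1 for n in shape], dtype=complex))


@pytest.fixture(scope="module")
def small_operator():
    timing = SequenceTiming(n_spokes_per_part=24, n_bins_per_part=6)
    traj = make_trajectory(timing, n_rep=2, ndim=2)
    return EncodingOperator(traj, (16, 16))


class TestEncodingOperator:
    def test_block_diagonal_structure(self, small_operator, rng):
        op = small_operator
        series = rng.standard_normal(op.x_shape) + 1j * rng.standard_normal(op.x_shape)
        base = op.split(op.forward(series))
        perturbed = series.copy()
        perturbed[3] += rng.standard_normal(op.grid_shape)
        new = op.split(op.forward(perturbed))
        for t in range(op.n_bins):
            if t == 3:
                assert np.linalg.norm(new[t] - base[t]) > 0
            else:
                np.testing.assert_array_equal(new[t], base[t])

    def test_operator_dot_test(self, small_operator, rng):
        op = small_operator
        u = rng.standard_normal(op.x_shape) + 1j * rng.standard_normal(op.x_shape)
        v = rng.standard_normal(op.n_samples) + 1j * rng.standard_normal(op.n_samples)
        lhs = np.vdot(v, op.forward(u))
        rhs = np.vdot(op.adjoint(v), u)
        assert abs(lhs - rhs) / abs(lhs) < 1e-6


def _identity_basis(t):
    return SubspaceBasis(basis=np.eye(t), singular_values=np.ones(t), k=t)


class TestSubspaceOperator:
    def test_identity_basis_reduces_to_plain_forward(self, small_operator, rng):
        op = small_operator
        sub = SubspaceOperator(op, _identity_basis(op.n_bins))
        x = rng.standard_normal(op.x_shape) + 1j * rng.standard_normal(op.x_shape)
        np.testing.assert_allclose(sub.forward(x), op.forward(x), rtol=1e-12)

    def test_single_coefficient_expansion_oracle(self, small_operator, rng):
        op = small_operator
        t = op.n_bins
        basis_mat = np.linalg.qr(rng.standard_normal((t, 4)))[0]
        basis = SubspaceBasis(basis=basis_mat, singular_values=np.ones(t), k=4)
        sub = SubspaceOperator(op, basis)
        image = rng.standard_normal(op.grid_shape) + 1j * rng.standard_normal(op.grid_shape)
        coeffs = np.zeros(sub.x_shape, dtype=np.complex128)
        k = 2
        coeffs[k] = image
        # expansion oracle: bin t sees u_k(t) * image
        expected = op.forward(np.stack([basis_mat[tt, k] * image for tt in range(t)]))
        np.testing.assert_allclose(sub.forward(coeffs), expected, rtol=1e-10)

    def test_composed_adjoint_dot_test(self, small_operator, rng):
        op = small_operator
        t = op.n_bins
        basis_mat = np.linalg.qr(rng.standard_normal((t, 4)))[0]
        sub = SubspaceOperator(
            op, SubspaceBasis(basis=basis_mat, singular_values=np.ones(t), k=4)
        )
        u = rng.standard_normal(sub.x_shape) + 1j * rng.standard_normal(sub.x_shape)
        v = rng.standard_normal(sub.n_samples) + 1j * rng.standard_normal(sub.n_samples)
        lhs = np.vdot(v, sub.forward(u))
        rhs = np.vdot(sub.adjoint(v), u)
        assert abs(lhs - rhs) / abs(lhs) < 1e-6

    def test_composed_norm_not_larger_than_base(self, small_operator, rng):
        # power iteration; the basis is an isometry so norms cannot grow
        op = small_operator
        t = op.n_bins
        basis_mat = np.linalg.qr(rng.standard_normal((t, 4)))[0]
        sub = SubspaceOperator(
            op, SubspaceBasis(basis=basis_mat, singular_values=np.ones(t), k=4)
        )

        def power_norm(o, iters=15):
            x = rng.standard_normal(o.x_shape) + 1j * rng.standard_normal(o.x_shape)
            for _ in range(iters):
                x = o.adjoint(o.forward(x))
                x /= np.linalg.norm(x)
            return np.sqrt(np.linalg.norm(o.adjoint(o.forward(x))))

        assert power_norm(sub) <= power_norm(op) * (1 + 1e-6)

    def test_mismatched_coefficient_count_rejected(self, small_operator, rng):
        sub = SubspaceOperator(small_operator, _identity_basis(small_operator.n_bins))
        with pytest.raises(ValueError):
            sub.forward(np.zeros((3, *small_operator.grid_shape), dtype=complex))
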
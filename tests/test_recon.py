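"""Regularizers, proximal operators, LSMR and ADMM solvers."""

import numpy as np
import pytest

from allt1.encoding import EncodingOperator, SubspaceOperator
from allt1.recon import (
    MODEL_ACRONYMS,
    admm_reconstruct,
    llr_value,
    lsmr_solve,
    model_from_acronym,
    prox_llr,
    prox_stv_shrink,
    series_stv,
    spatial_gradient,
    spatial_gradient_adjoint,
    stv_value,
)
from allt1.signal import SequenceTiming
from allt1.subspace import SubspaceBasis
from allt1.trajectory import make_trajectory


class _DenseOp:
    """Matrix wrapped with the operator interface used by the solvers."""

    def __init__(self, a: np.ndarray, x_shape):
        self.a = np.asarray(a, dtype=np.complex128)
        self.x_shape = tuple(x_shape)

    def forward(self, x):
        return self.a @ np.asarray(x).ravel()

    def adjoint(self, y):
        return (self.a.conj().T @ np.asarray(y)).reshape(self.x_shape)


def _identity_op(x_shape):
    n = int(np.prod(x_shape))
    return _DenseOp(np.eye(n), x_shape)


class TestSTV:
    def test_constant_volume_has_zero_tv(self):
        assert stv_value(np.full((8, 8), 3.7)) == 0.0

    def test_1d_step_tv_equals_height_times_crossings(self):
        u = np.zeros(32)
        u[10:20] = 2.5  # two crossings of height 2.5
        assert stv_value(u) == pytest.approx(5.0)

    def test_positive_homogeneity(self, rng):
        u = rng.standard_normal((6, 7))
        assert stv_value(-3.0 * u) == pytest.approx(3.0 * stv_value(u), rel=1e-12)

    def test_gradient_adjoint_dot_test(self, rng):
        x = rng.standard_normal((3, 8, 9)) + 1j * rng.standard_normal((3, 8, 9))
        g = spatial_gradient(x)
        y = rng.standard_normal(g.shape) + 1j * rng.standard_normal(g.shape)
        lhs = np.vdot(y, g)
        rhs = np.vdot(spatial_gradient_adjoint(y), x)
        assert abs(lhs - rhs) / abs(lhs) < 1e-12


class TestProxSTV:
    def test_zero_threshold_is_identity(self, rng):
        g = rng.standard_normal((2, 5, 5))
        np.testing.assert_array_equal(prox_stv_shrink(g, 0.0), g)

    def test_small_gradients_vanish(self):
        g = np.full((3, 4, 4), 0.1)
        assert np.all(prox_stv_shrink(g, 10.0) == 0)

    def test_matches_scalar_shrinkage_oracle(self):
        g = np.array([3.0, 4.0, 0.0]).reshape(3, 1, 1)
        out = prox_stv_shrink(g, 1.0)
        np.testing.assert_allclose(out.ravel(), [2.4, 3.2, 0.0], rtol=1e-12)

    def test_non_expansive(self, rng):
        a = rng.standard_normal((3, 6, 6)) + 1j * rng.standard_normal((3, 6, 6))
        b = rng.standard_normal((3, 6, 6)) + 1j * rng.standard_normal((3, 6, 6))
        d = np.linalg.norm(prox_stv_shrink(a, 0.7) - prox_stv_shrink(b, 0.7))
        assert d <= np.linalg.norm(a - b) + 1e-12


class TestProxLLR:
    def test_zero_threshold_is_identity(self, rng):
        s = rng.standard_normal((4, 8, 8))
        np.testing.assert_array_equal(prox_llr(s, 0.0, 4), s)

    def test_rank_one_block_shrinks_singular_value_only(self, rng):
        # one 4x4 block, rank-1 Casorati matrix
        u = rng.standard_normal(16)
        v = rng.standard_normal(4)
        s0 = 5.0
        u /= np.linalg.norm(u)
        v /= np.linalg.norm(v)
        series = (s0 * np.outer(u, v)).T.reshape(4, 4, 4)
        out = prox_llr(series, 1.0, 4)
        expected = ((s0 - 1.0) * np.outer(u, v)).T.reshape(4, 4, 4)
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_large_threshold_zeroes_series(self, rng):
        s = rng.standard_normal((3, 8, 8))
        out = prox_llr(s, 1e6, 4)
        assert np.all(out == 0)

    def test_oversized_block_warns_and_uses_global_block(self, rng):
        s = rng.standard_normal((3, 4, 4))
        with pytest.warns(UserWarning):
            prox_llr(s, 0.1, 99)

    def test_non_expansive(self, rng):
        a = rng.standard_normal((3, 8, 8)) + 1j * rng.standard_normal((3, 8, 8))
        b = rng.standard_normal((3, 8, 8)) + 1j * rng.standard_normal((3, 8, 8))
        d = np.linalg.norm(prox_llr(a, 0.5, 4) - prox_llr(b, 0.5, 4))
        assert d <= np.linalg.norm(a - b) + 1e-10


class TestLSMR:
    def test_identity_operator_returns_data_after_one_iteration(self, rng):
        op = _identity_op((1, 12))
        y = rng.standard_normal(12) + 1j * rng.standard_normal(12)
        x = lsmr_solve(op, y, n_iters=1)
        np.testing.assert_allclose(x.ravel(), y, rtol=1e-10)

    def test_matches_direct_least_squares(self, rng):
        a = rng.standard_normal((20, 10)) + 1j * rng.standard_normal((20, 10))
        y = rng.standard_normal(20) + 1j * rng.standard_normal(20)
        op = _DenseOp(a, (1, 10))
        x = lsmr_solve(op, y, n_iters=10).ravel()
        ref = np.linalg.lstsq(a, y, rcond=None)[0]
        assert np.linalg.norm(x - ref) / np.linalg.norm(ref) < 1e-6

    def test_residual_non_increasing_in_iterations(self, rng):
        a = rng.standard_normal((30, 15))
        y = rng.standard_normal(30)
        op = _DenseOp(a, (1, 15))
        res = [np.linalg.norm(a @ lsmr_solve(op, y, n_iters=k).ravel() - y)
               for k in (1, 2, 4, 8)]
        assert np.all(np.diff(res) <= 1e-10)

    def test_non_finite_data_rejected(self):
        op = _identity_op((1, 4))
        with pytest.raises(ValueError):
            lsmr_solve(op, np.array([1.0, np.nan, 0.0, 0.0]))


def _tv_denoise_dual_reference(y, alpha, n_iters=10_000):
    """Projected-gradient solve of the 1-D TV-denoising dual problem."""
    n = len(y)

    def dmat(x):  # forward differences, replicate boundary
        g = np.zeros_like(x)
        g[:-1] = x[1:] - x[:-1]
        return g

    def dtmat(p):
        out = np.zeros_like(p)
        out[:-1] -= p[:-1]
        out[1:] += p[:-1]
        return out

    p = np.zeros(n)
    step = 1.0 / 4.0
    for _ in range(n_iters):
        grad = dmat(y - dtmat(p))
        p = np.clip(p + step * grad, -alpha, alpha)
    return y - dtmat(p)


class TestADMM:
    def test_zero_weights_dispatch_to_plain_least_squares(self, rng):
        a = rng.standard_normal((24, 12)) + 1j * rng.standard_normal((24, 12))
        y = rng.standard_normal(24) + 1j * rng.standard_normal(24)
        op = _DenseOp(a, (2, 6))
        model = model_from_acronym("LS", lsmr_iters=8)
        res = admm_reconstruct(model, op, y)
        direct = lsmr_solve(op, y, n_iters=8)
        np.testing.assert_allclose(res.series, direct, rtol=1e-6)

    def test_zero_data_gives_zero_solution(self):
        op = _identity_op((1, 16))
        model = model_from_acronym("STV", alpha_stv=0.5)
        res = admm_reconstruct(model, op, np.zeros(16, dtype=complex))
        assert np.linalg.norm(res.series) < 1e-12

    def test_tv_denoising_matches_slow_dual_reference(self, rng):
        y = np.concatenate([np.zeros(10), np.ones(12), 0.3 * np.ones(10)])
        y = y + 0.15 * rng.standard_normal(32)
        alpha = 0.3
        op = _identity_op((1, 32))
        # long ADMM run: this checks that ADMM solves the TV problem, at a
        # budget where the splitting has converged
        model = model_from_acronym("STV", alpha_stv=alpha, n_outer=300, n_inner=2)
        res = admm_reconstruct(model, op, y.astype(complex))
        x_ref = _tv_denoise_dual_reference(y, alpha)

        def objective(x):
            return 0.5 * np.sum(np.abs(x - y) ** 2) + alpha * stv_value(x)

        obj_admm = objective(res.series.ravel())
        obj_ref = objective(x_ref)
        assert abs(obj_admm - obj_ref) / obj_ref < 1e-3

    def test_objective_decreases_from_initialization(self, rng):
        a = rng.standard_normal((40, 32)) + 1j * rng.standard_normal((40, 32))
        y = rng.standard_normal(40) + 1j * rng.standard_normal(40)
        op = _DenseOp(a, (2, 4, 4))
        model = model_from_acronym("STV+LLR", alpha_stv=0.1, alpha_llr=0.1,
                                   block_side=2, n_outer=10)
        res = admm_reconstruct(model, op, y)
        assert res.objective[-1] <= res.objective[0]
        assert np.all(np.isfinite(res.objective))

    def test_stronger_tv_never_increases_solution_tv(self, rng):
        y = rng.standard_normal(24) + 0.5
        op = _identity_op((1, 24))
        tvs = []
        for alpha in (0.05, 0.2, 0.8):
            model = model_from_acronym("STV", alpha_stv=alpha)
            res = admm_reconstruct(model, op, y.astype(complex))
            tvs.append(series_stv(res.series))
        assert tvs[0] >= tvs[1] >= tvs[2] - 1e-9


@pytest.fixture(scope="module")
def radial_setup():
    timing = SequenceTiming(n_spokes_per_part=24, n_bins_per_part=6)
    traj = make_trajectory(timing, n_rep=2, ndim=2)
    op = EncodingOperator(traj, (12, 12))
    rng = np.random.default_rng(5)
    x_true = np.zeros(op.x_shape, dtype=np.complex128)
    x_true[:, 3:9, 3:9] = 1.0 + 0.2j
    y = op.forward(x_true)
    return op, y


class TestSubspaceConstrainedADMM:
    def test_full_identity_basis_reproduces_unconstrained_model(self, radial_setup):
        op, y = radial_setup
        t = op.n_bins
        basis = SubspaceBasis(basis=np.eye(t), singular_values=np.ones(t), k=t)
        sub = SubspaceOperator(op, basis)
        plain = admm_reconstruct(
            model_from_acronym("STV", alpha_stv=1e-3, n_outer=10), op, y)
        constrained = admm_reconstruct(
            model_from_acronym("S-STV", alpha_stv=1e-3, n_outer=10), sub, y)
        err = (np.linalg.norm(constrained.series - plain.series)
               / np.linalg.norm(plain.series))
        assert err < 1e-6

    def test_subspace_result_lies_in_basis_span(self, radial_setup):
        op, y = radial_setup
        t = op.n_bins
        rng = np.random.default_rng(2)
        basis_mat = np.linalg.qr(rng.standard_normal((t, 3)))[0]
        basis = SubspaceBasis(basis=basis_mat, singular_values=np.ones(t), k=3)
        res = admm_reconstruct(
            model_from_acronym("S-LS"), SubspaceOperator(op, basis), y)
        flat = res.series.reshape(t, -1)
        proj = basis_mat @ (basis_mat.T @ flat)
        assert np.linalg.norm(flat - proj) / np.linalg.norm(flat) < 1e-10


class TestModelTable:
    @pytest.mark.parametrize("name,constraint,stv,llr", [
        ("Reference", "image_domain", False, True),
        ("STV", "image_domain", True, False),
        ("S-STV", "subspace", True, False),
        ("LLR", "image_domain", False, True),
        ("S-LLR", "subspace", False, True),
        ("STV+LLR", "image_domain", True, True),
        ("S-STV+LLR", "subspace", True, True),
        ("LS", "image_domain", False, False),
        ("S-LS", "subspace", False, False),
    ])
    def test_acronym_dispatch(self, name, constraint, stv, llr):
        m = model_from_acronym(name, alpha_stv=1.0, alpha_llr=1.0)
        assert m.constraint == constraint
        assert (m.alpha_stv > 0) == stv
        assert (m.alpha_llr > 0) == llr
        if name == "Reference":
            assert m.block_side == 13

    def test_unknown_acronym_lists_options(self):
        with pytest.raises(ValueError, match="S-STV\\+LLR"):
            model_from_acronym("TGV")

    def test_llr_value_counts_nuclear_norm(self, rng):
        s = rng.standard_normal((3, 4, 4))
        cas = s.reshape(3, -1)
        expected = np.linalg.svd(cas, compute_uv=False).sum()
        assert llr_value(s, 4) == pytest.approx(expected)
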
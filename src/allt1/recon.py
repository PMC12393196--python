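"""Image reconstruction models: least squares and ADMM with spatial total
variation (STV) and locally low-rank (LLR) regularization.

Eight models are supported, with or without the temporal subspace
constraint:

=============  ==========  ==============================
acronym        constraint  regularization
=============  ==========  ==============================
Reference      none        LLR (large blocks)
STV            none        STV
S-STV          subspace    STV
LLR            none        LLR
S-LLR          subspace    LLR
STV+LLR        none        STV and LLR
S-STV+LLR      subspace    STV and LLR
LS             none        none (plain least squares)
S-LS           subspace    none
=============  ==========  ==============================

Unregularized models are solved with (density-weighted) LSMR.  Regularized
models use scaled-form ADMM with one splitting variable per regularizer:
spatial gradients handled by a group soft-threshold, the series copy by
per-block singular-value soft-thresholding of Casorati matrices.  The
least-squares x-update runs a small number of warm-started LSMR iterations
on the stacked operator.  Subspace-constrained models optimize the K
coefficient images, with the regularizers applied to the coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.sparse.linalg import LinearOperator, lsmr

__all__ = [
    "ReconModel",
    "ReconResult",
    "MODEL_ACRONYMS",
    "model_from_acronym",
    "spatial_gradient",
    "spatial_gradient_adjoint",
    "stv_value",
    "llr_value",
    "prox_stv_shrink",
    "prox_llr",
    "lsmr_solve",
    "admm_reconstruct",
]


# ---------------------------------------------------------------------------
# regularizer values and proximal operators

def spatial_gradient(series: np.ndarray) -> np.ndarray:
    """First-order forward differences of each image along every spatial axis.

    ``series`` has shape (T, *grid); the result has shape (d, T, *grid) with
    the replicate boundary convention (the last difference along each axis is
    zero), so constant images have exactly zero gradient.
    """
    series = np.asarray(series)
    d = series.ndim - 1
    out = np.zeros((d, *series.shape), dtype=series.dtype)
    for ax in range(d):
        sl_lo = [slice(None)] * series.ndim
        sl_hi = [slice(None)] * series.ndim
        sl_lo[ax + 1] = slice(0, -1)
        sl_hi[ax + 1] = slice(1, None)
        out[ax][tuple(sl_lo)] = series[tuple(sl_hi)] - series[tuple(sl_lo)]
    return out


def spatial_gradient_adjoint(grads: np.ndarray) -> np.ndarray:
    """Exact adjoint of :func:`spatial_gradient` (negative divergence)."""
    grads = np.asarray(grads)
    d = grads.shape[0]
    out = np.zeros(grads.shape[1:], dtype=grads.dtype)
    for ax in range(d):
        g = grads[ax].copy()
        # forward difference transpose: out[j] += g[j-1] - g[j], g[-1] ignored
        sl_last = [slice(None)] * g.ndim
        sl_last[ax + 1] = slice(-1, None)
        g[tuple(sl_last)] = 0.0
        out -= g
        sl_to = [slice(None)] * g.ndim
        sl_from = [slice(None)] * g.ndim
        sl_to[ax + 1] = slice(1, None)
        sl_from[ax + 1] = slice(0, -1)
        out[tuple(sl_to)] += g[tuple(sl_from)]
    return out


def stv_value(u: np.ndarray) -> float:
    """Isotropic total variation of a single volume: sum over voxels of the
    root-sum-of-squares of the first-order differences along every dimension
    of ``u`` (replicate boundary)."""
    u = np.asarray(u)
    g = spatial_gradient(u[None])
    return float(np.sqrt(np.sum(np.abs(g) ** 2, axis=0)).sum())


def series_stv(series: np.ndarray) -> float:
    """Summed isotropic TV over the images of a series (T, *grid)."""
    g = spatial_gradient(series)
    return float(np.sqrt(np.sum(np.abs(g) ** 2, axis=0)).sum())


def prox_stv_shrink(gradients: np.ndarray, tau: float) -> np.ndarray:
    """Voxelwise group soft-threshold ``g * max(1 - tau/||g||, 0)``; the
    group norm runs over the leading (gradient-component) axis, jointly over
    real and imaginary parts."""
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if tau == 0:
        return gradients.copy()
    norm = np.sqrt(np.sum(np.abs(gradients) ** 2, axis=0, keepdims=True))
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(norm > 0, np.maximum(1.0 - tau / norm, 0.0), 0.0)
    return gradients * scale


def _iter_blocks(spatial_shape, block_side):
    starts = [range(0, n, block_side) for n in spatial_shape]
    if len(spatial_shape) == 2:
        for i in starts[0]:
            for j in starts[1]:
                yield (slice(i, i + block_side), slice(j, j + block_side))
    else:
        for i in starts[0]:
            for j in starts[1]:
                for k in starts[2]:
                    yield (slice(i, i + block_side), slice(j, j + block_side),
                           slice(k, k + block_side))


def prox_llr(series: np.ndarray, tau: float, block_side: int) -> np.ndarray:
    """Singular-value soft-thresholding of the Casorati matrix of every
    non-overlapping block (edge blocks truncated).

    The Casorati matrix of a block has one column per image; thresholding
    its singular values by ``tau`` promotes local temporal low-rankness.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    series = np.asarray(series)
    if tau == 0:
        return series.copy()
    spatial = series.shape[1:]
    if block_side > max(spatial):
        warnings.warn("LLR block larger than the volume; using one global block")
        block_side = max(spatial)
    n_t = series.shape[0]
    out = np.empty_like(series)
    for sl in _iter_blocks(spatial, block_side):
        block = series[(slice(None), *sl)]
        shape = block.shape
        cas = block.reshape(n_t, -1).T  # voxels x T
        u, s, vt = np.linalg.svd(cas, full_matrices=False)
        s = np.maximum(s - tau, 0.0)
        out[(slice(None), *sl)] = ((u * s) @ vt).T.reshape(shape)
    return out


def llr_value(series: np.ndarray, block_side: int) -> float:
    """Summed nuclear norm of the per-block Casorati matrices."""
    series = np.asarray(series)
    spatial = series.shape[1:]
    if block_side > max(spatial):
        block_side = max(spatial)
    n_t = series.shape[0]
    total = 0.0
    for sl in _iter_blocks(spatial, block_side):
        cas = series[(slice(None), *sl)].reshape(n_t, -1)
        total += float(np.linalg.svd(cas, compute_uv=False).sum())
    return total


# ---------------------------------------------------------------------------
# model description

MODEL_ACRONYMS = {
    "Reference": dict(constraint="image_domain", use_stv=False, use_llr=True, block_side=13),
    "STV": dict(constraint="image_domain", use_stv=True, use_llr=False),
    "S-STV": dict(constraint="subspace", use_stv=True, use_llr=False),
    "LLR": dict(constraint="image_domain", use_stv=False, use_llr=True),
    "S-LLR": dict(constraint="subspace", use_stv=False, use_llr=True),
    "STV+LLR": dict(constraint="image_domain", use_stv=True, use_llr=True),
    "S-STV+LLR": dict(constraint="subspace", use_stv=True, use_llr=True),
    "LS": dict(constraint="image_domain", use_stv=False, use_llr=False),
    "S-LS": dict(constraint="subspace", use_stv=False, use_llr=False),
}


@dataclass
class ReconModel:
    """Declarative description of one reconstruction model."""

    name: str = "LS"
    constraint: str = "image_domain"  # or "subspace"
    alpha_stv: float = 0.0
    alpha_llr: float = 0.0
    block_side: int = 8
    n_outer: int = 30
    n_inner: int = 2
    lsmr_iters: int = 5
    rho_stv: float | None = None  # None: scale-aware default (see admm_reconstruct)
    rho_llr: float | None = None
    warm_start: bool = True
    use_density_weights: bool = True

    def __post_init__(self) -> None:
        if self.alpha_stv < 0 or self.alpha_llr < 0:
            raise ValueError("regularization weights must be >= 0")
        if self.block_side < 1:
            raise ValueError("block_side must be >= 1")
        if self.constraint not in ("image_domain", "subspace"):
            raise ValueError(f"unknown constraint {self.constraint!r}")

    @property
    def is_subspace(self) -> bool:
        return self.constraint == "subspace"

    @property
    def is_regularized(self) -> bool:
        return self.alpha_stv > 0 or self.alpha_llr > 0


def model_from_acronym(acronym: str, alpha_stv: float = 0.0, alpha_llr: float = 0.0,
                       **overrides) -> ReconModel:
    """Build a :class:`ReconModel` for one of the standard acronyms; weights
    of unused regularizers are forced to zero."""
    if acronym not in MODEL_ACRONYMS:
        raise ValueError(
            f"unknown model {acronym!r}; options: {', '.join(MODEL_ACRONYMS)}"
        )
    spec = MODEL_ACRONYMS[acronym]
    model = ReconModel(
        name=acronym,
        constraint=spec["constraint"],
        alpha_stv=alpha_stv if spec["use_stv"] else 0.0,
        alpha_llr=alpha_llr if spec["use_llr"] else 0.0,
        block_side=spec.get("block_side", 8),
    )
    return replace(model, **overrides) if overrides else model


@dataclass
class ReconResult:
    """Reconstructed series with solver diagnostics."""

    series: np.ndarray
    coeffs: np.ndarray | None
    objective: list = field(default_factory=list)
    model: ReconModel | None = None


# ---------------------------------------------------------------------------
# solvers

def _as_linear_operator(forward, adjoint, x_shape, m, weights=None):
    n = int(np.prod(x_shape))
    w = None if weights is None else np.asarray(weights)

    def matvec(v):
        y = forward(v.reshape(x_shape))
        return y if w is None else w * y

    def rmatvec(y):
        if w is not None:
            y = w * y
        return adjoint(y).ravel()

    return LinearOperator((m, n), matvec=matvec, rmatvec=rmatvec, dtype=np.complex128)


def lsmr_solve(operator, data, n_iters: int = 5, weights=None, x0=None):
    """Approximate least-squares solve with a fixed LSMR iteration budget.

    ``weights`` (per-sample, real) turn the problem into weighted least
    squares — the density-compensation-style preconditioning used for radial
    data.  Deterministic given its inputs.
    """
    data = np.asarray(data, dtype=np.complex128).ravel()
    if not np.all(np.isfinite(data)):
        raise ValueError("data contains non-finite samples")
    x_shape = operator.x_shape
    w = None if weights is None else np.sqrt(np.asarray(weights, dtype=float))
    lin = _as_linear_operator(operator.forward, operator.adjoint, x_shape,
                              data.size, weights=w)
    rhs = data if w is None else w * data
    x0v = None if x0 is None else np.asarray(x0, dtype=np.complex128).ravel()
    sol = lsmr(lin, rhs, maxiter=max(1, n_iters), x0=x0v)[0]
    return sol.reshape(x_shape)


def _median_nonzero(values: np.ndarray) -> float:
    nz = values[values > 0]
    return float(np.median(nz)) if nz.size else 1.0


def _block_singular_values(series: np.ndarray, block_side: int) -> np.ndarray:
    spatial = series.shape[1:]
    if block_side > max(spatial):
        block_side = max(spatial)
    n_t = series.shape[0]
    out = []
    for sl in _iter_blocks(spatial, block_side):
        cas = series[(slice(None), *sl)].reshape(n_t, -1)
        out.append(np.linalg.svd(cas, compute_uv=False))
    return np.concatenate(out)


def _fidelity(operator, x, data, w):
    r = operator.forward(x) - data
    if w is not None:
        r = w * r
    return 0.5 * float(np.vdot(r, r).real)


def admm_reconstruct(model: ReconModel, operator, data) -> ReconResult:
    """Solve one reconstruction model.

    ``operator`` is an :class:`~allt1.encoding.EncodingOperator` (image-domain
    models) or :class:`~allt1.encoding.SubspaceOperator` (subspace models,
    in which case the regularizers act on the coefficient images and the
    image series is recovered as ``x = basis @ coeffs`` afterwards).
    With all weights zero this dispatches to :func:`lsmr_solve`.
    """
    data = np.asarray(data, dtype=np.complex128).ravel()
    x_shape = operator.x_shape
    weights = (operator.density_weights()
               if model.use_density_weights and hasattr(operator, "density_weights")
               else None)
    w = None if weights is None else np.sqrt(weights)

    if not model.is_regularized:
        x = lsmr_solve(operator, data, n_iters=model.lsmr_iters, weights=weights)
        return _package(model, operator, x, [_fidelity(operator, x, data, w)])

    use_stv = model.alpha_stv > 0
    use_llr = model.alpha_llr > 0
    # scale-aware penalty default: rho = alpha / delta with delta the median
    # magnitude of the splitting variable at a quick unregularized solve, so
    # the proximal threshold alpha/rho sits at the data's own scale
    # regardless of intensity normalization.
    rho1 = model.rho_stv
    rho2 = model.rho_llr
    if (use_stv and rho1 is None) or (use_llr and rho2 is None):
        x_probe = lsmr_solve(operator, data, n_iters=model.lsmr_iters,
                             weights=weights)
        if use_stv and rho1 is None:
            g = np.abs(spatial_gradient(x_probe))
            rho1 = model.alpha_stv / _median_nonzero(g)
        if use_llr and rho2 is None:
            sv = _block_singular_values(x_probe, model.block_side)
            rho2 = model.alpha_llr / _median_nonzero(sv)
    rho1 = rho1 if rho1 is not None else model.alpha_stv
    rho2 = rho2 if rho2 is not None else model.alpha_llr

    x = np.zeros(x_shape, dtype=np.complex128)
    d = len(x_shape) - 1
    if use_stv:
        z1 = np.zeros((d, *x_shape), dtype=np.complex128)
        u1 = np.zeros_like(z1)
    if use_llr:
        z2 = np.zeros(x_shape, dtype=np.complex128)
        u2 = np.zeros_like(z2)

    m_fid = data.size
    n_g = int(np.prod((d, *x_shape))) if use_stv else 0
    n_x = int(np.prod(x_shape))
    m_total = m_fid + (n_g if use_stv else 0) + (n_x if use_llr else 0)
    s1, s2 = np.sqrt(rho1), np.sqrt(rho2)

    def matvec_full(v):
        xx = v.reshape(x_shape)
        parts = [operator.forward(xx) if w is None else w * operator.forward(xx)]
        if use_stv:
            parts.append(s1 * spatial_gradient(xx).ravel())
        if use_llr:
            parts.append(s2 * xx.ravel())
        return np.concatenate(parts)

    def rmatvec_full(y):
        y_fid = y[:m_fid]
        out = operator.adjoint(y_fid if w is None else w * y_fid)
        off = m_fid
        if use_stv:
            out = out + s1 * spatial_gradient_adjoint(
                y[off:off + n_g].reshape((d, *x_shape)))
            off += n_g
        if use_llr:
            out = out + s2 * y[off:off + n_x].reshape(x_shape)
        return out.ravel()

    lin = LinearOperator((m_total, n_x), matvec=matvec_full, rmatvec=rmatvec_full,
                         dtype=np.complex128)
    wy = data if w is None else w * data

    def objective(xx):
        val = _fidelity(operator, xx, data, w)
        if use_stv:
            val += model.alpha_stv * series_stv(xx)
        if use_llr:
            val += model.alpha_llr * llr_value(xx, model.block_side)
        return val

    trace = [objective(x)]
    for _ in range(model.n_outer):
        rhs = [wy]
        if use_stv:
            rhs.append(s1 * (z1 - u1).ravel())
        if use_llr:
            rhs.append(s2 * (z2 - u2).ravel())
        x0 = x.ravel() if model.warm_start else None
        x = lsmr(lin, np.concatenate(rhs), maxiter=model.n_inner, x0=x0)[0].reshape(x_shape)
        if use_stv:
            gx = spatial_gradient(x)
            z1 = prox_stv_shrink(gx + u1, model.alpha_stv / rho1)
            u1 = u1 + gx - z1
        if use_llr:
            z2 = prox_llr(x + u2, model.alpha_llr / rho2, model.block_side)
            u2 = u2 + x - z2
        trace.append(objective(x))
    return _package(model, operator, x, trace)


def _package(model: ReconModel, operator, x: np.ndarray, trace) -> ReconResult:
    if hasattr(operator, "basis"):  # subspace-constrained
        series = operator.basis.expand(x)
        return ReconResult(series=series, coeffs=x, objective=list(trace), model=model)
    return ReconResult(series=x, coeffs=None, objective=list(trace), model=model)
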
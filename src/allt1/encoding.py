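"""Non-Cartesian Fourier encoding: gridding NUFFT and the multi-image
radial forward operator.

The forward model for the binned acquisition is block diagonal over image
bins: the samples of bin ``t`` are non-uniform Fourier samples of image
``t`` along that bin's spokes (optionally premultiplied by coil
sensitivities).  The NUFFT is a standard Kaiser-Bessel gridding transform:
the image is deapodized, zero-padded onto an oversampled grid, FFT'd, and
interpolated at the sample frequencies with a separable Kaiser-Bessel
kernel; the interpolation is materialized as a sparse matrix so the adjoint
is the exact conjugate transpose of the forward map.

Frequency coordinates are in cycles/FOV with the image-center phase
convention: a unit impulse at the center voxel transforms to a constant of
zero phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.special import i0

from .subspace import SubspaceBasis
from .trajectory import Trajectory

__all__ = [
    "NUFFT",
    "EncodingOperator",
    "SubspaceOperator",
    "spoke_sample_coords",
    "nufft_forward",
    "nufft_adjoint",
    "radial_density_weights",
]


def _kb_beta(width: int, oversamp: float) -> float:
    # Beatty et al. minimum-aliasing shape parameter.
    return np.pi * np.sqrt((width / oversamp) ** 2 * (oversamp - 0.5) ** 2 - 0.8)


def _kb_kernel(u: np.ndarray, width: int, beta: float) -> np.ndarray:
    """Kaiser-Bessel interpolation kernel on |u| <= width/2 (grid units)."""
    frac = 1.0 - (2.0 * u / width) ** 2
    out = np.zeros_like(u, dtype=float)
    inside = frac > 0
    out[inside] = i0(beta * np.sqrt(frac[inside]))
    return out


def _kb_transform(x: np.ndarray, width: int, beta: float) -> np.ndarray:
    """Continuous Fourier transform of the KB kernel at x cycles/grid-unit."""
    arg = beta ** 2 - (np.pi * width * x) ** 2
    out = np.empty_like(x, dtype=float)
    pos = arg > 0
    sq = np.sqrt(np.abs(arg))
    out[pos] = np.sinh(sq[pos]) / sq[pos]
    out[~pos] = np.sinc(sq[~pos] / np.pi)
    return width * out


class NUFFT:
    """Type-2 (forward) / type-1 (adjoint) NUFFT for one set of sample points.

    Parameters
    ----------
    grid_shape : tuple of int
        Image dimensions (2-D or 3-D).
    coords : (M, d) array
        Sample frequencies in cycles/FOV; must satisfy ``|k| <= side/2``.
    width : int
        Interpolation kernel width in oversampled grid units.
    oversamp : float
        Grid oversampling factor.
    """

    def __init__(self, grid_shape, coords, width: int = 7, oversamp: float = 2.0):
        self.grid_shape = tuple(int(n) for n in grid_shape)
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        if coords.shape[1] != len(self.grid_shape):
            raise ValueError(
                f"coords have {coords.shape[1]} dims for a "
                f"{len(self.grid_shape)}-D grid"
            )
        for d, n in enumerate(self.grid_shape):
            if np.any(np.abs(coords[:, d]) > n / 2 + 1e-9):
                raise ValueError("sample coordinates beyond the Nyquist radius")
        self.coords = coords
        self.width = int(width)
        self.os_shape = tuple(2 * int(np.ceil(oversamp * n / 2)) for n in self.grid_shape)
        self.n_samples = coords.shape[0]

        # separable deapodization on the image grid
        apod_axes = []
        betas = []
        for n, g in zip(self.grid_shape, self.os_shape):
            beta = _kb_beta(self.width, g / n)
            betas.append(beta)
            offsets = (np.arange(n) - n // 2) / g
            apod_axes.append(1.0 / _kb_transform(offsets, self.width, beta))
        self._deapod = apod_axes[0]
        for a in apod_axes[1:]:
            self._deapod = np.multiply.outer(self._deapod, a)

        self._interp = self._build_interp(betas)
        self._interp_h = self._interp.T.tocsr()

    def _build_interp(self, betas) -> sp.csr_matrix:
        d = len(self.grid_shape)
        w = self.width
        cols_axes, wts_axes = [], []
        for ax, (n, g) in enumerate(zip(self.grid_shape, self.os_shape)):
            gcoord = self.coords[:, ax] * (g / n)  # oversampled-grid units
            base = np.ceil(gcoord - w / 2.0).astype(np.int64)
            offs = base[:, None] + np.arange(w)[None, :]
            wts_axes.append(_kb_kernel(offs - gcoord[:, None], w, betas[ax]))
            cols_axes.append(np.mod(offs, g))
        # tensor-product expansion over dims
        m = self.n_samples
        cols = cols_axes[0]
        wts = wts_axes[0]
        for ax in range(1, d):
            g = self.os_shape[ax]
            cols = cols[:, :, None] * g + cols_axes[ax][:, None, :]
            cols = cols.reshape(m, -1)
            wts = (wts[:, :, None] * wts_axes[ax][:, None, :]).reshape(m, -1)
        rows = np.repeat(np.arange(m, dtype=np.int64), w ** d)
        mat = sp.csr_matrix(
            (wts.ravel(), (rows, cols.ravel())),
            shape=(m, int(np.prod(self.os_shape))),
        )
        mat.sum_duplicates()
        return mat

    def forward(self, image: np.ndarray) -> np.ndarray:
        """Non-uniform Fourier samples of ``image`` at the stored coords."""
        if image.shape != self.grid_shape:
            raise ValueError(f"image shape {image.shape} != {self.grid_shape}")
        x = image * self._deapod
        pad = np.zeros(self.os_shape, dtype=np.complex128)
        pad[tuple(slice(0, n) for n in self.grid_shape)] = x
        pad = np.roll(pad, [-(n // 2) for n in self.grid_shape],
                      axis=tuple(range(pad.ndim)))
        spectrum = np.fft.fftn(pad)
        return self._interp @ spectrum.ravel()

    def adjoint(self, samples: np.ndarray) -> np.ndarray:
        """Exact conjugate-transpose of :meth:`forward`."""
        samples = np.asarray(samples)
        if samples.shape != (self.n_samples,):
            raise ValueError(f"expected {self.n_samples} samples, got {samples.shape}")
        spectrum = (self._interp_h @ samples).reshape(self.os_shape)
        grid = np.fft.ifftn(spectrum) * np.prod(self.os_shape)
        grid = np.roll(grid, [n // 2 for n in self.grid_shape],
                       axis=tuple(range(grid.ndim)))
        out = grid[tuple(slice(0, n) for n in self.grid_shape)]
        return out * self._deapod


def nufft_forward(image, coords, width: int = 7, oversamp: float = 2.0):
    """One-shot forward NUFFT (builds and discards the plan)."""
    return NUFFT(np.shape(image), coords, width=width, oversamp=oversamp).forward(image)


def nufft_adjoint(samples, coords, grid_shape, width: int = 7, oversamp: float = 2.0):
    """One-shot adjoint NUFFT."""
    return NUFFT(grid_shape, coords, width=width, oversamp=oversamp).adjoint(samples)


def spoke_sample_coords(directions: np.ndarray, matrix_side: int,
                        samples_per_spoke: int) -> np.ndarray:
    """Center-out readout coordinates: for each spoke, samples at radii
    ``j * (side/2) / S`` for ``j = 0..S-1`` cycles/FOV along the direction.
    Returns an (n_spokes * S, d) array, spoke-major."""
    radii = np.arange(samples_per_spoke) * (matrix_side / 2.0) / samples_per_spoke
    return (directions[:, None, :] * radii[None, :, None]).reshape(-1, directions.shape[1])


def radial_density_weights(matrix_side: int, samples_per_spoke: int, ndim: int) -> np.ndarray:
    """Per-readout-sample density-compensation-style weights ~ kr^(d-1),
    normalized to unit mean; the DC sample gets a quarter-spacing radius."""
    radii = np.arange(samples_per_spoke) * (matrix_side / 2.0) / samples_per_spoke
    dr = (matrix_side / 2.0) / samples_per_spoke
    w = np.maximum(radii, dr / 4.0) ** (ndim - 1)
    return w / w.mean()


@dataclass
class _BinSpec:
    nufft: NUFFT
    n_spokes: int


class EncodingOperator:
    """Block-diagonal multi-image radial forward operator.

    Maps an image series (T, *grid) to the concatenated complex sample
    vector (bin-major, spoke-major, readout-minor).  Coil sensitivities, if
    given as a (C, *grid) array, multiply in image domain before encoding
    and the per-bin samples become coil-major.
    """

    def __init__(self, traj: Trajectory, grid_shape, samples_per_spoke: int | None = None,
                 width: int = 7, oversamp: float = 2.0, sens: np.ndarray | None = None):
        self.grid_shape = tuple(int(n) for n in grid_shape)
        side = max(self.grid_shape)
        if samples_per_spoke is None:
            samples_per_spoke = traj.samples_per_spoke
        if samples_per_spoke is None:
            samples_per_spoke = int(np.ceil(traj.oversampling * side / 2))
        self.samples_per_spoke = int(samples_per_spoke)
        self.n_bins = traj.n_bins
        self.sens = None if sens is None else np.asarray(sens, dtype=np.complex128)
        self.n_coils = 1 if self.sens is None else self.sens.shape[0]

        self._bins: list[_BinSpec] = []
        for b in range(self.n_bins):
            members = np.flatnonzero(traj.bin_of == b)
            members = members[np.argsort(traj.acq_position[members], kind="stable")]
            coords = spoke_sample_coords(
                traj.directions[members], side, self.samples_per_spoke
            )
            self._bins.append(
                _BinSpec(
                    nufft=NUFFT(self.grid_shape, coords, width=width, oversamp=oversamp),
                    n_spokes=len(members),
                )
            )
        self._dens = radial_density_weights(side, self.samples_per_spoke,
                                            len(self.grid_shape))

    @property
    def n_images(self) -> int:
        return self.n_bins

    @property
    def x_shape(self) -> tuple:
        """Shape of the operator's image-domain argument."""
        return (self.n_bins, *self.grid_shape)

    @property
    def sample_counts(self) -> np.ndarray:
        """Complex samples per bin (including coils)."""
        return np.array(
            [b.nufft.n_samples * self.n_coils for b in self._bins], dtype=np.int64
        )

    @property
    def n_samples(self) -> int:
        return int(self.sample_counts.sum())

    def split(self, samples: np.ndarray) -> list[np.ndarray]:
        """Split a concatenated sample vector into per-bin vectors."""
        return np.split(np.asarray(samples), np.cumsum(self.sample_counts)[:-1])

    def forward_bin(self, b: int, image: np.ndarray) -> np.ndarray:
        spec = self._bins[b]
        if self.sens is None:
            return spec.nufft.forward(image)
        return np.concatenate([spec.nufft.forward(c * image) for c in self.sens])

    def adjoint_bin(self, b: int, samples: np.ndarray) -> np.ndarray:
        spec = self._bins[b]
        if self.sens is None:
            return spec.nufft.adjoint(samples)
        per_coil = np.split(samples, self.n_coils)
        out = np.zeros(self.grid_shape, dtype=np.complex128)
        for c, y in zip(self.sens, per_coil):
            out += np.conj(c) * spec.nufft.adjoint(y)
        return out

    def forward(self, series: np.ndarray) -> np.ndarray:
        series = np.asarray(series)
        if series.shape != (self.n_bins, *self.grid_shape):
            raise ValueError(
                f"series shape {series.shape} != {(self.n_bins, *self.grid_shape)}"
            )
        return np.concatenate(
            [self.forward_bin(b, series[b]) for b in range(self.n_bins)]
        )

    def adjoint(self, samples: np.ndarray) -> np.ndarray:
        parts = self.split(samples)
        return np.stack(
            [self.adjoint_bin(b, parts[b]) for b in range(self.n_bins)]
        )

    def density_weights(self) -> np.ndarray:
        """Readout density weights tiled over the full sample vector."""
        out = []
        for spec in self._bins:
            w = np.tile(self._dens, spec.n_spokes)
            out.append(np.tile(w, self.n_coils))
        return np.concatenate(out)


class SubspaceOperator:
    """Composition of an encoding operator with a temporal subspace basis.

    Maps K coefficient images to samples by expanding, bin by bin, the
    series value ``x_t = sum_k basis[t, k] * lambda_k`` and encoding it —
    the full T-image series is never materialized.
    """

    def __init__(self, base: EncodingOperator, basis: SubspaceBasis):
        if basis.n_times != base.n_bins:
            raise ValueError(
                f"basis has {basis.n_times} time points, operator has "
                f"{base.n_bins} bins"
            )
        self.base = base
        self.basis = basis

    @property
    def k(self) -> int:
        return self.basis.k

    @property
    def grid_shape(self):
        return self.base.grid_shape

    @property
    def n_samples(self) -> int:
        return self.base.n_samples

    @property
    def x_shape(self) -> tuple:
        """Shape of the operator's coefficient-domain argument."""
        return (self.k, *self.base.grid_shape)

    def forward(self, coeffs: np.ndarray) -> np.ndarray:
        coeffs = np.asarray(coeffs)
        if coeffs.shape != (self.k, *self.base.grid_shape):
            raise ValueError(
                f"coeffs shape {coeffs.shape} != {(self.k, *self.base.grid_shape)}"
            )
        phi = self.basis.basis
        out = []
        for t in range(self.base.n_bins):
            image = np.tensordot(phi[t], coeffs, axes=(0, 0))
            out.append(self.base.forward_bin(t, image))
        return np.concatenate(out)

    def adjoint(self, samples: np.ndarray) -> np.ndarray:
        parts = self.base.split(samples)
        phi = self.basis.basis
        out = np.zeros((self.k, *self.base.grid_shape), dtype=np.complex128)
        shape = (self.k,) + (1,) * len(self.base.grid_shape)
        for t in range(self.base.n_bins):
            a = self.base.adjoint_bin(t, parts[t])
            out += np.conj(phi[t]).reshape(shape) * a[None]
        return out

    def density_weights(self) -> np.ndarray:
        return self.base.density_weights()
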
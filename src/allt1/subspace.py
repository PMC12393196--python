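"""Temporal subspace basis from an aLL signal dictionary.

A dictionary of recovery signals is simulated over dense grids of the model
parameters (Teff, Mss/M0, I; M0 normalized to 1), each entry being the
concatenated inverted / non-inverted curves sampled at the image bin times.
An SVD over the temporal dimension yields an orthonormal basis; keeping the
top K right singular vectors gives the rank-K temporal subspace used by the
subspace-constrained reconstruction.  The modelling error of the truncation
is summarized by the maximum signal-wise normalized RMSE over the dictionary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .signal import relaxation_curve

__all__ = ["ParamGrid", "SubspaceBasis", "build_dictionary", "compress", "max_signal_nrmse"]


@dataclass
class ParamGrid:
    """Cartesian parameter grids for dictionary generation (M0 = 1)."""

    teff_values: np.ndarray
    mss_over_m0_values: np.ndarray
    inv_values: np.ndarray

    def __post_init__(self) -> None:
        self.teff_values = np.atleast_1d(np.asarray(self.teff_values, float))
        self.mss_over_m0_values = np.atleast_1d(np.asarray(self.mss_over_m0_values, float))
        self.inv_values = np.atleast_1d(np.asarray(self.inv_values, float))
        for name in ("teff_values", "mss_over_m0_values", "inv_values"):
            if getattr(self, name).size == 0:
                raise ValueError(f"{name} is empty")
        if np.any(self.teff_values <= 0):
            raise ValueError("teff grid must be positive")

    @classmethod
    def default(cls, n_inv: int = 78) -> "ParamGrid":
        """Dense grids covering fixed ex vivo brain tissue at high field:
        401 Teff in [0.5, 0.9] s, 17 Mss/M0 in [0.74, 0.9], I in [0.23, 1.0]."""
        return cls(
            teff_values=np.linspace(0.5, 0.9, 401),
            mss_over_m0_values=np.linspace(0.74, 0.9, 17),
            inv_values=np.linspace(0.23, 1.0, n_inv),
        )

    @property
    def n_signals(self) -> int:
        return self.teff_values.size * self.mss_over_m0_values.size * self.inv_values.size


@dataclass
class SubspaceBasis:
    """Orthonormal T x K temporal basis and the dictionary singular values."""

    basis: np.ndarray
    singular_values: np.ndarray
    k: int = field(default=0)

    def __post_init__(self) -> None:
        self.basis = np.asarray(self.basis)
        if self.k == 0:
            self.k = self.basis.shape[1]
        gram = self.basis.conj().T @ self.basis
        if not np.allclose(gram, np.eye(self.k), atol=1e-10):
            raise ValueError("basis columns are not orthonormal")

    @property
    def n_times(self) -> int:
        return self.basis.shape[0]

    def project(self, signals: np.ndarray) -> np.ndarray:
        """Orthogonal projection of row-signals onto the subspace."""
        return (signals @ self.basis) @ self.basis.conj().T

    def expand(self, coeffs: np.ndarray) -> np.ndarray:
        """Coefficient images (K, ...) -> image series (T, ...)."""
        return np.tensordot(self.basis, coeffs, axes=(1, 0))


def build_dictionary(grid: ParamGrid, bin_times) -> np.ndarray:
    """Simulate the aLL dictionary: one row [S-(t_1..t_B), S+(t_1..t_B)] per
    Cartesian grid combination, M0 = 1.  Shape (n_signals, 2*len(bin_times))."""
    bin_times = np.asarray(bin_times, dtype=float)
    te, ms, iv = np.meshgrid(
        grid.teff_values, grid.mss_over_m0_values, grid.inv_values, indexing="ij"
    )
    te = te.reshape(-1, 1)
    ms = ms.reshape(-1, 1)
    iv = iv.reshape(-1, 1)
    s_minus = relaxation_curve(ms, 1.0, iv, te, bin_times[None, :], inverted=True)
    s_plus = relaxation_curve(ms, 1.0, iv, te, bin_times[None, :], inverted=False)
    return np.concatenate([s_minus, s_plus], axis=1)


def compress(dictionary: np.ndarray, k: int) -> SubspaceBasis:
    """Top-k right singular vectors of the dictionary (temporal dimension).

    The SVD sign ambiguity is fixed by making the largest-magnitude entry of
    each basis column positive.
    """
    dictionary = np.asarray(dictionary)
    n_t = dictionary.shape[1]
    if not 1 <= k <= n_t:
        raise ValueError(f"k must be in [1, {n_t}], got {k}")
    _, s, vt = np.linalg.svd(dictionary, full_matrices=False)
    basis = vt[:k].T.copy()
    flip = np.sign(basis[np.argmax(np.abs(basis), axis=0), np.arange(k)])
    basis *= np.where(flip == 0, 1.0, flip)
    return SubspaceBasis(basis=basis, singular_values=s, k=k)


def max_signal_nrmse(dictionary: np.ndarray, basis: SubspaceBasis) -> float:
    """Worst-case relative projection error over dictionary rows:
    ``max_s ||s - P s|| / ||s||`` with P the subspace projector.
    Zero-norm rows are excluded with a warning."""
    dictionary = np.asarray(dictionary)
    norms = np.linalg.norm(dictionary, axis=1)
    keep = norms > 0
    if not np.all(keep):
        warnings.warn("excluding zero-norm dictionary rows from nRMSE")
        dictionary = dictionary[keep]
        norms = norms[keep]
    resid = dictionary - basis.project(dictionary)
    return float(np.max(np.linalg.norm(resid, axis=1) / norms))
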
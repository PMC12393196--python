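"""Alternating Look-Locker (aLL) signal model and T1 estimation.

The aLL acquisition alternates two saturation-recovery segments: an
*inverted* part (signal ``S-``) in which the magnetization is inverted after
saturation and a relaxation delay, and a *non-inverted* part (``S+``) without
the inversion.  After binning the continuously sampled readout into images at
times ``t_i`` the per-voxel signal follows

    S-(t) = Mss - (Mss + I*M0) * exp(-t / Teff)
    S+(t) = Mss - (Mss - M0)  * exp(-t / Teff)

with ``Mss`` the steady-state magnetization under continuous excitation,
``M0`` the magnetization recovered after saturation and the relaxation delay
``Td``, ``I`` the inversion-efficiency parameter, and ``Teff`` the effective
relaxation time.  T1 follows from the M0/Mss ratio through the transcendental
relation

    T1 * (1 - exp(-Td / T1)) = M0 * TR / (Mss * (1 - exp(-TR / Teff)))

which is solved by bisection (the left-hand side is strictly increasing in T1
with supremum Td, so the root is unique when it exists).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ALLParams",
    "SequenceTiming",
    "all_signal",
    "relaxation_curve",
    "bin_time_points",
    "t1_lhs",
    "t1_from_ratio",
    "t1_from_parameters",
]


class InvalidParameterError(ValueError):
    """Raised for physically meaningless model parameters (e.g. Teff <= 0)."""


@dataclass
class ALLParams:
    """Per-voxel (or per-tissue) aLL model parameters.

    Parameters
    ----------
    mss, m0 : float
        Steady-state and post-delay magnetization, arbitrary units, >= 0.
    inv_eff : float
        Inversion parameter ``I``; physical inversions have ``0 <= I <= 1``
        but out-of-range values are flagged, not rejected.
    teff : float
        Effective relaxation time in seconds, > 0 (strict).
    phase : float
        Signal phase in radians; used when complex signals are requested.
    """

    mss: float
    m0: float
    inv_eff: float
    teff: float
    phase: float = 0.0

    def __post_init__(self) -> None:
        if not self.teff > 0:
            raise InvalidParameterError(f"teff must be > 0, got {self.teff}")

    @property
    def is_physical(self) -> bool:
        """True when all parameters are inside the physical ranges."""
        return (
            self.mss >= 0
            and self.m0 >= 0
            and 0.0 <= self.inv_eff <= 1.0
        )


@dataclass
class SequenceTiming:
    """Timing of one aLL part: repetition time, delay, spoke and bin counts.

    ``bin_times`` are the image time points within the relaxation segment,
    in seconds; by default the centers of contiguous equal spoke bins.
    """

    tr: float = 2.9624e-3
    td: float = 3.0
    n_spokes_per_part: int = 1476
    n_bins_per_part: int = 6
    bin_times: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.tr <= 0 or self.td <= 0:
            raise InvalidParameterError("tr and td must be positive")
        if self.n_spokes_per_part % self.n_bins_per_part != 0:
            raise ValueError(
                f"{self.n_spokes_per_part} spokes not divisible into "
                f"{self.n_bins_per_part} bins"
            )
        if self.bin_times is None:
            self.bin_times = bin_time_points(
                self.n_spokes_per_part, self.tr, self.n_bins_per_part
            )
        self.bin_times = np.asarray(self.bin_times, dtype=float)
        if np.any(self.bin_times <= 0) or np.any(np.diff(self.bin_times) <= 0):
            raise ValueError("bin_times must be strictly increasing and > 0")

    @property
    def n_images(self) -> int:
        """Total images per acquisition cycle (both parts)."""
        return 2 * self.n_bins_per_part


def relaxation_curve(mss, m0, inv_eff, teff, times, inverted):
    """Broadcasting evaluation of the aLL recovery curves (real-valued).

    All parameter arguments broadcast against ``times``.  ``inverted``
    selects S- (True) or S+ (False).
    """
    times = np.asarray(times, dtype=float)
    teff = np.asarray(teff, dtype=float)
    if np.any(teff <= 0):
        raise InvalidParameterError("teff must be > 0")
    decay = np.exp(-times / teff)
    if inverted:
        return mss - (mss + inv_eff * m0) * decay
    return mss - (mss - m0) * decay


def all_signal(params: ALLParams, times, part: str, complex_valued: bool | None = None):
    """Evaluate the aLL signal model for one voxel.

    Parameters
    ----------
    params : ALLParams
    times : array_like
        Time points within the relaxation segment, seconds, >= 0.
    part : {"inverted", "non_inverted"}
        Which acquisition part: S- or S+.
    complex_valued : bool, optional
        Multiply by ``exp(i*phase)``.  Default: complex when the phase is
        nonzero.
    """
    if part not in ("inverted", "non_inverted"):
        raise ValueError(f"part must be 'inverted' or 'non_inverted', got {part!r}")
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("times must be >= 0")
    s = relaxation_curve(
        params.mss, params.m0, params.inv_eff, params.teff, times,
        inverted=(part == "inverted"),
    )
    if complex_valued is None:
        complex_valued = params.phase != 0.0
    if complex_valued:
        return s * np.exp(1j * params.phase)
    return s


def bin_time_points(n_spokes: int, tr: float, n_bins: int, round_to: float | None = None):
    """Centers of contiguous equal spoke bins, ``t_i = (i - 1/2) * (n/b) * TR``.

    ``round_to`` optionally rounds to the nearest multiple (e.g. 10 ms for
    display); the internal representation is the unrounded center.
    """
    if tr <= 0:
        raise ValueError("tr must be > 0")
    if n_bins < 1 or n_spokes % n_bins != 0:
        raise ValueError(f"{n_spokes} spokes not divisible into {n_bins} bins")
    per_bin = n_spokes // n_bins
    centers = (np.arange(1, n_bins + 1) - 0.5) * per_bin * tr
    if round_to is not None:
        centers = np.round(centers / round_to) * round_to
    return centers


def t1_lhs(t1, td):
    """Left-hand side of the T1 relation: ``T1 * (1 - exp(-Td/T1))``.

    Strictly increasing in T1 for any ``td > 0`` with supremum ``td``.
    """
    t1 = np.asarray(t1, dtype=float)
    return t1 * -np.expm1(-td / t1)


def t1_from_ratio(rhs, td, bracket=(1e-3, 20.0), tol=1e-5):
    """Vectorized bisection for T1 from the right-hand-side value(s).

    ``rhs`` outside ``(t1_lhs(lo), t1_lhs(hi))`` (in particular >= Td, which
    admits no finite solution) yields NaN.  ``tol`` is the bracket half-width
    in seconds at termination (default 0.01 ms).
    """
    rhs = np.asarray(rhs, dtype=float)
    lo = np.full(rhs.shape, bracket[0])
    hi = np.full(rhs.shape, bracket[1])
    valid = (
        np.isfinite(rhs)
        & (rhs > t1_lhs(bracket[0], td))
        & (rhs < min(t1_lhs(bracket[1], td), td))
    )
    n_iter = int(np.ceil(np.log2((bracket[1] - bracket[0]) / tol))) + 1
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        below = t1_lhs(mid, td) < rhs
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    out = 0.5 * (lo + hi)
    return np.where(valid, out, np.nan) if out.ndim else (float(out) if valid else float("nan"))


def t1_from_parameters(
    params: ALLParams,
    timing: SequenceTiming,
    t1_max: float = 20.0,
    tol: float = 1e-5,
) -> float:
    """T1 from fitted aLL parameters via the M0/Mss relation and bisection.

    Returns NaN for voxels whose ratio admits no solution in
    ``(0, min(Td, t1_lhs(t1_max)))`` — e.g. Mss -> 0.
    """
    denom = params.mss * -np.expm1(-timing.tr / params.teff)
    if denom <= 0:
        return float("nan")
    rhs = params.m0 * timing.tr / denom
    return t1_from_ratio(np.float64(rhs), timing.td, bracket=(1e-3, t1_max), tol=tol)
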
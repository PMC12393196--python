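"""Radial k-space trajectories built from tiny golden means.

Spoke directions are generated by irrational (golden-means) increments so
that any contiguous subsequence covers the sphere (or circle, in 2-D)
quasi-uniformly — the property that makes retrospective undersampling by
simply truncating each bin's spoke list well-posed.

The stream of directions is partitioned into contiguous, near-equal sections,
one per image bin; the acquisition interleaves the sections so that each
repetition of the two-part saturation-recovery segment plays the next few
spokes of every section in turn.  Spokes can be inserted by spherical
interpolation wherever the acquisition order would jump by more than a
chosen angle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .signal import SequenceTiming

__all__ = [
    "Trajectory",
    "SamplingPlan",
    "tiny_golden_means",
    "tiny_golden_angle",
    "tgm_directions",
    "golden_angle_directions_2d",
    "spoke_directions",
    "partition_sections",
    "make_trajectory",
    "interpolate_gap_spokes",
    "full_sampling_spokes",
    "acceleration_factor",
    "undersample",
    "sampling_plan",
]

# Real root of x^3 = x^2 + 1; its fractional parts generate the standard
# 2-D golden means (0.4656..., 0.6823...) used for 3-D radial sampling.
_T_GM = 1.4655712318767682

# Golden ratio, for the 1-D (in-plane) golden angles.
_TAU = (1.0 + math.sqrt(5.0)) / 2.0


def tiny_golden_means(order: int = 1) -> tuple[float, float]:
    """Golden-means increment pair (phi1, phi2) for 3-D radial sampling.

    Order 1 gives the classical pair (t-1, 1/t) with t the real root of
    x^3 = x^2 + 1; higher orders shrink both increments, reducing the angle
    between consecutively acquired spokes, while 1, phi1, phi2 remain
    rationally independent so equidistribution on (cos theta, azimuth) holds.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    denom = _T_GM + order - 1
    return (_T_GM * _T_GM - _T_GM) / denom, 1.0 / denom


def tiny_golden_angle(order: int = 1) -> float:
    """Tiny golden angle (radians) for 2-D radial sampling:
    pi / (tau + order - 1), the classical golden angle at order 1."""
    if order < 1:
        raise ValueError("order must be >= 1")
    return math.pi / (_TAU + order - 1)


def tgm_directions(n: int, order: int = 55, seed_phase: float = 0.0,
                   ratios: tuple[float, float] | None = None) -> np.ndarray:
    """``n`` quasi-uniform unit spoke directions on the full sphere.

    The m-th spoke has ``cos(theta) = 2*frac((m+seed_phase)*phi1) - 1`` and
    azimuth ``2*pi*frac((m+seed_phase)*phi2)``; the pair (phi1, phi2) comes
    from :func:`tiny_golden_means` unless given explicitly via ``ratios``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    phi1, phi2 = ratios if ratios is not None else tiny_golden_means(order)
    m = np.arange(n, dtype=float) + seed_phase
    z = 2.0 * np.mod(m * phi1, 1.0) - 1.0
    az = 2.0 * np.pi * np.mod(m * phi2, 1.0)
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.stack([rho * np.cos(az), rho * np.sin(az), z], axis=1)


def golden_angle_directions_2d(n: int, order: int = 1, seed_phase: float = 0.0,
                               angle: float | None = None) -> np.ndarray:
    """``n`` unit directions on the circle with (tiny) golden-angle increments."""
    if n < 1:
        raise ValueError("n must be >= 1")
    psi = angle if angle is not None else tiny_golden_angle(order)
    theta = np.mod((np.arange(n, dtype=float) + seed_phase) * psi, 2.0 * np.pi)
    return np.stack([np.cos(theta), np.sin(theta)], axis=1)


def spoke_directions(n: int, ndim: int = 3, order: int | None = None, **kw) -> np.ndarray:
    """Dimension dispatch: 3-D tiny golden means or 2-D tiny golden angle."""
    if ndim == 3:
        return tgm_directions(n, order=55 if order is None else order, **kw)
    if ndim == 2:
        return golden_angle_directions_2d(n, order=1 if order is None else order, **kw)
    raise ValueError(f"ndim must be 2 or 3, got {ndim}")


def partition_sections(n_total: int, n_sections: int) -> list[tuple[int, int]]:
    """Contiguous near-equal index ranges [(start, stop), ...]; sizes differ
    by at most one, larger sections first."""
    if n_sections < 1:
        raise ValueError("n_sections must be >= 1")
    if n_sections > n_total:
        raise ValueError(f"cannot split {n_total} spokes into {n_sections} sections")
    base, extra = divmod(n_total, n_sections)
    ranges, start = [], 0
    for i in range(n_sections):
        size = base + (1 if i < extra else 0)
        ranges.append((start, start + size))
        start += size
    return ranges


@dataclass
class Trajectory:
    """Radial spoke set with acquisition bookkeeping.

    ``directions`` are n x d unit vectors (center-out spokes).
    ``acq_position[i]`` is the chronological acquisition index of spoke ``i``;
    ``bin_of`` maps each spoke to its image bin (0..T-1, the first half being
    the inverted part) and ``spoke_times`` gives each spoke's own time within
    the relaxation segment, in seconds.
    """

    directions: np.ndarray
    acq_position: np.ndarray
    section_of: np.ndarray
    bin_of: np.ndarray
    spoke_times: np.ndarray
    interpolated: np.ndarray
    n_bins: int
    samples_per_spoke: int | None = None
    oversampling: float = 2.0

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.directions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("spoke directions must be unit vectors")

    @property
    def n_spokes(self) -> int:
        return self.directions.shape[0]

    @property
    def ndim(self) -> int:
        return self.directions.shape[1]

    @property
    def acquisition_order(self) -> np.ndarray:
        """Spoke indices in chronological acquisition order."""
        return np.argsort(self.acq_position, kind="stable")

    @property
    def inverted_part(self) -> np.ndarray:
        """True for spokes of the inverted (S-) part."""
        return self.bin_of < self.n_bins // 2

    def spokes_per_bin(self) -> np.ndarray:
        return np.bincount(self.bin_of, minlength=self.n_bins)


@dataclass
class SamplingPlan:
    """Achieved sampling summary for one reconstruction."""

    af: float
    spokes_per_bin: np.ndarray
    matrix_side: int


def make_trajectory(timing: SequenceTiming, n_rep: int = 1, ndim: int = 3,
                    order: int | None = None, oversampling: float = 2.0,
                    samples_per_spoke: int | None = None,
                    ratios: tuple[float, float] | None = None) -> Trajectory:
    """Build the interleaved two-part trajectory for ``n_rep`` repetitions.

    The direction stream is split into ``T = 2 * n_bins_per_part`` contiguous
    sections (one per image); repetition ``j`` acquires spokes
    ``j*spb .. (j+1)*spb - 1`` of every section in bin order, where ``spb`` is
    the per-repetition spoke count of one bin.  Every spoke records its own
    time within the relaxation segment.
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    n_bins = timing.n_images
    spb = timing.n_spokes_per_part // timing.n_bins_per_part  # per rep, per bin
    n_total = n_rep * 2 * timing.n_spokes_per_part
    kw = {"ratios": ratios} if ndim == 3 else {}
    directions = spoke_directions(n_total, ndim=ndim, order=order, **kw)

    ranges = partition_sections(n_total, n_bins)
    starts = np.array([r[0] for r in ranges])
    section_of = np.empty(n_total, dtype=np.int64)
    for s, (a, b) in enumerate(ranges):
        section_of[a:b] = s

    rep = np.arange(n_rep)[:, None, None]          # repetition
    q = np.arange(timing.n_spokes_per_part)[None, :, None]  # position in part
    part = np.arange(2)[None, None, :]             # 0 = inverted, 1 = non-inverted
    b = part * timing.n_bins_per_part + q // spb   # bin index
    spoke = starts[b] + rep * spb + q % spb        # stream index of the spoke
    # chronological position: (rep, part, q)
    pos = (rep * 2 + part) * timing.n_spokes_per_part + q
    acq_position = np.empty(n_total, dtype=np.int64)
    acq_position[spoke.ravel()] = pos.ravel()
    spoke_times = np.empty(n_total, dtype=float)
    spoke_times[spoke.ravel()] = np.broadcast_to((q + 0.5) * timing.tr, spoke.shape).ravel()

    return Trajectory(
        directions=directions,
        acq_position=acq_position,
        section_of=section_of,
        bin_of=section_of.copy(),
        spoke_times=spoke_times,
        interpolated=np.zeros(n_total, dtype=bool),
        n_bins=n_bins,
        samples_per_spoke=samples_per_spoke,
        oversampling=oversampling,
    )


def _slerp(a: np.ndarray, b: np.ndarray, fracs: np.ndarray) -> np.ndarray:
    """Points along the great-circle arc from a to b at the given fractions."""
    dot = float(np.clip(np.dot(a, b), -1.0, 1.0))
    omega = math.acos(dot)
    if omega < 1e-12:
        return np.repeat(a[None, :], len(fracs), axis=0)
    if abs(math.pi - omega) < 1e-9:
        # antipodal: route through an arbitrary orthogonal direction
        perp = np.zeros_like(a)
        perp[int(np.argmin(np.abs(a)))] = 1.0
        perp = perp - np.dot(perp, a) * a
        perp /= np.linalg.norm(perp)
        out = []
        for f in fracs:
            ang = f * math.pi
            out.append(math.cos(ang) * a + math.sin(ang) * perp)
        return np.asarray(out)
    s = math.sin(omega)
    f = np.asarray(fracs)[:, None]
    pts = (np.sin((1 - f) * omega) * a[None, :] + np.sin(f * omega) * b[None, :]) / s
    return pts / np.linalg.norm(pts, axis=1, keepdims=True)


def consecutive_jumps(traj: Trajectory) -> np.ndarray:
    """Angles (radians) between consecutively acquired spokes."""
    d = traj.directions[traj.acquisition_order]
    dots = np.clip(np.sum(d[:-1] * d[1:], axis=1), -1.0, 1.0)
    return np.arccos(dots)


def interpolate_gap_spokes(traj: Trajectory, max_jump: float | None = None) -> Trajectory:
    """Insert interpolated spokes so no consecutive acquisition jump exceeds
    ``max_jump`` radians (default: twice the median jump of the input).

    Inserted spokes lie on the great-circle (2-D: circular arc) between their
    neighbors, are flagged in ``interpolated``, and inherit the bin, section
    and time of the spoke that follows them.
    """
    jumps = consecutive_jumps(traj)
    if max_jump is None:
        max_jump = 2.0 * float(np.median(jumps))
    if max_jump <= 0:
        raise ValueError("max_jump must be > 0")
    if not np.any(jumps > max_jump):
        return traj

    order = traj.acquisition_order
    chrono_dirs, chrono_sec, chrono_bin, chrono_time, chrono_interp = [], [], [], [], []
    for p, idx in enumerate(order):
        if p > 0 and jumps[p - 1] > max_jump:
            n_ins = int(math.ceil(jumps[p - 1] / max_jump)) - 1
            fracs = (np.arange(n_ins) + 1.0) / (n_ins + 1.0)
            prev = traj.directions[order[p - 1]]
            pts = _slerp(prev, traj.directions[idx], fracs)
            for pt in pts:
                chrono_dirs.append(pt)
                chrono_sec.append(traj.section_of[idx])
                chrono_bin.append(traj.bin_of[idx])
                chrono_time.append(traj.spoke_times[idx])
                chrono_interp.append(True)
        chrono_dirs.append(traj.directions[idx])
        chrono_sec.append(traj.section_of[idx])
        chrono_bin.append(traj.bin_of[idx])
        chrono_time.append(traj.spoke_times[idx])
        chrono_interp.append(bool(traj.interpolated[idx]))

    return Trajectory(
        directions=np.asarray(chrono_dirs),
        acq_position=np.arange(len(chrono_dirs), dtype=np.int64),
        section_of=np.asarray(chrono_sec, dtype=np.int64),
        bin_of=np.asarray(chrono_bin, dtype=np.int64),
        spoke_times=np.asarray(chrono_time, dtype=float),
        interpolated=np.asarray(chrono_interp, dtype=bool),
        n_bins=traj.n_bins,
        samples_per_spoke=traj.samples_per_spoke,
        oversampling=traj.oversampling,
    )


def full_sampling_spokes(matrix_side: int, ndim: int = 3) -> int:
    """Spokes required for Nyquist-complete radial sampling of an isotropic
    image of the given matrix side: pi * side^2 center-out spokes in 3-D,
    pi/2 * side in 2-D; non-integer counts round up."""
    if matrix_side < 1:
        raise ValueError("matrix_side must be >= 1")
    if ndim == 3:
        return int(math.ceil(math.pi * matrix_side ** 2))
    if ndim == 2:
        return int(math.ceil(math.pi * matrix_side / 2.0))
    raise ValueError(f"ndim must be 2 or 3, got {ndim}")


def acceleration_factor(matrix_side: int, spokes_per_image: float, ndim: int = 3) -> float:
    """Theoretical full-sampling spoke count divided by the count used."""
    if spokes_per_image <= 0:
        raise ValueError("spokes_per_image must be positive")
    return full_sampling_spokes(matrix_side, ndim) / spokes_per_image


def undersample(traj: Trajectory, af: float, matrix_side: int) -> Trajectory:
    """Retrospective undersampling: keep, per bin, the leading
    ``floor(full_sampling_spokes / af)`` spokes in acquisition order.

    The golden-means ordering guarantees the retained prefix of every bin is
    itself quasi-uniform.
    """
    if af <= 0:
        raise ValueError("af must be positive")
    n_keep = int(np.floor(full_sampling_spokes(matrix_side, traj.ndim) / af + 1e-9))
    per_bin = traj.spokes_per_bin()
    if n_keep < 1:
        raise ValueError(f"af={af} leaves no spokes per bin")
    if n_keep > per_bin.min():
        raise ValueError(
            f"af={af} requests {n_keep} spokes/bin but only "
            f"{per_bin.min()} are available in the smallest bin"
        )
    keep = np.zeros(traj.n_spokes, dtype=bool)
    for b in range(traj.n_bins):
        members = np.flatnonzero(traj.bin_of == b)
        ranked = members[np.argsort(traj.acq_position[members], kind="stable")]
        keep[ranked[:n_keep]] = True
    idx = np.flatnonzero(keep)
    return replace(
        traj,
        directions=traj.directions[idx],
        acq_position=np.argsort(np.argsort(traj.acq_position[idx], kind="stable")),
        section_of=traj.section_of[idx],
        bin_of=traj.bin_of[idx],
        spoke_times=traj.spoke_times[idx],
        interpolated=traj.interpolated[idx],
    )


def sampling_plan(traj: Trajectory, matrix_side: int) -> SamplingPlan:
    per_bin = traj.spokes_per_bin()
    af = acceleration_factor(matrix_side, float(per_bin.mean()), traj.ndim)
    return SamplingPlan(af=af, spokes_per_bin=per_bin, matrix_side=matrix_side)
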
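"""File I/O: HDF5 bundles for phantoms, trajectories, k-space data and
subspace bases; NIfTI output for parameter maps; YAML configs."""

from __future__ import annotations

from dataclasses import fields as dc_fields
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import yaml

from .fitting import ParameterMaps
from .phantom import Phantom
from .signal import ALLParams, SequenceTiming
from .subspace import SubspaceBasis
from .trajectory import Trajectory

__all__ = [
    "save_phantom", "load_phantom", "save_trajectory", "load_trajectory",
    "save_kspace", "load_kspace", "save_basis", "load_basis",
    "save_t1_map_nifti", "save_maps_nifti", "save_series", "load_series",
    "load_timing_config",
]

_PARAM_FIELDS = ("mss", "m0", "inv_eff", "teff", "phase")


def save_phantom(path, phantom: Phantom) -> None:
    with h5py.File(path, "w") as f:
        f["label_map"] = phantom.label_map
        f["phase_map"] = phantom.phase_map
        f["t1_truth"] = phantom.t1_truth
        f["roi_mask"] = phantom.roi_mask.astype(np.uint8)
        f["tissue_params"] = np.array(
            [[getattr(p, k) for k in _PARAM_FIELDS] for p in phantom.tissue_params]
        )


def load_phantom(path) -> Phantom:
    with h5py.File(path, "r") as f:
        params = [
            ALLParams(**dict(zip(_PARAM_FIELDS, row)))
            for row in np.asarray(f["tissue_params"])
        ]
        return Phantom(
            label_map=np.asarray(f["label_map"]),
            tissue_params=params,
            phase_map=np.asarray(f["phase_map"]),
            t1_truth=np.asarray(f["t1_truth"]),
            roi_mask=np.asarray(f["roi_mask"]).astype(bool),
        )


def save_trajectory(path, traj: Trajectory) -> None:
    with h5py.File(path, "w") as f:
        f["directions"] = traj.directions
        f["acq_position"] = traj.acq_position
        f["section_of"] = traj.section_of
        f["bin_of"] = traj.bin_of
        f["spoke_times"] = traj.spoke_times
        f["interpolated"] = traj.interpolated.astype(np.uint8)
        f.attrs["n_bins"] = traj.n_bins
        f.attrs["oversampling"] = traj.oversampling
        if traj.samples_per_spoke is not None:
            f.attrs["samples_per_spoke"] = traj.samples_per_spoke


def load_trajectory(path) -> Trajectory:
    with h5py.File(path, "r") as f:
        return Trajectory(
            directions=np.asarray(f["directions"]),
            acq_position=np.asarray(f["acq_position"]),
            section_of=np.asarray(f["section_of"]),
            bin_of=np.asarray(f["bin_of"]),
            spoke_times=np.asarray(f["spoke_times"]),
            interpolated=np.asarray(f["interpolated"]).astype(bool),
            n_bins=int(f.attrs["n_bins"]),
            samples_per_spoke=int(f.attrs["samples_per_spoke"])
            if "samples_per_spoke" in f.attrs else None,
            oversampling=float(f.attrs["oversampling"]),
        )


def save_kspace(path, samples: np.ndarray, noise_sigma: float = 0.0,
                traj: Trajectory | None = None) -> None:
    with h5py.File(path, "w") as f:
        f["samples"] = samples
        f.attrs["noise_sigma"] = noise_sigma
    if traj is not None:
        save_trajectory(str(path) + ".traj", traj)


def load_kspace(path):
    with h5py.File(path, "r") as f:
        return np.asarray(f["samples"]), float(f.attrs["noise_sigma"])


def save_basis(path, basis: SubspaceBasis) -> None:
    with h5py.File(path, "w") as f:
        f["basis"] = basis.basis
        f["singular_values"] = basis.singular_values
        f.attrs["k"] = basis.k


def load_basis(path) -> SubspaceBasis:
    with h5py.File(path, "r") as f:
        return SubspaceBasis(
            basis=np.asarray(f["basis"]),
            singular_values=np.asarray(f["singular_values"]),
            k=int(f.attrs["k"]),
        )


def _as_nifti(vol: np.ndarray) -> nib.Nifti1Image:
    v = np.asarray(vol, dtype=np.float64)
    if v.ndim == 2:
        v = v[:, :, None]
    return nib.Nifti1Image(v, affine=np.eye(4))


def save_t1_map_nifti(vol: np.ndarray, path) -> None:
    nib.save(_as_nifti(vol), str(path))


def save_maps_nifti(maps: ParameterMaps, outdir, prefix: str = "") -> None:
    """One NIfTI volume per fitted parameter plus T1 and residual."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for f in dc_fields(maps):
        vol = getattr(maps, f.name)
        if f.name == "valid":
            vol = vol.astype(np.float64)
        nib.save(_as_nifti(vol), str(out / f"{prefix}{f.name}.nii"))


def save_series(path, series: np.ndarray) -> None:
    with h5py.File(path, "w") as f:
        f["series"] = series


def load_series(path) -> np.ndarray:
    with h5py.File(path, "r") as f:
        return np.asarray(f["series"])


def load_timing_config(path) -> SequenceTiming:
    """Sequence timing from a YAML key-value file (keys: tr, td,
    n_spokes_per_part, n_bins_per_part, optional bin_times)."""
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    kw = {k: cfg[k] for k in
          ("tr", "td", "n_spokes_per_part", "n_bins_per_part", "bin_times")
          if k in cfg}
    if "bin_times" in kw:
        kw["bin_times"] = np.asarray(kw["bin_times"], dtype=float)
    return SequenceTiming(**kw)
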
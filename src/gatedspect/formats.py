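"""On-disk formats: 4-D NIfTI gated image series, HDF5 sinogram containers."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from gatedspect.gating import AcquisitionTimeMap, GatedSinogram
from gatedspect.recon import GatedImageSeries

__all__ = [
    "FormatError",
    "write_gated_nifti",
    "read_gated_nifti",
    "write_sinogram_h5",
    "read_sinogram_h5",
]


class FormatError(ValueError):
    """Raised on malformed or incomplete on-disk containers."""


def write_gated_nifti(series: GatedImageSeries, path: str | Path) -> Path:
    """Write a gated series as one 4-D NIfTI (x, y, z, ECG bin).

    Voxel size goes into the affine/zooms; provenance (mode, recon config)
    into a JSON sidecar next to the image.
    """
    path = Path(path)
    affine = np.diag([series.voxel_size_mm] * 3 + [1.0])
    img = nib.Nifti1Image(series.data.astype(np.float64), affine)
    img.header.set_zooms((series.voxel_size_mm,) * 3 + (1.0,))
    nib.save(img, path)
    sidecar = path.with_suffix("").with_suffix(".json")
    sidecar.write_text(json.dumps({"mode": series.mode, **series.meta}, indent=1))
    return path


def read_gated_nifti(path: str | Path) -> GatedImageSeries:
    path = Path(path)
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise FormatError(
            f"expected a 4-D gated series, got {data.ndim}-D data in {path}"
        )
    zooms = img.header.get_zooms()
    meta: dict = {}
    mode = ""
    sidecar = path.with_suffix("").with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        mode = meta.pop("mode", "")
    return GatedImageSeries(
        data=np.asarray(data, dtype=float),
        voxel_size_mm=float(zooms[0]),
        mode=mode,
        meta=meta,
    )


def write_sinogram_h5(
    path: str | Path,
    sino: GatedSinogram,
    tau: AcquisitionTimeMap,
    rr_intervals: np.ndarray | None = None,
) -> Path:
    """Write counts, acquisition times, angles and (optionally) the R-R
    series into an HDF5 container with named datasets."""
    if tau.tau.shape != sino.counts.shape[:2]:
        raise FormatError(
            f"tau shape {tau.tau.shape} does not match counts {sino.counts.shape[:2]}"
        )
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("counts", data=sino.counts, dtype=np.int64)
        f.create_dataset("tau", data=tau.tau)
        f.create_dataset("angles", data=np.asarray(sino.angles_deg, dtype=float))
        f.create_dataset(
            "rr_intervals",
            data=np.asarray(rr_intervals, dtype=float)
            if rr_intervals is not None
            else np.empty(0),
        )
        f.attrs["det_bin_mm"] = sino.det_bin_mm
    return path


def read_sinogram_h5(path: str | Path) -> tuple[GatedSinogram, AcquisitionTimeMap, np.ndarray]:
    path = Path(path)
    with h5py.File(path, "r") as f:
        for name in ("counts", "tau", "angles", "rr_intervals"):
            if name not in f:
                raise FormatError(f"dataset /{name} missing from {path}")
        counts = f["counts"][()]
        tau = f["tau"][()]
        angles = f["angles"][()]
        rr = f["rr_intervals"][()]
        det_bin = float(f.attrs.get("det_bin_mm", 0.0))
    if not np.issubdtype(counts.dtype, np.integer):
        raise FormatError("counts dataset must be integer-typed")
    if counts.ndim != 4:
        raise FormatError("counts dataset must be 4-D (angle, bin, u, v)")
    if tau.shape != counts.shape[:2]:
        raise FormatError(
            f"tau shape {tau.shape} inconsistent with counts {counts.shape[:2]}"
        )
    if angles.shape != (counts.shape[0],):
        raise FormatError("angles dataset must have one entry per projection angle")
    sino = GatedSinogram(counts=counts, angles_deg=tuple(angles), det_bin_mm=det_bin)
    return sino, AcquisitionTimeMap(tau=tau), rr
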
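"""OSEM and time-modified OSEM (TOSEM) reconstruction of gated sinograms.

The transition matrix is block-structured over projection angles,
``H = [[H¹]ᵀ, …, [H^L]ᵀ]ᵀ``.  In OSEM each block is ``H^l = P^l R^l``
(CDR-modelling forward projection after rotation); in TOSEM each block is
additionally scaled by the acquisition time of that angle (and ECG bin),
``H^l = τ^l P^l R^l``.  Because the time factors enter both the forward
model and the sensitivity ``Σ Hᵀ1``, reconstructing each ECG bin with TOSEM
yields images on a common activity-rate scale: bins acquired for less time
(the HRV-shortened last bin) are automatically scaled up, and the total
activity stays constant across bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from gatedspect.gating import AcquisitionTimeMap, GatedSinogram
from gatedspect.projector import Projector

__all__ = [
    "ReconConfig",
    "SystemModel",
    "GatedImageSeries",
    "osem_update",
    "reconstruct_bin",
    "reconstruct_series",
    "postprocess",
    "cylinder_mask",
    "poisson_loglik",
]


@dataclass(frozen=True)
class ReconConfig:
    """Iteration schedule and numerical guards for OSEM/TOSEM."""

    n_iterations: int = 10
    n_subsets: int = 8
    epsilon: float = 1e-12
    initial_value: float = 1.0

    def __post_init__(self) -> None:
        if self.n_iterations < 1 or self.n_subsets < 1:
            raise ValueError("n_iterations and n_subsets must be >= 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.initial_value <= 0:
            raise ValueError("initial image must be positive")


@dataclass
class SystemModel:
    """Projector plus reconstruction mode and (for TOSEM) acquisition times."""

    projector: Projector
    mode: Literal["osem", "tosem"] = "osem"
    tau: AcquisitionTimeMap | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("osem", "tosem"):
            raise ValueError("mode must be 'osem' or 'tosem'")
        if self.mode == "tosem":
            if self.tau is None:
                raise ValueError("TOSEM requires an acquisition-time map")
            if self.tau.n_angles != self.projector.geometry.n_angles:
                raise ValueError("tau must have one row per projection angle")

    def tau_for_bin(self, bin_index: int) -> np.ndarray:
        """Per-angle time factors for one ECG bin (ones in OSEM mode)."""
        L = self.projector.geometry.n_angles
        if self.mode == "osem":
            return np.ones(L)
        return self.tau.tau[:, bin_index].copy()


@dataclass
class GatedImageSeries:
    """One reconstructed volume per ECG bin, plus provenance."""

    data: np.ndarray = field(repr=False)  # (nx, ny, nz, n_bins)
    voxel_size_mm: float
    mode: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 4:
            raise ValueError("gated series data must be 4-D (x, y, z, bin)")
        if np.any(d < 0) or not np.all(np.isfinite(d)):
            raise ValueError("gated series must be finite and non-negative")
        self.data = d

    @property
    def n_bins(self) -> int:
        return self.data.shape[3]

    def volume(self, b: int) -> np.ndarray:
        return self.data[..., b]

    def bin_totals(self) -> np.ndarray:
        return self.data.sum(axis=(0, 1, 2))


def _subset_angles(L: int, n_subsets: int) -> list[np.ndarray]:
    if L % n_subsets != 0:
        raise ValueError(
            f"number of angles ({L}) must be divisible by n_subsets ({n_subsets})"
        )
    return [np.arange(s, L, n_subsets) for s in range(n_subsets)]


def _subset_order(n_subsets: int) -> list[int]:
    """Bit-reversed processing order, maximizing angular separation."""
    bits = int(np.log2(n_subsets))
    if 2**bits != n_subsets:
        return list(range(n_subsets))
    order = []
    for s in range(n_subsets):
        r = 0
        v = s
        for _ in range(bits):
            r = (r << 1) | (v & 1)
            v >>= 1
        order.append(r)
    return order


def osem_update(
    f: np.ndarray,
    subset: Sequence[int],
    g_bin: np.ndarray,
    model: SystemModel,
    bin_index: int = 0,
    epsilon: float = 1e-12,
    sens: np.ndarray | None = None,
) -> np.ndarray:
    """One ordered-subset EM update of the image for a single ECG bin.

    ``f ← (f / sens) ⊙ Σ_{l∈S} H^{lᵀ} (g^l / max(H^l f, ε))`` with
    ``sens = Σ_{l∈S} H^{lᵀ} 1``; ``H^l`` carries the τ factor iff the model
    is in TOSEM mode.  Voxels with zero sensitivity are set to 0 and frozen.
    """
    g_bin = np.asarray(g_bin, dtype=float)
    if np.any(g_bin < 0):
        raise ValueError("negative counts in the projection data")
    proj = model.projector
    tau = model.tau_for_bin(bin_index)
    if sens is None:
        bp1 = proj.bp_ones()
        sens = np.zeros_like(np.asarray(f, dtype=float))
        for l in subset:
            sens = sens + tau[l] * bp1[l]
    ratio_bp = np.zeros_like(np.asarray(f, dtype=float))
    for l in subset:
        q = tau[l] * proj.forward(f, l)
        ratio_bp += tau[l] * proj.back(g_bin[l] / np.maximum(q, epsilon), l)
    live = sens > 0
    out = np.zeros_like(ratio_bp)
    out[live] = f[live] / sens[live] * ratio_bp[live]
    return out


def reconstruct_bin(
    g_bin: np.ndarray,
    model: SystemModel,
    cfg: ReconConfig = ReconConfig(),
    bin_index: int = 0,
) -> np.ndarray:
    """Reconstruct one ECG bin with M iterations over N ordered subsets.

    Starts from a uniform positive image; deterministic given inputs.
    """
    proj = model.projector
    L = proj.geometry.n_angles
    g_bin = np.asarray(g_bin, dtype=float)
    if g_bin.shape != (L, *proj.geometry.detector_shape):
        raise ValueError("projection data shape does not match the geometry")
    subsets = _subset_angles(L, cfg.n_subsets)
    order = _subset_order(cfg.n_subsets)
    tau = model.tau_for_bin(bin_index)
    if model.mode == "tosem" and not np.any(tau > 0):
        raise ValueError(
            f"ECG bin {bin_index} has zero acquisition time everywhere; "
            "it cannot be reconstructed"
        )

    bp1 = proj.bp_ones()
    sens_per_subset = []
    for s in range(cfg.n_subsets):
        sens = np.zeros(proj.geometry.grid_shape)
        for l in subsets[s]:
            sens += tau[l] * bp1[l]
        sens_per_subset.append(sens)

    f = np.full(proj.geometry.grid_shape, cfg.initial_value)
    for _ in range(cfg.n_iterations):
        for s in order:
            f = osem_update(
                f, subsets[s], g_bin, model, bin_index,
                epsilon=cfg.epsilon, sens=sens_per_subset[s],
            )
    return f


def reconstruct_series(
    sino: GatedSinogram,
    tau: AcquisitionTimeMap | None,
    mode: Literal["osem", "tosem"],
    cfg: ReconConfig = ReconConfig(),
    projector: Projector | None = None,
    geometry=None,
    cdr=None,
) -> GatedImageSeries:
    """Reconstruct every ECG bin independently.

    In TOSEM mode per-bin totals are on a common activity-rate (counts/s)
    scale; in OSEM mode they follow the per-bin measured counts.
    """
    if projector is None:
        projector = Projector(geometry, cdr)
    model = SystemModel(projector=projector, mode=mode, tau=tau)
    vols = [
        reconstruct_bin(sino.counts[:, b].astype(float), model, cfg, bin_index=b)
        for b in range(sino.n_bins)
    ]
    return GatedImageSeries(
        data=np.stack(vols, axis=-1),
        voxel_size_mm=projector.geometry.voxel_size_mm,
        mode=mode,
        meta={
            "n_iterations": cfg.n_iterations,
            "n_subsets": cfg.n_subsets,
            "n_angles": projector.geometry.n_angles,
        },
    )


def cylinder_mask(
    grid_shape: tuple[int, int, int],
    voxel_size_mm: float,
    radius_mm: float,
    z_range: tuple[int, int] | None = None,
) -> np.ndarray:
    """Binary cylindrical mask centred on the grid (the known LV location)."""
    nx, ny, nz = grid_shape
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    r = np.hypot(ix - cx, iy - cy) * voxel_size_mm
    mask = np.zeros(grid_shape, dtype=bool)
    lo, hi = z_range if z_range is not None else (0, nz)
    mask[:, :, lo:hi] = (r <= radius_mm)[:, :, None]
    return mask


def postprocess(
    series: GatedImageSeries,
    sigma_voxels: float = 1.0,
    mask: np.ndarray | None = None,
) -> GatedImageSeries:
    """Post-reconstruction 3-D Gaussian smoothing, then extracardiac masking.

    Smoothing uses mirror boundary handling; the mask (if given) is a binary
    volume multiplied in after smoothing.
    """
    if sigma_voxels < 0:
        raise ValueError("sigma must be non-negative")
    data = series.data
    if sigma_voxels > 0:
        data = np.stack(
            [
                gaussian_filter(data[..., b], sigma=sigma_voxels, mode="mirror")
                for b in range(series.n_bins)
            ],
            axis=-1,
        )
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != data.shape[:3]:
            raise ValueError("mask shape must match the image grid")
        if not mask.any():
            raise ValueError("mask removes the entire image")
        data = data * mask[..., None]
    return GatedImageSeries(
        data=data,
        voxel_size_mm=series.voxel_size_mm,
        mode=series.mode,
        meta={**series.meta, "smoothed_sigma": sigma_voxels, "masked": mask is not None},
    )


def poisson_loglik(
    g: np.ndarray, expected: np.ndarray, epsilon: float = 1e-12
) -> float:
    """Poisson log-likelihood ``Σ g·log(λ) − λ`` up to a data-only constant."""
    lam = np.maximum(np.asarray(expected, dtype=float), epsilon)
    g = np.asarray(g, dtype=float)
    return float(np.sum(g * np.log(lam) - lam))
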
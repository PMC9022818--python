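"""Synthetic block-design data with condition-dependent coupling.

ROI signals share a latent standard-normal signal z(t) whose mixing
weight switches with the task condition, plus independent Gaussian
noise:

    x_r(t) = noise_sd * ( sqrt(rho(t)) * z(t) + sqrt(1 - rho(t)) * e_r(t) )

with z and e_r independent standard normal.  Every channel then has
variance noise_sd^2 at every time point and any two channels have
population correlation exactly rho(t), so the full-duration correlation
converges to the duration-weighted mixture of the task and rest
couplings.  The default design mirrors a
canonical sustained-attention block paradigm: five 30 s task blocks
alternating with five 30 s rest blocks at TR = 1 s (300 volumes).

Optionally the condition-switching weight profile is smoothed by
convolution with the canonical HRF, emulating the sluggish haemodynamic
transition between states.  The generator makes no attempt at realistic
fMRI noise (drift, motion spikes, spatial autocorrelation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import TaskDesign, design_boxcar, _sampled_hrf, HRFParams
from .io import ROIDefinition, ROITimeSeries, VolumeSeries


def default_block_design(tr: float = 1.0) -> TaskDesign:
    """Five 30 s rest / 30 s task alternations starting with rest."""
    n_tr = int(round(30.0 / tr))
    return TaskDesign(condition=(0, 1) * 5, durations=(n_tr,) * 10, tr=tr)


@dataclass
class SimSpec:
    """Settings of the synthetic ROI time-series generator."""

    n_rois: int = 10
    design: TaskDesign = field(default_factory=default_block_design)
    rho_task: float = 0.6
    rho_rest: float = 0.2
    noise_sd: float = 1.0
    hrf_smoothing: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for rho in (self.rho_task, self.rho_rest):
            if not 0.0 <= rho < 1.0:
                raise ValueError(
                    "a shared-latent coupling common to all ROIs requires "
                    "rho in [0, 1)"
                )
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_rois < 2:
            raise ValueError("need at least 2 ROIs")


def simulate_roi_timeseries(spec: SimSpec) -> ROITimeSeries:
    """Draw one subject's ROI time series under the given coupling spec."""
    rng = np.random.default_rng(spec.seed)
    design = spec.design
    T = design.n_timepoints
    box = design_boxcar(design)
    # per-TR target coupling; sqrt weights give corr(x_i, x_j) = rho(t)
    rho = np.where(box > 0, spec.rho_task, spec.rho_rest)
    if spec.hrf_smoothing:
        h = _sampled_hrf(design.tr, HRFParams())
        smoothed = np.convolve(box, h)[:T]
        peak = smoothed.max()
        if peak > 0:
            smoothed = smoothed / peak
        rho = spec.rho_rest + (spec.rho_task - spec.rho_rest) * np.clip(
            smoothed, 0.0, 1.0
        )
    z = rng.standard_normal(T)
    noise = rng.standard_normal((T, spec.n_rois))
    values = spec.noise_sd * (
        np.sqrt(rho)[:, None] * z[:, None]
        + np.sqrt(1.0 - rho)[:, None] * noise
    )
    return ROITimeSeries(values=values, tr=design.tr)


def simulate_volume(
    spec: SimSpec,
    rois: ROIDefinition,
    grid_shape: tuple[int, int, int] = (16, 16, 8),
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0),
    voxel_noise_sd: float = 0.0,
) -> tuple[VolumeSeries, ROITimeSeries]:
    """Paint simulated ROI series into ROI voxels of a 4D volume.

    Returns the volume and the generating ROI series.  With zero voxel
    noise, extracting the ROIs from the volume recovers the generating
    series exactly.  Overlapping ROIs are rejected.
    """
    ts = simulate_roi_timeseries(spec)
    affine = np.diag([*voxel_size, 1.0])
    T = ts.n_timepoints
    vol = VolumeSeries(
        data=np.zeros((*grid_shape, T)),
        voxel_size=voxel_size,
        tr=ts.tr,
        affine=affine,
    )
    from .io import _resolve_roi_masks  # resolved on this synthetic grid

    masks = _resolve_roi_masks(vol, rois)
    if len(masks) != spec.n_rois:
        raise ValueError(
            f"spec has {spec.n_rois} ROIs but {len(masks)} were resolved"
        )
    occupancy = np.zeros(grid_shape, dtype=int)
    for m in masks.values():
        occupancy += m
    if (occupancy > 1).any():
        raise ValueError("ROIs overlap on the simulation grid")
    for r, (name, m) in enumerate(masks.items()):
        vol.data[m, :] = ts.values[:, r]
    if voxel_noise_sd > 0:
        rng = np.random.default_rng(spec.seed + 1)
        vol.data += rng.standard_normal(vol.data.shape) * voxel_noise_sd
    ts.roi_labels = list(masks)
    return vol, ts


def block_roi_definition(
    n_rois: int, grid_shape: tuple[int, int, int] = (16, 16, 8)
) -> ROIDefinition:
    """Non-overlapping cubic ROIs laid out along the x axis (mask set)."""
    masks = {}
    labels = []
    width = grid_shape[0] // n_rois
    if width < 1:
        raise ValueError("grid too small for the requested number of ROIs")
    for r in range(n_rois):
        m = np.zeros(grid_shape, dtype=bool)
        m[r * width : r * width + width, : grid_shape[1] // 2, :] = True
        name = f"roi{r + 1}"
        masks[name] = m
        labels.append(name)
    return ROIDefinition(kind="mask-set", labels=labels, geometry=masks)
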
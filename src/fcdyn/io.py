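"""Reading fMRI volumes and ROI definitions, extracting ROI time series.

Volumes are NIfTI-1 images (plain or gzipped) read with nibabel.  ROIs may be
given as an integer label atlas, a set of binary masks, or spheres specified
by a centre in world (mm) coordinates and a radius.  ROI time series and
result tables travel as delimited text (TSV/CSV).

The atlas/data grid must agree exactly (same shape, affines equal within
1e-4); no resampling is performed here -- spatial normalisation belongs to
upstream preprocessing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import nibabel as nib
import numpy as np
import pandas as pd


class DimensionalError(ValueError):
    """Input image does not have the expected dimensionality."""


class GridMismatchError(ValueError):
    """Volume and ROI geometry are not on the same voxel grid."""


class EmptyROIError(ValueError):
    """An ROI resolves to zero voxels on the volume grid."""


@dataclass
class VolumeSeries:
    """A 4D BOLD series with its sampling metadata.

    Attributes
    ----------
    data : ndarray, shape (x, y, z, t)
    voxel_size : tuple of 3 floats, mm
    tr : float, seconds between volumes
    affine : (4, 4) voxel-to-world transform
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    tr: float
    affine: np.ndarray

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise DimensionalError(
                f"expected a 4D series, got {self.data.ndim}D data"
            )
        if self.tr <= 0:
            raise ValueError(f"tr must be positive, got {self.tr}")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]


@dataclass
class ROIDefinition:
    """Region definitions: a label atlas, binary masks, or mm spheres.

    ``kind`` selects how ``geometry`` is interpreted:

    - ``"label-atlas"``: geometry is an integer 3D array; each distinct
      non-zero label named in ``labels`` (mapping name -> label value).
    - ``"mask-set"``: geometry is a mapping name -> boolean 3D array.
    - ``"sphere-set"``: geometry is a mapping name -> (center_mm, radius_mm);
      a voxel belongs to the sphere iff its centre lies within the radius
      (inclusive).
    """

    kind: Literal["label-atlas", "mask-set", "sphere-set"]
    labels: Sequence[str]
    geometry: object
    atlas_affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("ROI labels must be unique")


@dataclass
class ROITimeSeries:
    """T x R matrix of per-ROI mean BOLD signal.

    Rows are time points (volumes), columns are ROIs in ``roi_labels``
    order.  ``tr`` is the sampling interval in seconds.
    """

    values: np.ndarray
    tr: float
    roi_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a T x R matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ROI time series contains non-finite values")
        if not self.roi_labels:
            self.roi_labels = [f"roi{i + 1}" for i in range(self.values.shape[1])]
        if len(self.roi_labels) != self.values.shape[1]:
            raise ValueError("roi_labels length must match number of columns")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]


def read_volume(path: str | Path, tr: float | None = None) -> VolumeSeries:
    """Read a 4D NIfTI image.

    The repetition time is taken from the header (``pixdim[4]``) unless
    overridden with ``tr``.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise DimensionalError(
            f"{path}: expected a 4D image, got {data.ndim}D"
        )
    zooms = img.header.get_zooms()
    header_tr = float(zooms[3]) if len(zooms) > 3 else 0.0
    tr_out = float(tr) if tr is not None else header_tr
    if tr_out <= 0:
        raise ValueError(
            f"{path}: repetition time not present in header; pass tr explicitly"
        )
    return VolumeSeries(
        data=data,
        voxel_size=tuple(float(z) for z in zooms[:3]),
        tr=tr_out,
        affine=np.asarray(img.affine, dtype=float),
    )


def write_volume(vol: VolumeSeries, path: str | Path) -> None:
    """Write a VolumeSeries as NIfTI-1, preserving TR in pixdim[4]."""
    img = nib.Nifti1Image(vol.data, vol.affine)
    img.header.set_zooms((*vol.voxel_size, vol.tr))
    nib.save(img, str(path))


def _check_grid(vol: VolumeSeries, affine: np.ndarray | None, shape) -> None:
    if shape is not None and tuple(shape) != vol.data.shape[:3]:
        raise GridMismatchError(
            f"ROI grid {tuple(shape)} does not match volume grid "
            f"{vol.data.shape[:3]}"
        )
    if affine is not None and not np.allclose(affine, vol.affine, atol=1e-4):
        raise GridMismatchError("ROI affine differs from volume affine")


def _resolve_roi_masks(
    vol: VolumeSeries, rois: ROIDefinition
) -> dict[str, np.ndarray]:
    """Resolve each ROI to a boolean mask on the volume grid."""
    masks: dict[str, np.ndarray] = {}
    if rois.kind == "label-atlas":
        atlas = np.asarray(rois.geometry)
        _check_grid(vol, rois.atlas_affine, atlas.shape)
        label_map = rois.labels
        if isinstance(label_map, dict):
            items = label_map.items()
        else:  # labels name the sorted distinct non-zero values
            values = sorted(int(v) for v in np.unique(atlas) if v != 0)
            if len(rois.labels) != len(values):
                raise EmptyROIError(
                    f"atlas has {len(values)} non-zero labels but "
                    f"{len(rois.labels)} names were given"
                )
            items = zip(rois.labels, values)
        for name, value in items:
            masks[name] = atlas == value
    elif rois.kind == "mask-set":
        for name in rois.labels:
            m = np.asarray(rois.geometry[name], dtype=bool)
            _check_grid(vol, rois.atlas_affine, m.shape)
            masks[name] = m
    elif rois.kind == "sphere-set":
        shape = vol.data.shape[:3]
        idx = np.indices(shape).reshape(3, -1)
        world = (vol.affine @ np.vstack([idx, np.ones(idx.shape[1])]))[:3]
        for name in rois.labels:
            center, radius = rois.geometry[name]
            center = np.asarray(center, dtype=float).reshape(3, 1)
            inside = np.sum((world - center) ** 2, axis=0) <= float(radius) ** 2
            masks[name] = inside.reshape(shape)
    else:
        raise ValueError(f"unknown ROI kind {rois.kind!r}")
    for name, m in masks.items():
        if not m.any():
            raise EmptyROIError(f"ROI {name!r} contains no voxels")
    return masks


def extract_roi_timeseries(vol: VolumeSeries, rois: ROIDefinition) -> ROITimeSeries:
    """Average the BOLD signal over each ROI's voxels at every time point.

    The ROI mean is the unweighted arithmetic mean over member voxels.
    """
    masks = _resolve_roi_masks(vol, rois)
    flat = vol.data.reshape(-1, vol.data.shape[3])
    cols = []
    labels = list(masks)
    for name in labels:
        cols.append(flat[masks[name].ravel()].mean(axis=0))
    return ROITimeSeries(
        values=np.column_stack(cols), tr=vol.tr, roi_labels=labels
    )


def read_matrix_timeseries(path: str | Path, tr: float) -> ROITimeSeries:
    """Read a delimited (TSV/CSV) time-series matrix: rows = time, cols = ROIs.

    A non-numeric first row is treated as a header of ROI labels.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else r"\s+"
    first = pd.read_csv(path, sep=sep, header=None, nrows=1)
    has_header = first.iloc[0].apply(
        lambda v: isinstance(v, str)
        and not v.replace(".", "", 1).lstrip("+-").replace("e", "", 1).isdigit()
    ).any()
    try:
        df = pd.read_csv(path, sep=sep, header=0 if has_header else None)
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cell in time-series matrix") from exc
    labels = [str(c) for c in df.columns] if has_header else []
    return ROITimeSeries(values=values, tr=tr, roi_labels=labels)


def write_matrix_timeseries(ts: ROITimeSeries, path: str | Path) -> None:
    """Write a time-series matrix as TSV with ROI labels as header."""
    df = pd.DataFrame(ts.values, columns=ts.roi_labels)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_sphere_sidecar(path: str | Path) -> ROIDefinition:
    """Read sphere ROI definitions from a JSON sidecar.

    The sidecar is a list of ``{"label": ..., "center_mm": [x, y, z],
    "radius_mm": r}`` objects.
    """
    with open(path) as fh:
        entries = json.load(fh)
    labels = [e["label"] for e in entries]
    geometry = {
        e["label"]: (tuple(e["center_mm"]), float(e["radius_mm"]))
        for e in entries
    }
    return ROIDefinition(kind="sphere-set", labels=labels, geometry=geometry)
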
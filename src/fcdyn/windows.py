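"""Sliding-window functional connectivity.

A window of ``window_size`` volumes is advanced by ``step_size``; within
each position the pairwise Pearson correlation of the ROI signals gives
one R x R connectivity matrix.  Each window is indexed by its *last*
volume ("the current and previous N volumes"); the 1-based index of that
volume is kept in ``window_last_tr`` so temporal masks can address
windows in scan time.  A Gaussian taper turns the plain correlation into
a weighted correlation with weights centred on the window midpoint.

Setting ``window_size`` equal to the series length reduces the analysis
to the ordinary static connectivity matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

from .io import ROITimeSeries

log = logging.getLogger(__name__)


class WindowParameterError(ValueError):
    """Window/step settings incompatible with the series."""


@dataclass
class WindowSpec:
    """Sliding-window settings (sizes in TR counts)."""

    window_size: int = 17
    step_size: int = 1
    taper: Literal["rectangular", "gaussian"] = "rectangular"
    gaussian_sigma: float | None = None  # TRs; default window_size / 6

    def __post_init__(self) -> None:
        if self.window_size < 1:
            raise WindowParameterError("window_size must be >= 1")
        if self.step_size < 1:
            raise WindowParameterError("step_size must be >= 1")
        if self.gaussian_sigma is not None and self.gaussian_sigma <= 0:
            raise WindowParameterError("gaussian_sigma must be positive")

    def weights(self) -> np.ndarray:
        """Per-volume weights within one window, normalised to sum 1."""
        N = self.window_size
        if self.taper == "rectangular":
            w = np.ones(N)
        else:
            sigma = self.gaussian_sigma if self.gaussian_sigma else N / 6.0
            center = (N - 1) / 2.0
            t = np.arange(N)
            w = np.exp(-0.5 * ((t - center) / sigma) ** 2)
        return w / w.sum()


@dataclass
class FCSeries:
    """Time-ordered windowed connectivity matrices.

    ``matrices`` has shape (W, R, R); entries may be NaN where a window
    contained a constant ROI signal (undefined correlation).
    ``window_last_tr`` holds the 1-based index of each window's final
    volume.
    """

    matrices: np.ndarray
    window_last_tr: np.ndarray
    window_spec: WindowSpec
    roi_labels: list[str]
    tr: float = 1.0

    @property
    def n_windows(self) -> int:
        return self.matrices.shape[0]

    @property
    def n_rois(self) -> int:
        return self.matrices.shape[1]

    def save(self, path: str | Path) -> None:
        """Persist as a compressed npz archive (format version 1)."""
        np.savez_compressed(
            path,
            format_version=1,
            matrices=self.matrices,
            window_last_tr=self.window_last_tr,
            window_size=self.window_spec.window_size,
            step_size=self.window_spec.step_size,
            taper=self.window_spec.taper,
            gaussian_sigma=self.window_spec.gaussian_sigma or np.nan,
            roi_labels=np.array(self.roi_labels),
            tr=self.tr,
        )

    @classmethod
    def load(cls, path: str | Path) -> "FCSeries":
        with np.load(path, allow_pickle=False) as z:
            sigma = float(z["gaussian_sigma"])
            spec = WindowSpec(
                window_size=int(z["window_size"]),
                step_size=int(z["step_size"]),
                taper=str(z["taper"]),
                gaussian_sigma=None if np.isnan(sigma) else sigma,
            )
            return cls(
                matrices=z["matrices"],
                window_last_tr=z["window_last_tr"],
                window_spec=spec,
                roi_labels=[str(x) for x in z["roi_labels"]],
                tr=float(z["tr"]),
            )


def count_windows(n_timepoints: int, spec: WindowSpec) -> int:
    """Number of full windows: floor((T - N) / step) + 1."""
    if spec.window_size > n_timepoints:
        raise WindowParameterError(
            f"window of {spec.window_size} TRs exceeds series length "
            f"{n_timepoints}"
        )
    return (n_timepoints - spec.window_size) // spec.step_size + 1


def weighted_pearson(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """Weighted Pearson correlation of two equal-length series.

    Uses weighted means and (co)variances; uniform weights reduce it to
    the ordinary Pearson coefficient.  Returns NaN when either series is
    constant under the weights.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if x.shape != y.shape or x.shape != w.shape:
        raise ValueError("x, y, w must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 samples for a correlation")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    w = w / w.sum()
    mx = np.sum(w * x)
    my = np.sum(w * y)
    cov = np.sum(w * (x - mx) * (y - my))
    vx = np.sum(w * (x - mx) ** 2)
    vy = np.sum(w * (y - my) ** 2)
    if vx <= 0 or vy <= 0:
        return float("nan")
    return float(np.clip(cov / np.sqrt(vx * vy), -1.0, 1.0))


def sliding_window_fc(ts: ROITimeSeries, spec: WindowSpec) -> FCSeries:
    """Windowed pairwise Pearson connectivity of an ROI time series.

    Window w (0-based) covers volumes ``[w*step, w*step + N)``; its matrix
    is the (possibly taper-weighted) correlation of the ROI columns over
    those volumes, with unit diagonal.  Edges touching an ROI that is
    constant within a window are set to NaN and a warning is logged.
    """
    if ts.n_rois < 2:
        raise WindowParameterError("connectivity needs at least 2 ROIs")
    T = ts.n_timepoints
    W = count_windows(T, spec)
    N = spec.window_size
    weights = spec.weights()
    R = ts.n_rois
    matrices = np.empty((W, R, R))
    last_tr = np.empty(W, dtype=int)
    n_bad = 0
    for w in range(W):
        start = w * spec.step_size
        seg = ts.values[start : start + N]
        mw = weights @ seg
        centered = seg - mw
        cov = (weights[:, None] * centered).T @ centered
        var = np.diag(cov).copy()
        bad = var <= 0
        if bad.any():
            n_bad += 1
            var[bad] = np.nan
        denom = np.sqrt(np.outer(var, var))
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.clip(cov / denom, -1.0, 1.0)
        np.fill_diagonal(corr, 1.0)
        matrices[w] = (corr + corr.T) / 2.0
        last_tr[w] = start + N  # 1-based index of final volume
    if n_bad:
        log.warning(
            "%d window(s) contained a constant ROI signal; their edges are "
            "marked missing (NaN)",
            n_bad,
        )
    return FCSeries(
        matrices=matrices,
        window_last_tr=last_tr,
        window_spec=spec,
        roi_labels=list(ts.roi_labels),
        tr=ts.tr,
    )
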
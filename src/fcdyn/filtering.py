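"""Band-limiting ROI time series before windowed correlation.

Two routes are offered:

* zero-phase frequency-domain masking (high-, low-, band-pass) with hard
  cutoffs specified as *periods in seconds* (1/frequency), and
* level-selective reconstruction from a maximal overlap discrete wavelet
  transform (MODWT).

The MODWT multiresolution analysis is computed here directly (pyramid of
circular filterings in the Fourier domain, after reflection extension);
PyWavelets supplies only the orthonormal filter coefficients.  For an
orthonormal filter pair the MODWT transfer functions tile the spectrum
exactly, so the detail series D_1..D_L plus the level-L smooth add back to
the input to machine precision.  Level-j details at sampling rate fs occupy
the nominal band [fs/2^(j+1), fs/2^j].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pywt

from .io import ROITimeSeries


class FilterParameterError(ValueError):
    """A cutoff or level choice is incompatible with the series."""


@dataclass
class FilterSpec:
    """Temporal filter settings.

    Cutoffs are periods in seconds: a high-pass with ``cutoff_low_s = 75``
    passes fluctuations faster than 1/75 Hz.  For ``mode="wavelet"``,
    ``wavelet_levels`` is the decomposition depth L and ``keep_levels`` the
    detail levels used for reconstruction; the level-L smooth
    (approximation) is added back only when ``keep_approximation`` is set.
    """

    mode: Literal["none", "highpass", "lowpass", "bandpass", "wavelet"] = "none"
    cutoff_low_s: float | None = None
    cutoff_high_s: float | None = None
    wavelet_levels: int = 5
    keep_levels: tuple[int, ...] = (3, 4, 5)
    keep_approximation: bool = False
    wavelet: str = "sym8"

    def __post_init__(self) -> None:
        if self.mode == "bandpass":
            if self.cutoff_low_s is None or self.cutoff_high_s is None:
                raise FilterParameterError("bandpass requires both cutoffs")
            if not self.cutoff_high_s > self.cutoff_low_s:
                raise FilterParameterError(
                    "bandpass needs cutoff_low_s < cutoff_high_s (periods)"
                )
        if self.mode == "wavelet":
            if self.wavelet_levels < 1:
                raise FilterParameterError("wavelet_levels must be >= 1")
            if not self.keep_levels:
                raise FilterParameterError("keep_levels must be non-empty")
            bad = set(self.keep_levels) - set(range(1, self.wavelet_levels + 1))
            if bad:
                raise FilterParameterError(
                    f"keep_levels {sorted(bad)} outside 1..{self.wavelet_levels}"
                )


def frequency_filter(ts: ROITimeSeries, spec: FilterSpec) -> ROITimeSeries:
    """Zero-phase hard-cutoff filtering of every ROI column.

    The series is transformed with a real FFT, bins outside the passband
    are zeroed, and the series is transformed back.  High- and band-pass
    remove the mean (DC bin); low-pass preserves it.
    """
    if spec.mode not in ("highpass", "lowpass", "bandpass"):
        raise FilterParameterError(f"not a frequency filter mode: {spec.mode}")
    T = ts.n_timepoints
    if T < 8:
        raise FilterParameterError("series too short to filter (T < 8)")
    nyquist = 1.0 / (2.0 * ts.tr)
    f_lo = 1.0 / spec.cutoff_low_s if spec.cutoff_low_s else None
    f_hi = 1.0 / spec.cutoff_high_s if spec.cutoff_high_s else None
    for f in (f_lo, f_hi):
        if f is not None and f > nyquist:
            raise FilterParameterError(
                f"cutoff frequency {f:.4g} Hz beyond Nyquist {nyquist:.4g} Hz"
            )
    freqs = np.fft.rfftfreq(T, d=ts.tr)
    keep = np.ones_like(freqs, dtype=bool)
    if spec.mode == "highpass":
        if f_lo is None:
            raise FilterParameterError("highpass requires cutoff_low_s")
        keep &= freqs >= f_lo
    elif spec.mode == "lowpass":
        if f_hi is None and spec.cutoff_high_s is None:
            raise FilterParameterError("lowpass requires a cutoff")
        # the lowpass cutoff is the shorter period bound
        f_cut = 1.0 / (spec.cutoff_high_s or spec.cutoff_low_s)
        keep &= freqs <= f_cut
    else:  # bandpass: periods (low, high) -> frequencies (1/high, 1/low)
        keep &= (freqs >= 1.0 / spec.cutoff_high_s) & (freqs <= 1.0 / spec.cutoff_low_s)
    if spec.mode in ("highpass", "bandpass"):
        keep[0] = False
    spectrum = np.fft.rfft(ts.values, axis=0)
    spectrum[~keep] = 0.0
    out = np.fft.irfft(spectrum, n=T, axis=0)
    return ROITimeSeries(values=out, tr=ts.tr, roi_labels=list(ts.roi_labels))


def _modwt_transfer(N: int, wavelet: str, levels: int) -> tuple[np.ndarray, np.ndarray]:
    """Squared-gain transfer functions for an MODWT MRA of length N.

    Returns ``(details, smooth)`` where ``details[j-1]`` is the real
    spectral gain of detail level j and ``smooth`` that of the level-L
    approximation; the gains sum to one at every frequency.
    """
    w = pywt.Wavelet(wavelet)
    g = np.asarray(w.dec_lo) / np.sqrt(2.0)  # MODWT scaling filter
    h = np.asarray(w.dec_hi) / np.sqrt(2.0)  # MODWT wavelet filter
    G = np.fft.fft(g, N)
    H = np.fft.fft(h, N)
    idx = np.arange(N)
    details = []
    low_prod = np.ones(N, dtype=complex)  # product of G at dyadic strides
    for j in range(1, levels + 1):
        stride = 2 ** (j - 1)
        Hj = H[(stride * idx) % N]
        details.append(np.abs(low_prod * Hj) ** 2)
        low_prod = low_prod * G[(stride * idx) % N]
    smooth = np.abs(low_prod) ** 2
    return np.array(details), smooth


def modwt_mra(x: np.ndarray, wavelet: str = "sym8", levels: int = 5) -> np.ndarray:
    """Additive MODWT multiresolution analysis of a 1D series.

    Returns an array of shape ``(levels + 1, T)``: detail series D_1..D_L
    followed by the level-L smooth S_L.  The rows sum to ``x`` exactly (to
    machine precision).  Boundaries are handled by reflection: the series
    is extended to length 2T, analysed circularly, and truncated.
    """
    x = np.asarray(x, dtype=float)
    T = x.shape[0]
    if T < 2**levels:
        raise FilterParameterError(
            f"series of length {T} too short for {levels} wavelet levels"
        )
    ext = np.concatenate([x, x[::-1]])
    N = ext.shape[0]
    details, smooth = _modwt_transfer(N, wavelet, levels)
    X = np.fft.fft(ext)
    out = np.empty((levels + 1, T))
    for j in range(levels):
        out[j] = np.real(np.fft.ifft(details[j] * X))[:T]
    out[levels] = np.real(np.fft.ifft(smooth * X))[:T]
    return out


def wavelet_filter(ts: ROITimeSeries, spec: FilterSpec) -> ROITimeSeries:
    """Reconstruct every ROI column from selected MODWT detail levels.

    The output is the sum of the detail series named in
    ``spec.keep_levels`` (plus the approximation when
    ``spec.keep_approximation``), so keeping every level and the
    approximation reproduces the input.
    """
    if spec.mode != "wavelet":
        raise FilterParameterError(f"not a wavelet filter spec: {spec.mode}")
    L = spec.wavelet_levels
    out = np.empty_like(ts.values)
    for r in range(ts.n_rois):
        mra = modwt_mra(ts.values[:, r], wavelet=spec.wavelet, levels=L)
        col = mra[[j - 1 for j in spec.keep_levels]].sum(axis=0)
        if spec.keep_approximation:
            col = col + mra[L]
        out[:, r] = col
    return ROITimeSeries(values=out, tr=ts.tr, roi_labels=list(ts.roi_labels))


def level_band(level: int, fs: float) -> tuple[float, float]:
    """Nominal passband [fs/2^(j+1), fs/2^j] in Hz of detail level j."""
    return fs / 2 ** (level + 1), fs / 2**level
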
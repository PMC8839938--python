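"""Single-lead R-peak detectors.

Six classical detector families are provided behind one pluggable
interface: Pan-Tompkins, Hamilton, Two-Average (Elgendi), stationary
wavelet transform (SWT), Christov and Engzee. Each is a pure function of
one lead and the sampling rate, returning sorted 0-based candidate sample
indices. The implementations follow the published processing chains
(band-pass / derivative / squaring / integration stages and the
adaptive-threshold logic specific to each family), streamlined to
deterministic, offline form.

Every detector refines its raw detections to the local extremum of the
band-passed lead, so candidates land on the R wave rather than on the
envelope maximum.
"""

from __future__ import annotations

import numpy as np
import pywt
from scipy import signal as sps
from scipy.ndimage import maximum_filter1d

__all__ = ["DETECTOR_NAMES", "detect", "get_detector"]


def _bandpass(x: np.ndarray, fs: float, lo: float, hi: float, order: int = 2) -> np.ndarray:
    nyq = fs / 2.0
    b, a = sps.butter(order, [lo / nyq, hi / nyq], btype="band")
    return sps.filtfilt(b, a, x)


def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    width = max(1, width)
    return np.convolve(x, np.ones(width) / width, mode="same")


def _refine(x_band: np.ndarray, approx: np.ndarray, fs: float, window: float = 0.1) -> np.ndarray:
    """Snap approximate detections to the nearest extremum of |band-passed lead|."""
    half = max(1, int(window * fs / 2))
    mag = np.abs(x_band)
    out = []
    for p in approx:
        lo, hi = max(0, p - half), min(len(mag), p + half + 1)
        out.append(lo + int(np.argmax(mag[lo:hi])))
    peaks = np.unique(np.asarray(out, dtype=int))
    # collapse refinements that merged to within a refractory distance
    if peaks.size > 1:
        keep = [peaks[0]]
        for p in peaks[1:]:
            if p - keep[-1] > int(0.2 * fs):
                keep.append(p)
            elif mag[p] > mag[keep[-1]]:
                keep[-1] = p
        peaks = np.asarray(keep)
    return peaks


def _spki_npki_peaks(env: np.ndarray, fs: float, *, gain: float = 0.25,
                     learn: float = 2.0) -> np.ndarray:
    """Classic dual running-estimate thresholding (signal/noise peak levels).

    ``SPKI`` tracks accepted QRS envelope peaks, ``NPKI`` rejected noise
    peaks; the decision threshold is ``NPKI + gain * (SPKI - NPKI)``,
    re-estimated per peak exactly as in the Pan-Tompkins recipe.
    """
    cand, _ = sps.find_peaks(env, distance=max(1, int(0.2 * fs)))
    if cand.size == 0:
        return cand
    head = env[: int(learn * fs)]
    spki = 0.25 * float(head.max(initial=0.0))
    npki = 0.5 * float(head.mean()) if head.size else 0.0
    accepted = []
    for p in cand:
        v = env[p]
        thr = npki + gain * (spki - npki)
        if v > thr and v > 0:
            accepted.append(p)
            spki = 0.125 * v + 0.875 * spki
        else:
            npki = 0.125 * v + 0.875 * npki
    return np.asarray(accepted, dtype=int)


def _two_average_blocks(env: np.ndarray, fs: float, *, w_event: float,
                        w_cycle: float, beta: float) -> np.ndarray:
    """Elgendi-style block thresholding with two moving averages."""
    ma_event = _moving_average(env, int(w_event * fs))
    ma_cycle = _moving_average(env, int(w_cycle * fs))
    thr = ma_cycle + beta * float(env.mean())
    interest = ma_event > thr
    if not interest.any():
        return np.asarray([], dtype=int)
    idx = np.flatnonzero(interest)
    blocks = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    min_len = int(w_event * fs * 0.7)
    peaks = [b[np.argmax(env[b])] for b in blocks if len(b) >= min_len]
    return np.asarray(sorted(peaks), dtype=int)


def _maxfilter_peaks(env: np.ndarray, fs: float, frac: float = 0.4) -> np.ndarray:
    """Peaks above a fraction of the local (2.5 s window) envelope maximum."""
    local_max = maximum_filter1d(env, size=max(1, int(2.5 * fs)))
    cand, _ = sps.find_peaks(env, distance=max(1, int(0.2 * fs)))
    return cand[env[cand] > frac * local_max[cand]]


# --- the six detector families -------------------------------------------

def pan_tompkins(x: np.ndarray, fs: float) -> np.ndarray:
    """Band-pass 5-15 Hz, derivative, squaring, 150 ms integration,
    dual-threshold peak acceptance."""
    if np.ptp(x) == 0:
        return np.asarray([], dtype=int)
    band = _bandpass(x, fs, 5.0, 15.0)
    env = _moving_average(np.gradient(band) ** 2, int(0.15 * fs))
    return _refine(band, _spki_npki_peaks(env, fs), fs)


def hamilton(x: np.ndarray, fs: float) -> np.ndarray:
    """Band-pass 8-16 Hz, rectification, 80 ms smoothing, running
    signal/noise level thresholding."""
    if np.ptp(x) == 0:
        return np.asarray([], dtype=int)
    band = _bandpass(x, fs, 8.0, 16.0)
    env = _moving_average(np.abs(band), int(0.08 * fs))
    return _refine(band, _spki_npki_peaks(env, fs, gain=0.45), fs)


def two_average(x: np.ndarray, fs: float) -> np.ndarray:
    """Two-moving-average (Elgendi) blocks on the squared 8-20 Hz band."""
    if np.ptp(x) == 0:
        return np.asarray([], dtype=int)
    band = _bandpass(x, fs, 8.0, 20.0)
    env = np.square(band)
    peaks = _two_average_blocks(env, fs, w_event=0.12, w_cycle=0.6, beta=0.08)
    return _refine(band, peaks, fs)


def swt(x: np.ndarray, fs: float) -> np.ndarray:
    """Stationary wavelet transform detector: level-3 db3 detail
    coefficients, squared, block-thresholded."""
    if np.ptp(x) == 0:
        return np.asarray([], dtype=int)
    level = 3
    pad = (-len(x)) % (1 << level)
    padded = np.pad(x, (0, pad), mode="edge")
    coeffs = pywt.swt(padded, "db3", level=level)
    detail = coeffs[0][1][: len(x)]  # deepest-scale detail
    env = detail**2
    peaks = _two_average_blocks(env, fs, w_event=0.12, w_cycle=0.6, beta=0.3)
    band = _bandpass(x, fs, 8.0, 20.0)
    return _refine(band, peaks, fs)


def christov(x: np.ndarray, fs: float) -> np.ndarray:
    """Comb moving-average power-line/low-frequency suppression, absolute
    derivative complex lead, adaptive-level thresholding."""
    if np.ptp(x) == 0:
        return np.asarray([], dtype=int)
    y = _moving_average(x, max(1, int(fs / 50.0)))       # 50 Hz comb
    y = _moving_average(y, max(1, int(fs / 35.0)))       # ~28.6 ms smoothing
    complex_lead = _moving_average(np.abs(np.gradient(y)), int(0.04 * fs))
    peaks = _maxfilter_peaks(complex_lead, fs, frac=0.5)
    return _refine(_bandpass(x, fs, 5.0, 25.0), peaks, fs)


def engzee(x: np.ndarray, fs: float) -> np.ndarray:
    """Four-sample differentiator with [1,4,6,4,1] low-pass, squared and
    adaptively thresholded (streamlined offline variant)."""
    if np.ptp(x) == 0:
        return np.asarray([], dtype=int)
    diff = np.zeros_like(x)
    diff[4:] = x[4:] - x[:-4]
    low = sps.lfilter(np.array([1.0, 4.0, 6.0, 4.0, 1.0]), [1.0], diff)
    env = low**2
    peaks = _maxfilter_peaks(env, fs, frac=0.3)
    return _refine(_bandpass(x, fs, 5.0, 25.0), peaks, fs)


_DETECTORS = {
    "pan-tompkins": pan_tompkins,
    "hamilton": hamilton,
    "two-average": two_average,
    "swt": swt,
    "christov": christov,
    "engzee": engzee,
}

DETECTOR_NAMES: tuple[str, ...] = tuple(_DETECTORS)


def get_detector(name: str):
    """Look up a detector by name; raises ``KeyError``-style ValueError."""
    try:
        return _DETECTORS[name]
    except KeyError:
        raise ValueError(
            f"unknown detector {name!r}; available: {', '.join(DETECTOR_NAMES)}"
        ) from None


def detect(name: str, lead: np.ndarray, fs: float) -> np.ndarray:
    """Run one named detector on a single lead."""
    return get_detector(name)(np.asarray(lead, dtype=float), fs)
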
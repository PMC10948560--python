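"""Carrier- and watermark-quality metrics.

Carrier quality compares the original and the watermarked (or recovered)
speech signal: power SNR in dB, frame-wise spectral distortion (mean
absolute difference of magnitude spectra in dB), the Itakura log-likelihood
ratio built on LPC models of each frame, and the Pearson correlation C_s.
Watermark fidelity compares the embedded and extracted payload matrices
(Pearson correlation C_w and maximum absolute error).

Argument order is always (original, degraded); SNR and LLR are not
symmetric in their inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_toeplitz

from .errors import ParameterError

_DB_FLOOR_AMP = 1e-10  # -200 dB magnitude floor


@dataclass
class QualityReport:
    """Carrier-quality summary for one original/degraded pair."""

    snr_db: float
    sd: float
    llr: float
    c_s: float
    frames_used: int
    config: dict = field(default_factory=dict)


@dataclass
class WatermarkFidelity:
    """Watermark-integrity summary: correlation and worst-case error."""

    c_w: float
    max_abs_error: float


def snr(original: np.ndarray, degraded: np.ndarray) -> float:
    """10 log10 of signal power over error power; +inf when identical."""
    s = np.asarray(original, dtype=float)
    y = np.asarray(degraded, dtype=float)
    if s.shape != y.shape:
        raise ParameterError("signals must have equal length")
    err = np.sum((s - y) ** 2)
    if err == 0.0:
        return float("inf")
    return float(10.0 * np.log10(np.sum(s**2) / err))


def _lpc(frame: np.ndarray, order: int) -> np.ndarray | None:
    """LPC coefficient vector [1, -a_1, ..., -a_p] via the autocorrelation
    normal equations; None when the frame is numerically singular."""
    r = np.correlate(frame, frame, mode="full")[frame.size - 1:
                                                frame.size + order]
    if r[0] <= 0:
        return None
    r = r.copy()
    r[0] *= 1.0 + 1e-9  # ridge against exactly singular Toeplitz systems
    try:
        a = solve_toeplitz((r[:order], r[:order]), r[1:order + 1])
    except np.linalg.LinAlgError:
        return None
    if not np.all(np.isfinite(a)):
        return None
    return np.concatenate([[1.0], -a])


def _autocorr_matrix(frame: np.ndarray, order: int) -> np.ndarray:
    r = np.correlate(frame, frame, mode="full")[frame.size - 1:
                                                frame.size + order]
    idx = np.abs(np.subtract.outer(np.arange(order + 1),
                                   np.arange(order + 1)))
    return r[idx]


def llr(original: np.ndarray, degraded: np.ndarray, lpc_order: int = 10,
        frame_len: int = 240, energy_floor: float = 1e-3) -> float:
    """Mean Itakura log-likelihood ratio over voiced-energy frames.

    Per frame: |log( l_s R_y l_s^T / l_y R_y l_y^T )| with l the LPC
    coefficient vectors and R_y the autocorrelation matrix of the degraded
    frame. Frames whose original energy falls below ``energy_floor`` times
    the maximum frame energy — or with singular LPC systems — are skipped.
    """
    s = np.asarray(original, dtype=float)
    y = np.asarray(degraded, dtype=float)
    if s.shape != y.shape:
        raise ParameterError("signals must have equal length")
    if frame_len <= lpc_order:
        raise ParameterError("frame_len must exceed lpc_order")

    n_frames = s.size // frame_len
    if n_frames == 0:
        raise ParameterError("signal shorter than one frame")
    energies = np.array([np.sum(s[i * frame_len:(i + 1) * frame_len] ** 2)
                         for i in range(n_frames)])
    floor = energy_floor * energies.max()

    vals = []
    for i in range(n_frames):
        if energies[i] < floor:
            continue
        fs = s[i * frame_len:(i + 1) * frame_len]
        fy = y[i * frame_len:(i + 1) * frame_len]
        l_s, l_y = _lpc(fs, lpc_order), _lpc(fy, lpc_order)
        if l_s is None or l_y is None:
            warnings.warn("skipping frame with singular autocorrelation")
            continue
        r_y = _autocorr_matrix(fy, lpc_order)
        num = float(l_s @ r_y @ l_s)
        den = float(l_y @ r_y @ l_y)
        if num <= 0 or den <= 0:
            warnings.warn("skipping frame with non-positive quadratic form")
            continue
        vals.append(abs(np.log(num / den)))
    if not vals:
        raise ParameterError("no usable frames for LLR")
    return float(np.mean(vals))


def spectral_distortion(original: np.ndarray, degraded: np.ndarray,
                        n_s: int = 256, fft_size: int | None = None) -> float:
    """Mean absolute difference of framewise magnitude spectra, in dB.

    Non-overlapping frames of ``n_s`` samples; magnitudes floored at
    -200 dB; zero-energy frame pairs contribute nothing.
    """
    s = np.asarray(original, dtype=float)
    y = np.asarray(degraded, dtype=float)
    if s.shape != y.shape:
        raise ParameterError("signals must have equal length")
    if n_s > s.size:
        raise ParameterError("frame length exceeds signal length")
    fft_size = fft_size or n_s

    n_frames = s.size // n_s
    diffs = []
    for i in range(n_frames):
        fs = s[i * n_s:(i + 1) * n_s]
        fy = y[i * n_s:(i + 1) * n_s]
        if not fs.any() and not fy.any():
            continue
        ms = 20.0 * np.log10(np.maximum(np.abs(np.fft.rfft(fs, fft_size)),
                                        _DB_FLOOR_AMP))
        my = 20.0 * np.log10(np.maximum(np.abs(np.fft.rfft(fy, fft_size)),
                                        _DB_FLOOR_AMP))
        diffs.append(np.abs(ms - my))
    if not diffs:
        return 0.0
    return float(np.mean(np.concatenate(diffs)))


def correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation; applied to signals (C_s) and payloads (C_w)."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ParameterError("inputs must have equal length")
    if x.std() == 0 or y.std() == 0:
        raise ParameterError("zero-variance input")
    return float(np.corrcoef(x, y)[0, 1])


def evaluate(original: np.ndarray, degraded: np.ndarray,
             lpc_order: int = 10, frame_len: int = 240,
             n_s: int = 256) -> QualityReport:
    """Full carrier-quality report for one signal pair."""
    n_frames = len(original) // frame_len
    return QualityReport(
        snr_db=snr(original, degraded),
        sd=spectral_distortion(original, degraded, n_s=n_s),
        llr=llr(original, degraded, lpc_order=lpc_order, frame_len=frame_len),
        c_s=correlation(original, degraded),
        frames_used=n_frames,
        config={"lpc_order": lpc_order, "frame_len": frame_len, "n_s": n_s},
    )


def watermark_fidelity(p: np.ndarray | list[np.ndarray],
                       p_star: np.ndarray | list[np.ndarray]) -> WatermarkFidelity:
    """C_w and max abs error between embedded and extracted payloads."""
    if isinstance(p, list):
        p = np.concatenate([np.ravel(b) for b in p])
        p_star = np.concatenate([np.ravel(b) for b in p_star])
    p = np.asarray(p, dtype=float).ravel()
    p_star = np.asarray(p_star, dtype=float).ravel()
    return WatermarkFidelity(
        c_w=correlation(p, p_star),
        max_abs_error=float(np.max(np.abs(p - p_star))),
    )
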
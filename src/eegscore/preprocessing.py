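"""Bandpass filtering and simplified artifact subspace reconstruction (ASR).

The cleaning stage follows the ASR contract -- attenuate signal
components whose amplitude exceeds ``kappa`` standard deviations of a
clean calibration portion -- in a deliberately stationary form:

* calibrate once on the eyes-open baseline (PCA of its covariance,
  per-component RMS statistics over non-overlapping 1-s windows);
* per analysis window, zero any component whose RMS exceeds
  ``mean + kappa * sd`` of the calibration RMS, then back-project.

Windows with no flagged component are copied through untouched
(bit-identical), which makes the operation idempotent and guarantees
the output energy never exceeds the input energy in flagged windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .recording import EEGRecording

logger = logging.getLogger(__name__)


def bandpass(rec: EEGRecording, low: float = 0.1, high: float = 100.0, order: int = 4) -> EEGRecording:
    """Zero-phase Butterworth bandpass, applied per channel.

    ``order`` is the design order of each band edge (the conventional
    "4th-order bandpass" usage).  Forward-backward application doubles
    the effective attenuation and removes phase distortion.
    """
    nyq = rec.fs / 2.0
    if not 0 < low < high:
        raise ValueError(f"need 0 < low < high, got low={low}, high={high}")
    if high >= nyq:
        raise ValueError(f"high corner {high} Hz must be below Nyquist {nyq} Hz")
    sos = signal.butter(order, [low, high], btype="bandpass", output="sos", fs=rec.fs)
    filtered = signal.sosfiltfilt(sos, rec.data, axis=1)
    return rec.copy_with(filtered)


@dataclass
class ASRModel:
    """Calibration statistics for stationary ASR cleaning.

    ``mixing`` holds the orthonormal PCA component basis (columns) of the
    calibration covariance; ``component_mean``/``component_sd`` are the
    mean and SD of per-window component RMS over calibration windows.
    """

    mixing: np.ndarray
    component_mean: np.ndarray
    component_sd: np.ndarray
    kappa: float = 15.0
    window_s: float = 1.0
    channel_labels: tuple[str, ...] = ()

    @property
    def thresholds(self) -> np.ndarray:
        return self.component_mean + self.kappa * self.component_sd


MIN_CALIBRATION_WINDOWS = 10


def asr_calibrate(
    rec: EEGRecording,
    segment_label: str = "EO",
    window_s: float = 1.0,
    kappa: float = 15.0,
) -> ASRModel:
    """Fit the ASR model on a clean calibration segment (eyes-open default)."""
    seg = rec.segment_data(segment_label)
    win = int(round(window_s * rec.fs))
    n_win = seg.shape[1] // win
    if n_win < MIN_CALIBRATION_WINDOWS:
        raise ValueError(
            f"calibration segment {segment_label!r} has {n_win} windows of {window_s} s; "
            f"at least {MIN_CALIBRATION_WINDOWS} required"
        )
    cov = np.cov(seg)
    evals, evecs = np.linalg.eigh(cov)  # ascending; columns orthonormal
    windows = seg[:, : n_win * win].reshape(seg.shape[0], n_win, win)
    comps = np.einsum("ji,jnw->inw", evecs, windows)  # V.T @ x per window
    rms = np.sqrt(np.mean(comps**2, axis=2))  # (component, window)
    return ASRModel(
        mixing=evecs,
        component_mean=rms.mean(axis=1),
        component_sd=rms.std(axis=1),
        kappa=kappa,
        window_s=window_s,
        channel_labels=rec.channel_labels,
    )


def asr_clean(rec: EEGRecording, model: ASRModel) -> EEGRecording:
    """Apply the fitted ASR model over non-overlapping analysis windows.

    Only windows containing at least one over-threshold component are
    rewritten; everything else passes through bit-identical.  A trailing
    partial window is never touched.
    """
    if model.channel_labels and tuple(model.channel_labels) != tuple(rec.channel_labels):
        raise ValueError(
            f"channel mismatch: model {model.channel_labels} vs recording {rec.channel_labels}"
        )
    win = int(round(model.window_s * rec.fs))
    n_win = rec.n_samples // win
    out = rec.copy_with(rec.data)
    if n_win == 0:
        return out

    V = model.mixing
    thresholds = model.thresholds
    X = rec.data[:, : n_win * win].reshape(rec.data.shape[0], n_win, win)
    comps = np.einsum("ji,jnw->inw", V, X)  # (component, window, sample)
    rms = np.sqrt(np.mean(comps**2, axis=2))
    flagged = rms > thresholds[:, None]  # (component, window)
    bad_windows = np.flatnonzero(flagged.any(axis=0))
    for w in bad_windows:
        y = comps[:, w, :].copy()
        y[flagged[:, w], :] = 0.0  # no cross-projection defined: zero in component space
        out.data[:, w * win : (w + 1) * win] = V @ y
    if bad_windows.size:
        logger.info("ASR rewrote %d of %d windows", bad_windows.size, n_win)
    return out


def clean_recording(
    rec: EEGRecording,
    low: float = 0.1,
    high: float = 100.0,
    order: int = 4,
    kappa: float = 15.0,
    calib_segment: str = "EO",
    window_s: float = 1.0,
) -> EEGRecording:
    """Standard preprocessing chain: bandpass, then calibrate + apply ASR.

    The upper corner is clamped to 0.99 x Nyquist (and logged) when the
    requested value would sit at or above Nyquist, so the default 100-Hz
    corner also works at low sampling rates.
    """
    nyq = rec.fs / 2.0
    if high >= nyq:
        clamped = 0.99 * nyq
        logger.warning("clamping bandpass corner %.3g Hz to %.3g Hz (< Nyquist)", high, clamped)
        high = clamped
    filtered = bandpass(rec, low=low, high=high, order=order)
    model = asr_calibrate(filtered, segment_label=calib_segment, window_s=window_s, kappa=kappa)
    return asr_clean(filtered, model)
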
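"""Signal conditioning: referencing, resampling, filtering, band power.

The conditioning chain reproduces a standard clinical-EEG connectivity
pipeline: drop bad channels → average reference → downsample to 250 Hz with
anti-aliasing → zero-phase high-pass 0.1 Hz, low-pass 45 Hz and 60 Hz notch.
All filters are applied forward–backward so that filtering cannot introduce
artificial phase leads, a prerequisite for unbiased directed-connectivity
estimation downstream.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
from scipy import signal

from .recording import Epochs, Recording

logger = logging.getLogger(__name__)

TARGET_FS_HZ = 250.0
HP_HZ = 0.1
LP_HZ = 45.0
NOTCH_HZ = 60.0
NOTCH_Q = 30.0
ALPHA_BAND = (8.0, 13.0)
FILTER_ORDER = 4


def _butter_sos(fs_hz: float, lo_hz: float | None, hi_hz: float | None,
                order: int = FILTER_ORDER) -> np.ndarray:
    nyq = fs_hz / 2.0
    if lo_hz is not None and hi_hz is not None:
        return signal.butter(order, [lo_hz / nyq, hi_hz / nyq], "bandpass",
                             output="sos")
    if lo_hz is not None:
        return signal.butter(order, lo_hz / nyq, "highpass", output="sos")
    if hi_hz is not None:
        return signal.butter(order, hi_hz / nyq, "lowpass", output="sos")
    raise ValueError("at least one cutoff required")


def _zero_phase(sos: np.ndarray, data: np.ndarray) -> np.ndarray:
    return signal.sosfiltfilt(sos, data, axis=-1)


def average_reference(data: np.ndarray) -> np.ndarray:
    """Subtract the per-sample mean over channels (column sums become 0)."""
    return data - data.mean(axis=0, keepdims=True)


def preprocess(rec: Recording, drop_labels: Iterable[str] = ()) -> Recording:
    """Condition a raw recording for connectivity/complexity analysis.

    Order of operations: remove channels in ``drop_labels``; average-reference
    the retained channels; downsample to 250 Hz with polyphase anti-alias
    filtering (skipped, with a logged notice, when the input rate is below
    500 Hz); then zero-phase high-pass 0.1 Hz, low-pass 45 Hz and notch 60 Hz.

    Raises
    ------
    KeyError
        If a drop label is not present in the recording.
    ValueError
        If dropping would leave fewer than 2 channels.
    """
    drop_labels = set(drop_labels)
    rec = rec.drop(drop_labels) if drop_labels else rec
    data = average_reference(rec.data)
    fs = rec.fs_hz

    if fs >= 2 * TARGET_FS_HZ:
        up, down = 1, int(round(fs / TARGET_FS_HZ))
        if abs(fs / down - TARGET_FS_HZ) > 1e-9:
            # non-integer ratio: use a rational approximation
            from fractions import Fraction

            frac = Fraction(TARGET_FS_HZ / fs).limit_denominator(1000)
            up, down = frac.numerator, frac.denominator
        data = signal.resample_poly(data, up, down, axis=-1)
        fs = fs * up / down
    elif fs > TARGET_FS_HZ:
        logger.info(
            "input rate %.1f Hz below 500 Hz; resampling to %.0f Hz skipped",
            fs, TARGET_FS_HZ,
        )
    # else: already at/below target rate; nothing to do

    data = _zero_phase(_butter_sos(fs, HP_HZ, None), data)
    data = _zero_phase(_butter_sos(fs, None, LP_HZ), data)
    if NOTCH_HZ < fs / 2.0:
        b, a = signal.iirnotch(NOTCH_HZ, NOTCH_Q, fs=fs)
        data = signal.filtfilt(b, a, data, axis=-1)
    return Recording(rec.labels, fs, data, rec.state)


def bandpass_alpha(ep: Epochs, band: tuple[float, float] = ALPHA_BAND) -> Epochs:
    """Zero-phase band-pass each window to the alpha band (8–13 Hz).

    The sampling rate must resolve the upper band edge (fs ≥ 2 × hi).
    """
    lo, hi = band
    if ep.fs_hz < 2 * hi:
        raise ValueError(
            f"sampling rate {ep.fs_hz} Hz too low for a {lo}-{hi} Hz band"
        )
    sos = _butter_sos(ep.fs_hz, lo, hi)
    return ep.map_windows(lambda w: _zero_phase(sos, w))


def band_power(ep: Epochs, lo_hz: float, hi_hz: float) -> np.ndarray:
    """Mean over windows of integrated spectral power in [lo_hz, hi_hz].

    Returns one nonnegative value per channel.  The per-window spectrum is a
    plain periodogram so that Parseval's identity relates the full-band
    integral to the window variance.
    """
    if not (0 < lo_hz < hi_hz < ep.fs_hz / 2.0):
        raise ValueError(
            f"invalid band ({lo_hz}, {hi_hz}) for fs={ep.fs_hz} Hz"
        )
    powers = []
    for w in ep.windows:
        freqs, psd = signal.periodogram(w, fs=ep.fs_hz, axis=-1)
        mask = (freqs >= lo_hz) & (freqs <= hi_hz)
        powers.append(np.trapezoid(psd[:, mask], freqs[mask], axis=-1))
    return np.mean(powers, axis=0)


def reject_artifact_windows(ep: Epochs, threshold_uv: float = 150.0) -> Epochs:
    """Drop windows containing any sample exceeding ``threshold_uv`` (abs).

    A reproducible stand-in for visual artifact inspection.  Rejections are
    logged; rejecting every window raises.
    """
    keep, rejected = [], []
    for k, w in enumerate(ep.windows):
        if np.abs(w).max() > threshold_uv:
            rejected.append(k)
        else:
            keep.append(w)
    if rejected:
        logger.warning(
            "rejected %d/%d windows exceeding %.0f uV: %s",
            len(rejected), ep.n_windows, threshold_uv, rejected,
        )
    if not keep:
        raise ValueError("artifact rejection removed every window")
    return Epochs(keep, ep.window_s, ep.fs_hz, ep.labels)
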
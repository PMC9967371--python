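"""Offline preprocessing chain for multichannel EEG.

Fixed stage order: DC removal -> 60 Hz notch -> 1-70 Hz band-pass ->
average re-reference -> artifact-screened epoch selection. All filters
are linear-phase FIR (windowed-sinc, Hamming) applied forward-backward,
so the net response is zero-phase — phase distortion would bias any
downstream phase-synchrony measure.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve, firwin

from .exceptions import EpochUnavailableError
from .recording import Recording

#: FIR transition width in Hz; tap count is derived from it.
TRANSITION_HZ = 2.0


def fir_taps(fs: float, transition_hz: float = TRANSITION_HZ) -> int:
    """Smallest odd tap count giving a Hamming-window transition width
    of at most ``transition_hz`` at sampling rate ``fs``."""
    n = int(np.ceil(3.3 * fs / transition_hz))
    return n if n % 2 == 1 else n + 1


def _apply_fir(samples: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Zero-phase forward-backward application along the time axis.

    The kernels here are symmetric (linear phase), so forward and
    time-reversed passes are identical and the double pass is two FFT
    convolutions with the same kernel: net response |H(f)|^2 with zero
    phase, as with filtfilt, at a fraction of the cost for long kernels.
    Edge samples (within one kernel length of each end) carry the usual
    zero-padding transient; downstream consumers trim at least one
    kernel length before estimating phase synchrony.
    """
    kernel = taps if samples.ndim == 1 else taps[np.newaxis, :]
    once = fftconvolve(samples, kernel, mode="same", axes=-1)
    return fftconvolve(once, kernel, mode="same", axes=-1)


def bandpass_taps(fs: float, low: float, high: float) -> np.ndarray:
    if not (0 < low < high < fs / 2):
        raise ValueError(
            f"invalid band ({low}, {high}) Hz for fs={fs}: need 0 < low < high < fs/2"
        )
    return firwin(fir_taps(fs), [low, high], fs=fs, pass_zero=False)


def bandpass_array(samples: np.ndarray, fs: float, low: float, high: float) -> np.ndarray:
    """Zero-phase band-pass of a (channels x time) or 1-D array."""
    return _apply_fir(samples, bandpass_taps(fs, low, high))


def remove_dc(recording: Recording) -> Recording:
    """Subtract the per-channel mean."""
    x = recording.samples
    return recording.with_samples(x - x.mean(axis=-1, keepdims=True))


def notch_filter(recording: Recording, freq: float = 60.0, width: float = 4.0) -> Recording:
    """Band-stop FIR of total width ``width`` Hz centred on ``freq``."""
    fs = recording.fs
    if freq >= fs / 2:
        raise ValueError(f"notch frequency {freq} Hz must be below fs/2 = {fs / 2}")
    lo, hi = freq - width / 2, freq + width / 2
    if lo <= 0 or hi >= fs / 2:
        raise ValueError(f"notch stop band ({lo}, {hi}) Hz out of range for fs={fs}")
    taps = firwin(fir_taps(fs), [lo, hi], fs=fs, pass_zero=True)
    return recording.with_samples(_apply_fir(recording.samples, taps))


def bandpass_filter(recording: Recording, low: float = 1.0, high: float = 70.0) -> Recording:
    """Zero-phase linear-phase FIR band-pass."""
    return recording.with_samples(
        bandpass_array(recording.samples, recording.fs, low, high)
    )


def rereference_average(recording: Recording) -> Recording:
    """Re-reference to the instantaneous across-channel average."""
    if recording.n_channels < 2:
        raise ValueError("average re-reference needs at least 2 channels")
    x = recording.samples
    return recording.with_samples(x - x.mean(axis=0, keepdims=True))


@dataclass(frozen=True)
class EpochSelection:
    """A continuous analysis window inside a recording.

    ``clean`` is True when no sample in the window exceeds the amplitude
    threshold; otherwise the window minimising the number of threshold
    crossings was chosen and ``n_crossings`` reports how many remain.
    """

    start: int
    length: int
    clean: bool
    n_crossings: int


def select_epoch(
    recording: Recording, length_s: float, threshold: float = 100.0
) -> EpochSelection:
    """Earliest artifact-free window of ``length_s`` seconds.

    A sample is an artifact crossing when its absolute amplitude exceeds
    ``threshold`` on any channel. If no fully clean window exists the
    window with the fewest crossings (earliest on ties) is returned with
    ``clean=False``.
    """
    length = int(round(length_s * recording.fs))
    if length < 1:
        raise ValueError("epoch length must be at least one sample")
    n = recording.n_samples
    if length > n:
        raise EpochUnavailableError(
            f"recording {recording.subject_id}/{recording.condition} has "
            f"{n / recording.fs:.1f} s but {length_s} s requested"
        )
    bad = (np.abs(recording.samples) > threshold).any(axis=0).astype(np.int64)
    # crossings per window via cumulative sum
    csum = np.concatenate([[0], np.cumsum(bad)])
    counts = csum[length:] - csum[: n - length + 1]
    start = int(np.argmax(counts == 0)) if (counts == 0).any() else int(np.argmin(counts))
    return EpochSelection(
        start=start,
        length=length,
        clean=bool(counts[start] == 0),
        n_crossings=int(counts[start]),
    )


def apply_epoch(recording: Recording, selection: EpochSelection) -> Recording:
    sl = slice(selection.start, selection.start + selection.length)
    return recording.with_samples(recording.samples[:, sl])


def preprocess_recording(
    recording: Recording,
    notch_hz: float = 60.0,
    band: tuple[float, float] = (1.0, 70.0),
    epoch_seconds: float = 180.0,
    amplitude_threshold: float = 100.0,
) -> tuple[Recording, EpochSelection]:
    """Run the full chain in its fixed order and return the epoched
    recording together with the epoch bookkeeping."""
    rec = remove_dc(recording)
    rec = notch_filter(rec, notch_hz)
    rec = bandpass_filter(rec, *band)
    rec = rereference_average(rec)
    selection = select_epoch(rec, epoch_seconds, amplitude_threshold)
    return apply_epoch(rec, selection), selection
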
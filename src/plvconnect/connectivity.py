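"""Phase-locking-value connectivity.

For a channel pair with instantaneous phases phi_a(t), phi_b(t),

    PLV = | (1/N) * sum_t exp(i * (phi_a(t) - phi_b(t))) |

i.e. the mean resultant length of the phase difference: 1 for perfect
phase locking, near 0 for independent phases. Phases are extracted as
the angle of the Hilbert analytic signal of the band-filtered channel,
with edge samples trimmed to exclude filter and Hilbert transients.
Global connectivity for one recording x band is the mean PLV over all
unordered channel pairs.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from .bands import DEFAULT_BANDS, BandSpec
from .preprocess import bandpass_array, fir_taps
from .recording import Recording

TABLE_COLUMNS = ["subject_id", "group", "condition", "band", "global_plv"]


def default_trim(fs: float) -> int:
    """Edge samples dropped per side before PLV: the larger of the FIR
    length and one second."""
    return max(fir_taps(fs), int(round(fs)))


def instantaneous_phase(channel: np.ndarray, trim: int = 0) -> np.ndarray:
    """Analytic-signal phase of a narrowband series, edge-trimmed.

    Returns values in (-pi, pi]; ``trim`` samples are removed from each
    end. The input must already be band-filtered and zero-mean.
    """
    x = np.asarray(channel, dtype=float)
    if x.ndim != 1:
        raise ValueError("instantaneous_phase expects a single channel")
    if trim < 0:
        raise ValueError("trim must be >= 0")
    if x.size < 2 * trim + 1:
        raise ValueError(
            f"series of {x.size} samples too short for trim={trim} per side"
        )
    phase = np.angle(hilbert(x))
    return phase[trim: x.size - trim] if trim else phase


def plv_pair(phase_a: np.ndarray, phase_b: np.ndarray) -> float:
    """PLV of two phase series (radians). Symmetric; in [0, 1]."""
    a = np.asarray(phase_a, dtype=float)
    b = np.asarray(phase_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"phase series shapes differ: {a.shape} vs {b.shape}")
    if a.size < 1:
        raise ValueError("phase series must be non-empty")
    return float(np.abs(np.mean(np.exp(1j * (a - b)))))


@dataclass
class PLVMatrix:
    """Symmetric channel x channel PLV matrix for one recording x band."""

    band: BandSpec
    subject_id: str
    group: str
    condition: str
    channel_labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("PLV matrix must be square")
        self.values = v


def plv_matrix(recording: Recording, band: BandSpec, trim: int | None = None) -> PLVMatrix:
    """Band-filter every channel, extract phases, and fill all unordered
    channel pairs.

    Uses the same zero-phase FIR design as the preprocessing band-pass,
    at the band's printed edges. ``trim`` defaults to
    :func:`default_trim` samples per side.
    """
    fs = recording.fs
    if band.high >= fs / 2:
        raise ValueError(
            f"band {band.name} upper edge {band.high} Hz not below fs/2 = {fs / 2}"
        )
    if trim is None:
        trim = default_trim(fs)
    if recording.n_samples < 2 * trim + 2:
        raise ValueError(
            f"recording too short ({recording.n_samples} samples) for trim={trim}"
        )
    filtered = bandpass_array(recording.samples, fs, band.low, band.high)
    phases = np.angle(hilbert(filtered, axis=-1))[:, trim: recording.n_samples - trim]
    z = np.exp(1j * phases)
    m = np.abs(z @ z.conj().T) / phases.shape[1]
    m = np.clip(m, 0.0, 1.0)
    np.fill_diagonal(m, 1.0)
    return PLVMatrix(
        band=band,
        subject_id=recording.subject_id,
        group=recording.group,
        condition=recording.condition,
        channel_labels=list(recording.channel_labels),
        values=m,
    )


def global_plv(matrix: PLVMatrix | np.ndarray) -> float:
    """Mean of the strict upper triangle (diagonal excluded)."""
    values = matrix.values if isinstance(matrix, PLVMatrix) else np.asarray(matrix)
    n = values.shape[0]
    if values.ndim != 2 or values.shape[1] != n:
        raise ValueError("global_plv expects a square matrix")
    if n < 2:
        raise ValueError("global_plv needs at least 2 channels")
    iu = np.triu_indices(n, k=1)
    return float(values[iu].mean())


def connectivity_table(
    cohort: list[Recording],
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS,
    trim: int | None = None,
) -> pd.DataFrame:
    """Long-format global connectivity: one row per recording x band.

    Columns: subject_id, group, condition, band, global_plv. A full
    cohort of S subjects x 2 conditions yields S * 2 * len(bands) rows.
    """
    seen: set[tuple[str, str]] = set()
    rows = []
    for rec in cohort:
        key = (rec.subject_id, rec.condition)
        if key in seen:
            raise ValueError(f"duplicate recording for subject/condition {key}")
        seen.add(key)
        for band in bands:
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    "group": rec.group,
                    "condition": rec.condition,
                    "band": band.name,
                    "global_plv": global_plv(plv_matrix(rec, band, trim=trim)),
                }
            )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def write_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = set(TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"connectivity table missing columns: {sorted(missing)}")
    return table
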
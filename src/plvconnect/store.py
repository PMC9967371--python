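"""Recording persistence: a flat-binary store plus optional readers for
standard EEG interchange formats.

The internal store keeps one ``<subject>_<condition>.npy`` array
(channels x time, float64) per recording with a JSON sidecar carrying
the sampling rate, labels, group and condition.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .recording import Recording


def _stem(recording: Recording) -> str:
    return f"{recording.subject_id}_{recording.condition}"


def write_recording(recording: Recording, directory: str | Path) -> Path:
    """Write one recording; returns the path of the .npy payload."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = _stem(recording)
    npy = directory / f"{stem}.npy"
    np.save(npy, recording.samples)
    sidecar = {
        "fs": recording.fs,
        "channel_labels": recording.channel_labels,
        "subject_id": recording.subject_id,
        "group": recording.group,
        "condition": recording.condition,
        "meta": {k: v for k, v in recording.meta.items()},
    }
    (directory / f"{stem}.json").write_text(json.dumps(sidecar, indent=1))
    return npy


def read_recording(npy_path: str | Path) -> Recording:
    npy_path = Path(npy_path)
    sidecar = json.loads(npy_path.with_suffix(".json").read_text())
    return Recording(
        samples=np.load(npy_path),
        fs=sidecar["fs"],
        channel_labels=sidecar["channel_labels"],
        subject_id=sidecar["subject_id"],
        group=sidecar["group"],
        condition=sidecar["condition"],
        meta=sidecar.get("meta", {}),
    )


def write_cohort(cohort: list[Recording], directory: str | Path) -> list[Path]:
    return [write_recording(rec, directory) for rec in cohort]


def read_cohort(directory: str | Path) -> list[Recording]:
    """Read every recording in a store directory, sorted by filename."""
    directory = Path(directory)
    paths = sorted(directory.glob("*.npy"))
    if not paths:
        raise FileNotFoundError(f"no recordings found in {directory}")
    return [read_recording(p) for p in paths]


# ---------------------------------------------------------------------------
# optional interchange-format readers (require mne)


def _require_mne():
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError(
            "reading EDF/BrainVision files requires the optional 'mne' "
            "dependency (pip install plvconnect[io])"
        ) from exc
    return mne


def _from_raw(raw, subject_id: str, group: str, condition: str) -> Recording:
    data = raw.get_data()
    return Recording(
        samples=data * 1e6,  # volts -> microvolt-like units
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        subject_id=subject_id,
        group=group,
        condition=condition,
    )


def read_edf(path: str | Path, subject_id: str, group: str, condition: str) -> Recording:
    """Read an EDF file into a Recording (optional convenience)."""
    mne = _require_mne()
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return _from_raw(raw, subject_id, group, condition)


def read_brainvision(
    vhdr_path: str | Path, subject_id: str, group: str, condition: str
) -> Recording:
    """Read a BrainVision (.vhdr/.eeg/.vmrk) set into a Recording."""
    mne = _require_mne()
    raw = mne.io.read_raw_brainvision(str(vhdr_path), preload=True, verbose="error")
    return _from_raw(raw, subject_id, group, condition)
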
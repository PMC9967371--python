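"""The in-memory container for one multichannel EEG recording."""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

GROUPS = ("PD", "HC")
CONDITIONS = ("rest", "motor")


@dataclass
class Recording:
    """One subject x condition multichannel signal.

    Attributes
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Signal amplitudes in arbitrary microvolt-like units.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        Unique labels, one per row of ``samples``.
    subject_id : str
    group : {"PD", "HC"}
    condition : {"rest", "motor"}
    """

    samples: np.ndarray
    fs: float
    channel_labels: list[str]
    subject_id: str
    group: str
    condition: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (channels x time) array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        labels = list(self.channel_labels)
        if len(labels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(labels)} channel labels for {self.samples.shape[0]} channels"
            )
        if len(set(labels)) != len(labels):
            raise ValueError("channel labels must be unique")
        self.channel_labels = labels
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def with_samples(self, samples: np.ndarray) -> "Recording":
        """Copy of this recording with ``samples`` replaced (metadata kept)."""
        return replace(self, samples=np.asarray(samples, dtype=float))
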
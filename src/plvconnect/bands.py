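"""Frequency-band definitions for the connectivity analysis.

The default scheme follows the IPEG-derived bands used throughout the
pipeline: delta 2-4, theta 5-7, alpha 8-12, beta 13-29, gamma 30-60 Hz.
"""
from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandSpec:
    """A named frequency interval in Hz.

    Parameters
    ----------
    name : str
        Band label (e.g. ``"delta"``).
    low, high : float
        Lower and upper band edges in Hz; ``0 < low < high`` required.
    """

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise ValueError(
                f"invalid band {self.name!r}: need 0 < low < high, "
                f"got ({self.low}, {self.high})"
            )

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.low + self.high)


DEFAULT_BANDS: tuple[BandSpec, ...] = (
    BandSpec("delta", 2.0, 4.0),
    BandSpec("theta", 5.0, 7.0),
    BandSpec("alpha", 8.0, 12.0),
    BandSpec("beta", 13.0, 29.0),
    BandSpec("gamma", 30.0, 60.0),
)

BAND_ORDER: tuple[str, ...] = tuple(b.name for b in DEFAULT_BANDS)


def band_by_name(name: str, bands: tuple[BandSpec, ...] = DEFAULT_BANDS) -> BandSpec:
    for b in bands:
        if b.name == name:
            return b
    raise KeyError(f"unknown band {name!r}; known: {[b.name for b in bands]}")
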
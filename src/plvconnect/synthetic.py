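"""Synthetic multichannel EEG with analytically known phase coupling.

The generator builds, per frequency band, a common carrier phase that
wanders as a Gaussian random walk around the band's carrier frequency.
Channel 1 carries that base phase; every other channel adds independent
von Mises phase jitter whose concentration ``kappa`` is configured per
(group, condition, band) cell. The von Mises construction is chosen
because its population phase-locking value is closed form: the mean
resultant length ``I1(kappa)/I0(kappa)`` (ratio of modified Bessel
functions). That gives every downstream PLV estimator an exact oracle.

Two jitter time courses are used:

* :func:`generate_coupled_phase_pair` draws the jitter i.i.d. von Mises
  per sample — the pure phase-level oracle, never filtered.
* :func:`synthesize_recording` uses band-limited Gaussian phase noise
  (white noise smoothed with a Gaussian kernel, default 0.8 s) scaled to
  variance ``sigma^2 = -2 ln(I1(kappa)/I0(kappa))``, so its population
  PLV ``E[exp(i delta)] = exp(-sigma^2/2)`` equals the same Bessel ratio
  exactly. Unlike per-sample i.i.d. jitter — which is wideband, gets
  removed by the band-pass filter, and drives filtered PLV to 1
  regardless of kappa — this smooth modulation passes the filter, so the
  *signal-level* PLV (filter + Hilbert phase) converges to the same
  target as the phase-level oracle.

Coupling is channel-1-referenced (star topology): the PLV between
channel 1 and any other channel approaches ``I1(k)/I0(k)``; between two
jittered channels it approaches the square of that ratio (their offsets
are independent, so the resultants multiply). Each channel additionally has a
fixed, evenly spaced phase offset per band. Offsets leave every
pairwise PLV unchanged but cancel the coherent part of the
across-channel mean, so average re-referencing (which subtracts that
mean) does not strip the shared oscillation and invert the designed
group contrast.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import i0, i1

from .bands import DEFAULT_BANDS, BandSpec
from .exceptions import ConfigurationError
from .recording import CONDITIONS, GROUPS, Recording

#: kappa at or above this is treated as the no-jitter limit (delta == 0).
KAPPA_INF = 1e6

#: Default carrier frequency per band: the band midpoint, so the
#: oscillation stays inside its analysis band after filtering.
DEFAULT_CARRIERS: dict[str, float] = {
    "delta": 3.0,
    "theta": 6.0,
    "alpha": 10.0,
    "beta": 21.0,
    "gamma": 45.0,
}


def bessel_ratio_plv(kappa: float) -> float:
    """Population PLV of von Mises(0, kappa) phase differences: I1/I0."""
    if kappa < 0:
        raise ValueError(f"kappa must be >= 0, got {kappa}")
    if kappa >= KAPPA_INF:
        return 1.0
    return float(i1(kappa) / i0(kappa))


def default_kappa_map(
    baseline: float = 1.0,
    hc_motor_delta: float = 2.5,
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS,
) -> dict[tuple[str, str, str], float]:
    """Coupling concentrations for every (group, condition, band) cell.

    All cells share ``baseline`` except delta-band coupling for healthy
    controls during the motor task, which is elevated — the qualitative
    structure the study design probes (HC modulate delta synchrony
    during movement, PD do not). The effect size is a synthetic choice,
    not an estimate from any dataset.
    """
    kappa = {
        (g, c, b.name): baseline for g in GROUPS for c in CONDITIONS for b in bands
    }
    kappa[("HC", "motor", "delta")] = hc_motor_delta
    return kappa


@dataclass
class SimConfig:
    """Cohort-level simulation parameters.

    Defaults emulate the study conditions: 26 PD and 13 HC subjects,
    64 channels at 500 Hz, 180 s per recording, with the delta-band
    coupling elevated for HC during the motor task. For fast tests use
    :meth:`test_scale`.
    """

    n_pd: int = 26
    n_hc: int = 13
    n_channels: int = 64
    fs: float = 500.0
    duration: float = 180.0
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS
    carrier_freqs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CARRIERS)
    )
    kappa: dict[tuple[str, str, str], float] = field(default_factory=default_kappa_map)
    phase_drift_sd: float = 0.05
    snr: float = 10.0
    subject_kappa_sd: float = 0.15
    jitter_smooth_s: float = 0.8
    master_seed: int = 0

    @classmethod
    def test_scale(cls, **overrides) -> "SimConfig":
        """Small configuration (8 channels, 60 s, 250 Hz) for fast runs."""
        defaults = dict(n_channels=8, fs=250.0, duration=60.0)
        defaults.update(overrides)
        return cls(**defaults)

    def validate(self) -> None:
        if self.n_pd < 1 or self.n_hc < 1:
            raise ConfigurationError("n_pd and n_hc must each be >= 1")
        if self.n_channels < 2:
            raise ConfigurationError("need at least 2 channels")
        highest = max(b.high for b in self.bands)
        if self.fs <= 2 * highest:
            raise ConfigurationError(
                f"fs={self.fs} must exceed twice the highest band edge ({highest} Hz)"
            )
        if self.duration <= 0:
            raise ConfigurationError("duration must be positive")
        if not self.snr > 0:
            raise ConfigurationError("snr must be > 0 (use math.inf for noiseless)")
        if self.phase_drift_sd < 0:
            raise ConfigurationError("phase_drift_sd must be >= 0")
        if self.jitter_smooth_s <= 0:
            raise ConfigurationError("jitter_smooth_s must be positive")
        for key, k in self.kappa.items():
            if k < 0:
                raise ConfigurationError(f"kappa must be >= 0; got {k} for {key}")
        for b in self.bands:
            if b.name not in self.carrier_freqs:
                raise ConfigurationError(f"no carrier frequency for band {b.name!r}")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))


def _wrap(phase: np.ndarray) -> np.ndarray:
    """Wrap phases to (-pi, pi]."""
    return np.pi - np.mod(np.pi - phase, 2 * np.pi)


def generate_coupled_phase_pair(
    n_samples: int,
    kappa: float,
    phase_drift_sd: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Pair of phase series with population PLV exactly I1(kappa)/I0(kappa).

    Channel 1 is a wrapped Gaussian random walk with per-sample step
    standard deviation ``phase_drift_sd``; channel 2 adds i.i.d.
    von Mises(0, kappa) deflections. ``kappa >= 1e6`` is treated as the
    perfect-coupling limit (zero deflection); ``kappa == 0`` gives
    uniform jitter (population PLV 0).
    """
    if n_samples < 1:
        raise ValueError(f"n_samples must be >= 1, got {n_samples}")
    if kappa < 0:
        raise ValueError(f"kappa must be >= 0, got {kappa}")
    rng = np.random.default_rng(seed)
    base = np.cumsum(rng.normal(0.0, phase_drift_sd, n_samples))
    base += rng.uniform(-np.pi, np.pi)
    if kappa >= KAPPA_INF:
        delta = np.zeros(n_samples)
    elif kappa == 0.0:
        delta = rng.uniform(-np.pi, np.pi, n_samples)
    else:
        delta = rng.vonmises(0.0, kappa, n_samples)
    return _wrap(base), _wrap(base + delta)


#: floor on the resultant used when converting kappa to jitter variance,
#: so kappa = 0 maps to a finite sigma with population PLV ~ 1e-4.
_MIN_RESULTANT = 1e-4


def _smooth_jitter(
    rng: np.random.Generator, kappa: float, n_samples: int, smooth: float
) -> np.ndarray:
    """Band-limited Gaussian phase noise with population PLV I1(k)/I0(k).

    White noise is smoothed with a Gaussian kernel of ``smooth`` samples
    and rescaled to standard deviation sigma with
    ``exp(-sigma^2/2) = I1(kappa)/I0(kappa)``, so the mean resultant of
    the jitter matches the von Mises target while staying slow enough to
    survive band-pass filtering.
    """
    if kappa >= KAPPA_INF:
        return np.zeros(n_samples)
    sigma = math.sqrt(-2.0 * math.log(max(bessel_ratio_plv(kappa), _MIN_RESULTANT)))
    noise = rng.normal(0.0, 1.0, n_samples)
    radius = int(4.0 * smooth)
    if radius >= 1:
        # circular Gaussian smoothing via FFT (kernel wrapped to length n)
        idx = np.arange(-radius, radius + 1)
        kernel = np.exp(-0.5 * np.square(idx / smooth))
        kernel /= kernel.sum()
        wrapped = np.zeros(n_samples)
        np.add.at(wrapped, idx % n_samples, kernel)
        noise = np.fft.irfft(
            np.fft.rfft(noise) * np.fft.rfft(wrapped), n_samples
        )
    sd = noise.std()
    if sd == 0.0:
        return np.zeros(n_samples)
    return noise * (sigma / sd)


def synthesize_recording(
    config: SimConfig,
    group: str,
    condition: str,
    subject_seed: int,
    subject_id: str | None = None,
    kappa_scale: float = 1.0,
) -> Recording:
    """One subject x condition recording under ``config``.

    The signal is the sum over bands of unit-amplitude cosines of the
    per-channel phases plus white Gaussian noise scaled to ``config.snr``
    (oscillation power over noise power). Deterministic given
    ``subject_seed``. ``kappa_scale`` multiplies every kappa for this
    subject (used by :func:`generate_cohort` for between-subject
    variability).
    """
    config.validate()
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}, got {group!r}")
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}, got {condition!r}")
    n = config.n_samples
    n_ch = config.n_channels
    fs = config.fs
    rng = np.random.default_rng(subject_seed)
    smooth = config.jitter_smooth_s * fs
    t = np.arange(n) / fs

    samples = np.zeros((n_ch, n))
    for band in config.bands:
        key = (group, condition, band.name)
        if key not in config.kappa:
            raise ConfigurationError(f"kappa map is missing the cell {key}")
        kappa = config.kappa[key] * kappa_scale
        f_c = config.carrier_freqs[band.name]
        base = (
            2 * np.pi * f_c * t
            + np.cumsum(rng.normal(0.0, config.phase_drift_sd, n))
            + rng.uniform(-np.pi, np.pi)
        )
        # fixed, evenly spaced per-channel phase offsets: PLV-invariant,
        # but they cancel the coherent part of the across-channel mean so
        # average re-referencing does not strip the common oscillation
        offsets = 2 * np.pi * np.arange(n_ch) / n_ch + rng.uniform(0, 2 * np.pi)
        samples[0] += np.cos(base + offsets[0])
        for ch in range(1, n_ch):
            delta = _smooth_jitter(rng, kappa, n, smooth)
            samples[ch] += np.cos(base + offsets[ch] + delta)

    if math.isfinite(config.snr):
        # each band contributes power 1/2 per channel
        signal_power = 0.5 * len(config.bands)
        noise_sd = math.sqrt(signal_power / config.snr)
        samples += rng.normal(0.0, noise_sd, samples.shape)

    if subject_id is None:
        subject_id = f"{group}-{subject_seed}"
    labels = [f"ch{i + 1:02d}" for i in range(n_ch)]
    return Recording(
        samples=samples,
        fs=fs,
        channel_labels=labels,
        subject_id=subject_id,
        group=group,
        condition=condition,
        meta={"subject_seed": int(subject_seed), "kappa_scale": float(kappa_scale)},
    )


def _subject_seed(master_seed: int, subject_index: int, condition_index: int) -> int:
    """Deterministic per-recording seed below 2**31."""
    ss = np.random.SeedSequence((int(master_seed), subject_index, condition_index))
    return int(ss.generate_state(1)[0] % (2**31))


def generate_cohort(config: SimConfig) -> list[Recording]:
    """Full cohort: (n_pd + n_hc) subjects x 2 conditions recordings.

    Per-recording seeds are hashed from ``config.master_seed`` with the
    subject and condition indices, so cohorts are reproducible and
    subjects independent. Each subject carries a lognormal kappa
    multiplier (sd ``config.subject_kappa_sd`` in log space) shared
    across both conditions, giving stable between-subject variability.
    """
    config.validate()
    recordings: list[Recording] = []
    groups = ["PD"] * config.n_pd + ["HC"] * config.n_hc
    counters = {"PD": 0, "HC": 0}
    for idx, group in enumerate(groups):
        counters[group] += 1
        subject_id = f"{group}{counters[group]:02d}"
        trait_rng = np.random.default_rng(
            np.random.SeedSequence((int(config.master_seed), idx, 999))
        )
        kappa_scale = (
            float(np.exp(trait_rng.normal(0.0, config.subject_kappa_sd)))
            if config.subject_kappa_sd > 0
            else 1.0
        )
        for cond_idx, condition in enumerate(CONDITIONS):
            seed = _subject_seed(config.master_seed, idx, cond_idx)
            recordings.append(
                synthesize_recording(
                    config,
                    group,
                    condition,
                    subject_seed=seed,
                    subject_id=subject_id,
                    kappa_scale=kappa_scale,
                )
            )
    return recordings
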
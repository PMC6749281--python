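"""Seeded generator of two-class motor-imagery-like EEG sessions.

The generator emulates the structure the classification pipeline
assumes: a small set of source channels carries a band-limited mu
rhythm whose power drops in class-1 trials (event-related
desynchronisation, ERD), every source carries 1/f background activity,
and the sources are mixed across channels by a diagonally dominant
matrix standing in for volume conduction.  White sensor noise is added
after mixing.  The ground-truth ERD channels and mixing are returned
alongside the epochs so recovery can be scored.

The ERD is modelled as a multiplicative variance reduction of filtered
white noise, not as deterministic sinusoids, so band power fluctuates
from trial to trial the way real rhythms do.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import BandSpec, EpochSet, bandpass_array

#: samples generated on each side of the epoch and discarded, so filter
#: edge transients never reach the returned data
_PAD = 100


def default_mixing(n_channels: int, falloff: float = 2.0) -> np.ndarray:
    """Row-normalised ``exp(-|a - b| / falloff)`` volume-conduction stand-in."""
    idx = np.arange(n_channels)
    m = np.exp(-np.abs(idx[:, None] - idx[None, :]) / falloff)
    return m / m.sum(axis=1, keepdims=True)


@dataclass(frozen=True)
class SynthConfig:
    """Session parameters; the defaults are the "easy preset".

    ``erd_depth`` is the fractional band-power reduction of the mu
    rhythm in class-1 trials on the ERD source channels.  ``mixing``
    may be an explicit (K, K) matrix; ``None`` selects the default
    exponential-falloff mixing.
    """

    n_channels: int = 18
    trials_per_class: int = 100
    n_samples: int = 200
    fs: float = 100.0
    erd_channels: tuple[int, ...] = (7, 8, 9)
    erd_band: tuple[float, float] = (8.0, 12.0)
    erd_depth: float = 0.6
    mixing: np.ndarray | None = None
    osc_std: float = 2.0
    background_std: float = 1.0
    sensor_noise_std: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.erd_depth < 1.0:
            raise ValueError(f"erd_depth must lie in (0, 1), got {self.erd_depth}")
        if self.trials_per_class < 1 or self.n_channels < 2:
            raise ValueError("need at least 1 trial per class and 2 channels")
        for c in self.erd_channels:
            if not 0 <= c < self.n_channels:
                raise ValueError(f"ERD channel {c} outside 0..{self.n_channels - 1}")

    def mixing_matrix(self) -> np.ndarray:
        if self.mixing is None:
            return default_mixing(self.n_channels)
        m = np.asarray(self.mixing, dtype=float)
        if m.shape != (self.n_channels, self.n_channels):
            raise ValueError(
                f"mixing must be {self.n_channels} x {self.n_channels}, got {m.shape}"
            )
        if not np.all(np.isfinite(m)) or np.linalg.cond(m) > 1e12:
            raise ValueError("mixing matrix is singular or non-finite")
        return m


@dataclass(frozen=True)
class SynthGroundTruth:
    """What the generator actually injected, for recovery scoring.

    ``band_powers`` holds the realised per-trial variance of the mu
    oscillation on each ERD source (after the class-dependent
    attenuation); ``mixed_erd_power`` is the expected oscillation power
    reaching each observed channel through the mixing, whose maxima are
    the channels a correct selection should find.
    """

    erd_channels: tuple[int, ...]
    mixing: np.ndarray
    band_powers: np.ndarray
    mixed_erd_power: np.ndarray
    labels: np.ndarray = field(repr=False)

    def dominant_channels(self, frac: float = 0.5) -> tuple[int, ...]:
        """Observed channels receiving at least ``frac`` of the peak ERD power."""
        peak = self.mixed_erd_power.max()
        return tuple(int(k) for k in np.flatnonzero(self.mixed_erd_power >= frac * peak))


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...], fs: float) -> np.ndarray:
    """1/f-power background noise along the last axis, unit global std."""
    white = rng.standard_normal(shape)
    freqs = np.fft.rfftfreq(shape[-1], d=1.0 / fs)
    amp = 1.0 / np.sqrt(np.maximum(freqs, 1.0))  # flat below 1 Hz
    amp[0] = 0.0
    x = np.fft.irfft(np.fft.rfft(white, axis=-1) * amp, n=shape[-1], axis=-1)
    return x / x.std()


def generate_session(config: SynthConfig) -> tuple[EpochSet, SynthGroundTruth]:
    """Generate one fully seeded two-class session with ground truth."""
    rng = np.random.default_rng(config.seed)
    tpc, K, N, fs = config.trials_per_class, config.n_channels, config.n_samples, config.fs
    n_trials = 2 * tpc
    L = N + 2 * _PAD
    mix = config.mixing_matrix()

    labels = rng.permutation(np.repeat([1, 2], tpc))

    sources = config.background_std * _pink_noise(rng, (n_trials, K, L), fs)

    erd = np.asarray(config.erd_channels)
    band = BandSpec(*config.erd_band, order=4)
    osc = bandpass_array(rng.standard_normal((n_trials, erd.size, L)), band, fs)
    osc *= config.osc_std / osc.std()
    osc[labels == 1] *= np.sqrt(1.0 - config.erd_depth)
    sources[:, erd, :] += osc

    observed = np.einsum("ab,ibn->ian", mix, sources)
    observed += config.sensor_noise_std * rng.standard_normal(observed.shape)
    data = observed[:, :, _PAD : _PAD + N]

    band_powers = osc[:, :, _PAD : _PAD + N].var(axis=-1)
    mixed_erd_power = (config.osc_std**2) * (mix[:, erd] ** 2).sum(axis=1)

    epochs = EpochSet(data=data, labels=labels, fs=fs)
    truth = SynthGroundTruth(
        erd_channels=tuple(int(c) for c in config.erd_channels),
        mixing=mix,
        band_powers=band_powers,
        mixed_erd_power=mixed_erd_power,
        labels=labels,
    )
    return epochs, truth


def easy_preset(seed: int = 0, **overrides) -> SynthConfig:
    """The default high-SNR session configuration, with a chosen seed."""
    return SynthConfig(seed=seed, **overrides)
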
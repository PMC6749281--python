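"""Epoch handling, broadband filtering and the filter bank.

The preprocessing chain is fixed: epochs are cut from the continuous
recording first, then filtered.  All filtering is zero-phase
(forward-backward Butterworth) so the short analysis window is not
shifted by group delay.  Sample indexing is 0-based with half-open
windows, i.e. a window of ``[0.5, 2.5]`` s at 100 Hz yields exactly 200
samples per trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
from scipy import signal


class PreprocessError(ValueError):
    """Raised for invalid epoching or filtering requests."""


@dataclass(frozen=True)
class BandSpec:
    """Butterworth band-pass specification.

    Parameters
    ----------
    low_hz, high_hz : float
        Passband edges in Hz, ``0 < low_hz < high_hz``.
    order : int
        Overall band-pass filter order (even, >= 2).  The zero-phase
        forward-backward application squares the magnitude response.
    """

    low_hz: float
    high_hz: float
    order: int = 4

    def __post_init__(self) -> None:
        if not (0.0 < self.low_hz < self.high_hz):
            raise PreprocessError(
                f"invalid band edges [{self.low_hz}, {self.high_hz}] Hz: "
                "need 0 < low < high"
            )
        if self.order < 2 or self.order % 2:
            raise PreprocessError(f"filter order must be even and >= 2, got {self.order}")

    def design(self, fs: float) -> np.ndarray:
        """Second-order sections for this band at sampling rate ``fs``."""
        if self.high_hz >= fs / 2.0:
            raise PreprocessError(
                f"band edge {self.high_hz} Hz at or above Nyquist ({fs / 2.0} Hz)"
            )
        # scipy's butter doubles the order for band-pass designs; order//2
        # keeps the overall order equal to ``order``.
        return signal.butter(
            self.order // 2,
            [self.low_hz, self.high_hz],
            btype="bandpass",
            fs=fs,
            output="sos",
        )


@dataclass(frozen=True)
class FilterBank:
    """Ordered collection of band-pass filters; band ``m`` is ``bands[m]``."""

    bands: tuple[BandSpec, ...]

    def __post_init__(self) -> None:
        if len(self.bands) < 2:
            raise PreprocessError("a filter bank needs at least two bands")
        object.__setattr__(self, "bands", tuple(self.bands))

    def __len__(self) -> int:
        return len(self.bands)

    def __iter__(self) -> Iterator[BandSpec]:
        return iter(self.bands)

    def __getitem__(self, m: int) -> BandSpec:
        return self.bands[m]


def default_filterbank(order: int = 4) -> FilterBank:
    """The eight 4-Hz bands covering 4-36 Hz used for FBCSP feature extraction."""
    edges = range(4, 36, 4)
    return FilterBank(tuple(BandSpec(lo, lo + 4, order=order) for lo in edges))


def _default_names(n_channels: int) -> tuple[str, ...]:
    return tuple(f"ch{k + 1:02d}" for k in range(n_channels))


@dataclass
class EpochSet:
    """Pre-cut EEG trials: ``data`` is trials x channels x samples (microvolts).

    ``labels`` holds the motor-imagery class of each trial, coded 1/2; it
    may be ``None`` for to-be-classified epochs.  When labels are present
    both classes must occur.
    """

    data: np.ndarray
    labels: np.ndarray | None
    fs: float
    channel_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 3:
            raise PreprocessError(f"epoch data must be 3-D, got shape {data.shape}")
        if data.shape[0] < 1:
            raise PreprocessError("epoch set holds no trials")
        if not np.all(np.isfinite(data)):
            raise PreprocessError("epoch data contains non-finite samples")
        if not self.fs > 0:
            raise PreprocessError(f"sampling rate must be positive, got {self.fs}")
        self.data = data
        if self.labels is not None:
            labels = np.asarray(self.labels, dtype=int).ravel()
            if labels.shape[0] != data.shape[0]:
                raise PreprocessError(
                    f"{labels.shape[0]} labels for {data.shape[0]} trials"
                )
            present = set(np.unique(labels).tolist())
            if present != {1, 2}:
                raise PreprocessError(
                    f"labels must use codes 1 and 2 with both classes present, got {sorted(present)}"
                )
            self.labels = labels
        if not self.channel_names:
            self.channel_names = _default_names(data.shape[1])
        else:
            self.channel_names = tuple(self.channel_names)
            if len(self.channel_names) != data.shape[1]:
                raise PreprocessError(
                    f"{len(self.channel_names)} channel names for {data.shape[1]} channels"
                )

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def require_labels(self) -> np.ndarray:
        if self.labels is None:
            raise PreprocessError("this operation needs labelled epochs")
        return self.labels

    def class_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Trial index arrays for class 1 and class 2."""
        labels = self.require_labels()
        return np.flatnonzero(labels == 1), np.flatnonzero(labels == 2)


def extract_epochs(
    continuous: np.ndarray,
    cue_times: Sequence[float],
    window: Sequence[float],
    fs: float,
    labels: Sequence[int] | None = None,
    channel_names: Sequence[str] | None = None,
) -> EpochSet:
    """Cut fixed-length trials from a continuous recording.

    Each trial covers the half-open sample range
    ``[round((cue + t0) * fs), round((cue + t0) * fs) + round((t1 - t0) * fs))``
    so every trial has an identical sample count regardless of cue jitter.

    Parameters
    ----------
    continuous : array, channels x time
    cue_times : sequence of cue onsets in seconds
    window : ``(t0, t1)`` in seconds relative to each cue, ``t0 < t1``
    fs : sampling rate in Hz
    """
    cont = np.asarray(continuous, dtype=float)
    if cont.ndim == 1:
        cont = cont[np.newaxis, :]
    if cont.ndim != 2:
        raise PreprocessError(f"continuous data must be 2-D, got shape {cont.shape}")
    t0, t1 = float(window[0]), float(window[1])
    if not t0 < t1:
        raise PreprocessError(f"window [{t0}, {t1}] s is not increasing")
    n = int(round((t1 - t0) * fs))
    if n < 1:
        raise PreprocessError(f"window [{t0}, {t1}] s shorter than one sample")
    n_time = cont.shape[1]
    trials = []
    for cue in cue_times:
        start = int(round((cue + t0) * fs))
        if start < 0 or start + n > n_time:
            raise PreprocessError(
                f"cue at {cue} s: window [{cue + t0}, {cue + t1}] s falls outside "
                f"the recording ({n_time / fs} s)"
            )
        trials.append(cont[:, start : start + n])
    if not trials:
        raise PreprocessError("no cue times given")
    return EpochSet(
        data=np.stack(trials),
        labels=None if labels is None else np.asarray(labels),
        fs=float(fs),
        channel_names=tuple(channel_names) if channel_names else (),
    )


def _check_length(sos: np.ndarray, n_samples: int) -> None:
    # sosfiltfilt's default padding; epochs shorter than this are rejected
    # rather than padded, because a padding policy would silently change
    # the variance-based features downstream.
    padlen = 3 * (2 * sos.shape[0] + 1)
    if n_samples <= padlen:
        raise PreprocessError(
            f"epochs of {n_samples} samples are too short for stable zero-phase "
            f"filtering (need more than {padlen})"
        )


def bandpass_array(data: np.ndarray, band: BandSpec, fs: float) -> np.ndarray:
    """Zero-phase band-pass along the last axis."""
    sos = band.design(fs)
    data = np.asarray(data, dtype=float)
    _check_length(sos, data.shape[-1])
    return signal.sosfiltfilt(sos, data, axis=-1)


def bandpass(epoch_set: EpochSet, band: BandSpec) -> EpochSet:
    """Return a new :class:`EpochSet` filtered to ``band`` (zero-phase)."""
    return replace(epoch_set, data=bandpass_array(epoch_set.data, band, epoch_set.fs))
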
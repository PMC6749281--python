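"""File formats: the epoch container, EDF interchange, ground-truth sidecars.

Epoch container
---------------
A plain NumPy ``.npz`` archive with arrays

* ``data``  -- trials x channels x samples, float64 microvolts
* ``labels`` -- length-trials int vector in {1, 2} (omitted if unknown)
* ``fs``    -- scalar sampling rate, Hz
* ``channel_names`` -- length-channels unicode array

EDF
---
Continuous recordings are read with MNE (annotations become cue times).
Writing uses a minimal single-segment EDF encoder (16-bit, 1-second
records) sufficient for interchange of simulated sessions; EDF+
annotation channels are not written -- cue times travel in a JSON
sidecar instead.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .preprocess import EpochSet
from .synth import SynthGroundTruth


def save_epochs(path, epochs: EpochSet) -> None:
    """Write an :class:`EpochSet` to the ``.npz`` epoch container."""
    payload = {
        "data": epochs.data,
        "fs": np.float64(epochs.fs),
        "channel_names": np.array(epochs.channel_names, dtype="U32"),
    }
    if epochs.labels is not None:
        payload["labels"] = epochs.labels
    np.savez(path, **payload)


def load_epochs(path) -> EpochSet:
    """Read an :class:`EpochSet` from the ``.npz`` epoch container."""
    with np.load(path, allow_pickle=False) as archive:
        return EpochSet(
            data=archive["data"],
            labels=archive["labels"] if "labels" in archive else None,
            fs=float(archive["fs"]),
            channel_names=tuple(archive["channel_names"].tolist()),
        )


def save_ground_truth(path, truth: SynthGroundTruth) -> None:
    """Write a generator ground-truth sidecar as JSON."""
    Path(path).write_text(
        json.dumps(
            {
                "erd_channels": list(truth.erd_channels),
                "mixing": truth.mixing.tolist(),
                "band_powers": truth.band_powers.tolist(),
                "mixed_erd_power": truth.mixed_erd_power.tolist(),
                "labels": truth.labels.tolist(),
            },
            indent=1,
        )
    )


def load_ground_truth(path) -> SynthGroundTruth:
    raw = json.loads(Path(path).read_text())
    return SynthGroundTruth(
        erd_channels=tuple(raw["erd_channels"]),
        mixing=np.asarray(raw["mixing"]),
        band_powers=np.asarray(raw["band_powers"]),
        mixed_erd_power=np.asarray(raw["mixed_erd_power"]),
        labels=np.asarray(raw["labels"]),
    )


def read_raw_edf(path) -> tuple[np.ndarray, float, tuple[str, ...], list[float]]:
    """Read a continuous EDF recording.

    Returns ``(data, fs, channel_names, cue_times)`` with ``data`` in
    microvolts (channels x time) and cue times taken from the file's
    annotation onsets (empty for plain EDF).
    """
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data(units="uV")
    cues = [float(t) for t in raw.annotations.onset]
    return data, float(raw.info["sfreq"]), tuple(raw.ch_names), cues


def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path, data: np.ndarray, fs: float, channel_names=None) -> None:
    """Write a continuous recording as minimal EDF (16-bit, 1-s records).

    ``data`` is channels x time in microvolts; ``fs`` must be a whole
    number of samples per second.  Samples beyond the last whole second
    are dropped.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    fs_int = int(round(fs))
    if abs(fs - fs_int) > 1e-9 or fs_int < 1:
        raise ValueError(f"EDF export needs an integer sampling rate, got {fs}")
    n_channels, n_time = data.shape
    n_records = n_time // fs_int
    if n_records < 1:
        raise ValueError("recording shorter than one EDF record (1 s)")
    if channel_names is None:
        channel_names = [f"ch{k + 1:02d}" for k in range(n_channels)]
    data = data[:, : n_records * fs_int]

    phys_max = max(float(np.abs(data).max()), 1.0)
    phys_min = -phys_max
    dig_max, dig_min = 32767, -32768
    scaled = np.clip(
        np.round((data - phys_min) / (phys_max - phys_min) * (dig_max - dig_min) + dig_min),
        dig_min,
        dig_max,
    ).astype("<i2")

    header = b"".join(
        [
            _edf_field("0", 8),
            _edf_field("X X X X", 80),
            _edf_field("Startdate X X X X", 80),
            _edf_field("01.01.00", 8),
            _edf_field("00.00.00", 8),
            _edf_field(256 * (1 + n_channels), 8),
            _edf_field("", 44),
            _edf_field(n_records, 8),
            _edf_field(1, 8),
            _edf_field(n_channels, 4),
        ]
    )

    def per_signal(values, width):
        return b"".join(_edf_field(v, width) for v in values)

    header += per_signal([str(n)[:16] for n in channel_names], 16)
    header += per_signal(["SimEEG"] * n_channels, 80)
    header += per_signal(["uV"] * n_channels, 8)
    header += per_signal([f"{phys_min:.6g}" for _ in range(n_channels)], 8)
    header += per_signal([f"{phys_max:.6g}" for _ in range(n_channels)], 8)
    header += per_signal([dig_min] * n_channels, 8)
    header += per_signal([dig_max] * n_channels, 8)
    header += per_signal([""] * n_channels, 80)
    header += per_signal([fs_int] * n_channels, 8)
    header += per_signal([""] * n_channels, 32)

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            block = scaled[:, r * fs_int : (r + 1) * fs_int]
            fh.write(block.tobytes())
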
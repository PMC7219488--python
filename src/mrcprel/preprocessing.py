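"""EEG preprocessing: zero-phase band-pass filtering, large-Laplacian spatial
filtering to a single virtual channel, and cue-locked epoch extraction.

The processing chain mirrors standard MRCP practice: each channel of a
continuous recording is band-pass filtered (default 0.05--5 Hz, second-order
zero-phase Butterworth), a large Laplacian centred on Cz collapses the montage
to one virtual channel, and the virtual channel is cut into fixed-length
cue-locked epochs (default 3 s pre-cue, 1.5 s post-cue at 500 Hz, i.e. 2250
samples with the cue at within-epoch index 1500).

Conventions: all amplitudes are in microvolts, indexing is 0-based with
half-open sample intervals, and cue times in seconds are mapped to samples by
round-half-away-from-zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import signal as sps

__all__ = [
    "ContinuousRecording",
    "FilterSpec",
    "EpochSet",
    "butterworth_bandpass",
    "bandpass_recording",
    "large_laplacian",
    "extract_epochs",
    "read_delimited_recording",
    "read_edf",
    "read_cue_times",
    "write_epoch_set",
    "read_epoch_set",
]

#: Default Laplacian geometry for the sparse 10--20 montage used here: the only
#: electrodes surrounding Cz are Fz, Pz, C3 and C4, weighted uniformly.
DEFAULT_CENTRE = "Cz"
DEFAULT_NEIGHBOURS = ("Fz", "Pz", "C3", "C4")


@dataclass
class ContinuousRecording:
    """Multi-channel continuous EEG, ``data`` is channels x samples in uV."""

    channel_names: list[str]
    data: np.ndarray
    fs: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples array")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} data rows"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, name: str) -> np.ndarray:
        try:
            i = self.channel_names.index(name)
        except ValueError:
            raise ValueError(f"channel {name!r} not present in recording") from None
        return self.data[i]


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass filter design: Butterworth, optionally applied zero-phase.

    ``order`` is the design order passed to the Butterworth design (the
    band-pass realisation has ``2 * order`` poles, the convention of the usual
    MATLAB/scipy ``butter`` call).
    """

    low_hz: float = 0.05
    high_hz: float = 5.0
    order: int = 2
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        if not 0.0 < self.low_hz < self.high_hz < fs / 2.0:
            raise ValueError(
                f"band edges must satisfy 0 < low < high < Nyquist; got "
                f"low={self.low_hz}, high={self.high_hz}, fs={fs}"
            )
        if self.order < 1:
            raise ValueError("filter order must be >= 1")


@dataclass
class EpochSet:
    """Cue-locked epochs of the virtual channel for one dataset.

    ``epochs`` is n_epochs x n_samples (uV); ``cue_index`` is the 0-based
    within-epoch sample of the cue to move.
    """

    dataset_id: str
    condition: str
    epochs: np.ndarray
    fs: float
    cue_index: int

    def __post_init__(self) -> None:
        self.epochs = np.atleast_2d(np.asarray(self.epochs, dtype=float))
        if not 0 <= self.cue_index < self.epochs.shape[1]:
            raise ValueError("cue_index outside the epoch window")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_samples(self) -> int:
        return self.epochs.shape[1]

    @property
    def time_ms(self) -> np.ndarray:
        """Time axis in ms relative to the cue (negative = pre-cue)."""
        return (np.arange(self.n_samples) - self.cue_index) * 1000.0 / self.fs


def butterworth_bandpass(
    x: np.ndarray, fs: float, spec: FilterSpec = FilterSpec()
) -> np.ndarray:
    """Apply the Butterworth band-pass of `spec` to a 1-D signal.

    With ``zero_phase`` the filter runs forward and backward (sosfiltfilt), so
    the effective magnitude response is |H(f)|^2 and the phase response is
    identically zero. Output length equals input length.
    """
    spec.validate(fs)
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("butterworth_bandpass expects a 1-D signal")
    sos = sps.butter(
        spec.order, [spec.low_hz, spec.high_hz], btype="bandpass", fs=fs, output="sos"
    )
    if spec.zero_phase:
        return sps.sosfiltfilt(sos, x)
    return sps.sosfilt(sos, x)


def bandpass_recording(
    rec: ContinuousRecording, spec: FilterSpec = FilterSpec()
) -> ContinuousRecording:
    """Filter every channel of a recording with the same band-pass."""
    filtered = np.vstack([butterworth_bandpass(ch, rec.fs, spec) for ch in rec.data])
    return ContinuousRecording(
        channel_names=list(rec.channel_names),
        data=filtered,
        fs=rec.fs,
        start_time=rec.start_time,
    )


def large_laplacian(
    rec: ContinuousRecording,
    centre: str = DEFAULT_CENTRE,
    neighbours: Sequence[str] = DEFAULT_NEIGHBOURS,
) -> np.ndarray:
    """Collapse the montage to one virtual channel: centre - mean(neighbours).

    The uniform-weight large Laplacian rejects any signal common to all
    channels and leaves a signal present only at the centre untouched.
    """
    if not neighbours:
        raise ValueError("at least one neighbour channel is required")
    centre_sig = rec.channel(centre)
    neigh = np.vstack([rec.channel(name) for name in neighbours])
    return centre_sig - neigh.mean(axis=0)


def _cue_to_sample(cue_s: float, fs: float) -> int:
    """Map a cue time in seconds to a sample index, round half away from zero."""
    x = cue_s * fs
    return int(np.floor(x + 0.5)) if x >= 0 else int(np.ceil(x - 0.5))


def extract_epochs(
    virtual: np.ndarray,
    fs: float,
    cue_times: Sequence[float],
    pre_s: float = 3.0,
    post_s: float = 1.5,
    dataset_id: str = "",
    condition: str = "",
) -> EpochSet:
    """Cut the virtual channel into cue-locked epochs.

    Each epoch covers the half-open sample interval
    ``[cue - pre_s*fs, cue + post_s*fs)`` so the cue sits at within-epoch
    index ``pre_s * fs`` (1500 for the 3 s / 500 Hz default).

    Raises
    ------
    ValueError
        If any cue is too close to a recording edge; the message lists every
        offending cue time.
    """
    virtual = np.asarray(virtual, dtype=float)
    if virtual.ndim != 1:
        raise ValueError("virtual channel must be 1-D")
    pre_n = int(round(pre_s * fs))
    post_n = int(round(post_s * fs))
    n = virtual.shape[0]

    bad: list[float] = []
    starts: list[int] = []
    for cue in cue_times:
        c = _cue_to_sample(float(cue), fs)
        if c - pre_n < 0 or c + post_n > n:
            bad.append(float(cue))
        else:
            starts.append(c - pre_n)
    if bad:
        raise ValueError(
            f"cue(s) too close to the recording edge for a "
            f"{pre_s}+{post_s} s window: {bad}"
        )
    epochs = np.vstack([virtual[s : s + pre_n + post_n] for s in starts])
    return EpochSet(
        dataset_id=dataset_id,
        condition=condition,
        epochs=epochs,
        fs=fs,
        cue_index=pre_n,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_delimited_recording(
    path: str | Path, fs: float, delimiter: str | None = None
) -> ContinuousRecording:
    """Read a continuous recording from delimited text.

    First row holds channel names; subsequent rows are samples (one row per
    time point, one column per channel). The sampling rate is not stored in
    the file and must be supplied.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
    names = header.split(delimiter) if delimiter else header.split()
    data = np.loadtxt(path, skiprows=1, delimiter=delimiter)
    data = np.atleast_2d(data)
    if data.shape[1] != len(names):
        raise ValueError(
            f"{path}: {len(names)} channel names but {data.shape[1]} columns"
        )
    return ContinuousRecording(channel_names=names, data=data.T, fs=fs)


def read_edf(path: str | Path) -> ContinuousRecording:
    """Read a continuous recording from EDF (amplitudes converted to uV).

    Requires the optional ``mne`` dependency.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - env-dependent
        raise ImportError("reading EDF requires the optional 'mne' package") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return ContinuousRecording(
        channel_names=list(raw.ch_names),
        data=raw.get_data() * 1e6,
        fs=float(raw.info["sfreq"]),
    )


def read_cue_times(path: str | Path) -> np.ndarray:
    """Read cue onset times (seconds), one per line."""
    return np.atleast_1d(np.loadtxt(path, dtype=float))


def write_epoch_set(es: EpochSet, matrix_path: str | Path, meta_path: str | Path | None = None) -> None:
    """Write an EpochSet as a delimited matrix (rows = epochs) + JSON metadata."""
    matrix_path = Path(matrix_path)
    np.savetxt(matrix_path, es.epochs, fmt="%.6f")
    if meta_path is None:
        meta_path = matrix_path.with_suffix(".json")
    meta = {
        "dataset_id": es.dataset_id,
        "condition": es.condition,
        "fs": es.fs,
        "cue_index": es.cue_index,
        "n_epochs": es.n_epochs,
        "n_samples": es.n_samples,
    }
    Path(meta_path).write_text(json.dumps(meta, indent=1))


def read_epoch_set(matrix_path: str | Path, meta_path: str | Path | None = None) -> EpochSet:
    matrix_path = Path(matrix_path)
    if meta_path is None:
        meta_path = matrix_path.with_suffix(".json")
    meta = json.loads(Path(meta_path).read_text())
    epochs = np.atleast_2d(np.loadtxt(matrix_path))
    return EpochSet(
        dataset_id=meta["dataset_id"],
        condition=meta["condition"],
        epochs=epochs,
        fs=meta["fs"],
        cue_index=meta["cue_index"],
    )
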
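"""Recording containers, file readers/writers and preprocessing.

Recordings travel on disk as delimited numeric matrices (one column per
electrode, header row of electrode labels, one sample per row) or as EDF
files read through MNE.  Preprocessing band-pass filters the signal
(zero-phase), optionally notch-filters mains, cuts fixed-length epochs and
drops epochs that exceed an amplitude threshold — a deliberately simple
artifact criterion standing in for manual artifact review.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .exceptions import (
    DegenerateInputError,
    EmptyDataError,
    FormatError,
    MontageError,
)
from .montage import MONTAGE


@dataclass
class EEGRecording:
    """A labelled multichannel time series.

    data : (n_channels, n_samples) array, arbitrary amplitude units
           (microvolts when read from EDF).
    """

    data: np.ndarray
    fs: float
    montage: tuple[str, ...] = MONTAGE
    subject_id: str | None = None
    timepoint: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise FormatError("recording data must be 2-D (channels x samples)")
        if len(self.montage) != self.data.shape[0]:
            raise MontageError(
                f"{self.data.shape[0]} channel rows but "
                f"{len(self.montage)} montage labels"
            )
        if not self.fs > 0:
            raise FormatError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class EpochedEEG:
    """Fixed-length epochs with a keep/drop mask and per-epoch reason codes."""

    epochs: np.ndarray  # (n_epochs, n_channels, samples_per_epoch)
    fs: float
    montage: tuple[str, ...] = MONTAGE
    keep: np.ndarray = field(default=None)  # bool per epoch
    reasons: list[str | None] = field(default=None)
    subject_id: str | None = None
    timepoint: str | None = None

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.keep is None:
            self.keep = np.ones(self.epochs.shape[0], dtype=bool)
        self.keep = np.asarray(self.keep, dtype=bool)
        if self.reasons is None:
            self.reasons = [None] * self.epochs.shape[0]

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_kept(self) -> int:
        return int(self.keep.sum())

    @property
    def kept(self) -> np.ndarray:
        """(n_kept, n_channels, samples_per_epoch) view of retained epochs."""
        return self.epochs[self.keep]


@dataclass
class PreprocessConfig:
    """Preprocessing defaults for resting EEG.

    epoch_s: epoch length in seconds (2 s, non-overlapping at rejection).
    artifact_threshold: absolute-amplitude rejection threshold in the
        recording's units (100, read as microvolts for clinical data).
    bandpass_hz: zero-phase Butterworth band edges in Hz.
    notch_hz: optional mains notch frequency (None disables).
    """

    epoch_s: float = 2.0
    artifact_threshold: float = 100.0
    bandpass_hz: tuple[float, float] = (0.5, 40.0)
    notch_hz: float | None = None
    filter_order: int = 4


def _resolve_labels(labels: list[str], montage: tuple[str, ...]) -> list[int]:
    """Map montage labels to row indices in ``labels`` (case-insensitive,
    tolerating 'EEG '-style prefixes as found in EDF headers)."""

    def norm(s: str) -> str:
        s = s.strip().upper()
        for prefix in ("EEG ", "EEG-"):
            if s.startswith(prefix):
                s = s[len(prefix):]
        # referenced labels like "F3-REF" resolve to the electrode name
        return s.split("-")[0].strip()

    normed = [norm(lbl) for lbl in labels]
    indices = []
    for want in montage:
        matches = [i for i, lbl in enumerate(normed) if lbl == want.upper()]
        if not matches:
            raise MontageError(
                f"electrode {want!r} missing from file labels {labels}"
            )
        indices.append(matches[0])
    return indices


def read_recording(path: str | Path, fmt: str | None = None,
                   montage: tuple[str, ...] = MONTAGE,
                   fs: float | None = None) -> EEGRecording:
    """Read a recording from a delimited matrix or EDF file.

    Channel rows are reordered to canonical montage order; a label missing
    from the file raises :class:`MontageError`.  For matrix files the
    sampling rate is taken from ``fs`` (or a ``# fs=...`` comment line).
    """
    path = Path(path)
    if fmt is None:
        fmt = "edf" if path.suffix.lower() == ".edf" else "matrix"
    if fmt == "edf":
        import mne

        try:
            raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
        except Exception as err:  # mne raises various types for bad files
            raise FormatError(f"cannot read EDF file {path}: {err}") from err
        order = _resolve_labels(list(raw.ch_names), montage)
        data = raw.get_data()[order] * 1e6  # volts -> microvolts
        return EEGRecording(data=data, fs=float(raw.info["sfreq"]),
                            montage=montage, subject_id=path.stem)
    if fmt == "matrix":
        file_fs = None
        with open(path) as fh:
            first = fh.readline()
        if first.startswith("#"):
            for token in first[1:].replace(",", " ").split():
                if token.startswith("fs="):
                    file_fs = float(token[3:])
        try:
            df = pd.read_csv(path, comment="#",
                             float_precision="round_trip")
        except Exception as err:
            raise FormatError(f"cannot parse matrix file {path}: {err}") from err
        order = _resolve_labels([str(c) for c in df.columns], montage)
        data = df.to_numpy(dtype=float).T[order]
        use_fs = fs if fs is not None else file_fs
        if use_fs is None:
            raise FormatError(
                f"no sampling rate for {path}: pass fs= or add a '# fs=' line"
            )
        return EEGRecording(data=data, fs=float(use_fs), montage=montage,
                            subject_id=path.stem)
    raise FormatError(f"unknown recording format {fmt!r}")


def write_recording(rec: EEGRecording, path: str | Path) -> Path:
    """Write a recording as a delimited matrix (samples x channels, header
    row of electrode labels, ``# fs=`` comment).  Floats are written with 17
    significant digits so write/read round-trips are bit-exact."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# fs={rec.fs:.17g}\n")
        fh.write(",".join(rec.montage) + "\n")
        np.savetxt(fh, rec.data.T, fmt="%.17g", delimiter=",")
    return path


def _epoch(data: np.ndarray, samples_per_epoch: int) -> np.ndarray:
    n_full = data.shape[1] // samples_per_epoch
    trimmed = data[:, : n_full * samples_per_epoch]
    return trimmed.reshape(data.shape[0], n_full, samples_per_epoch
                           ).transpose(1, 0, 2)


def preprocess(rec: EEGRecording,
               cfg: PreprocessConfig | None = None) -> EpochedEEG:
    """Filter, epoch and artifact-reject a recording.

    Band-pass (zero-phase Butterworth) and optional notch filtering, then
    non-overlapping fixed-length epochs; any epoch whose absolute amplitude
    exceeds the threshold is dropped with reason ``"amplitude"``.
    """
    cfg = cfg or PreprocessConfig()
    samples_per_epoch = int(round(cfg.epoch_s * rec.fs))
    if rec.n_samples < 2 * samples_per_epoch:
        raise DegenerateInputError(
            f"recording of {rec.duration:.1f}s is shorter than two "
            f"{cfg.epoch_s}s epochs"
        )
    lo, hi = cfg.bandpass_hz
    nyq = rec.fs / 2.0
    hi = min(hi, 0.95 * nyq)
    sos = signal.butter(cfg.filter_order, [lo, hi], btype="bandpass",
                        output="sos", fs=rec.fs)
    data = signal.sosfiltfilt(sos, rec.data, axis=1)
    if cfg.notch_hz is not None and cfg.notch_hz < nyq:
        b, a = signal.iirnotch(cfg.notch_hz, Q=30.0, fs=rec.fs)
        data = signal.filtfilt(b, a, data, axis=1)
    if not np.all(np.isfinite(data)):
        raise DegenerateInputError("non-finite samples after filtering")

    epochs = _epoch(data, samples_per_epoch)
    peak = np.abs(epochs).max(axis=(1, 2))
    keep = peak <= cfg.artifact_threshold
    reasons = [None if k else "amplitude" for k in keep]
    if not keep.any():
        raise EmptyDataError(
            "every epoch exceeded the artifact threshold "
            f"({cfg.artifact_threshold})"
        )
    return EpochedEEG(epochs=epochs, fs=rec.fs, montage=rec.montage,
                      keep=keep, reasons=reasons,
                      subject_id=rec.subject_id, timepoint=rec.timepoint)
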
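"""Shared Welch-style segmentation used by both spectral and coherence
estimators, so power spectra and cross-spectra are averaged over identical
Hann-windowed segments."""

from __future__ import annotations

import numpy as np
from scipy.signal import get_window

from .exceptions import DegenerateInputError
from .io import EpochedEEG


def segment_fft(ep: EpochedEEG, window_s: float = 2.0,
                overlap: float = 0.5):
    """One-sided FFTs of Hann-windowed, mean-removed segments.

    Segments of ``window_s`` seconds are slid with the given fractional
    overlap *within* each kept epoch (epochs equal to the window length
    yield one segment each).  Returns ``(freqs, X, psd_scale)`` where ``X``
    has shape (n_segments, n_channels, n_freqs) and ``psd_scale`` converts
    ``|X|^2`` averages into one-sided power spectral density (units^2/Hz),
    matching scipy.signal.welch's density scaling.
    """
    kept = ep.kept
    if kept.shape[0] == 0:
        raise DegenerateInputError("no kept epochs")
    nper = int(round(window_s * ep.fs))
    epoch_len = kept.shape[2]
    if nper > epoch_len:
        nper = epoch_len
    step = max(1, int(round(nper * (1.0 - overlap))))
    win = get_window("hann", nper)  # periodic Hann, as in Welch estimation
    segs = []
    for start in range(0, epoch_len - nper + 1, step):
        segs.append(kept[:, :, start:start + nper])
    seg = np.concatenate(segs, axis=0)  # (n_segments, n_channels, nper)
    seg = seg - seg.mean(axis=2, keepdims=True)
    X = np.fft.rfft(seg * win, axis=2)
    freqs = np.fft.rfftfreq(nper, 1.0 / ep.fs)
    # one-sided density scaling; interior bins carry the doubled power
    scale = np.full(freqs.size, 2.0 / (ep.fs * (win ** 2).sum()))
    scale[0] = 1.0 / (ep.fs * (win ** 2).sum())
    if nper % 2 == 0:
        scale[-1] = 1.0 / (ep.fs * (win ** 2).sum())
    return freqs, X, scale
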
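"""Pairwise magnitude-squared coherence over all unique electrode pairs.

For channels x and y the magnitude-squared coherence at frequency w is

    C(w) = |S_xy(w)|^2 / (S_xx(w) S_yy(w)),

with the cross- and auto-spectra averaged over Hann-windowed segments
(shared with the spectral module).  A band's coherence is the arithmetic
mean of per-frequency coherence across the band; "overall" averages across
the full analysis range.  Coherence of a single segment is identically 1,
so at least two averaging segments are required.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._segments import segment_fft
from .exceptions import DegenerateInputError
from .io import EpochedEEG
from .montage import (ANALYSIS_RANGE, BANDS, PAIR_LABELS, PAIRS, SPECTRA,
                      pair_label)


@dataclass
class CoherenceMatrix:
    """Symmetric per-spectrum coherence matrices with unit diagonal.

    ``values`` maps spectrum name ("overall" and each band) to a
    channels x channels array; ``pair_index`` fixes the canonical ordering
    of the unique off-diagonal pairs used by :func:`flatten_pairs`.
    """

    values: dict[str, np.ndarray]
    montage: tuple[str, ...]
    n_segments: int

    @property
    def pair_index(self) -> list[str]:
        from .montage import canonical_pairs
        return [pair_label(a, b) for a, b in canonical_pairs(self.montage)]

    def __getitem__(self, spectrum: str) -> np.ndarray:
        return self.values[spectrum]


def pairwise_coherence(ep: EpochedEEG,
                       bands: dict[str, tuple[float, float]] = BANDS,
                       analysis_range: tuple[float, float] = ANALYSIS_RANGE,
                       window_s: float = 2.0,
                       overlap: float = 0.5) -> CoherenceMatrix:
    """Estimate coherence matrices for the overall range and each band."""
    freqs, X, _scale = segment_fft(ep, window_s, overlap)
    m = X.shape[0]
    if m < 2:
        raise DegenerateInputError(
            "coherence needs >= 2 averaging segments (a single segment "
            "gives coherence identically 1)"
        )
    sxx = (np.abs(X) ** 2).mean(axis=0)  # (n_ch, n_freq)
    in_range = (freqs >= analysis_range[0]) & (freqs < analysis_range[1])
    if np.any(sxx[:, in_range].sum(axis=1) <= 0):
        raise DegenerateInputError("zero-power channel in the analysis range")
    sxy = np.einsum("sif,sjf->ijf", X, np.conj(X)) / m
    denom = sxx[:, None, :] * sxx[None, :, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        coh_f = np.abs(sxy) ** 2 / denom
    coh_f = np.nan_to_num(coh_f, nan=0.0)

    spectra = {"overall": analysis_range, **bands}
    values = {}
    for name, band in spectra.items():
        mask = (freqs >= band[0]) & (freqs < band[1])
        if not mask.any():
            raise DegenerateInputError(f"band {band} has no frequency bins")
        mat = coh_f[:, :, mask].mean(axis=2)
        np.fill_diagonal(mat, 1.0)
        values[name] = np.clip(mat, 0.0, 1.0)
    return CoherenceMatrix(values=values, montage=ep.montage, n_segments=m)


def flatten_pairs(cm: CoherenceMatrix, spectrum: str = "overall"
                  ) -> np.ndarray:
    """Canonical 28-element feature vector (upper triangle, row-major)."""
    mat = cm.values[spectrum]
    n = len(cm.montage)
    iu = np.triu_indices(n, k=1)
    return mat[iu].copy()


def unflatten_pairs(vec: np.ndarray, n_channels: int = 8) -> np.ndarray:
    """Inverse of :func:`flatten_pairs`: symmetric matrix, unit diagonal."""
    vec = np.asarray(vec, dtype=float)
    expected = n_channels * (n_channels - 1) // 2
    if vec.size != expected:
        raise DegenerateInputError(
            f"expected {expected} pair values, got {vec.size}")
    mat = np.eye(n_channels)
    iu = np.triu_indices(n_channels, k=1)
    mat[iu] = vec
    mat[(iu[1], iu[0])] = vec
    return mat


def coherence_feature_row(cm: CoherenceMatrix) -> dict[str, float]:
    """Flat feature dict (5 spectra x 28 pairs) with stable column order;
    overall-spectrum columns are the bare pair labels used downstream."""
    row: dict[str, float] = {}
    for spectrum in SPECTRA:
        vec = flatten_pairs(cm, spectrum)
        for (a, b), val in zip(PAIRS, vec):
            key = pair_label(a, b) if spectrum == "overall" \
                else f"{spectrum}:{pair_label(a, b)}"
            row[key] = float(val)
    return row


def features_to_frame(rows: list[dict]) -> pd.DataFrame:
    """Stack per-subject-timepoint feature dicts into a tidy DataFrame."""
    return pd.DataFrame(rows)
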
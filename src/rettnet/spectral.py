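"""Per-channel power spectra, band-relative power and hemispheric asymmetry.

Power spectral densities are averaged periodograms (Welch estimates) over
the kept epochs.  Relative band power divides each band's power integral by
the total power inside the analysis range, so values per channel sum to one
over a band set that tiles the range.  Asymmetry profiles subtract
right-hemisphere from left-hemisphere power (in dB) for each homologous
electrode pair, per region and averaged over the hemisphere, overall and
within each band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._segments import segment_fft
from .exceptions import DegenerateInputError, MontageError
from .io import EpochedEEG
from .montage import ANALYSIS_RANGE, BANDS, HOMOLOGUES, REGIONS

_DB_FLOOR = 1e-300  # avoids log(0) on identically-zero channels


@dataclass
class PowerSpectrum:
    """One-sided PSD per channel (units^2/Hz) on a common frequency grid."""

    freqs: np.ndarray
    psd: np.ndarray  # (n_channels, n_freqs)
    montage: tuple[str, ...]
    n_segments: int

    @property
    def psd_db(self) -> np.ndarray:
        return 10.0 * np.log10(np.maximum(self.psd, _DB_FLOOR))

    @property
    def mean_psd(self) -> np.ndarray:
        """Cross-channel mean spectrum (the 'overall' spectrum)."""
        return self.psd.mean(axis=0)


@dataclass
class BandPowerProfile:
    bands: dict[str, tuple[float, float]]
    relative_power: pd.DataFrame  # channels x bands, dimensionless
    overall_power_db: pd.Series  # per channel, dB re 1 unit^2


@dataclass
class AsymmetryProfile:
    """Left-minus-right spectral power differences in dB.

    With one homologous pair per region in the default montage, the
    per-region values coincide with the per-pair values; the hemisphere
    value is the mean over homologous pairs.
    """

    pair_overall: pd.Series  # per homologous pair, dB
    pair_band: pd.DataFrame  # pairs x bands, dB
    region_overall: pd.Series = field(default=None)
    hemisphere_overall: float = 0.0
    hemisphere_band: pd.Series = field(default=None)


def compute_psd(ep: EpochedEEG, window_s: float = 2.0,
                overlap: float = 0.5) -> PowerSpectrum:
    """Welch PSD over kept epochs (Hann windows, Parseval-consistent
    density scaling)."""
    if ep.n_kept < 1:
        raise DegenerateInputError("no kept epochs to average")
    freqs, X, scale = segment_fft(ep, window_s, overlap)
    psd = (np.abs(X) ** 2).mean(axis=0) * scale
    return PowerSpectrum(freqs=freqs, psd=psd, montage=ep.montage,
                         n_segments=X.shape[0])


def _band_mask(freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    return (freqs >= band[0]) & (freqs < band[1])


def band_power(ps: PowerSpectrum, band: tuple[float, float]) -> np.ndarray:
    """Per-channel power integral (units^2) over a [lo, hi) band."""
    mask = _band_mask(ps.freqs, band)
    if not mask.any():
        raise DegenerateInputError(f"band {band} contains no frequency bins")
    df = ps.freqs[1] - ps.freqs[0]
    return ps.psd[:, mask].sum(axis=1) * df


def band_relative_power(ps: PowerSpectrum,
                        bands: dict[str, tuple[float, float]] = BANDS,
                        analysis_range: tuple[float, float] = ANALYSIS_RANGE
                        ) -> BandPowerProfile:
    """Relative power per band, normalised to total analysis-range power."""
    total = band_power(ps, analysis_range)
    if np.any(total <= 0):
        raise DegenerateInputError("zero total power in the analysis range")
    rel = {name: band_power(ps, b) / total for name, b in bands.items()}
    rel_df = pd.DataFrame(rel, index=list(ps.montage))
    overall_db = pd.Series(10.0 * np.log10(total), index=list(ps.montage))
    return BandPowerProfile(bands=dict(bands), relative_power=rel_df,
                            overall_power_db=overall_db)


def asymmetry(ps: PowerSpectrum,
              bands: dict[str, tuple[float, float]] = BANDS,
              analysis_range: tuple[float, float] = ANALYSIS_RANGE,
              homologues: tuple[tuple[str, str], ...] = HOMOLOGUES
              ) -> AsymmetryProfile:
    """Left-minus-right power differences (dB), overall and per band."""
    channels = list(ps.montage)
    for left, right in homologues:
        if left not in channels or right not in channels:
            raise MontageError(
                f"homologue pair ({left}, {right}) not fully present in "
                f"montage {ps.montage}"
            )

    def db_diff(band: tuple[float, float]) -> pd.Series:
        power = band_power(ps, band)
        vals = {}
        for left, right in homologues:
            p_l = max(power[channels.index(left)], _DB_FLOOR)
            p_r = max(power[channels.index(right)], _DB_FLOOR)
            vals[f"{left}-{right}"] = 10.0 * np.log10(p_l / p_r)
        return pd.Series(vals)

    pair_overall = db_diff(analysis_range)
    pair_band = pd.DataFrame({name: db_diff(b) for name, b in bands.items()})
    region_overall = pd.Series(
        {region: pair_overall[f"{l}-{r}"]
         for region, (l, r) in REGIONS.items()
         if l in channels and r in channels})
    return AsymmetryProfile(
        pair_overall=pair_overall,
        pair_band=pair_band,
        region_overall=region_overall,
        hemisphere_overall=float(pair_overall.mean()),
        hemisphere_band=pair_band.mean(axis=0),
    )


def spectral_feature_row(ps: PowerSpectrum,
                         bands: dict[str, tuple[float, float]] = BANDS
                         ) -> dict[str, float]:
    """Flat feature dict (stable column order) for one subject-timepoint:
    per-channel overall dB power, per-channel band relative powers, and the
    asymmetry profile."""
    bp = band_relative_power(ps, bands)
    asym = asymmetry(ps, bands)
    row: dict[str, float] = {}
    for ch in ps.montage:
        row[f"power_db:{ch}"] = float(bp.overall_power_db[ch])
    for band in bands:
        for ch in ps.montage:
            row[f"relpower:{band}:{ch}"] = float(bp.relative_power.loc[ch, band])
    for pair, val in asym.pair_overall.items():
        row[f"asym:overall:{pair}"] = float(val)
    for band in bands:
        for pair in asym.pair_band.index:
            row[f"asym:{band}:{pair}"] = float(asym.pair_band.loc[pair, band])
    row["asym:overall:hemisphere"] = asym.hemisphere_overall
    return row
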
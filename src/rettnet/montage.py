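"""Electrode montage, frequency bands and electrode-pair bookkeeping.

The eight-electrode montage covers left/right homologues over frontal,
temporal, parietal and occipital cortex.  Every module that emits per-pair
features uses the canonical pair ordering defined here (upper triangle of the
channel x channel matrix in montage order), so feature vectors are comparable
across subjects, timepoints and files.
"""

from __future__ import annotations

from itertools import combinations

from .exceptions import MontageError

#: Canonical montage order. Left/right homologue pairs: (F3,F4), (T3,T4),
#: (P3,P4), (O1,O2).
MONTAGE: tuple[str, ...] = ("F3", "F4", "T3", "T4", "P3", "P4", "O1", "O2")

#: Left hemisphere channels and their right-hemisphere homologues.
HOMOLOGUES: tuple[tuple[str, str], ...] = (
    ("F3", "F4"),
    ("T3", "T4"),
    ("P3", "P4"),
    ("O1", "O2"),
)

#: Region name for each homologue pair (one pair per region in this montage).
REGIONS: dict[str, tuple[str, str]] = {
    "frontal": ("F3", "F4"),
    "temporal": ("T3", "T4"),
    "parietal": ("P3", "P4"),
    "occipital": ("O1", "O2"),
}

#: Clinical frequency bands (Hz, half-open [lo, hi) intervals) tiling the
#: analysis range.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}

#: Full analysis range in Hz; "overall" spectra and coherences average over it.
ANALYSIS_RANGE: tuple[float, float] = (0.5, 30.0)

#: Spectrum labels used in feature files: the overall range plus each band.
SPECTRA: tuple[str, ...] = ("overall",) + tuple(BANDS)


def canonical_pairs(montage: tuple[str, ...] = MONTAGE) -> list[tuple[str, str]]:
    """All unique electrode pairs in canonical (upper-triangle) order."""
    return list(combinations(montage, 2))


def pair_label(a: str, b: str) -> str:
    return f"{a}-{b}"


#: The 28 canonical pairs and their column labels, fixed for the default montage.
PAIRS: list[tuple[str, str]] = canonical_pairs()
PAIR_LABELS: list[str] = [pair_label(a, b) for a, b in PAIRS]

#: Named pair groups used when reporting regional claims.
PAIR_GROUPS: dict[str, list[str]] = {
    "occipital_interhemispheric": [pair_label("O1", "O2")],
    "frontal_occipital": [
        pair_label(f, o) for f in ("F3", "F4") for o in ("O1", "O2")
    ],
    "temporal": [
        pair_label(a, b) for a, b in PAIRS if "T3" in (a, b) or "T4" in (a, b)
    ],
    "interhemispheric": [pair_label(a, b) for a, b in HOMOLOGUES],
}


def channel_index(label: str, montage: tuple[str, ...] = MONTAGE) -> int:
    try:
        return montage.index(label)
    except ValueError as err:
        raise MontageError(
            f"electrode {label!r} not in montage {montage}"
        ) from err


def normalize_pair(pair: tuple[str, str] | str,
                   montage: tuple[str, ...] = MONTAGE) -> tuple[str, str]:
    """Return a pair as (earlier, later) in montage order; accepts 'A-B'."""
    if isinstance(pair, str):
        parts = pair.split("-")
        if len(parts) != 2:
            raise MontageError(f"cannot parse pair label {pair!r}")
        pair = (parts[0], parts[1])
    a, b = pair
    ia, ib = channel_index(a, montage), channel_index(b, montage)
    if ia == ib:
        raise MontageError(f"pair {pair!r} names the same electrode twice")
    return (a, b) if ia < ib else (b, a)
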
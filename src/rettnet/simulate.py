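"""Synthetic 8-channel EEG cohorts with known cross-coherence structure.

The generative model is a linear mixing of band-limited Gaussian sources
into channels plus independent 1/f-shaped background noise:

    x_i(t) = sum_k w_ik * s_k(t) + n_i(t)

Each shared source s_k has a flat power spectrum inside a declared frequency
band and zero power outside; the noise n_i has power spectral density
proportional to f^(-alpha).  Because the noise is independent across
channels, the magnitude-squared coherence between channels i and j at any
frequency where a single shared source has power is available in closed
form,

    C_ij = (w_i w_j s2)^2 / ((w_i^2 s2 + n2)(w_j^2 s2 + n2)),

with s2 and n2 the source and noise spectral power at that frequency.  This
closed form is the oracle every downstream coherence estimate is tested
against, and its inversion is how cohort designs inject group-, responder-
and timepoint-dependent coherence effects at named electrode pairs.

Cohorts mimic a two-group, two-timepoint treatment study: a background
source shared by all electrodes sets a common baseline coherence, dedicated
pair sources raise the coherence of chosen electrode pairs in chosen
design cells, and a clinical table (ages, ISS severity scores at baseline
and 12 months) is drawn alongside, with responder labels following the
strict-decrease rule applied to the generated ISS values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, DesignError
from .io import EEGRecording
from .montage import ANALYSIS_RANGE, MONTAGE, normalize_pair

__all__ = [
    "SharedSource", "SimConfig", "Effect", "IssModel", "CohortDesign",
    "analytic_pair_coherence", "required_pair_weight",
    "expected_pair_coherence", "generate_recording", "generate_cohort",
    "generate_coherence_features", "subject_configs",
    "response_study_design",
]


# --------------------------------------------------------------------------
# configuration types

@dataclass
class SharedSource:
    """A band-limited Gaussian source mixed into all channels.

    band: (lo, hi) Hz; the source spectrum is flat inside and zero outside.
    weights: per-channel mixing weights (len == n_channels).
    variance: total source variance (signal units squared).
    """

    band: tuple[float, float]
    weights: np.ndarray
    variance: float = 1.0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        lo, hi = self.band
        if not 0 <= lo < hi:
            raise DesignError(f"invalid source band {self.band}")
        if self.variance < 0:
            raise DesignError("source variance must be >= 0")


@dataclass
class SimConfig:
    """Configuration for a single synthetic recording."""

    sources: list[SharedSource] = field(default_factory=list)
    montage: tuple[str, ...] = MONTAGE
    fs: float = 128.0
    duration: float = 1200.0
    noise_power: float = 1.0
    background_exponent: float = 1.0

    def __post_init__(self) -> None:
        n_ch = len(self.montage)
        for src in self.sources:
            if src.weights.shape != (n_ch,):
                raise DesignError(
                    f"source weight vector has shape {src.weights.shape}, "
                    f"montage has {n_ch} channels"
                )
            if src.band[1] > self.fs / 2:
                raise DesignError("source band exceeds the Nyquist frequency")
        if self.noise_power < 0:
            raise DesignError("noise power must be >= 0")
        if self.n_samples < 2 * int(round(2.0 * self.fs)):
            raise DesignError(
                "duration must cover at least two 2-second analysis windows"
            )

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))


@dataclass
class Effect:
    """A coherence elevation at one electrode pair in one design cell.

    ``group``/``timepoint`` of None mean the effect applies to every group /
    every timepoint.  ``delta`` is added to the design's background
    coherence; the resulting target must stay in [0, 1).
    """

    pair: tuple[str, str] | str
    delta: float
    group: str | None = None
    timepoint: str | None = None


@dataclass
class IssModel:
    """Distribution of ISS severity scores.

    Baseline scores are Normal(mean, sd) truncated to [lo, hi] and rounded
    to integers.  Twelve-month change scores are uniform over the stated
    integer ranges: responders improve by 1-6 points, nonresponders stay
    flat or worsen by 1, untreated subjects drift within [-1, 5].
    """

    baseline_mean: float = 17.4
    baseline_sd: float = 4.5
    score_range: tuple[int, int] = (0, 40)
    responder_change: tuple[int, int] = (-6, -1)
    nonresponder_change: tuple[int, int] = (0, 1)
    untreated_change: tuple[int, int] = (-1, 5)


@dataclass
class CohortDesign:
    """Design of a synthetic cohort.

    groups: design cell labels, e.g. ("treated", "untreated") or
        ("responder", "nonresponder"); responder/nonresponder groups are
        treated subjects split by clinical response.
    n_per_cell: subjects per group (int for all, or one int per group).
    background_coherence: target pairwise coherence shared by all pairs in
        the absence of effects.
    subject_sd: between-subject SD of the background coherence level.
    """

    groups: tuple[str, ...] = ("treated", "untreated")
    n_per_cell: int | tuple[int, ...] = 9
    timepoints: tuple[str, ...] = ("baseline", "month12")
    effects: list[Effect] = field(default_factory=list)
    background_coherence: float = 0.2
    subject_sd: float = 0.03
    iss_model: IssModel = field(default_factory=IssModel)
    n_responders: int | None = None  # for a "treated" group; None = half
    seed: int = 0
    montage: tuple[str, ...] = MONTAGE
    fs: float = 128.0
    duration: float = 1200.0
    noise_power: float = 1.0
    background_exponent: float = 1.0
    # extends slightly past the analysis range so scored bands sit in the
    # source interior (window leakage dilutes coherence at source-band edges)
    source_band: tuple[float, float] = (ANALYSIS_RANGE[0], 32.0)

    def __post_init__(self) -> None:
        if isinstance(self.n_per_cell, int):
            self.n_per_cell = (self.n_per_cell,) * len(self.groups)
        if len(self.n_per_cell) != len(self.groups):
            raise DesignError("n_per_cell must match the number of groups")
        if not 0 <= self.background_coherence < 1:
            raise DesignError("background coherence must be in [0, 1)")
        for eff in self.effects:
            normalize_pair(eff.pair, self.montage)  # raises MontageError
            if eff.group is not None and eff.group not in self.groups:
                raise DesignError(f"effect names unknown group {eff.group!r}")
            if (eff.timepoint is not None
                    and eff.timepoint not in self.timepoints):
                raise DesignError(
                    f"effect names unknown timepoint {eff.timepoint!r}")
            target = self.background_coherence + eff.delta
            if eff.delta < 0:
                raise DesignError(
                    "negative coherence deltas are not realisable with the "
                    "shared-source parameterisation; lower the background "
                    "coherence instead"
                )
            if not 0 <= target < 1:
                raise DesignError(
                    f"target coherence {target:.3f} outside [0, 1) "
                    f"for pair {eff.pair}"
                )

    @property
    def n_subjects(self) -> int:
        return int(sum(self.n_per_cell))


# --------------------------------------------------------------------------
# coherence oracle and its inversion

def analytic_pair_coherence(signal_var: float, noise_var: float,
                            w_i: float, w_j: float) -> float:
    """Closed-form magnitude-squared coherence of the single-shared-source
    mixing model at frequencies where the source has power."""
    if signal_var < 0 or noise_var < 0:
        raise DegenerateInputError("variances must be >= 0")
    p_i = w_i ** 2 * signal_var + noise_var
    p_j = w_j ** 2 * signal_var + noise_var
    if p_i == 0 or p_j == 0 or p_i * p_j == 0:  # includes underflow
        raise DegenerateInputError("zero total power at a channel")
    return min((w_i * w_j * signal_var) ** 2 / (p_i * p_j), 1.0)


def required_pair_weight(coherence: float, signal_var: float,
                         noise_var: float) -> float:
    """Invert :func:`analytic_pair_coherence` for the symmetric weight w
    giving the requested coherence between two channels sharing one source."""
    if not 0 <= coherence < 1:
        raise DesignError(f"coherence target {coherence} not in [0, 1)")
    if signal_var <= 0:
        raise DesignError("signal variance must be positive to invert")
    root = math.sqrt(coherence)
    w_sq = noise_var * root / (signal_var * (1.0 - root))
    return math.sqrt(w_sq)


def _noise_norm(alpha: float, f_lo: float, f_hi: float) -> float:
    """Integral of f^-alpha over [f_lo, f_hi]."""
    if alpha == 1.0:
        return math.log(f_hi / f_lo)
    return (f_hi ** (1 - alpha) - f_lo ** (1 - alpha)) / (1 - alpha)


def noise_band_fraction(band: tuple[float, float], alpha: float,
                        fs: float, f_floor: float = 0.5) -> float:
    """Fraction of total 1/f^alpha noise variance falling inside ``band``
    (noise support is [f_floor, fs/2))."""
    lo, hi = max(band[0], f_floor), min(band[1], fs / 2)
    if hi <= lo:
        return 0.0
    return _noise_norm(alpha, lo, hi) / _noise_norm(alpha, f_floor, fs / 2)


def _spectra_on_grid(config: SimConfig, freqs: np.ndarray):
    """Per-frequency source PSDs (n_sources, n_freqs) and noise PSD on a
    frequency grid, in variance per Hz."""
    src_psd = np.zeros((len(config.sources), freqs.size))
    for k, src in enumerate(config.sources):
        lo, hi = src.band
        mask = (freqs >= lo) & (freqs < hi)
        if mask.any():
            src_psd[k, mask] = src.variance / (hi - lo)
    f_floor = 0.5
    noise_psd = np.zeros(freqs.size)
    mask = freqs >= f_floor
    alpha = config.background_exponent
    norm = _noise_norm(alpha, f_floor, config.fs / 2)
    noise_psd[mask] = config.noise_power * freqs[mask] ** (-alpha) / norm
    return src_psd, noise_psd


def expected_pair_coherence(config: SimConfig, pair: tuple[str, str] | str,
                            band: tuple[float, float] = ANALYSIS_RANGE,
                            df: float = 0.5) -> float:
    """Band-averaged expected coherence under the full mixing model.

    Evaluates the per-frequency closed form on a grid and averages over the
    band, exactly as the estimator averages per-frequency coherence; this is
    the forward oracle for parameter-recovery tests (it accounts for the
    1/f variation of the noise floor inside the band, which the flat
    closed form does not).
    """
    a, b = normalize_pair(pair, config.montage)
    i, j = config.montage.index(a), config.montage.index(b)
    # grid matches the rfft bins of 2-s analysis windows (df = 0.5 Hz)
    freqs = np.arange(band[0], band[1], df)
    src_psd, noise_psd = _spectra_on_grid(config, freqs)
    w = np.array([s.weights for s in config.sources])  # (n_src, n_ch)
    if w.size == 0:
        return 0.0
    cross = (w[:, i] * w[:, j]) @ src_psd
    p_i = (w[:, i] ** 2) @ src_psd + noise_psd
    p_j = (w[:, j] ** 2) @ src_psd + noise_psd
    valid = (p_i > 0) & (p_j > 0)
    if not valid.any():
        raise DegenerateInputError("zero power across the requested band")
    coh = np.zeros(freqs.size)
    coh[valid] = cross[valid] ** 2 / (p_i[valid] * p_j[valid])
    return float(coh[valid].mean())


# --------------------------------------------------------------------------
# signal synthesis

def _band_limited_noise(rng: np.random.Generator, n: int, fs: float,
                        shape: np.ndarray) -> np.ndarray:
    """Gaussian signal with spectral amplitude ``shape`` on the rfft grid,
    normalised to unit variance (zero if the shape is empty)."""
    spec = (rng.standard_normal(shape.size)
            + 1j * rng.standard_normal(shape.size)) * shape
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    if sd == 0:
        return np.zeros(n)
    return x / sd


def generate_recording(config: SimConfig, seed: int | np.random.Generator
                       ) -> EEGRecording:
    """Synthesise one recording; deterministic for a fixed seed."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    n = config.n_samples
    n_ch = len(config.montage)
    freqs = np.fft.rfftfreq(n, 1.0 / config.fs)
    data = np.zeros((n_ch, n))
    for src in config.sources:
        lo, hi = src.band
        shape = ((freqs >= lo) & (freqs < hi)).astype(float)
        s = _band_limited_noise(rng, n, config.fs, shape)
        s *= math.sqrt(src.variance)
        data += src.weights[:, None] * s[None, :]
    if config.noise_power > 0:
        alpha = config.background_exponent
        shape = np.zeros(freqs.size)
        mask = freqs >= 0.5
        shape[mask] = freqs[mask] ** (-alpha / 2.0)
        sd_n = math.sqrt(config.noise_power)
        for ch in range(n_ch):
            data[ch] += sd_n * _band_limited_noise(rng, n, config.fs, shape)
    return EEGRecording(data=data, fs=config.fs, montage=config.montage)


# --------------------------------------------------------------------------
# cohort synthesis

def _cell_targets(design: CohortDesign, group: str, timepoint: str
                  ) -> dict[tuple[str, str], float]:
    """Coherence targets (above background) for one design cell."""
    targets: dict[tuple[str, str], float] = {}
    for eff in design.effects:
        if eff.group is not None and eff.group != group:
            continue
        if eff.timepoint is not None and eff.timepoint != timepoint:
            continue
        pair = normalize_pair(eff.pair, design.montage)
        targets[pair] = targets.get(pair, 0.0) + eff.delta
    return targets


def _calibrate_weights(design: CohortDesign, background: float,
                       targets: dict[tuple[str, str], float]
                       ) -> tuple[float, dict[tuple[str, str], float]]:
    """Solve the background weight g and per-pair source weights so the
    band-averaged expected coherence hits ``background`` everywhere and
    ``background + delta`` at the effect pairs.

    Uses the flat closed form for initialisation and a short fixed-point /
    bisection refinement against the per-frequency forward model (the 1/f
    noise floor makes band-mean coherence deviate slightly from the flat
    closed form).
    """
    band = ANALYSIS_RANGE
    n_in = design.noise_power * noise_band_fraction(
        band, design.background_exponent, design.fs)
    montage = design.montage

    def build(g: float, ws: dict) -> SimConfig:
        sources = []
        if g > 0:
            sources.append(SharedSource(band=design.source_band,
                                        weights=np.full(len(montage), g)))
        for (a, b), w in ws.items():
            vec = np.zeros(len(montage))
            vec[montage.index(a)] = w
            vec[montage.index(b)] = w
            sources.append(SharedSource(band=design.source_band, weights=vec))
        return SimConfig(sources=sources, montage=montage, fs=design.fs,
                         duration=design.duration,
                         noise_power=design.noise_power,
                         background_exponent=design.background_exponent)

    def bisect(fun, lo, hi, target, tol=1e-6):
        flo, fhi = fun(lo) - target, fun(hi) - target
        grow = 0
        while fhi < 0 and grow < 40:
            hi *= 2.0
            fhi = fun(hi) - target
            grow += 1
        if flo > 0 or fhi < 0:
            raise DesignError("coherence target unreachable")
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if fun(mid) - target > 0:
                hi = mid
            else:
                lo = mid
        return 0.5 * (lo + hi)

    # background weight: coherence of a clean pair sharing only the
    # background source
    if background > 0:
        g0 = required_pair_weight(background, 1.0, n_in)
        clean = [m for m in montage
                 if not any(m in p for p in targets)] or list(montage[:2])
        probe = (clean[0], clean[1]) if len(clean) >= 2 else tuple(montage[:2])

        def bg_coh(g):
            return expected_pair_coherence(build(g, {}), probe, band)

        g = bisect(bg_coh, 0.0, max(2 * g0, 1e-3), background)
    else:
        g = 0.0

    ws = {}
    for pair, delta in targets.items():
        total = background + delta
        w0 = required_pair_weight(total, 1.0, n_in)
        ws[pair] = max(w0, 1e-6)
    # fixed-point refinement: pair sources sharing an electrode dilute each
    # other's coherence through the channel power terms
    for _ in range(3 if ws else 0):
        for pair, delta in targets.items():
            total = background + delta
            others = {p: w for p, w in ws.items() if p != pair}

            def pair_coh(w):
                trial = dict(others)
                trial[pair] = w
                return expected_pair_coherence(build(g, trial), pair, band)

            ws[pair] = bisect(pair_coh, 0.0, 2 * ws[pair] + 1e-3, total)
    return g, ws


def subject_configs(design: CohortDesign):
    """Yield (subject_id, group, timepoint, SimConfig, target_dict) for each
    subject-timepoint cell, with per-subject background jitter.

    ``target_dict`` maps every canonical pair to its designed band-mean
    coherence (background level plus any cell effect), before estimator
    noise — the ground truth parameter-recovery tests compare against.
    """
    rng = np.random.default_rng([design.seed, 1])
    sid = 0
    for group, n_g in zip(design.groups, design.n_per_cell):
        for _ in range(n_g):
            sid += 1
            subject_id = f"S{sid:02d}"
            b_s = float(np.clip(
                design.background_coherence
                + design.subject_sd * rng.standard_normal(),
                0.0, 0.95))
            for timepoint in design.timepoints:
                targets = _cell_targets(design, group, timepoint)
                g, ws = _calibrate_weights(design, b_s, targets)
                cfg = _config_from_weights(design, g, ws)
                truth = {"background": b_s}
                for pair, delta in targets.items():
                    truth[pair] = b_s + delta
                yield subject_id, group, timepoint, cfg, truth


def _config_from_weights(design: CohortDesign, g: float,
                         ws: dict[tuple[str, str], float]) -> SimConfig:
    montage = design.montage
    sources = []
    if g > 0:
        sources.append(SharedSource(band=design.source_band,
                                    weights=np.full(len(montage), g)))
    for (a, b), w in ws.items():
        vec = np.zeros(len(montage))
        vec[montage.index(a)] = w
        vec[montage.index(b)] = w
        sources.append(SharedSource(band=design.source_band, weights=vec))
    return SimConfig(sources=sources, montage=montage, fs=design.fs,
                     duration=design.duration,
                     noise_power=design.noise_power,
                     background_exponent=design.background_exponent)


def generate_clinical_table(design: CohortDesign) -> pd.DataFrame:
    """Clinical table for the cohort: subject_id, group, age, iss_t1,
    iss_t2, responder (strict ISS decrease; null for untreated)."""
    rng = np.random.default_rng([design.seed, 2])
    m = design.iss_model
    rows = []
    sid = 0
    for group, n_g in zip(design.groups, design.n_per_cell):
        if group in ("responder", "nonresponder"):
            treatment, statuses = "treated", [group] * n_g
        elif group == "treated":
            n_r = design.n_responders
            if n_r is None:
                n_r = n_g // 2 + n_g % 2
            statuses = (["responder"] * n_r
                        + ["nonresponder"] * (n_g - n_r))
            treatment = "treated"
        else:
            treatment, statuses = "untreated", [None] * n_g
        for status in statuses:
            sid += 1
            age = int(np.clip(round(7 + 4 * rng.standard_normal()), 2, 15))
            lo, hi = m.score_range
            iss1 = int(np.clip(round(m.baseline_mean
                                     + m.baseline_sd * rng.standard_normal()),
                               lo, hi))
            if status == "responder":
                change = int(rng.integers(m.responder_change[0],
                                          m.responder_change[1] + 1))
            elif status == "nonresponder":
                change = int(rng.integers(m.nonresponder_change[0],
                                          m.nonresponder_change[1] + 1))
            else:
                change = int(rng.integers(m.untreated_change[0],
                                          m.untreated_change[1] + 1))
            iss2 = int(np.clip(iss1 + change, lo, hi))
            if status == "responder" and iss2 >= iss1:
                iss2 = iss1 - 1  # truncation at the floor cannot erase response
            responder = None
            if treatment == "treated":
                responder = "responder" if iss2 < iss1 else "nonresponder"
            rows.append({"subject_id": f"S{sid:02d}", "group": treatment,
                         "design_group": group, "age": age,
                         "iss_t1": iss1, "iss_t2": iss2,
                         "responder": responder})
    return pd.DataFrame(rows)


def generate_cohort(design: CohortDesign, lazy: bool = False):
    """Generate a full cohort of recordings plus its clinical table.

    Returns ``(recordings, table)`` where recordings is a list (or, with
    ``lazy=True``, a generator — recordings at the default 20-minute
    duration are ~10 MB each) of ``(subject_id, timepoint, EEGRecording)``.
    Deterministic for a fixed design seed: per-subject random streams are
    derived from the master seed and the subject/timepoint indices.
    """
    table = generate_clinical_table(design)

    def _iter():
        for subject_id, _group, timepoint, cfg, _truth in \
                subject_configs(design):
            idx = int(subject_id[1:])
            tp_idx = design.timepoints.index(timepoint)
            rec = generate_recording(
                cfg, np.random.default_rng([design.seed, 3, idx, tp_idx]))
            rec = replace(rec, subject_id=subject_id, timepoint=timepoint)
            yield subject_id, timepoint, rec

    recs = _iter() if lazy else list(_iter())
    return recs, table


def response_study_design(seed: int = 0,
                          timepoints: tuple[str, ...] = ("baseline",),
                          o1o2_delta: float = 0.3,
                          fronto_occipital_delta: float = 0.15
                          ) -> CohortDesign:
    """The responder-prediction study cell: nine treated subjects (five
    responders, four nonresponders) whose responder group carries elevated
    baseline coherence at the occipital interhemispheric pair (O1-O2,
    +0.3) and, more weakly, at the four frontal-occipital pairs (+0.15),
    over a background coherence of 0.3."""
    effects = [Effect(pair=("O1", "O2"), delta=o1o2_delta,
                      group="responder", timepoint="baseline")]
    for f in ("F3", "F4"):
        for o in ("O1", "O2"):
            effects.append(Effect(pair=(f, o), delta=fronto_occipital_delta,
                                  group="responder", timepoint="baseline"))
    return CohortDesign(groups=("responder", "nonresponder"),
                        n_per_cell=(5, 4), timepoints=timepoints,
                        effects=effects, background_coherence=0.3,
                        seed=seed)


# --------------------------------------------------------------------------
# feature-level cohort (coherence features drawn directly)

def generate_coherence_features(design: CohortDesign,
                                noise_sd: float = 0.05) -> tuple[pd.DataFrame,
                                                                 pd.DataFrame]:
    """Draw per-subject coherence feature rows directly, bypassing signal
    synthesis: each of the 28 pair features is the cell's designed coherence
    plus independent Gaussian noise of SD ``noise_sd``, clipped to [0, 1].

    Fast stand-in for the full pipeline when only the downstream statistics
    or the classifier are under study.  Returns (feature table, clinical
    table); the feature table has one row per subject x timepoint with
    metadata columns subject_id, group, design_group, timepoint, responder.
    """
    from .montage import PAIRS, PAIR_LABELS, pair_label

    table = generate_clinical_table(design)
    rng = np.random.default_rng([design.seed, 4])
    rows = []
    for _, subj in table.iterrows():
        group = subj["design_group"]
        for timepoint in design.timepoints:
            targets = _cell_targets(design, group, timepoint)
            base = np.full(len(PAIRS), design.background_coherence)
            for pair, delta in targets.items():
                base[PAIR_LABELS.index(pair_label(*pair))] += delta
            vals = np.clip(base + noise_sd * rng.standard_normal(base.size),
                           0.0, 1.0)
            row = {"subject_id": subj["subject_id"], "group": subj["group"],
                   "design_group": group, "timepoint": timepoint,
                   "responder": subj["responder"]}
            row.update(dict(zip(PAIR_LABELS, vals)))
            rows.append(row)
    return pd.DataFrame(rows), table
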
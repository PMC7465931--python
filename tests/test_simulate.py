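"""Generator tests: the closed-form coherence oracle, its inversion, and
parameter recovery through the estimation pipeline."""

import numpy as np
import pytest

from rettnet import (CohortDesign, Effect, PreprocessConfig, SharedSource,
                     SimConfig, analytic_pair_coherence,
                     expected_pair_coherence, generate_cohort,
                     generate_coherence_features, generate_recording,
                     pairwise_coherence, preprocess, required_pair_weight)
from rettnet.exceptions import DegenerateInputError, DesignError
from rettnet.montage import PAIR_LABELS
from rettnet.simulate import noise_band_fraction, subject_configs


@pytest.mark.parametrize("s2,n2,wi,wj,expected", [
    (1.0, 0.0, 1.0, 1.0, 1.0),      # noiseless common source
    (1.0, 1.0, 0.0, 1.0, 0.0),      # no shared signal at one channel
    (1.0, 1.0, 1.0, 1.0, 0.25),     # SNR 1: (1/(1+1))^2
    (2.0, 1.0, 1.0, 1.0, (2 / 3) ** 2),
])
def test_analytic_coherence_closed_form(s2, n2, wi, wj, expected):
    assert analytic_pair_coherence(s2, n2, wi, wj) == pytest.approx(expected)


def test_analytic_coherence_zero_power_is_degenerate():
    with pytest.raises(DegenerateInputError):
        analytic_pair_coherence(1.0, 0.0, 0.0, 1.0)


def test_weight_inversion_round_trips():
    for target in (0.05, 0.25, 0.6, 0.95):
        w = required_pair_weight(target, signal_var=1.0, noise_var=2.0)
        back = analytic_pair_coherence(1.0, 2.0, w, w)
        assert back == pytest.approx(target, abs=1e-12)


def test_weight_inversion_rejects_unreachable_targets():
    with pytest.raises(DesignError):
        required_pair_weight(1.0, 1.0, 1.0)
    with pytest.raises(DesignError):
        required_pair_weight(-0.1, 1.0, 1.0)


def test_recording_is_bit_identical_for_fixed_seed():
    cfg = SimConfig(sources=[SharedSource(band=(8.0, 13.0),
                                          weights=np.ones(8))],
                    fs=128.0, duration=10.0)
    a = generate_recording(cfg, 99)
    b = generate_recording(cfg, 99)
    assert np.array_equal(a.data, b.data)
    c = generate_recording(cfg, 100)
    assert not np.array_equal(a.data, c.data)


def test_noiseless_common_source_gives_unit_coherence():
    cfg = SimConfig(sources=[SharedSource(band=(8.0, 13.0),
                                          weights=np.ones(8))],
                    fs=128.0, duration=60.0, noise_power=0.0)
    rec = generate_recording(cfg, 3)
    ep = preprocess(rec, PreprocessConfig(artifact_threshold=1e12))
    cm = pairwise_coherence(ep)
    off = cm.values["alpha"][np.triu_indices(8, 1)]
    assert off.min() > 0.99


def test_estimated_coherence_matches_oracle_at_snr_one():
    """Band coherence of a shared alpha source at in-band SNR 1 estimates
    the closed-form value 0.25 (5-minute recording, wider tolerance than
    the 20-minute convergence check)."""
    band = (8.0, 13.0)
    src = (7.0, 14.0)  # band edges sit inside the source support
    inband = (band[1] - band[0]) / (src[1] - src[0])
    noise_power = inband / noise_band_fraction(band, 1.0, 128.0)
    cfg = SimConfig(sources=[SharedSource(band=src, weights=np.ones(8))],
                    fs=128.0, duration=300.0, noise_power=noise_power)
    rec = generate_recording(cfg, 21)
    ep = preprocess(rec, PreprocessConfig(artifact_threshold=1e9))
    cm = pairwise_coherence(ep)
    est = cm.values["alpha"][6, 7]  # O1-O2
    assert est == pytest.approx(0.25, abs=0.04)
    assert est == pytest.approx(expected_pair_coherence(cfg, "O1-O2", band),
                                abs=0.04)


def test_null_design_has_no_group_differences():
    design = CohortDesign(groups=("responder", "nonresponder"),
                          n_per_cell=20, timepoints=("baseline",),
                          effects=[], background_coherence=0.25, seed=5)
    feats, _ = generate_coherence_features(design, noise_sd=0.05)
    base = feats[feats["timepoint"] == "baseline"]
    a = base[base["design_group"] == "responder"][PAIR_LABELS].mean()
    b = base[base["design_group"] == "nonresponder"][PAIR_LABELS].mean()
    assert np.abs(a - b).max() < 0.05


def test_cohort_table_matches_requested_group_sizes():
    design = CohortDesign(groups=("responder", "nonresponder"),
                          n_per_cell=(5, 4), timepoints=("baseline",),
                          duration=10.0, seed=1)
    recs, table = generate_cohort(design)
    assert (table["group"] == "treated").sum() == 9
    assert (table["responder"] == "responder").sum() == 5
    assert (table["responder"] == "nonresponder").sum() == 4
    assert len(recs) == 9
    assert table["subject_id"].is_unique


def test_cohort_is_deterministic():
    design = CohortDesign(groups=("treated", "untreated"), n_per_cell=2,
                          timepoints=("baseline",), duration=10.0, seed=8)
    (recs_a, tab_a) = generate_cohort(design)
    (recs_b, tab_b) = generate_cohort(design)
    assert tab_a.equals(tab_b)
    for (sa, ta, ra), (sb, tb, rb) in zip(recs_a, recs_b):
        assert (sa, ta) == (sb, tb)
        assert np.array_equal(ra.data, rb.data)


def test_injected_effect_recovered_through_pipeline():
    """A +0.3 O1-O2 coherence effect injected in one group is recovered as
    a group difference of 0.3 within +/-0.05 by the estimation pipeline."""
    design = CohortDesign(
        groups=("responder", "nonresponder"), n_per_cell=(3, 3),
        timepoints=("baseline",),
        effects=[Effect(pair=("O1", "O2"), delta=0.3, group="responder")],
        background_coherence=0.2, subject_sd=0.0,
        duration=300.0, fs=128.0, seed=7)
    lab = PAIR_LABELS.index("O1-O2")
    vals = {"responder": [], "nonresponder": []}
    for sid, grp, _tp, cfg, _truth in subject_configs(design):
        rec = generate_recording(
            cfg, np.random.default_rng([7, 3, int(sid[1:]), 0]))
        ep = preprocess(rec, PreprocessConfig(artifact_threshold=1e9))
        cm = pairwise_coherence(ep)
        vals[grp].append(cm.values["overall"][np.triu_indices(8, 1)][lab])
    diff = np.mean(vals["responder"]) - np.mean(vals["nonresponder"])
    assert diff == pytest.approx(0.3, abs=0.05)


def test_negative_delta_rejected():
    with pytest.raises(DesignError):
        CohortDesign(effects=[Effect(pair=("O1", "O2"), delta=-0.1)],
                     background_coherence=0.3)


def test_target_above_one_rejected():
    with pytest.raises(DesignError):
        CohortDesign(effects=[Effect(pair=("O1", "O2"), delta=0.9)],
                     background_coherence=0.3)


def test_injected_targets_stay_in_unit_interval():
    design = CohortDesign(
        groups=("responder", "nonresponder"), n_per_cell=(2, 2),
        timepoints=("baseline",),
        effects=[Effect(pair=("O1", "O2"), delta=0.6, group="responder")],
        background_coherence=0.35, subject_sd=0.05, duration=10.0, seed=3)
    for _sid, _grp, _tp, cfg, truth in subject_configs(design):
        for key, val in truth.items():
            assert 0.0 <= val <= 1.0, key
        for src in cfg.sources:
            assert np.all(np.isfinite(src.weights))


def test_iss_labels_follow_strict_decrease_rule():
    design = CohortDesign(groups=("treated", "untreated"),
                          n_per_cell=(9, 9), n_responders=5,
                          timepoints=("baseline",), duration=10.0, seed=2)
    from rettnet.simulate import generate_clinical_table
    table = generate_clinical_table(design)
    treated = table[table["group"] == "treated"]
    improved = treated["iss_t2"] < treated["iss_t1"]
    assert (treated.loc[improved, "responder"] == "responder").all()
    assert (treated.loc[~improved, "responder"] == "nonresponder").all()
    assert (treated["responder"] == "responder").sum() == 5
    assert table.loc[table["group"] == "untreated", "responder"].isna().all()
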
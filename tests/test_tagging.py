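import numpy as np
import pytest

import tdcircuit as tc
from tdcircuit.core import SpikeTrain
from tdcircuit.synthetic import sample_task_protocol, TaskProtocol
from tdcircuit.tagging import (UnitQCMetrics, WaveformPair, classify_odor_responsive,
                               classify_optotagged, collision_test,
                               first_significant_bin, latency_significance_test,
                               waveform_similarity)


def _poisson_train(rng, rate, duration):
    return np.sort(rng.uniform(0.0, duration, rng.poisson(rate * duration)))


ONSETS = 10.0 + 3.0 * np.arange(60)
BASELINE = [(ONSETS[-1] + 20.0, ONSETS[-1] + 520.0)]
DURATION = BASELINE[0][1] + 10.0


# ---------------------------------------------------------------------------
# latency test
# ---------------------------------------------------------------------------

def test_latency_null_p_values_roughly_uniform(rng):
    ps = []
    for i in range(200):
        st = _poisson_train(rng, 5.0, DURATION)
        ps.append(latency_significance_test(SpikeTrain("u", st), ONSETS,
                                            (0.001, 0.020), BASELINE,
                                            n_perm=300, seed=i))
    ps = np.array(ps)
    # stochastically >= uniform but not grossly conservative
    assert 0.40 <= ps.mean() <= 0.62
    assert np.mean(ps < 0.05) <= 0.10


def test_latency_power_on_injected_response(rng):
    hits = 0
    for i in range(50):
        st = _poisson_train(rng, 5.0, DURATION)
        evoked = ONSETS + np.clip(0.003 + 0.0005 * rng.standard_normal(60), 1e-4, None)
        st = np.sort(np.concatenate([st, evoked]))
        p = latency_significance_test(SpikeTrain("u", st), ONSETS, (0.002, 0.006),
                                      BASELINE, n_perm=300, seed=i)
        hits += p < 0.01
    assert hits >= 47


def test_latency_degenerate_unit():
    p = latency_significance_test(SpikeTrain("u", []), ONSETS, (0.001, 0.020),
                                  BASELINE, n_perm=100, seed=0)
    assert p == 1.0
    with pytest.raises(ValueError):
        latency_significance_test(SpikeTrain("u", []), ONSETS, (0.001, 0.020), None)


# ---------------------------------------------------------------------------
# first significant bin
# ---------------------------------------------------------------------------

def test_first_significant_bin_flat_and_injected(rng):
    flat = SpikeTrain("u", _poisson_train(rng, 5.0, DURATION))
    assert first_significant_bin(flat, ONSETS, BASELINE, seed=0) is None
    evoked = ONSETS + 0.0095 + 0.0001 * rng.standard_normal(60)
    unit = SpikeTrain("u", np.sort(np.concatenate([flat.times, evoked])))
    t_resp = first_significant_bin(unit, ONSETS, BASELINE, seed=0)
    assert t_resp == pytest.approx(0.009, abs=1e-12)
    # threshold is strict: an unreachable threshold finds nothing
    assert first_significant_bin(unit, ONSETS, BASELINE, seed=0,
                                 z_threshold=np.inf) is None


# ---------------------------------------------------------------------------
# collision test
# ---------------------------------------------------------------------------

def test_collision_vacuous_pass():
    # unit with only evoked spikes: no spontaneous spike in any pre-window
    unit = SpikeTrain("u", ONSETS + 0.0095)
    assert collision_test(unit, ONSETS, t_resp=0.009)


def test_collision_antidromic_units_pass(optotag_session):
    ses = optotag_session
    for u in ses.units:
        if u.truth != "antidromic":
            continue
        t_resp = first_significant_bin(u.spikes, ses.light_onsets,
                                       ses.baseline_intervals, seed=0)
        assert t_resp is not None
        assert collision_test(u.spikes, ses.light_onsets, t_resp)


def test_collision_rejects_mimics_at_analytic_rate():
    """Orthodromic mimics fail at the closed-form collision probability."""
    n_sims = 150
    fails = 0
    for i in range(n_sims):
        ses = tc.simulate_optotag_session(n_tagged=0, n_untagged=1,
                                          mimic_fraction=1.0, latency_jitter=1e-4,
                                          spont_rate=5.0, n_light_trials=120,
                                          seed=5000 + i, baseline_duration=60.0)
        u = ses.units[0]
        fails += not collision_test(u.spikes, ses.light_onsets, t_resp=0.009)
    # analytic failure probability: at least one trial has a spontaneous
    # spike in the 5 ms collision window AND a spike in the response bin
    p_coll = 1 - np.exp(-5.0 * 0.005)
    p_fail = 1 - (1 - p_coll) ** 120
    assert p_fail >= 0.95
    se = np.sqrt(p_fail * (1 - p_fail) / n_sims)
    assert fails / n_sims == pytest.approx(p_fail, abs=4 * se + 0.02)


# ---------------------------------------------------------------------------
# waveforms
# ---------------------------------------------------------------------------

def test_waveform_similarity_limits(rng):
    w = rng.standard_normal(60)
    assert waveform_similarity(WaveformPair(w, w.copy())) == pytest.approx(1.0)
    assert waveform_similarity(WaveformPair(w, -w)) == pytest.approx(-1.0)
    with pytest.raises(ValueError):
        waveform_similarity(WaveformPair(np.zeros(60), w))


def test_waveform_similarity_at_snr10(rng):
    template = np.sin(np.linspace(0, 3 * np.pi, 60))
    sd = template.std() / 10.0
    good = sum(
        waveform_similarity(WaveformPair(template + sd * rng.standard_normal(60),
                                         template + sd * rng.standard_normal(60))) > 0.9
        for _ in range(200))
    assert good >= 190


# ---------------------------------------------------------------------------
# full tagging decision
# ---------------------------------------------------------------------------

def _decide(ses, u, **kw):
    qc = UnitQCMetrics(u.isi_viol, u.amplitude_cutoff, u.presence_ratio, u.mean_rate)
    wf = WaveformPair(u.evoked_mean, u.spontaneous_mean)
    return classify_optotagged(u.spikes, ses.light_block1, ses.light_block2,
                               ses.baseline_intervals, qc, wf, seed=11, **kw)


def test_classify_optotagged_separates_ground_truth(optotag_session):
    ses = optotag_session
    for u in ses.units:
        d = _decide(ses, u)
        assert d.tagged == (u.truth == "antidromic"), (u.unit_id, u.truth, d)
        # decision is the AND of its criteria
        assert d.tagged == (d.latency_p_block1 < 0.01 and d.latency_p_block2 < 0.01
                            and d.qc_pass and d.waveform_r >= 0.9
                            and d.collision_pass and d.rate_pass)


def test_classify_optotagged_is_monotone_in_thresholds(optotag_session):
    ses = optotag_session
    unit = next(u for u in ses.units if u.truth == "antidromic")
    base = _decide(ses, unit)
    assert base.tagged
    relaxed = _decide(ses, unit, alpha=0.05, waveform_threshold=0.5,
                      rate_limits=(0.01, 100.0))
    assert relaxed.tagged  # relaxing any threshold never un-tags


def test_qc_thresholds_are_strict(optotag_session):
    ses = optotag_session
    unit = next(u for u in ses.units if u.truth == "antidromic")
    qc_bad = UnitQCMetrics(0.5, unit.amplitude_cutoff, unit.presence_ratio,
                           unit.mean_rate)
    assert not qc_bad.passes()  # isi_viol = 0.5 fails the strict inequality
    wf = WaveformPair(unit.evoked_mean, unit.spontaneous_mean)
    d = classify_optotagged(unit.spikes, ses.light_block1, ses.light_block2,
                            ses.baseline_intervals, qc_bad, wf, seed=11)
    assert not d.tagged


def test_single_block_response_is_not_tagged(rng):
    """A unit locked to light only in block 1 fails the two-block criterion."""
    ses = tc.simulate_optotag_session(n_tagged=1, n_untagged=0, seed=21)
    u = ses.units[0]
    # strip evoked spikes from block 2 (keep only spikes away from its onsets)
    st = u.spikes.times.copy()
    for onset in ses.light_block2.times:
        st = st[(st < onset + 0.005) | (st > onset + 0.015)]
    hacked = SpikeTrain(u.unit_id, st)
    qc = UnitQCMetrics(u.isi_viol, u.amplitude_cutoff, u.presence_ratio, u.mean_rate)
    wf = WaveformPair(u.evoked_mean, u.spontaneous_mean)
    d = classify_optotagged(hacked, ses.light_block1, ses.light_block2,
                            ses.baseline_intervals, qc, wf, seed=11)
    assert d.latency_p_block1 < 0.01 and d.latency_p_block2 > 0.01
    assert not d.tagged


# ---------------------------------------------------------------------------
# odor responsiveness
# ---------------------------------------------------------------------------

def _trials_for_odor_test(seed=0):
    return sample_task_protocol(TaskProtocol(), seed=seed)


def test_odor_classifier_null_units_rarely_flagged(rng):
    trials = _trials_for_odor_test()
    duration = trials.odor_onset_s.max() + 30.0
    flagged = 0
    n = 300
    for _ in range(n):
        st = SpikeTrain("u", _poisson_train(rng, 4.0, duration))
        res = classify_odor_responsive(st, trials, "CSplus")
        flagged += res.excited or res.inhibited
    assert flagged / n <= 0.01 + 3 * np.sqrt(0.01 * 0.99 / n)


def test_odor_classifier_power_and_direction(rng):
    trials = _trials_for_odor_test()
    duration = trials.odor_onset_s.max() + 30.0
    onsets = trials.loc[trials.trial_type.str.startswith("CSplus"),
                        "odor_onset_s"].to_numpy()
    excited = 0
    for i in range(60):
        st = _poisson_train(rng, 2.0, duration)
        extra = np.concatenate([o + np.sort(rng.uniform(0, 1, rng.poisson(4.0)))
                                for o in onsets])
        unit = SpikeTrain("u", np.sort(np.concatenate([st, extra])))
        res = classify_odor_responsive(unit, trials, "CSplus")
        excited += res.excited and not res.inhibited
    assert excited >= 58  # 2 -> 6 Hz in the first second, 80 trials

    # rate drop: inhibited, not excited
    st = _poisson_train(rng, 6.0, duration)
    keep = np.ones(st.size, bool)
    for o in onsets:
        in_win = (st >= o) & (st < o + 1.0)
        keep &= ~(in_win & (rng.random(st.size) < 2 / 3))
    unit = SpikeTrain("u", st[keep])
    res = classify_odor_responsive(unit, trials, "CSplus")
    assert res.inhibited and not res.excited


def test_odor_classifier_requires_trials():
    trials = _trials_for_odor_test().head(10)
    with pytest.raises(ValueError):
        classify_odor_responsive(SpikeTrain("u", [1.0]), trials, "CSplus")
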
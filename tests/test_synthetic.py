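import numpy as np
import pandas as pd
import pytest
from scipy.signal import lfilter

import tdcircuit as tc
from tdcircuit.core import EventTable, UniformTimeSeries
from tdcircuit.synthetic import (GroundTruthCircuit, TaskProtocol, pattern_value_traces,
                                 sample_truncated_exp, truncated_exp_rate)
from tdcircuit.td import TDParameters


# ---------------------------------------------------------------------------
# trial tables
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("seed", [0, 1, 99])
def test_trial_counts_exact_for_every_seed(seed):
    trials = tc.sample_task_protocol(TaskProtocol(), seed=seed)
    counts = trials.trial_type.value_counts().to_dict()
    assert counts == {"CSminus": 80, "CSplus_stim": 60, "CSplus_omit": 20}
    assert trials.odor_onset_s.is_monotonic_increasing
    itis = np.diff(np.concatenate([[0.0], trials.odor_onset_s.to_numpy()]))
    assert itis.min() >= 8.5 and itis.max() <= 20.5


def test_trial_table_deterministic_and_rejects_fractional_split(tmp_path):
    a = tc.sample_task_protocol(TaskProtocol(), seed=7)
    b = tc.sample_task_protocol(TaskProtocol(), seed=7)
    pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
    a.to_csv(pa, index=False)
    b.to_csv(pb, index=False)
    assert pa.read_bytes() == pb.read_bytes()
    with pytest.raises(ValueError):
        tc.sample_task_protocol(TaskProtocol(n_cs_plus=79), seed=0)


def test_truncated_exponential_calibration(rng):
    lam = truncated_exp_rate(4.0, 12.0)
    # naive truncation of a mean-4 exponential at 12 s would give mean ~3.37 s
    assert lam < 0.25
    x = sample_truncated_exp(30000, 4.0, 12.0, rng)
    assert 0 <= x.min() and x.max() <= 12.0
    assert x.mean() == pytest.approx(4.0, abs=0.1)


# ---------------------------------------------------------------------------
# stimulation patterns
# ---------------------------------------------------------------------------

def test_stim_pattern_catalog():
    pats = tc.generate_stim_patterns()
    assert [p.n_pulses for p in pats] == [20, 40, 40, 40, 15, 30, 60]
    # pattern 1: exactly 20 pulses inside 1 s
    assert pats[0].pulse_times.max() < 1.0
    # patterns 5-7 span 3 s
    for p, rate in zip(pats[4:], (5, 10, 20)):
        assert p.pulse_times.max() < 3.0
        assert p.n_pulses == rate * 3
    # up-ramp starts at zero rate: no pulse at t=0, count = integral of rate
    up = pats[2]
    assert up.pulse_times[0] > 0.0
    assert abs(up.n_pulses - 0.5 * 40 * 2.0) <= 1
    # all pulses 1 ms
    assert all(p.pulse_width == 0.001 for p in pats)


# ---------------------------------------------------------------------------
# value learning
# ---------------------------------------------------------------------------

def _many_sessions(n, alpha_seed=0):
    proto = TaskProtocol()
    return pd.concat([tc.sample_task_protocol(proto, seed=alpha_seed + s)
                      for s in range(n)], ignore_index=True)


def test_value_learning_fixed_point_and_null_cases():
    trials = _many_sessions(300)
    res = tc.simulate_value_learning(trials, gamma=0.8, alpha=0.05, state_dt=0.1)
    # analytic TD(0) fixed point: p(stim) * R * gamma**delay
    assert res.value_plus[0] == pytest.approx(0.75 * 0.8 ** 1.5, abs=0.02)
    # CS- states never followed by reward stay at zero
    assert np.all(res.value_minus == 0.0)
    # cue value rises from zero toward the fixed point
    assert res.cue_value_history[0] == 0.0
    assert res.cue_value_history[-1] > 0.9 * res.value_plus[0]
    # alpha = 0: no update ever
    frozen = tc.simulate_value_learning(trials, gamma=0.8, alpha=0.0)
    assert np.all(frozen.value_plus == 0.0)
    with pytest.raises(ValueError):
        tc.simulate_value_learning(trials, gamma=0.8, alpha=1.5)


# ---------------------------------------------------------------------------
# D1 population
# ---------------------------------------------------------------------------

def test_d1_population_rates_and_determinism():
    dt = 0.001
    zero_drive = UniformTimeSeries(0.0, dt, np.zeros(300_000))
    trains = tc.simulate_d1_population(zero_drive, n_units=3, baseline_rate=4.0,
                                       gain=1.0, seed=0)
    for tr in trains:
        rate = tr.n / 300.0
        assert rate == pytest.approx(4.0, abs=3 * np.sqrt(4.0 / 300.0))
    again = tc.simulate_d1_population(zero_drive, n_units=3, baseline_rate=4.0,
                                      gain=1.0, seed=0)
    for a, b in zip(trains, again):
        np.testing.assert_array_equal(a.times, b.times)
    with pytest.raises(ValueError):
        tc.simulate_d1_population(zero_drive, 1, baseline_rate=-1.0, gain=1.0, seed=0)


def test_d1_population_tracks_drive_plateau():
    """Trial-averaged rate during a 20 Hz plateau matches baseline + gain*20."""
    pattern7 = tc.generate_stim_patterns()[6]  # 20 Hz, 3 s train
    drive = tc.smooth_pulse_train(pattern7, dt=0.001, t0=0.0, t_end=3.5)
    n_units = 200
    trains = tc.simulate_d1_population(drive, n_units=n_units, baseline_rate=3.0,
                                       gain=1.0, seed=1)
    lo, hi = 0.5, 2.5  # interior plateau
    counts = sum(tr.count_in(lo, hi) for tr in trains)
    expected = n_units * (hi - lo) * (3.0 + 1.0 * 20.0)
    assert counts == pytest.approx(expected, abs=4 * np.sqrt(expected))


# ---------------------------------------------------------------------------
# dopamine responses
# ---------------------------------------------------------------------------

def _oracle_dopamine(v: np.ndarray, dt: float, gamma: float, tau: float,
                     gain: float) -> np.ndarray:
    """Independent discrete-convolution oracle for the ground-truth circuit."""
    # TD kernel applied to edge-padded trace, then exponential smoothing by
    # explicit convolution with a long truncated kernel.
    kernel = np.array([1.0 / dt + np.log(gamma), -1.0 / dt])
    padded = np.concatenate([[v[0]], v])
    td = np.convolve(padded, kernel)[1:1 + v.size]
    a = np.exp(-dt / tau)
    n_k = int(40 * tau / dt)
    smooth_k = (1 - a) * a ** np.arange(n_k)
    return gain * np.convolve(td, smooth_k)[: v.size]


def test_dopamine_response_matches_convolution_oracle():
    u = pattern_value_traces(dt=0.001)[0]
    circ = GroundTruthCircuit(gamma_true=0.5, smoothing_time_constant=0.15,
                              gain=1.7, output_noise_sd=0.0)
    out = tc.simulate_dopamine_response(u, circ)
    oracle = _oracle_dopamine(u.values, u.dt, 0.5, 0.15, 1.7)
    rel = np.max(np.abs(out.values - oracle)) / np.max(np.abs(oracle))
    assert rel < 1e-6


def test_dopamine_steady_state_and_linearity():
    dt = 0.001
    v = np.concatenate([np.zeros(100), np.full(6000, 3.0)])
    u = UniformTimeSeries(0.0, dt, v)
    # gamma=1: pure smoothed derivative returns to zero
    out1 = tc.simulate_dopamine_response(u, GroundTruthCircuit(gamma_true=1.0))
    assert abs(out1.values[-1]) < 1e-9
    # gamma=0.5: steady state = gain * ln(0.5) * v
    circ = GroundTruthCircuit(gamma_true=0.5, gain=2.0)
    out = tc.simulate_dopamine_response(u, circ)
    assert out.values[-1] == pytest.approx(2.0 * np.log(0.5) * 3.0, rel=1e-6)
    # linearity: doubling the input doubles the output pointwise
    out2 = tc.simulate_dopamine_response(u.with_values(2 * v), circ)
    np.testing.assert_allclose(out2.values, 2 * out.values, rtol=1e-12, atol=1e-12)
    with pytest.raises(ValueError):
        GroundTruthCircuit(gamma_true=0.0)


def test_dopamine_spiking_rates():
    dt = 0.001
    u = UniformTimeSeries(0.0, dt, np.zeros(200_000))
    circ = GroundTruthCircuit(gamma_true=0.5, baseline_rate=6.0)
    trains = tc.simulate_dopamine_spiking(u, circ, n_units=2, seed=5)
    for tr in trains:
        assert tr.n / 200.0 == pytest.approx(6.0, abs=3 * np.sqrt(6.0 / 200.0))


# ---------------------------------------------------------------------------
# raw photometry
# ---------------------------------------------------------------------------

def test_raw_photometry_flat_and_deterministic():
    ev = EventTable.from_times([], "none")
    raw, ctrl = tc.simulate_raw_photometry(ev, duration=120.0, noise_sd=0.0,
                                           drift_slope=0.0, drift_sine_amp=0.0)
    assert ctrl is None
    dff = tc.compute_dff(raw)
    assert np.max(np.abs(dff.values)) < 1e-12
    ev2 = EventTable.from_times([50.0], "r")
    a, _ = tc.simulate_raw_photometry(ev2, duration=100.0, noise_sd=0.3, seed=9)
    b, _ = tc.simulate_raw_photometry(ev2, duration=100.0, noise_sd=0.3, seed=9)
    np.testing.assert_array_equal(a.values, b.values)


def test_raw_photometry_transient_recovered_by_dff():
    ev = EventTable.from_times([60.0, 150.0], "reward")
    raw, _ = tc.simulate_raw_photometry(ev, amplitude=0.20, duration=240.0,
                                        noise_sd=0.0)
    dff = tc.compute_dff(raw)
    assert dff.values.max() == pytest.approx(0.20, rel=0.05)


# ---------------------------------------------------------------------------
# optotag session generator
# ---------------------------------------------------------------------------

def test_optotag_generator_enforces_collisions(optotag_session):
    ses = optotag_session
    onsets = ses.light_onsets.times
    for u in ses.units:
        if u.truth != "antidromic":
            continue
        st = u.spikes.times
        for onset in onsets:
            t_ev = onset + 0.0095
            prior = np.searchsorted(st, t_ev - 0.007) < np.searchsorted(st, t_ev - 0.002)
            if prior:
                resp = np.searchsorted(st, t_ev + 0.0015) - np.searchsorted(st, t_ev - 0.0015)
                assert resp == 0


def test_optotag_latency_statistics():
    ses = tc.simulate_optotag_session(n_tagged=4, n_untagged=0, seed=11,
                                      latency_jitter=0.0004, spont_rate=0.5)
    onsets = ses.light_onsets.times
    for u in ses.units:
        lat = []
        for onset in onsets:
            st = u.spikes.times
            i0, i1 = np.searchsorted(st, [onset + 0.005, onset + 0.014])
            if i1 > i0:
                lat.append(st[i0] - onset)
        lat = np.array(lat)
        assert lat.mean() == pytest.approx(0.0095, abs=0.0005)
        assert lat.std() == pytest.approx(0.0004, rel=0.4)


def test_optotag_mimic_ignores_collisions():
    ses = tc.simulate_optotag_session(n_tagged=0, n_untagged=20, mimic_fraction=1.0,
                                      mimic_response_prob=1.0, seed=13)
    onsets = ses.light_onsets.times
    responded = 0
    for u in ses.units:
        st = u.spikes.times
        hits = np.searchsorted(st, onsets + 0.012) - np.searchsorted(st, onsets + 0.007)
        responded += int(np.all(hits >= 1))
    assert responded == 20  # mimics respond on every trial, collisions or not
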
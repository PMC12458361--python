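"""Synthetic generators for every input the analysis pipeline consumes.

The generators emulate an opto-conditioning experiment in which odor cues
predict optogenetic stimulation of striatal D1 neurons, whose activity
drives dopamine through a ground-truth temporal-difference (TD) filter:

* trial tables for the conditioning task (CS+ / CS-, 75% stimulated,
  truncated-exponential inter-trial intervals),
* the seven optogenetic pulse-train patterns used to probe the circuit,
* tabular TD(0) value learning on a tapped-delay-line state space,
* D1-neuron spike trains that follow their drive with no dynamics,
* dopamine responses produced by a causal, low-pass-smoothed TD filter
  with known discount factor, as noisy traces or as spike trains,
* optotagging sessions with ground-truth antidromic units, orthodromic
  mimics and untagged units, and
* raw drifting photometry for testing dF/F extraction.

All randomness flows through ``numpy.random.default_rng(seed)``; a fixed
seed reproduces every output bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.signal import lfilter

from .core import EventTable, SpikeTrain, UniformTimeSeries
from .td import StimPattern, TDParameters, smooth_pulse_train, td_error_continuous

__all__ = [
    "TaskProtocol",
    "GroundTruthCircuit",
    "truncated_exp_rate",
    "sample_truncated_exp",
    "sample_task_protocol",
    "generate_stim_patterns",
    "simulate_value_learning",
    "ValueLearningResult",
    "simulate_d1_population",
    "simulate_dopamine_response",
    "simulate_dopamine_spiking",
    "simulate_optotag_session",
    "OptotagSession",
    "UnitRecord",
    "simulate_raw_photometry",
    "pattern_value_traces",
    "generate_pattern_responses",
]

GENERATOR_VERSION = "1.0"


# ---------------------------------------------------------------------------
# task protocol and trial tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TaskProtocol:
    """Opto-conditioning session layout.

    Defaults reproduce the conditioning design: 80 CS+ and 80 CS- trials,
    75% of CS+ trials stimulated, 1 s odor + 0.5 s trace, and a total ITI
    of 8.5 s fixed plus a truncated-exponential component whose
    *post-truncation* mean is 4 s (max 12 s), i.e. total ITI in
    [8.5, 20.5] s with mean 12.5 s.
    """

    n_cs_plus: int = 80
    n_cs_minus: int = 80
    stim_probability: float = 0.75
    odor_duration: float = 1.0
    trace_duration: float = 0.5
    iti_fixed: float = 8.5
    iti_exp_mean: float = 4.0
    iti_exp_max: float = 12.0
    stim_pulse_rate: float = 40.0
    stim_train_duration: float = 0.5
    n_free_stim: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.stim_probability <= 1):
            raise ValueError("stim_probability must be in [0, 1]")
        for name in ("odor_duration", "trace_duration", "iti_fixed", "iti_exp_mean",
                     "iti_exp_max", "stim_train_duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def outcome_delay(self) -> float:
        return self.odor_duration + self.trace_duration

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(asdict(self), f, indent=1)

    @classmethod
    def from_json(cls, path) -> "TaskProtocol":
        with open(path) as f:
            return cls(**json.load(f))


def truncated_exp_rate(target_mean: float, t_max: float) -> float:
    """Rate of an exponential truncated at ``t_max`` whose truncated mean is ``target_mean``.

    Naive truncation lowers the mean (a mean-4 exponential cut at 12 s has
    mean ~3.37 s), so the rate is calibrated by 1-D root finding.
    """
    if not (0 < target_mean < t_max / 2):
        raise ValueError("need 0 < target_mean < t_max/2 for a valid truncated mean")

    def trunc_mean(lam: float) -> float:
        with np.errstate(over="ignore"):
            return 1.0 / lam - t_max / np.expm1(lam * t_max)

    return brentq(lambda lam: trunc_mean(lam) - target_mean, 1e-8, 1e3 / t_max, xtol=1e-12)


def sample_truncated_exp(n: int, target_mean: float, t_max: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Inverse-CDF draws from the calibrated truncated exponential."""
    lam = truncated_exp_rate(target_mean, t_max)
    u = rng.random(n)
    return -np.log1p(-u * (-np.expm1(-lam * t_max))) / lam


def sample_task_protocol(protocol: TaskProtocol, seed: int) -> pd.DataFrame:
    """One session's trial table under the protocol.

    Stimulated/omission CS+ trials are an exact partition (not per-trial
    coin flips), so every session has exactly
    ``stim_probability * n_cs_plus`` stimulated trials; the trial order is
    a seeded pseudo-random interleaving.  Each ITI is
    ``iti_fixed + truncated-exponential`` draw.

    Returns a DataFrame with columns ``trial_index``, ``trial_type``,
    ``odor_onset_s``, ``outcome_onset_s`` (NaN where no outcome occurs).
    """
    n_stim_f = protocol.stim_probability * protocol.n_cs_plus
    n_stim = round(n_stim_f)
    if abs(n_stim_f - n_stim) > 1e-9:
        raise ValueError("stim_probability * n_cs_plus must be an integer "
                         "(stimulation assignment is an exact partition)")
    rng = np.random.default_rng(seed)
    types = (["CSplus_stim"] * n_stim
             + ["CSplus_omit"] * (protocol.n_cs_plus - n_stim)
             + ["CSminus"] * protocol.n_cs_minus)
    types = list(rng.permutation(np.array(types, dtype=object)))
    types += ["free_stim"] * protocol.n_free_stim

    n_trials = len(types)
    itis = protocol.iti_fixed + sample_truncated_exp(
        n_trials, protocol.iti_exp_mean, protocol.iti_exp_max, rng)
    onsets = np.cumsum(itis)
    outcome = np.full(n_trials, np.nan)
    for i, tt in enumerate(types):
        if tt in ("CSplus_stim", "CSplus_omit"):
            outcome[i] = onsets[i] + protocol.outcome_delay
        elif tt == "free_stim":
            outcome[i] = onsets[i]
    return pd.DataFrame({
        "trial_index": np.arange(n_trials),
        "trial_type": types,
        "odor_onset_s": onsets,
        "outcome_onset_s": outcome,
    })


# ---------------------------------------------------------------------------
# stimulation patterns
# ---------------------------------------------------------------------------

def generate_stim_patterns(dt: float = 0.001, ramp_duration: float = 2.0,
                           pulse_width: float = 0.001) -> list[StimPattern]:
    """The seven optogenetic pulse-train patterns used to probe the circuit.

    1. 1 s train at 20 Hz          5. 3 s train at 5 Hz
    2. 2 s train at 20 Hz          6. 3 s train at 10 Hz
    3. linear ramp 0 -> 40 Hz       7. 3 s train at 20 Hz
    4. linear ramp 40 -> 0 Hz

    Ramp pulse times are found by integrating the instantaneous rate: the
    k-th pulse fires when the cumulative rate crosses k, so a ramp that
    starts at 0 Hz emits no pulse at t = 0.  All pulses are 1 ms wide.
    """
    if dt > pulse_width:
        raise ValueError("dt must be at most the pulse width (1 ms)")

    def const_train(rate: float, duration: float) -> np.ndarray:
        n = int(round(rate * duration))
        return np.arange(n) / rate

    def ramp_train(r0: float, r1: float, duration: float) -> np.ndarray:
        # cumulative rate C(t) = r0 t + (r1-r0) t^2 / (2 T); pulses at C(t)=k
        grid = np.arange(0.0, duration + dt / 2, dt)
        cum = r0 * grid + (r1 - r0) * grid ** 2 / (2 * duration)
        ks = np.arange(1, int(np.floor(cum[-1])) + 1)
        return np.interp(ks, cum, grid)

    specs = [
        (1, const_train(20, 1.0), "20 Hz, 1 s"),
        (2, const_train(20, 2.0), "20 Hz, 2 s"),
        (3, ramp_train(0, 40, ramp_duration), f"ramp 0->40 Hz, {ramp_duration:g} s"),
        (4, ramp_train(40, 0, ramp_duration), f"ramp 40->0 Hz, {ramp_duration:g} s"),
        (5, const_train(5, 3.0), "5 Hz, 3 s"),
        (6, const_train(10, 3.0), "10 Hz, 3 s"),
        (7, const_train(20, 3.0), "20 Hz, 3 s"),
    ]
    return [StimPattern(label=lbl, pulse_times=t, pulse_width=pulse_width, description=d)
            for lbl, t, d in specs]


def stim_patterns_to_csv(patterns: list[StimPattern], path) -> None:
    rows = [(p.label, t, p.pulse_width) for p in patterns for t in p.pulse_times]
    pd.DataFrame(rows, columns=["pattern", "pulse_time_s", "pulse_width_s"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# value learning (tabular TD(0) on a tapped delay line)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ValueLearningResult:
    """Per-trial value traces from TD(0) on the complete-serial-compound states."""

    state_dt: float
    state_times: np.ndarray          # seconds from odor onset
    traces: dict                     # trial_type -> (n_trials, n_states) pre-update values
    value_plus: np.ndarray           # final CS+ value table
    value_minus: np.ndarray          # final CS- value table
    cue_value_history: np.ndarray    # V(cue-onset state) before each CS+ trial


def simulate_value_learning(trials: pd.DataFrame, gamma: float, alpha: float,
                            state_dt: float = 0.1, reward_magnitude: float = 1.0,
                            outcome_delay: float | None = None) -> ValueLearningResult:
    """Tabular TD(0) over the session's trials.

    Each odor has its own tapped-delay-line (complete serial compound)
    chain spanning odor onset to the outcome time; stimulation acts as a
    unit reward delivered at the outcome state on stimulated trials.  The
    per-step discount is ``gamma ** state_dt`` (gamma is per second), so
    the CS+ cue-onset value converges to
    ``p(stim) * reward * gamma ** delay``.
    """
    if not (0 <= alpha <= 1):
        raise ValueError("alpha must be in [0, 1] (0 disables learning)")
    if not (0 < gamma <= 1):
        raise ValueError("gamma must be in (0, 1]")
    if outcome_delay is None:
        plus = trials.loc[trials.trial_type.str.startswith("CSplus")]
        if plus.outcome_onset_s.notna().any():
            outcome_delay = float(
                (plus.outcome_onset_s - plus.odor_onset_s).dropna().iloc[0])
        else:
            outcome_delay = 1.5
    n_steps = int(round(outcome_delay / state_dt))
    g_step = gamma ** state_dt
    v_plus = np.zeros(n_steps + 1)
    v_minus = np.zeros(n_steps + 1)

    traces: dict[str, list[np.ndarray]] = {}
    cue_hist = []
    for tt in trials.trial_type:
        is_plus = str(tt).startswith("CSplus")
        if not (is_plus or tt == "CSminus"):
            continue
        V = v_plus if is_plus else v_minus
        if is_plus:
            cue_hist.append(V[0])
        traces.setdefault(str(tt), []).append(V.copy())
        rewards = np.zeros(n_steps + 1)
        if tt == "CSplus_stim":
            rewards[n_steps] = reward_magnitude
        # delta_k = R_k + g_step * V[k+1] - V[k], terminal value 0
        v_next = np.append(V[1:], 0.0)
        delta = rewards + g_step * v_next - V
        V += alpha * delta

    return ValueLearningResult(
        state_dt=state_dt,
        state_times=state_dt * np.arange(n_steps + 1),
        traces={k: np.array(v) for k, v in traces.items()},
        value_plus=v_plus,
        value_minus=v_minus,
        cue_value_history=np.array(cue_hist),
    )


# ---------------------------------------------------------------------------
# ground-truth circuit: D1 population and dopamine output
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroundTruthCircuit:
    """Ground truth for the D1 -> dopamine transformation.

    The noiseless output is ``gain * smooth(dV/dt + ln(gamma_true) V)``
    where the smoothing is a causal single-exponential low pass with the
    given time constant (it renders the improper TD operator realizable).
    """

    gamma_true: float = 0.5
    smoothing_time_constant: float = 0.15
    gain: float = 1.0
    output_noise_sd: float = 0.0
    baseline_rate: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.gamma_true <= 1):
            raise ValueError("gamma_true must be in (0, 1]")
        if self.output_noise_sd < 0:
            raise ValueError("output_noise_sd must be nonnegative")
        if self.smoothing_time_constant <= 0:
            raise ValueError("smoothing_time_constant must be positive")

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(asdict(self), f, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruthCircuit":
        with open(path) as f:
            return cls(**json.load(f))


def _sample_inhomogeneous(rate: np.ndarray, dt: float, t0: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Bernoulli-per-bin sampling of an inhomogeneous point process."""
    p = np.clip(rate, 0.0, None) * dt
    if np.any(p > 1):
        raise ValueError("rate * dt exceeds 1; use a finer grid")
    hits = rng.random(rate.size) < p
    return t0 + dt * np.flatnonzero(hits)


def simulate_d1_population(drive: UniformTimeSeries, n_units: int,
                           baseline_rate: float, gain: float,
                           seed: int) -> list[SpikeTrain]:
    """Independent D1 units firing at ``baseline + gain * drive`` (rectified).

    D1 neurons track their input with essentially no dynamics, so the
    intensity is simply an affine function of the drive.
    """
    if baseline_rate < 0:
        raise ValueError("baseline_rate must be nonnegative")
    rate = np.clip(baseline_rate + gain * drive.values, 0.0, None)
    rng = np.random.default_rng(seed)
    return [SpikeTrain(unit_id=f"d1_{i:03d}",
                       times=_sample_inhomogeneous(rate, drive.dt, drive.t0, rng))
            for i in range(n_units)]


def _td_filter_output(inp: UniformTimeSeries, circuit: GroundTruthCircuit) -> np.ndarray:
    td = td_error_continuous(inp, TDParameters(gamma=circuit.gamma_true, dt=inp.dt))
    a = np.exp(-inp.dt / circuit.smoothing_time_constant)
    smoothed = lfilter([1.0 - a], [1.0, -a], td.values)  # unit-DC causal low pass
    return circuit.gain * smoothed


def simulate_dopamine_response(inp: UniformTimeSeries, circuit: GroundTruthCircuit,
                               seed: int | None = None) -> UniformTimeSeries:
    """Photometry-like dopamine trace driven by ``inp`` through the TD circuit.

    Output = ``gain * lowpass(dV/dt + ln(gamma_true) V) + white noise``.
    For gamma_true = 1 the DC gain is zero (pure smoothed derivative);
    for gamma_true < 1 a sustained input of amplitude v settles at
    ``gain * ln(gamma_true) * v``.
    """
    out = _td_filter_output(inp, circuit)
    if circuit.output_noise_sd > 0:
        rng = np.random.default_rng(circuit.seed if seed is None else seed)
        out = out + rng.normal(0.0, circuit.output_noise_sd, out.size)
    return inp.with_values(out, units="dopamine")


def simulate_dopamine_spiking(inp: UniformTimeSeries, circuit: GroundTruthCircuit,
                              n_units: int, seed: int | None = None) -> list[SpikeTrain]:
    """Spiking variant: baseline + TD output as intensity, rectified, then sampled."""
    rate = np.clip(circuit.baseline_rate + _td_filter_output(inp, circuit), 0.0, None)
    rng = np.random.default_rng(circuit.seed if seed is None else seed)
    return [SpikeTrain(unit_id=f"da_{i:03d}",
                       times=_sample_inhomogeneous(rate, inp.dt, inp.t0, rng))
            for i in range(n_units)]


# ---------------------------------------------------------------------------
# optotagging sessions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UnitRecord:
    """One simulated unit with its ground-truth label and QC inputs."""

    unit_id: str
    truth: str                 # "antidromic" | "mimic" | "untagged"
    spikes: SpikeTrain
    evoked_mean: np.ndarray
    spontaneous_mean: np.ndarray
    isi_viol: float
    amplitude_cutoff: float
    presence_ratio: float
    mean_rate: float


@dataclass(frozen=True)
class OptotagSession:
    """Light-trial blocks, baseline epochs and the simulated units."""

    units: list[UnitRecord]
    light_block1: EventTable
    light_block2: EventTable
    baseline_intervals: list[tuple[float, float]]
    duration: float

    @property
    def light_onsets(self) -> EventTable:
        return EventTable.from_times(
            np.concatenate([self.light_block1.times, self.light_block2.times]), "light")


def _waveform_template(rng: np.random.Generator, n: int = 60) -> np.ndarray:
    """Biphasic extracellular-like template with unit peak-to-peak amplitude."""
    t = np.linspace(-1.0, 2.0, n)
    trough = -np.exp(-((t - 0.0) ** 2) / (2 * 0.12 ** 2))
    hump = (0.35 + 0.15 * rng.random()) * np.exp(-((t - 0.55 - 0.2 * rng.random()) ** 2)
                                                 / (2 * 0.3 ** 2))
    w = trough + hump
    return w / np.ptp(w)


# Collision rule of the generator, relative to the expected evoked-spike time.
# Slightly wider than the 2-7 ms window the downstream collision test uses
# (which is anchored at the estimated response *bin*, not the jittered evoked
# time), so that every trial the test can flag as a collision trial is one on
# which the generator suppressed the antidromic spike.
COLLISION_WINDOW = (-0.0085, -0.001)


def simulate_optotag_session(n_tagged: int, n_untagged: int,
                             latency_mean: float = 0.0095,
                             latency_jitter: float = 0.0002,
                             spont_rate: float = 5.0,
                             n_light_trials: int = 120,
                             seed: int = 0,
                             mimic_fraction: float = 0.5,
                             mimic_response_prob: float = 1.0,
                             baseline_duration: float = 600.0,
                             waveform_noise_sd: float = 0.05) -> OptotagSession:
    """Simulated optotagging session with ground-truth unit identities.

    Tagged (antidromic) units fire one light-locked spike per pulse at
    ``latency_mean +/- latency_jitter`` and obey the collision rule: when
    a spontaneous spike fell shortly (1-8.5 ms) before the expected evoked
    time, the antidromic spike is annihilated and the soma (still
    refractory from the orthodromic spike) emits no spike within 2 ms of
    the expected evoked time.  A ``mimic_fraction`` of untagged units are
    orthodromic mimics that respond at ``mimic_response_prob`` per pulse
    regardless of collisions; the rest ignore light.  Light trials are
    split into two equal blocks at the start and end of the session, with
    a long light-free baseline period between them.
    """
    rng = np.random.default_rng(seed)
    n_b1 = n_light_trials // 2
    n_b2 = n_light_trials - n_b1
    spacing = 3.0
    b1 = 10.0 + spacing * np.arange(n_b1)
    base_start = b1[-1] + 10.0 if n_b1 else 10.0
    b2_start = base_start + baseline_duration
    b2 = b2_start + spacing * np.arange(n_b2)
    duration = (b2[-1] if n_b2 else b2_start) + 10.0
    onsets = np.concatenate([b1, b2])

    n_mimic = int(round(mimic_fraction * n_untagged))
    labels = (["antidromic"] * n_tagged + ["mimic"] * n_mimic
              + ["untagged"] * (n_untagged - n_mimic))

    units: list[UnitRecord] = []
    for i, truth in enumerate(labels):
        spont = np.sort(rng.uniform(0.0, duration, rng.poisson(spont_rate * duration)))
        keep_spont = np.ones(spont.size, dtype=bool)
        evoked = []
        if truth != "untagged":
            for onset in onsets:
                lat = max(1e-4, latency_mean + latency_jitter * rng.standard_normal())
                t_evoked = onset + lat
                if truth == "antidromic":
                    lo, hi = t_evoked + COLLISION_WINDOW[0], t_evoked + COLLISION_WINDOW[1]
                    if np.searchsorted(spont, hi) > np.searchsorted(spont, lo):
                        # collision: antidromic spike annihilated, and the
                        # refractory soma stays silent around the evoked time
                        i0 = np.searchsorted(spont, t_evoked - 0.002)
                        i1 = np.searchsorted(spont, t_evoked + 0.002)
                        keep_spont[i0:i1] = False
                        continue
                elif rng.random() >= mimic_response_prob:
                    continue
                evoked.append(t_evoked)
        spont = spont[keep_spont]
        evoked = np.array(evoked)
        spikes = np.sort(np.concatenate([spont, evoked]))

        template = _waveform_template(rng)
        n_ev = max(len(evoked), 1)
        n_sp = max(len(spont), 1)
        if truth == "untagged":
            # "evoked" average built from whatever chance spikes fall near light
            n_chance = max(int(np.searchsorted(spont, onsets + 0.01).sum()
                               - np.searchsorted(spont, onsets).sum()), 1)
            evoked_mean = template + waveform_noise_sd / np.sqrt(n_chance) \
                * rng.standard_normal(template.size) * np.sqrt(n_sp / n_chance)
        else:
            evoked_mean = template + waveform_noise_sd / np.sqrt(n_ev) \
                * rng.standard_normal(template.size)
        spont_mean = template + waveform_noise_sd / np.sqrt(n_sp) \
            * rng.standard_normal(template.size)

        isi = np.diff(spikes)
        isi_viol = float(np.mean(isi < 0.002)) if isi.size else 0.0
        bins = np.linspace(0, duration, 101)
        presence = float(np.mean(np.histogram(spikes, bins)[0] > 0))
        units.append(UnitRecord(
            unit_id=f"u{i:03d}", truth=truth,
            spikes=SpikeTrain(unit_id=f"u{i:03d}", times=spikes),
            evoked_mean=evoked_mean, spontaneous_mean=spont_mean,
            isi_viol=isi_viol, amplitude_cutoff=float(0.01 + 0.02 * rng.random()),
            presence_ratio=presence, mean_rate=float(spikes.size / duration)))

    return OptotagSession(
        units=units,
        light_block1=EventTable.from_times(b1, "light"),
        light_block2=EventTable.from_times(b2, "light"),
        baseline_intervals=[(base_start + 1.0, b2_start - 1.0)],
        duration=duration,
    )


# ---------------------------------------------------------------------------
# raw photometry
# ---------------------------------------------------------------------------

def simulate_raw_photometry(events: EventTable, amplitude: float = 0.2,
                            duration: float | None = None, fs: float = 20.0,
                            baseline: float = 100.0, transient_tau: float = 1.0,
                            drift_slope: float = -1e-4, drift_sine_amp: float = 0.01,
                            drift_sine_period: float = 120.0,
                            noise_sd: float = 0.0, seed: int = 0,
                            artifact: UniformTimeSeries | None = None,
                            artifact_gain: float = 0.0,
                            ) -> tuple[UniformTimeSeries, UniformTimeSeries | None]:
    """Raw fluorescence at 20 Hz: drifting baseline + event transients + noise.

    Each event adds an exponential transient of *relative* amplitude
    ``amplitude`` (fraction of the local baseline).  When an ``artifact``
    trace is supplied, the signal receives ``artifact_gain * artifact``
    and a control channel carrying the raw artifact is returned alongside,
    for isosbestic-correction tests.
    """
    if duration is None:
        duration = (events.times[-1] if events.n else 0.0) + 30.0
    dt = 1.0 / fs
    t = np.arange(0.0, duration, dt)
    base = baseline * (1.0 + drift_slope * t
                       + drift_sine_amp * np.sin(2 * np.pi * t / drift_sine_period))
    f = base.copy()
    for te in events.times:
        mask = t >= te
        f[mask] += amplitude * base[mask] * np.exp(-(t[mask] - te) / transient_tau)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        f = f + rng.normal(0.0, noise_sd, f.size)
    control = None
    if artifact is not None:
        if artifact.values.size != t.size:
            raise ValueError("artifact trace must match the raw grid")
        f = f + artifact_gain * artifact.values
        cvals = baseline * 0.5 + artifact.values
        if noise_sd > 0:
            cvals = cvals + rng.normal(0.0, noise_sd, cvals.size)
        control = UniformTimeSeries(t0=0.0, dt=dt, values=cvals, units="control")
    return UniformTimeSeries(t0=0.0, dt=dt, values=f, units="F"), control


# ---------------------------------------------------------------------------
# pattern-probe sessions for system identification
# ---------------------------------------------------------------------------

def pattern_value_traces(patterns: list[StimPattern] | None = None, dt: float = 0.001,
                         kernel_sd: float = 0.050, pre: float = 2.0,
                         post: float = 4.0) -> list[UniformTimeSeries]:
    """Smoothed pulse trains with baseline padding, used as fit inputs V(t)."""
    if patterns is None:
        patterns = generate_stim_patterns()
    return [smooth_pulse_train(p, dt=dt, kernel_sd=kernel_sd, t0=-pre,
                               t_end=p.duration + post) for p in patterns]


def generate_pattern_responses(gamma_true: float, snr: float = 10.0,
                               n_neurons: int = 1, seed: int = 0,
                               dt: float = 0.001, tau: float = 0.15,
                               gain: float = 1.0, pre: float = 2.0,
                               post: float = 4.0, noise_sd_smooth: float = 0.050,
                               ) -> tuple[list[UniformTimeSeries], list[list[UniformTimeSeries]]]:
    """Inputs and per-neuron dopamine responses to the 7 stimulation patterns.

    Each neuron's response to each pattern is the noiseless ground-truth
    TD output plus band-limited noise with SD = (overall noiseless signal
    SD)/snr, independent across neurons and patterns.  The noise is white
    noise passed through the same 50 ms Gaussian as the preprocessing
    smoothing stage, because trial-averaged traces entering the fits are
    smoothed signals whose noise is correlated on that time scale -- white
    noise at the sample rate would carry unrealistically much information.
    Returns ``(inputs, neurons)`` where ``neurons[i][j]`` is neuron i's
    response to pattern j.
    """
    from scipy.ndimage import gaussian_filter1d

    # the ground-truth circuit is continuous-time: simulate it on a fine
    # (<= 1 ms) grid and decimate, so the analysis grid does not change the
    # ground truth
    sim_dt = dt if dt <= 0.001 else 0.001
    stride = int(round(dt / sim_dt))
    if abs(stride * sim_dt - dt) > 1e-12:
        raise ValueError("dt must be an integer multiple of 1 ms when above 1 ms")
    inputs_fine = pattern_value_traces(dt=sim_dt, pre=pre, post=post)
    circuit = GroundTruthCircuit(gamma_true=gamma_true, smoothing_time_constant=tau,
                                 gain=gain, output_noise_sd=0.0)
    clean_fine = [simulate_dopamine_response(u, circuit) for u in inputs_fine]

    def _decimate(ts: UniformTimeSeries) -> UniformTimeSeries:
        return UniformTimeSeries(t0=ts.t0, dt=dt, values=ts.values[::stride],
                                 units=ts.units)

    inputs = [_decimate(u) for u in inputs_fine]
    clean = [_decimate(c) for c in clean_fine]
    sd_signal = float(np.std(np.concatenate([c.values for c in clean])))
    noise_sd = sd_signal / snr if snr > 0 else 0.0
    sigma_bins = noise_sd_smooth / dt
    # unit-mass Gaussian filtering shrinks white-noise SD by sqrt(sum k^2)
    kernel_sq = np.sum(gaussian_filter1d(
        np.eye(1, int(16 * sigma_bins) + 1, int(8 * sigma_bins))[0], sigma_bins) ** 2)
    scale = noise_sd / np.sqrt(kernel_sq) if noise_sd > 0 else 0.0
    rng = np.random.default_rng(seed)
    neurons = []
    for _ in range(n_neurons):
        resp = []
        for c in clean:
            if scale > 0:
                noise = gaussian_filter1d(rng.standard_normal(c.n), sigma_bins,
                                          mode="constant") * scale
            else:
                noise = 0.0
            resp.append(c.with_values(c.values + noise))
        neurons.append(resp)
    return inputs, neurons
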
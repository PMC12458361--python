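"""Temporal-difference (TD) error in continuous and discrete time.

The continuous TD error of a value trace V(t), in the absence of reward,
is ``TD(t) = dV/dt + ln(gamma) * V(t)`` with gamma the per-second temporal
discount factor.  At gamma = 1 this is a pure time derivative; for
gamma < 1 sustained value produces a *negative* steady state
``ln(gamma) * V``, the signature that separates TD from a derivative.

On a uniform grid the derivative is discretized as a backward difference,
so the TD operator is a two-tap causal filter
``h[0] = 1/dt + ln(gamma), h[1] = -1/dt`` (the grid realization of
``delta'(t) + ln(gamma) * delta(t)``).  Traces are assumed to sit at their
first sample before the window starts (edge replication), which makes the
TD of a constant trace exactly ``ln(gamma) * V`` from the first sample on.

The discrete-time tabular form ``delta_t = R_t + gamma_step * V(S_{t+1})
- V(S_t)`` and its TD(0) update are provided for the value-learning
simulations; per-step discounting uses ``gamma ** dt`` so that gamma is
always expressed per second.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import UniformTimeSeries

__all__ = [
    "TDParameters",
    "StimPattern",
    "DiscreteTDConfig",
    "td_error_continuous",
    "td_impulse_response",
    "apply_td_filter",
    "td_error_discrete",
    "td_update",
    "smooth_pulse_train",
    "simulate_td_of_patterns",
]


@dataclass(frozen=True)
class TDParameters:
    """Continuous-time TD operator parameters.

    gamma : per-second discount factor in (0, 1].
    dt : grid step used to discretize the derivative, seconds.
    """

    gamma: float
    dt: float

    def __post_init__(self) -> None:
        if not (0 < self.gamma <= 1):
            raise ValueError("gamma must be in (0, 1]")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


@dataclass(frozen=True)
class StimPattern:
    """Optogenetic pulse train: sorted pulse onset times and pulse width."""

    label: int
    pulse_times: np.ndarray
    pulse_width: float = 0.001
    description: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.pulse_times, dtype=float)
        object.__setattr__(self, "pulse_times", t)
        if t.size and np.any(np.diff(t) < 0):
            raise ValueError("pulse times must be sorted")
        if self.pulse_width <= 0:
            raise ValueError("pulse width must be positive")

    @property
    def n_pulses(self) -> int:
        return self.pulse_times.size

    @property
    def duration(self) -> float:
        return float(self.pulse_times[-1]) if self.pulse_times.size else 0.0


@dataclass(frozen=True)
class DiscreteTDConfig:
    """Tabular TD(0) configuration: per-step discount, learning rate, states."""

    gamma_step: float
    alpha: float
    n_states: int

    def __post_init__(self) -> None:
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")
        if not (0 < self.gamma_step <= 1):
            raise ValueError("gamma_step must be in (0, 1]")


# ---------------------------------------------------------------------------
# continuous-time TD
# ---------------------------------------------------------------------------

def td_impulse_response(params: TDParameters) -> np.ndarray:
    """Two-tap grid realization of ``delta'(t) + ln(gamma) delta(t)``.

    Convolving a trace with this kernel (with edge-replicated history)
    reproduces :func:`td_error_continuous` exactly.  Its DC gain (kernel
    sum) is ``ln(gamma)``: zero for gamma = 1.
    """
    return np.array([1.0 / params.dt + np.log(params.gamma), -1.0 / params.dt])


def apply_td_filter(values: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Causal FIR filtering with the pre-window history pinned at values[0]."""
    values = np.asarray(values, float)
    padded = np.concatenate([np.full(kernel.size - 1, values[0] if values.size else 0.0), values])
    return np.convolve(padded, kernel, mode="full")[kernel.size - 1: kernel.size - 1 + values.size]


def td_error_continuous(value: UniformTimeSeries, params: TDParameters,
                        reward: UniformTimeSeries | None = None) -> UniformTimeSeries:
    """TD error trace ``r(t) + dV/dt + ln(gamma) V(t)`` on the value's grid.

    The derivative is a backward difference; the sample before the window
    is taken equal to the first sample, so a constant trace maps to the
    exact steady state ``ln(gamma) * V`` everywhere.
    """
    if value.dt != params.dt:
        params = TDParameters(gamma=params.gamma, dt=value.dt)
    kernel = td_impulse_response(params)
    out = apply_td_filter(value.values, kernel)
    if reward is not None:
        if reward.n != value.n or reward.dt != value.dt:
            raise ValueError("reward trace must share the value trace's grid")
        out = out + reward.values
    return value.with_values(out, units="TD")


# ---------------------------------------------------------------------------
# discrete-time tabular TD(0)
# ---------------------------------------------------------------------------

def td_error_discrete(V: np.ndarray, states: np.ndarray, rewards: np.ndarray,
                      cfg: DiscreteTDConfig) -> np.ndarray:
    """Per-step TD error for a state/reward sequence under value table V.

    ``delta_t = R_t + gamma_step * V(S_{t+1}) - V(S_t)``; the value of the
    post-terminal state is 0.
    """
    states = np.asarray(states, int)
    rewards = np.asarray(rewards, float)
    v_now = V[states]
    v_next = np.append(V[states[1:]], 0.0)
    return rewards + cfg.gamma_step * v_next - v_now


def td_update(V: np.ndarray, states: np.ndarray, delta: np.ndarray,
              cfg: DiscreteTDConfig) -> np.ndarray:
    """One TD(0) sweep ``V(S_t) <- V(S_t) + alpha * delta_t`` (sequential)."""
    V = V.copy()
    for s, d in zip(np.asarray(states, int), np.asarray(delta, float)):
        V[s] += cfg.alpha * d
    return V


# ---------------------------------------------------------------------------
# pulse trains as value proxies
# ---------------------------------------------------------------------------

def smooth_pulse_train(pattern: StimPattern, dt: float, kernel_sd: float = 0.050,
                       t0: float = 0.0, t_end: float | None = None) -> UniformTimeSeries:
    """Instantaneous-rate trace of a pulse train (unit-mass Gaussian per pulse).

    Each pulse contributes a Gaussian of area one, so the interior plateau
    of a constant-rate train equals its rate in Hz and the trace integral
    equals the pulse count.
    """
    from scipy.ndimage import gaussian_filter1d

    if t_end is None:
        t_end = (pattern.duration if pattern.n_pulses else 0.0) + 6 * kernel_sd
    n = int(round((t_end - t0) / dt)) + 1
    x = np.zeros(n)
    if pattern.n_pulses:
        idx = np.round((pattern.pulse_times - t0) / dt).astype(int)
        ok = (idx >= 0) & (idx < n)
        np.add.at(x, idx[ok], 1.0 / dt)
    y = gaussian_filter1d(x, sigma=kernel_sd / dt, mode="constant")
    return UniformTimeSeries(t0=t0, dt=dt, values=y, units="Hz")


def simulate_td_of_patterns(patterns: list[StimPattern], gammas: list[float],
                            dt: float = 0.001, kernel_sd: float = 0.050,
                            pre: float = 2.0, post: float = 4.0,
                            ) -> dict[float, list[UniformTimeSeries]]:
    """TD error of each smoothed pulse train, for each discount factor.

    The smoothed train is treated as the value trace V(t); the result is
    a family of TD traces (one list entry per pattern) keyed by gamma.
    """
    out: dict[float, list[UniformTimeSeries]] = {}
    smoothed = [smooth_pulse_train(p, dt=dt, kernel_sd=kernel_sd, t0=-pre,
                                   t_end=p.duration + post) for p in patterns]
    for g in gammas:
        if not (0 < g <= 1):
            raise ValueError("gammas must lie in (0, 1]")
        out[g] = [td_error_continuous(v, TDParameters(gamma=g, dt=dt)) for v in smoothed]
    return out
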
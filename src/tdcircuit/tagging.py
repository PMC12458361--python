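"""Unit-gating statistics for optogenetic tagging and odor responsiveness.

A unit counts as optotagged when it passes ALL of:

* a light-response latency test (p < 0.01) independently in two blocks of
  light trials delivered at the start and end of the session,
* spike-sorting quality gates: isi_viol < 0.5, amplitude_cutoff < 0.1,
  presence_ratio > 0.9 (strict inequalities, metrics supplied by an
  external sorting pipeline),
* Pearson correlation >= 0.9 between light-evoked and spontaneous mean
  waveforms,
* the antidromic collision test: on trials with a spontaneous spike 2-7 ms
  before the response latency, the response bin must be empty (vacuous
  pass when no such trial exists), and
* mean firing rate strictly between 0.2 and 10 Hz.

The latency test is a permutation test: the post-light latency histogram
(1 ms bins) is compared, via Jensen-Shannon divergence against the pooled
histogram of the others, with many same-sized histograms anchored at
random inter-trial-interval times; since under the null all histograms are
exchangeable, the tail rank yields a valid p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import xlogy
from scipy.stats import mannwhitneyu

from .core import EventTable, SpikeTrain

__all__ = [
    "UnitQCMetrics",
    "WaveformPair",
    "TagDecision",
    "OdorResponseClass",
    "latency_significance_test",
    "first_significant_bin",
    "collision_test",
    "waveform_similarity",
    "classify_optotagged",
    "classify_odor_responsive",
]


@dataclass(frozen=True)
class UnitQCMetrics:
    """Sorting quality metrics (precomputed by the sorting pipeline)."""

    isi_viol: float
    amplitude_cutoff: float
    presence_ratio: float
    mean_rate: float

    def passes(self) -> bool:
        return (self.isi_viol < 0.5 and self.amplitude_cutoff < 0.1
                and self.presence_ratio > 0.9)


@dataclass(frozen=True)
class WaveformPair:
    evoked_mean: np.ndarray
    spontaneous_mean: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.evoked_mean, float)
        s = np.asarray(self.spontaneous_mean, float)
        object.__setattr__(self, "evoked_mean", e)
        object.__setattr__(self, "spontaneous_mean", s)
        if e.shape != s.shape:
            raise ValueError("waveforms must have equal length")
        if not (np.all(np.isfinite(e)) and np.all(np.isfinite(s))):
            raise ValueError("waveforms must be finite")


@dataclass(frozen=True)
class TagDecision:
    unit_id: str
    latency_p_block1: float
    latency_p_block2: float
    t_resp: float | None
    collision_pass: bool
    waveform_r: float
    qc_pass: bool
    rate_pass: bool
    tagged: bool


@dataclass(frozen=True)
class OdorResponseClass:
    odor: str
    excited: bool
    inhibited: bool
    p_right: np.ndarray
    p_left: np.ndarray


# ---------------------------------------------------------------------------
# windowed latency histograms
# ---------------------------------------------------------------------------

def _window_spike_bins(st: np.ndarray, anchors: np.ndarray, lo: float, hi: float,
                       bin_dt: float) -> tuple[np.ndarray, np.ndarray]:
    """(anchor index, bin index) of every spike in [anchor+lo, anchor+hi)."""
    nbins = int(round((hi - lo) / bin_dt))
    i0 = np.searchsorted(st, anchors + lo)
    i1 = np.searchsorted(st, anchors + hi)
    reps = i1 - i0
    total = int(reps.sum())
    if total == 0:
        return np.zeros(0, int), np.zeros(0, int)
    cum = np.cumsum(reps)
    idx = np.arange(total) - np.repeat(cum - reps, reps) + np.repeat(i0, reps)
    which = np.repeat(np.arange(anchors.size), reps)
    rel = st[idx] - (anchors[which] + lo)
    bins = np.minimum((rel / bin_dt).astype(int), nbins - 1)
    return which, bins


def _latency_histogram(st: np.ndarray, anchors: np.ndarray, lo: float, hi: float,
                       bin_dt: float) -> np.ndarray:
    nbins = int(round((hi - lo) / bin_dt))
    _, bins = _window_spike_bins(st, anchors, lo, hi, bin_dt)
    return np.bincount(bins, minlength=nbins).astype(float)


def _first_spike_bins(st: np.ndarray, anchors: np.ndarray, lo: float, hi: float,
                      bin_dt: float) -> np.ndarray:
    """Per-anchor first-spike latency bin; ``nbins`` codes 'no spike'.

    The no-spike category makes the latency histogram a distribution over
    *trials* rather than spikes, so a reliable short-latency response
    separates from the sparse baseline both in shape and in mass.
    """
    nbins = int(round((hi - lo) / bin_dt))
    i0 = np.searchsorted(st, anchors + lo)
    safe = np.minimum(i0, max(st.size - 1, 0))
    if st.size:
        has = (i0 < st.size) & (st[safe] < anchors + hi)
    else:
        has = np.zeros(anchors.size, bool)
    bins = np.full(anchors.size, nbins)
    rel = st[safe] - (anchors + lo) if st.size else np.zeros(anchors.size)
    bins[has] = np.minimum((rel[has] / bin_dt).astype(int), nbins - 1)
    return bins


def _sample_baseline_anchors(intervals: list[tuple[float, float]], n: int,
                             margin: float, rng: np.random.Generator) -> np.ndarray:
    """Uniform anchor times over the ITI intervals (keeping the window inside)."""
    spans = np.array([max(b - a - margin, 0.0) for a, b in intervals])
    if spans.sum() <= 0:
        raise ValueError("baseline intervals too short for the analysis window")
    starts = np.array([a for a, _ in intervals])
    u = rng.random(n) * spans.sum()
    which = np.searchsorted(np.cumsum(spans), u, side="right")
    offset = u - np.concatenate([[0.0], np.cumsum(spans)])[which]
    return starts[which] + offset


def _jsd_leave_one_out(counts: np.ndarray) -> np.ndarray:
    """Jensen-Shannon divergence of each histogram to the pool of the others.

    Rows with zero total get -inf (no distribution; ranks at the bottom,
    which keeps the permutation p-value conservative).
    """
    totals = counts.sum(axis=1)
    pooled = counts.sum(axis=0)
    loo = pooled[None, :] - counts
    loo_tot = totals.sum() - totals
    with np.errstate(invalid="ignore", divide="ignore"):
        p = counts / totals[:, None]
        q = loo / loo_tot[:, None]
        m = 0.5 * (p + q)
        ent = lambda x: -np.sum(xlogy(x, x), axis=1)  # noqa: E731
        d = ent(m) - 0.5 * (ent(p) + ent(q))
    d[(totals == 0) | (loo_tot == 0)] = -np.inf
    return d


def latency_significance_test(spikes: SpikeTrain, light_onsets: EventTable | np.ndarray,
                              response_window: tuple[float, float] = (0.001, 0.020),
                              baseline_intervals: list[tuple[float, float]] | None = None,
                              n_perm: int = 1000, bin_dt: float = 0.001,
                              seed: int = 0) -> float:
    """Permutation p-value for light-locked spike latencies.

    The response histogram -- the distribution over trials of first-spike
    latency in ``response_window`` after light onset (1 ms bins, plus a
    no-spike category) -- is compared with ``n_perm`` equally sized
    histograms anchored at random ITI times.  The statistic is each
    histogram's Jensen-Shannon divergence from the pooled remainder; since
    under the null all histograms are exchangeable, the tail rank of the
    response among the baselines is a valid p-value.  A unit with no
    spikes in any window is degenerate and gets p = 1.
    """
    onsets = light_onsets.times if isinstance(light_onsets, EventTable) else np.asarray(light_onsets)
    if baseline_intervals is None:
        raise ValueError("baseline (ITI) intervals are required")
    lo, hi = response_window
    ncat = int(round((hi - lo) / bin_dt)) + 1  # latency bins + no-spike
    st = spikes.times
    rng = np.random.default_rng(seed)

    resp_bins = _first_spike_bins(st, onsets, lo, hi, bin_dt)
    resp = np.bincount(resp_bins, minlength=ncat).astype(float)
    anchors = _sample_baseline_anchors(baseline_intervals, n_perm * onsets.size,
                                       hi - lo, rng)
    bins = _first_spike_bins(st, anchors, 0.0, hi - lo, bin_dt)
    sets = np.arange(anchors.size) // onsets.size
    base = np.bincount(sets * ncat + bins, minlength=n_perm * ncat) \
        .reshape(n_perm, ncat).astype(float)

    counts = np.vstack([resp, base])
    if counts[:, :-1].sum() == 0:
        return 1.0  # no spikes in any window: degenerate
    d = _jsd_leave_one_out(counts)
    if not np.isfinite(d[0]):
        return 1.0
    return float((1 + np.sum(d[1:] >= d[0])) / (n_perm + 1))


def first_significant_bin(spikes: SpikeTrain, light_onsets: EventTable | np.ndarray,
                          baseline_intervals: list[tuple[float, float]],
                          shuffle_draws: int = 1000, window: float = 0.020,
                          bin_dt: float = 0.001, z_threshold: float = 5.0,
                          seed: int = 0) -> float | None:
    """First post-onset 1 ms bin whose count exceeds the shuffle by > 5 SD.

    Returns the bin's left edge (seconds after light onset), or ``None``
    when no bin qualifies (the threshold is strict: z must exceed 5).
    """
    onsets = light_onsets.times if isinstance(light_onsets, EventTable) else np.asarray(light_onsets)
    st = spikes.times
    rng = np.random.default_rng(seed)
    nbins = int(round(window / bin_dt))
    obs = _latency_histogram(st, onsets, 0.0, window, bin_dt)

    anchors = _sample_baseline_anchors(baseline_intervals, shuffle_draws * onsets.size,
                                       window, rng)
    which, bins = _window_spike_bins(st, anchors, 0.0, window, bin_dt)
    sets = which // onsets.size
    shuf = np.bincount(sets * nbins + bins, minlength=shuffle_draws * nbins) \
        .reshape(shuffle_draws, nbins).astype(float)
    mu = shuf.mean(axis=0)
    sd = shuf.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (obs - mu) / sd
    z[(sd == 0) & (obs > mu)] = np.inf
    z[(sd == 0) & (obs <= mu)] = -np.inf
    hits = np.flatnonzero(z > z_threshold)
    return float(hits[0] * bin_dt) if hits.size else None


def collision_test(spikes: SpikeTrain, light_onsets: EventTable | np.ndarray,
                   t_resp: float, pre_window: tuple[float, float] = (-0.007, -0.002),
                   bin_dt: float = 0.001) -> bool:
    """Antidromic collision test.

    Trials with a spontaneous spike in ``[t_resp - 7 ms, t_resp - 2 ms)``
    before the response bin must contain zero spikes in the 1 ms bin at
    ``t_resp``; a unit with no such trial passes vacuously (an antidromic
    spike collides with a just-fired orthodromic spike, so a genuine
    antidromic unit cannot respond on those trials).
    """
    onsets = light_onsets.times if isinstance(light_onsets, EventTable) else np.asarray(light_onsets)
    st = spikes.times
    w_lo = onsets + t_resp + pre_window[0]
    w_hi = onsets + t_resp + pre_window[1]
    has_prior = np.searchsorted(st, w_hi) > np.searchsorted(st, w_lo)
    if not has_prior.any():
        return True
    r_lo = onsets[has_prior] + t_resp
    r_hi = r_lo + bin_dt
    n_resp = np.searchsorted(st, r_hi) - np.searchsorted(st, r_lo)
    return bool(np.all(n_resp == 0))


def waveform_similarity(pair: WaveformPair) -> float:
    """Pearson correlation between evoked and spontaneous mean waveforms."""
    e, s = pair.evoked_mean, pair.spontaneous_mean
    if np.std(e) == 0 or np.std(s) == 0:
        raise ValueError("zero-variance waveform")
    return float(np.corrcoef(e, s)[0, 1])


def classify_optotagged(spikes: SpikeTrain,
                        light_block1: EventTable,
                        light_block2: EventTable,
                        baseline_intervals: list[tuple[float, float]],
                        qc: UnitQCMetrics,
                        waveforms: WaveformPair,
                        response_window: tuple[float, float] = (0.001, 0.020),
                        n_perm: int = 1000,
                        waveform_threshold: float = 0.9,
                        alpha: float = 0.01,
                        rate_limits: tuple[float, float] = (0.2, 10.0),
                        seed: int = 0) -> TagDecision:
    """Full optotagging decision: AND of every gating criterion."""
    p1 = latency_significance_test(spikes, light_block1, response_window,
                                   baseline_intervals, n_perm=n_perm, seed=seed)
    p2 = latency_significance_test(spikes, light_block2, response_window,
                                   baseline_intervals, n_perm=n_perm, seed=seed + 1)
    all_onsets = np.concatenate([light_block1.times, light_block2.times])
    t_resp = first_significant_bin(spikes, all_onsets, baseline_intervals,
                                   window=response_window[1], seed=seed + 2)
    coll = collision_test(spikes, all_onsets, t_resp) if t_resp is not None else False
    try:
        r = waveform_similarity(waveforms)
    except ValueError:
        r = 0.0
    qc_ok = qc.passes()
    rate_ok = rate_limits[0] < qc.mean_rate < rate_limits[1]
    tagged = (p1 < alpha and p2 < alpha and qc_ok and r >= waveform_threshold
              and coll and rate_ok)
    return TagDecision(unit_id=spikes.unit_id, latency_p_block1=p1, latency_p_block2=p2,
                       t_resp=t_resp, collision_pass=coll, waveform_r=r,
                       qc_pass=qc_ok, rate_pass=rate_ok, tagged=tagged)


def classify_odor_responsive(spikes: SpikeTrain, trials, odor: str,
                             alpha: float = 0.001, n_post_bins: int = 5,
                             min_trials: int = 20) -> OdorResponseClass:
    """One-tailed rank-sum classification of odor excitation/inhibition.

    Per-trial spike counts in five 1 s bins after odor onset are each
    compared with the 1 s pre-odor bin (one-tailed rank-sum, n = trials);
    the unit is excited (inhibited) if any right-tail (left-tail) p falls
    below 0.001.  No multiple-comparison correction is applied; the strict
    threshold controls the per-neuron false-positive rate by union bound.
    """
    onsets = trials.loc[trials.trial_type.astype(str).str.startswith(odor),
                        "odor_onset_s"].to_numpy(float)
    if onsets.size < min_trials:
        raise ValueError(f"need at least {min_trials} trials of odor {odor!r}")
    st = spikes.times

    def counts(lo_off: float, hi_off: float) -> np.ndarray:
        return (np.searchsorted(st, onsets + hi_off)
                - np.searchsorted(st, onsets + lo_off)).astype(float)

    pre = counts(-1.0, 0.0)
    p_right = np.ones(n_post_bins)
    p_left = np.ones(n_post_bins)
    for b in range(n_post_bins):
        post = counts(float(b), float(b + 1))
        if np.all(post == post[0]) and np.all(pre == post[0]):
            continue  # identical constant samples: no evidence either way
        p_right[b] = mannwhitneyu(post, pre, alternative="greater").pvalue
        p_left[b] = mannwhitneyu(post, pre, alternative="less").pvalue
    return OdorResponseClass(odor=odor, excited=bool(np.any(p_right < alpha)),
                             inhibited=bool(np.any(p_left < alpha)),
                             p_right=p_right, p_left=p_left)
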
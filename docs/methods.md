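# Methods

This note documents the models behind `tdcircuit`, the numerical choices,
the synthetic-data generators' assumptions, and what the package's tests
do and do not establish about real recordings.

## The TD operator as an LTI system

The discrete reward prediction error is δ_t = R_t + γ·V(S_{t+1}) − V(S_t)
with γ the per-step discount.  Expressing γ per second and letting the
step shrink gives the continuous form TD(t) = r(t) + V̇(t) + ln(γ)·V(t).
With r = 0 this is a linear time-invariant operator with impulse response
h_TD(t) = δ′(t) + ln(γ)·δ(t): one zero at σ₁ = −ln γ, no poles.  It is
improper (pure differentiation), so any physical system implementing it
must append smoothing — at least one extra pole.  That is why the package
fits the order-n model with n zeros and n + 1 poles: order 1 is "one TD
transformation plus smoothing and scaling", order 0 is smoothing and
scaling alone, higher orders allow higher derivatives.  The discount
factor is recovered from the fitted zero as γ̂ = e^(−σ₁), and equivalently
from the biphasic impulse response: the DC gain H(0) = P − N (positive
minus negative lobe area) equals ln γ̂ up to scale, so P/N = 1 exactly
when γ̂ = 1 and P/N < 1 when γ̂ < 1.

On the grid, V̇ is a backward difference (causal; the sample before the
window is pinned at the first sample, so constants map to ln(γ)·V exactly
from the first sample).  The discretization error on smooth traces is
first order in dt, verified by a convergence test.

## Ground-truth circuit

`GroundTruthCircuit` produces dopamine output as
gain · lowpass(dV/dt + ln(γ*)·V) + noise, where the low pass is a causal
single-exponential filter with unit DC gain and time constant 0.15 s by
default.  The smoothing renders the improper TD operator realizable; its
value is a free config, and γ recovery is insensitive to it (tested at
0.08–0.30 s).  The circuit is conceptually continuous-time: it is always
simulated at a grid of at most 1 ms and decimated to the analysis grid, so
the analysis grid cannot change the ground truth.  Written as a transfer
function the circuit is (gain/τ)(s + ln γ*)/(s + 1/τ) — one zero at
−ln γ*, one pole.  Note this makes the circuit biproper: its impulse
response contains a delta-like fast lobe, so the "true" P/N for the
default circuit at γ* = 0.5 is (1/τ)/((1/τ) − ln γ*) ≈ 0.91, not a
function of γ* alone.

## Synthetic data: what is emulated, what is not

* **Task generator.**  80 CS+ / 80 CS− trials, exactly 75% of CS+
  stimulated (an exact partition shuffled per seed, not per-trial coin
  flips), 1 s odor + 0.5 s trace, ITI = 8.5 s + truncated exponential.
  Naive truncation of a mean-4 s exponential at 12 s yields mean ≈ 3.37 s,
  so the rate is calibrated by 1-D root finding until the post-truncation
  mean is 4 s, giving total ITIs on [8.5, 20.5] s with mean 12.5 s.
* **Stimulation patterns.**  Seven pulse trains of 1 ms pulses: 20 Hz for
  1 s and 2 s; linear rate ramps 0→40 Hz and 40→0 Hz (pulse times by
  integrating the instantaneous rate, so a ramp from 0 Hz emits no pulse
  at t = 0); and 3 s trains at 5/10/20 Hz.  The ramp duration is not
  dictated by the experimental description; the default is 2 s and is a
  config parameter.
* **Value learning.**  Tabular TD(0) on a tapped-delay-line state space
  per odor, reward at the outcome state on stimulated trials, per-step
  discount γ^dt.  The cue-state value converges to p(stim)·R·γ^delay
  (the closed-form check in the tests).  A learning rate of 0 is accepted
  and means "no update".
* **Spiking.**  Inhomogeneous point processes sampled per time bin
  (Bernoulli with p = rate·dt), rates rectified at zero.  No refractory
  period, bursting or rate adaptation.
* **Pattern responses for fitting.**  Per-neuron traces are the noiseless
  circuit output plus band-limited noise: white noise passed through the
  same 50 ms Gaussian as the preprocessing smoothing, scaled so the trace
  SD ratio equals the requested SNR (default 10).  White noise at the
  sample rate would give each neuron ~50k independent samples and an
  absurdly tight bootstrap; smoothed noise matches what trial-averaged,
  smoothed recordings actually carry.  Not emulated: trial-to-trial gain
  drift, slow state changes, cross-neuron noise correlations — so passing
  recovery tests shows the estimator is correct under the stated model,
  not that real data satisfy the model.
* **Optotagging sessions.**  Antidromically tagged units fire one
  light-locked spike per pulse at 9.5 ± 0.2 ms and obey spike collision:
  if a spontaneous spike occurred shortly before the expected evoked time
  the antidromic spike is annihilated and the refractory soma stays
  silent within 2 ms of it.  The generator's collision window (1–8.5 ms
  before the expected evoked time) is slightly wider than the 2–7 ms test
  window, because the test anchors at the estimated response *bin* while
  the generator anchors at the jittered per-trial evoked time; the margin
  guarantees genuine antidromic units pass the collision test.  Orthodromic
  mimics respond with configurable probability regardless of collisions;
  plain untagged units ignore light.  Waveforms are a biphasic template
  plus averaging noise; isi violations and presence ratios are computed
  from the generated trains, the amplitude cutoff is a plausible constant
  (the real metric comes from a sorting pipeline this package does not
  reimplement).
* **Raw photometry.**  Drifting baseline (linear + slow sine) with
  event-locked exponential transients of known relative amplitude, white
  noise, and an optional control channel carrying a shared artifact for
  isosbestic-correction tests.

## Preprocessing conventions

dF/F uses a rolling 10th-percentile baseline in a 30 s window; the window
is centered and shrunk at the edges (the trailing/centered choice is not
dictated by the experimental description; centered avoids onset bias on
short fixtures).  Traces are linearly interpolated to 1 kHz and smoothed
with a 50 ms SD Gaussian (reflect padding, unit-mass kernel truncated at
4σ — mass preservation is asserted for interior events only).  Z-scoring
uses only ITI samples, defined by excluding 0.5 s before to 3 s after
every trial start.  Isosbestic correction fits a robust line (IRLS,
Tukey-bisquare weights) of signal on control over ITI samples only and
subtracts it from the whole trace; channels whose units label carries the
`!noiso` tag (dopamine sensors, unknown isosbestic wavelength) are
refused.  Spike trains are binned at 1 ms into rates before the same
smoothing and z-scoring; an empty train yields a defined constant trace.
PSTH SEM uses the n − 1 denominator.

## Transfer-function estimation

The estimator minimizes summed squared *simulation* error (output error)
across the seven pattern segments, each simulated from zero initial state
as an independent record — no state carries across pattern boundaries,
avoiding artificial boundary transients.  Each segment includes 2 s of
pre-onset and 4 s of post-offset baseline (configurable).  No
regularization is used.

Numerics:

* **Simulation.**  Exact zero-order-hold discretization via closed-form
  partial fractions of the step response (the "conv" backend), checked
  against an independent matrix-exponential state-space recursion ("ss");
  the two agree to < 10⁻⁶ relative error on random stable fixtures.
* **Variable projection.**  For fixed poles the numerator is linear, so
  it is solved by linear least squares inside a damped Gauss–Newton
  (Levenberg–Marquardt) search over the monic denominator coefficients.
* **Starts.**  State-variable-filtering linear least squares at four
  filter bandwidths (2, 6, 20, 60 rad/s) plus seeded random stable pole
  draws, eight starts total; starts are ranked by initial cost and refined
  best-first, stopping early when two starts agree on the optimum or the
  in-sample R² exceeds 0.995.  Ties break by lower residual, then lower
  parameter norm.  Bootstrap replicates warm-start from the
  full-population fit (single start, slightly looser termination) — the
  optimum moves little between resamples.
* **Stability and identifiability.**  Unstable candidate poles are
  reflected into the left half-plane during the search; zeros are
  unconstrained (a right-half-plane zero is the expected TD signature).
  Pole magnitudes are additionally capped at 20/dt: poles far beyond the
  sample bandwidth are not identifiable from band-limited data (they only
  trade off against the gain) and, uncapped, wander to ~10⁶–10⁷ rad/s,
  making the impulse response impossible to integrate on any practical
  grid.  The cap leaves fit quality and the zero unchanged.
* **Cross-validation.**  Leave-one-pattern-out; held-out predictions are
  concatenated and R² = 1 − SS_res/SS_tot is computed against the
  concatenated data with its grand mean.
* **Derivative-constrained model.**  The input is backward-differenced
  and a 0-zero/2-pole model is fit — equivalent to pinning σ₁ = 0
  (γ = 1).
* **Impulse features.**  h(t) is evaluated in closed form from residues
  on a grid that resolves the fastest pole (refined automatically, capped
  at 2·10⁶ samples), tail-truncated where the remaining absolute area is
  below 10⁻⁶ of the total; P, N and the DC gain are trapezoid integrals
  and t_min is the grid argmin.  A response with no negative lobe reports
  P/N = +inf with a flag rather than raising.

## Bootstrap inference

Each of 1000 replicates resamples neurons with replacement at full
population size, averages their per-pattern responses, refits the order-1
model and records γ̂ = e^(−σ₁) and P/N from the same fitted model.
Replicates whose fit fails or yields a degenerate zero are excluded and
counted; more than 20% failures raises an error (that is fit instability,
not sampling noise).  Intervals are 2.5–97.5 percentile — matching a
histogram-and-median presentation; no BCa correction — so their coverage
of γ* is itself a ~93–95%-probability event per simulated population; the
acceptance test therefore checks coverage across three independent
populations (≥ 2 of 3) rather than gambling on one draw.  The P/N-vs-γ̂
relation is summarized by least squares on a·e^(b·γ̂) + c.  Region
summaries stop at mean ± SEM (n − 1), with a flag when a region has a
single subject.

## Unit-selection statistics

* **Latency test.**  The published stimulus-associated latency test is
  specified only by citation, so the package implements the same
  inputs/outputs as an exchangeable permutation test: the distribution
  over trials of *first-spike* latency after light onset (1 ms bins over
  the response window — 1–20 ms for dopamine-style 20 ms pulses, 2–6 ms
  for D1-style 1 ms pulses — plus a no-spike category) is compared with
  n_perm = 1000 equally sized histograms anchored at uniform random ITI
  times.  The statistic is each histogram's Jensen–Shannon divergence from
  the pooled remainder; because the null makes all histograms
  exchangeable, the tail rank of the response is a valid p-value
  (measured null rejection at p < 0.01 is 1.0% over 2000 simulated units;
  power > 95% on a 3 ms ± 0.5 ms injected response at 60 trials).  The
  first-spike-per-trial construction matters: normalized all-spike
  histograms discard response mass and have essentially no power against
  sparse baselines.  A unit with no spikes in any window returns p = 1.
* **Response latency (t_resp).**  First 1 ms post-onset bin whose
  trial-summed count exceeds the mean of 1000 ITI-anchored shuffles by
  strictly more than 5 shuffle SDs; absent when no bin qualifies.
* **Collision test.**  Trials with a spontaneous spike in
  [t_resp − 7 ms, t_resp − 2 ms) must have zero spikes in the 1 ms bin at
  t_resp; vacuous pass when no such trial exists.
* **Full decision.**  Tagged = latency p < 0.01 in both light-trial
  blocks AND isi_viol < 0.5, amplitude_cutoff < 0.1, presence_ratio > 0.9
  (strict, supplied by the sorting pipeline) AND waveform Pearson r ≥ 0.9
  AND collision pass AND mean rate in (0.2, 10) Hz.  The decision is
  monotone: relaxing any threshold never un-tags a unit.
* **Odor responsiveness.**  Per-trial spike counts in five 1 s post-odor
  bins, each compared with the 1 s pre-odor bin by one-tailed rank-sum;
  excited/inhibited if any right/left-tail p < 0.001, no
  multiple-comparison correction (the strict threshold bounds the
  per-neuron false-positive rate at 1% by union over 5 bins × 2 tails).

## Problem sizes used by the test suite

The suite runs everything at desk scale, chosen as the package's own
operating points: single-trace γ recovery and the order sweep on the
1 kHz grid; bootstrap and coverage checks on a 2 ms analysis grid
(ground truth still simulated at 1 ms and decimated — the 50 ms smoothing
makes decimation information-preserving); 20–50 neuron populations;
latency-test calibration over 2000 null units at n_perm = 1000; 200-run
power and collision Monte Carlos.  The bootstrap interval-coverage
property is verified as a scaled sanity band (8 populations, ≥ 6
covering) rather than the full 200-population calibration.

## Known limitations

* The estimator assumes the noise is additive on the output and roughly
  stationary; it has no innovation model (pure output-error), so heavy
  autocorrelated noise inflates γ̂ variance though not, in our
  simulations, its bias.
* The identifiability cap (20/dt) means a genuinely ultra-fast biological
  pole would be reported at the cap; at 1 kHz that is 2·10⁴ rad/s, far
  beyond anything the 50 ms-smoothed signals can express.
* P/N of the fitted filter depends on the circuit's smoothing as well as
  γ (see the biproper ground truth above); only the zero σ₁ is a pure
  readout of γ.
* The generators make no attempt at biophysics: no refractoriness,
  bursting, sensor kinetics beyond a single exponential, or hemodynamic
  artifacts beyond a shared-artifact control channel.
* The amplitude-cutoff QC metric is accepted as an input; recomputing
  sorting-quality metrics from raw voltage is out of scope.
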
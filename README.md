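# tdcircuit

Temporal-difference (TD) system identification of the transformation from
striatal D1 medium spiny neuron (D1-MSN) activity to midbrain dopamine
activity.

## The scientific problem

In reinforcement-learning accounts of the basal ganglia, dopamine neurons
broadcast a reward prediction error

δ_t = R_t + γ·V(S_{t+1}) − V(S_t),

whose continuous-time form in the absence of reward is

TD(t) = V̇(t) + ln(γ)·V(t),

where V is the value function and γ the per-second temporal discount
factor.  At γ = 1 this operator is a pure time derivative; for γ < 1 it
acquires a negative DC gain, so sustained value produces a *negative*
steady-state response — the experimentally decisive signature.  As an LTI
system, the TD operator has one zero at σ₁ = −ln γ and no poles, so if
dopamine activity is (a smoothed, scaled) TD transform of D1-MSN activity,
an order-1 rational transfer function

H(s) = K·(s − σ₁) / ((s − ρ₁)(s − ρ₂))

fit from D1-MSN input to dopamine output should capture the data, and the
discount factor can be read off the fitted zero as **γ̂ = e^(−σ₁)**.
Equivalently, the fitted impulse response is biphasic — a fast positive
lobe of area P and a delayed negative lobe of area N — and P/N → 1 as
γ̂ → 1.

`tdcircuit` implements this analysis end to end for synthetic data whose
ground truth is known: the opto-conditioning task generator, the seven
optogenetic pulse-train probe patterns (1 s/2 s/3 s constant-rate trains
and up/down rate ramps), photometry and spike-train preprocessing
(rolling-percentile dF/F, isosbestic correction, 1 kHz upsampling, 50 ms
Gaussian smoothing, ITI z-scoring, PSTHs), output-error transfer-function
estimation with leave-one-pattern-out cross-validation, the
derivative-constrained (γ = 1) comparison model, bootstrap population
inference on γ̂ and P/N, and the optotagging statistics (latency
permutation test, antidromic collision test, waveform similarity, QC and
rate gates, odor-responsiveness classification) that gate which neurons
enter such analyses.

It is aimed at systems neuroscientists who want a reproducible, fully
synthetic test bed for TD-style systems identification of neural circuits.

## Worked example

```python
import tdcircuit as tc

# dopamine responses of one synthetic neuron to the 7 stimulation
# patterns, generated by a ground-truth TD circuit with gamma* = 0.5
inputs, neurons = tc.generate_pattern_responses(gamma_true=0.5, snr=10,
                                                n_neurons=1, seed=0)
fit = tc.fit_transfer_function(inputs, neurons[0], order=1, seed=0)
est = tc.extract_gamma(fit.model)
h = tc.impulse_response(fit.model)
feats = tc.impulse_features(h)
print(f"gamma_hat = {est.gamma_hat:.3f}")
print(f"P/N = {feats.ratio:.3f}, t_min = {feats.t_min*1000:.0f} ms")
print(f"in-sample R^2 = {fit.r2_insample:.3f}")
```

prints

```
gamma_hat = 0.499
P/N = 0.909, t_min = 1 ms
in-sample R^2 = 0.989
```

`gamma_hat` recovers the generator's discount factor (0.5) from the fitted
zero; `P/N < 1` is the biphasic-filter expression of the same fact (the
negative lobe outweighs the positive one whenever γ̂ < 1, and P − N equals
the filter's DC gain ln γ̂ up to scale); `t_min` marks the handover from
the positive to the negative lobe, which for this near-instantaneous
ground-truth circuit sits right after the fast positive transient; and the
in-sample R² near 0.99 reflects the generator's 10:1 signal-to-noise
ratio.

The same pipeline runs from the shell:

```bash
tdcircuit demo --seed 0 --out bundle/
```

which writes trial tables, the order sweep of cross-validated R²
(plateauing at order 1), the fitted model, bootstrap samples of γ̂ and
P/N, and a manifest with the seed and config hash.

## Layout

- `src/tdcircuit/core.py` — trace/spike/event/PSTH containers and I/O
- `src/tdcircuit/synthetic.py` — task, stimulation-pattern, value-learning,
  circuit, optotagging and photometry generators
- `src/tdcircuit/signals.py` — dF/F, isosbestic correction, resampling,
  smoothing, ITI z-scoring, PSTHs
- `src/tdcircuit/td.py` — the TD operator in continuous and discrete time
- `src/tdcircuit/sysid.py` — transfer-function fitting, cross-validation,
  impulse responses and features, γ̂ extraction
- `src/tdcircuit/population.py` — bootstrap inference, P/N-vs-γ̂ curve,
  region summaries
- `src/tdcircuit/tagging.py` — optotagging and odor-responsiveness
  statistics
- `src/tdcircuit/pipeline.py`, `cli.py` — end-to-end orchestration and CLI
- `docs/methods.md` — models, assumptions, numerical choices, limitations
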
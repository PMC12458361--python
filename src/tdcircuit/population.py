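"""Population-level inference: bootstrapped discount-factor estimates,
the P/N-versus-gamma exponential relation, and per-region summaries.

Each bootstrap replicate resamples neurons with replacement at full
population size, averages their per-pattern responses, refits the order-1
transfer-function model, and records ``gamma_hat = exp(-sigma_1)``
together with the P/N lobe ratio of the fitted impulse response.  The
population estimate is the median over replicates with a 2.5-97.5
percentile interval.  Replicates whose fit fails (non-convergence or a
complex/degenerate zero) are excluded and counted; more than 20% failures
aborts with an error since that signals fit instability rather than
sampling noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .core import UniformTimeSeries
from .sysid import (TransferFunctionModel, extract_gamma, fit_transfer_function,
                    impulse_features, impulse_response)

__all__ = [
    "BootstrapDistribution",
    "ExpFitParams",
    "bootstrap_gamma",
    "fit_pn_gamma_curve",
    "summarize_regions",
]


@dataclass
class BootstrapDistribution:
    n_boot: int
    seed: int
    gamma_hat: np.ndarray
    pn_ratio: np.ndarray
    fit_ok: np.ndarray
    n_failed: int
    median_gamma: float
    interval: tuple[float, float]
    full_fit_model: TransferFunctionModel | None = None

    def samples(self) -> pd.DataFrame:
        return pd.DataFrame({
            "replicate": np.arange(self.n_boot),
            "gamma_hat": self.gamma_hat,
            "pn_ratio": self.pn_ratio,
            "fit_ok": self.fit_ok,
        })


@dataclass(frozen=True)
class ExpFitParams:
    """Parameters of ``y = a * exp(b * x) + c``."""

    a: float
    b: float
    c: float


def _gamma_and_pn(model: TransferFunctionModel, dt: float) -> tuple[float, float]:
    est = extract_gamma(model)
    h = impulse_response(model, dt=dt)
    feats = impulse_features(h)
    return est.gamma_hat, feats.ratio


def bootstrap_gamma(neuron_psths: list[list[UniformTimeSeries]],
                    inputs: list[UniformTimeSeries],
                    n_boot: int = 1000, seed: int = 0,
                    max_failed_frac: float = 0.2,
                    **fit_kwargs) -> BootstrapDistribution:
    """Bootstrap the gamma estimate over a population of neurons.

    ``neuron_psths[i][j]`` is neuron i's trial-averaged response to
    stimulation pattern j (all on the inputs' grid).  The full-population
    fit initializes each replicate's refit (the model changes little
    between resamples, so the warm start converges in a few damped
    Gauss-Newton steps without changing the optimum).
    """
    n_neurons = len(neuron_psths)
    if n_neurons < 2:
        raise ValueError("need at least two neurons to bootstrap")
    n_patterns = len(inputs)
    if any(len(np_) != n_patterns for np_ in neuron_psths):
        raise ValueError("every neuron needs a response to every pattern")
    dt = inputs[0].dt
    # neuron-by-sample stack per pattern for fast resampled averages
    stacks = [np.array([neuron_psths[i][j].values for i in range(n_neurons)])
              for j in range(n_patterns)]

    full_avg = [inputs[j].with_values(stacks[j].mean(axis=0)) for j in range(n_patterns)]
    full_fit = fit_transfer_function(inputs, full_avg, order=1, **fit_kwargs)
    init_den = full_fit.model.den

    rng = np.random.default_rng(seed)
    gamma = np.full(n_boot, np.nan)
    pn = np.full(n_boot, np.nan)
    ok = np.zeros(n_boot, dtype=bool)
    warm_kwargs = dict(fit_kwargs)
    warm_kwargs.update(n_starts=1, init_den=init_den)
    full_vals = [ts.values for ts in full_avg]
    full_gpn: tuple[float, float] | None = None
    for b in range(n_boot):
        idx = rng.integers(0, n_neurons, n_neurons)
        avg_vals = [stacks[j][idx].mean(axis=0) for j in range(n_patterns)]
        try:
            if all(np.allclose(a, f, rtol=1e-12, atol=1e-14)
                   for a, f in zip(avg_vals, full_vals)):
                # resample reproduced the full-population average (always the
                # case for a degenerate population): reuse the full fit
                if full_gpn is None:
                    full_gpn = _gamma_and_pn(full_fit.model, dt)
                g, r = full_gpn
            else:
                avg = [inputs[j].with_values(avg_vals[j]) for j in range(n_patterns)]
                fit = fit_transfer_function(inputs, avg, order=1, **warm_kwargs)
                g, r = _gamma_and_pn(fit.model, dt)
        except (RuntimeError, ValueError):
            continue
        gamma[b], pn[b], ok[b] = g, r, True

    n_failed = int(n_boot - ok.sum())
    if n_failed > max_failed_frac * n_boot:
        raise RuntimeError(f"{n_failed}/{n_boot} bootstrap replicates failed to fit; "
                           "the model is unstable on these data")
    good = gamma[ok]
    return BootstrapDistribution(
        n_boot=n_boot, seed=seed, gamma_hat=gamma, pn_ratio=pn, fit_ok=ok,
        n_failed=n_failed, median_gamma=float(np.median(good)),
        interval=(float(np.percentile(good, 2.5)), float(np.percentile(good, 97.5))),
        full_fit_model=full_fit.model)


def fit_pn_gamma_curve(gamma_hat: np.ndarray, pn_ratio: np.ndarray,
                       min_points: int = 10) -> ExpFitParams:
    """Least-squares fit of ``P/N = a * exp(b * gamma_hat) + c``."""
    x = np.asarray(gamma_hat, float)
    y = np.asarray(pn_ratio, float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < min_points:
        raise ValueError(f"need at least {min_points} finite points")
    if np.ptp(x) < 1e-9:
        raise ValueError("degenerate spread in gamma_hat; exponential fit undefined")

    def f(xx, a, b, c):
        return a * np.exp(b * xx) + c

    best = None
    spread = np.ptp(y) if np.ptp(y) > 0 else 1.0
    for p0 in ((spread, 1.0, float(np.min(y))),
               (-spread, -1.0, float(np.max(y))),
               (0.1, 2.0, 0.0)):
        try:
            popt, _ = curve_fit(f, x, y, p0=p0, maxfev=20000)
        except RuntimeError:
            continue
        sse = float(np.sum((y - f(x, *popt)) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt)
    if best is None:
        raise RuntimeError("exponential fit did not converge")
    a, b, c = best[1]
    return ExpFitParams(a=float(a), b=float(b), c=float(c))


def summarize_regions(per_subject: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SEM of impulse features per region.

    ``per_subject`` has one row per (region, subject) with columns
    ``pn_ratio`` and ``t_min``.  Regions with a single subject get a NaN
    SEM and ``sem_defined = False``.  Subject order does not affect the
    summary.
    """
    required = {"region", "subject", "pn_ratio", "t_min"}
    if not required.issubset(per_subject.columns):
        raise ValueError(f"per_subject table needs columns {sorted(required)}")

    def sem(v: pd.Series) -> float:
        return float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else float("nan")

    rows = []
    for region, grp in per_subject.groupby("region", sort=True):
        rows.append({
            "region": region,
            "n_subjects": len(grp),
            "pn_ratio_mean": float(grp.pn_ratio.mean()),
            "pn_ratio_sem": sem(grp.pn_ratio),
            "t_min_mean": float(grp.t_min.mean()),
            "t_min_sem": sem(grp.t_min),
            "sem_defined": len(grp) > 1,
        })
    return pd.DataFrame(rows)
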
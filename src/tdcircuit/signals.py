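"""Signal preprocessing: dF/F, isosbestic correction, resampling, smoothing,
ITI z-scoring, spike-rate conversion and PSTHs.

Conventions, chosen to match standard fiber-photometry / electrophysiology
practice: the dF/F baseline F0 is a rolling 10th percentile in a 30 s
window (centered, shrunk at the edges); traces are upsampled to 1 kHz by
linear interpolation and smoothed with a 50 ms SD Gaussian; z-scoring uses
only inter-trial-interval (ITI) samples, defined by excluding 0.5 s before
to 3 s after every trial start; spike trains are binned at 1 ms before the
same smoothing and z-scoring.
"""

from __future__ import annotations

import numpy as np
import statsmodels.api as sm
from scipy.ndimage import gaussian_filter1d

from .core import EventTable, PSTH, SpikeTrain, UniformTimeSeries

__all__ = [
    "compute_dff",
    "iti_mask",
    "isosbestic_correct",
    "resample_and_smooth",
    "zscore_to_iti",
    "spikes_to_zscored_rate",
    "compute_psth",
]

NO_ISOSBESTIC_TAG = "!noiso"


def compute_dff(raw: UniformTimeSeries, window: float = 30.0,
                percentile: float = 0.10) -> UniformTimeSeries:
    """dF/F with a rolling-percentile baseline.

    ``dF/F = (F - F0) / F0`` where F0 is the ``percentile`` quantile of F in
    a centered rolling window of length ``window`` seconds (shrunk at the
    edges).  Invariant to positive rescaling of F.
    """
    import pandas as pd

    if np.any(raw.values <= 0):
        raise ValueError("raw fluorescence must be strictly positive")
    w = max(int(round(window / raw.dt)), 1)
    f0 = (pd.Series(raw.values)
          .rolling(window=w, center=True, min_periods=1)
          .quantile(percentile)
          .to_numpy())
    if np.any(f0 <= 0):
        raise ValueError("rolling baseline F0 is nonpositive somewhere; "
                         "check the raw trace for dropouts")
    return raw.with_values((raw.values - f0) / f0, units="dF/F")


def iti_mask(x: UniformTimeSeries, trial_starts: EventTable,
             exclude_pre: float = 0.5, exclude_post: float = 3.0) -> np.ndarray:
    """Boolean mask of samples outside every trial's exclusion window."""
    t = x.times
    mask = np.ones(x.n, dtype=bool)
    for ts in trial_starts.times:
        mask &= ~((t >= ts - exclude_pre) & (t <= ts + exclude_post))
    return mask


def isosbestic_correct(signal: UniformTimeSeries, control: UniformTimeSeries,
                       mask: np.ndarray, min_samples: int = 100) -> UniformTimeSeries:
    """Regress out the activity-independent control channel.

    A robust linear fit (IRLS with bisquare weights) of signal on control
    is estimated on ITI samples only and subtracted from the whole trace.
    Channels tagged ``!noiso`` (dopamine sensors, whose isosbestic
    wavelength is unknown) are rejected.
    """
    if NO_ISOSBESTIC_TAG in signal.units:
        raise ValueError("this channel is flagged as never isosbestic-corrected")
    if signal.n != control.n or signal.dt != control.dt:
        raise ValueError("signal and control must share a sampling grid")
    mask = np.asarray(mask, bool)
    if mask.sum() < min_samples:
        raise ValueError(f"ITI mask selects fewer than {min_samples} samples")
    X = sm.add_constant(control.values[mask])
    fit = sm.RLM(signal.values[mask], X, M=sm.robust.norms.TukeyBiweight()).fit()
    intercept, slope = fit.params
    corrected = signal.values - (intercept + slope * control.values)
    return signal.with_values(corrected, units=signal.units + " (iso-corrected)")


def resample_and_smooth(x: UniformTimeSeries, target_dt: float = 0.001,
                        gaussian_sd: float = 0.050) -> UniformTimeSeries:
    """Linear interpolation to ``target_dt`` then Gaussian smoothing.

    The kernel is normalized to unit mass (reflect padding at the edges),
    so trace integrals of interior events are preserved.
    """
    if target_dt > x.dt:
        raise ValueError("target_dt must not exceed the source dt")
    t_new = np.arange(x.t0, x.t_end + target_dt / 2, target_dt)
    y = np.interp(t_new, x.times, x.values)
    if gaussian_sd > 0:
        y = gaussian_filter1d(y, sigma=gaussian_sd / target_dt, mode="reflect")
    return UniformTimeSeries(t0=x.t0, dt=target_dt, values=y, units=x.units)


def zscore_to_iti(x: UniformTimeSeries, trial_starts: EventTable,
                  exclude_pre: float = 0.5, exclude_post: float = 3.0) -> UniformTimeSeries:
    """Z-score the trace against its ITI mean and SD.

    ITI samples are all time points outside [start - exclude_pre,
    start + exclude_post] around every trial start.
    """
    mask = iti_mask(x, trial_starts, exclude_pre, exclude_post)
    if not mask.any():
        raise ValueError("no ITI samples remain after exclusion")
    mu = float(x.values[mask].mean())
    sd = float(x.values[mask].std())
    if sd == 0:
        raise ValueError("ITI standard deviation is zero; cannot z-score")
    return x.with_values((x.values - mu) / sd, units="z")


def spikes_to_zscored_rate(spikes: SpikeTrain, trial_starts: EventTable,
                           duration: float, bin_dt: float = 0.001,
                           gaussian_sd: float = 0.050,
                           exclude_pre: float = 0.5, exclude_post: float = 3.0,
                           zscore: bool = True) -> UniformTimeSeries:
    """Smoothed (and optionally ITI-z-scored) firing-rate trace of one unit.

    Spikes are binned at 1 ms into a rate trace (counts / bin width),
    smoothed with a 50 ms SD Gaussian.  An empty train yields a defined
    constant trace (the z-score of zero rate), not an error.
    """
    n = int(round(duration / bin_dt))
    counts = np.histogram(spikes.times, bins=n, range=(0.0, n * bin_dt))[0].astype(float)
    rate = counts / bin_dt
    if gaussian_sd > 0:
        rate = gaussian_filter1d(rate, sigma=gaussian_sd / bin_dt, mode="reflect")
    ts = UniformTimeSeries(t0=bin_dt / 2, dt=bin_dt, values=rate, units="Hz")
    if not zscore:
        return ts
    mask = iti_mask(ts, trial_starts, exclude_pre, exclude_post)
    mu = float(ts.values[mask].mean())
    sd = float(ts.values[mask].std())
    if sd == 0:
        # silent unit: constant trace at the (degenerate) baseline z-value
        return ts.with_values(np.zeros(ts.n), units="z")
    return ts.with_values((ts.values - mu) / sd, units="z")


def compute_psth(x: UniformTimeSeries | SpikeTrain, align_events: EventTable,
                 window: tuple[float, float], bin_dt: float | None = None,
                 baseline_window: tuple[float, float] | None = None) -> PSTH:
    """Event-aligned mean +/- SEM across trials.

    For a uniform trace, per-trial segments are cut on the trace's own
    grid; for a spike train they are 1 ms-binned rate histograms (or
    ``bin_dt`` if given).  Events whose window extends past the recording
    are dropped; if none remain this is an error.  With
    ``baseline_window``, each trial's mean in that window is subtracted
    before averaging.  SEM uses the n-1 denominator.
    """
    t_pre, t_post = window
    if t_post <= t_pre:
        raise ValueError("window must satisfy t_post > t_pre")

    segments = []
    if isinstance(x, SpikeTrain):
        if bin_dt is None:
            bin_dt = 0.001
        edges = np.arange(t_pre, t_post + bin_dt / 2, bin_dt)
        for ev in align_events.times:
            if ev + t_pre < 0:
                continue
            seg = np.histogram(x.times - ev, bins=edges)[0] / bin_dt
            segments.append(seg)
        units = "Hz"
    else:
        bin_dt = x.dt
        n_seg = int(round((t_post - t_pre) / bin_dt))
        for ev in align_events.times:
            i0 = int(round((ev + t_pre - x.t0) / x.dt))
            if i0 < 0 or i0 + n_seg > x.n:
                continue
            segments.append(x.values[i0:i0 + n_seg])
        units = x.units

    if not segments:
        raise ValueError("no alignment event lies fully inside the recording")
    seg = np.array(segments, dtype=float)
    if baseline_window is not None:
        b0, b1 = baseline_window
        lags = t_pre + bin_dt * np.arange(seg.shape[1])
        bmask = (lags >= b0) & (lags < b1)
        if not bmask.any():
            raise ValueError("baseline window contains no samples")
        seg = seg - seg[:, bmask].mean(axis=1, keepdims=True)
    mean = seg.mean(axis=0)
    if seg.shape[0] > 1:
        sem = seg.std(axis=0, ddof=1) / np.sqrt(seg.shape[0])
    else:
        sem = np.zeros_like(mean)
    return PSTH(window=window, bin_dt=bin_dt, mean=mean, sem=sem,
                n_trials=seg.shape[0], units=units)
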
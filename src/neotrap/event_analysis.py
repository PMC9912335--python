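"""Event detection, dwell-time statistics and capture/escape rates.

Trapping events appear as downward excursions from the docked baseline.
Detection uses a two-threshold (hysteresis) scheme standard in nanopore
dwell analysis: an event opens when the current falls below
``baseline - k*sigma`` and closes when it recovers above
``baseline - k/2*sigma``; events shorter than a minimum duration are
discarded, and events truncated by the trace boundaries are dropped from
the dwell statistics (their occupancy still counts against the
unoccupied time used for the capture rate).

Dwell times of a memoryless trap are exponential, so the maximum-
likelihood time constant is the sample mean and the escape rate its
inverse; uncertainties come from bootstrap resampling, mirroring common
practice for single-molecule kinetics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import scipy.signal
import scipy.stats

from .trace_synthesis import CurrentTrace

__all__ = [
    "EventTable",
    "DwellFit",
    "RateEstimates",
    "find_levels",
    "estimate_baseline_sigma",
    "detect_events",
    "fit_dwell_exponential",
    "bootstrap_sd",
    "capture_rate",
    "event_scatter",
]


@dataclass
class EventTable:
    """Per-event records plus the per-trace time bookkeeping.

    ``events`` columns: start, end (sample indices; end exclusive),
    dwell_s, mean_pA, blockade (relative to the baseline, clipped to
    [0, 1]), reliable (False when the dwell is within ~3 filter rise
    times, where the filter attenuates the amplitude).
    """

    events: pd.DataFrame
    sample_rate: float
    baseline: float
    sigma: float
    total_time: float
    unoccupied_time: float
    n_censored: int = 0

    def __len__(self) -> int:
        return len(self.events)

    @property
    def dwells(self) -> np.ndarray:
        return self.events["dwell_s"].to_numpy()

    def waiting_times(self) -> np.ndarray:
        """Unoccupied gaps preceding each event (s), for rate bootstraps."""
        starts = self.events["start"].to_numpy()
        ends = self.events["end"].to_numpy()
        prev_end = np.concatenate([[0], ends[:-1]])
        return (starts - prev_end) / self.sample_rate

    def to_csv(self, path) -> None:
        self.events.to_csv(path, index=False)


@dataclass(frozen=True)
class DwellFit:
    """Exponential dwell-time fit: tau (s), rate = 1/tau (1/s), bootstrap SD."""

    tau: float
    rate: float
    sd_tau: float
    n: int
    method: str = "exponential-mle"


@dataclass(frozen=True)
class RateEstimates:
    """Capture and escape rates (1/s) with bootstrap standard deviations."""

    capture: float
    capture_sd: float
    escape: float
    escape_sd: float
    n_events: int


def _as_samples(trace) -> np.ndarray:
    return trace.samples if isinstance(trace, CurrentTrace) else np.asarray(trace, float)


def find_levels(
    trace,
    max_points: int = 200_000,
    grid: int = 2048,
    min_weight: float = 0.02,
) -> np.ndarray:
    """Current levels (pA) from the all-points histogram, sorted descending.

    A Gaussian KDE of (a subsample of) the samples is peak-picked, and each
    level mean is refined as the average of the samples nearest that mode —
    unbiased for well-separated levels regardless of the KDE bandwidth.
    Modes attracting less than ``min_weight`` of the samples are dropped.
    """
    x = _as_samples(trace)
    if x.size == 0:
        raise ValueError("empty trace")
    if np.ptp(x) == 0:
        return np.array([x[0]])
    sub = x if x.size <= max_points else x[:: x.size // max_points + 1]
    kde = scipy.stats.gaussian_kde(sub)
    lo, hi = sub.min(), sub.max()
    pad = 0.05 * (hi - lo)
    g = np.linspace(lo - pad, hi + pad, grid)
    dens = kde(g)
    peaks, _ = scipy.signal.find_peaks(dens, prominence=0.01 * dens.max())
    if len(peaks) == 0:
        peaks = [int(np.argmax(dens))]
    modes = g[peaks]
    # assign samples to the nearest mode, refine level means
    idx = np.argmin(np.abs(sub[:, None] - modes[None, :]), axis=1)
    levels = []
    for k in range(len(modes)):
        sel = idx == k
        if sel.sum() >= min_weight * sub.size:
            levels.append(sub[sel].mean())
    if not levels:
        levels = [sub.mean()]
    return np.sort(np.asarray(levels))[::-1]


def estimate_baseline_sigma(trace, n_iter: int = 3) -> tuple[float, float]:
    """Robust (baseline, sigma) of the dominant upper level of a trace.

    Starts from the highest histogram level and iteratively re-estimates
    mean and MAD-based sigma from samples within +-4 sigma of it, which
    rejects the event excursions below the baseline.
    """
    x = _as_samples(trace)
    baseline = float(find_levels(x)[0])
    sigma = 1.4826 * float(np.median(np.abs(x - np.median(x))))
    for _ in range(n_iter):
        sel = np.abs(x - baseline) < 4.0 * sigma
        if sel.sum() < 10:
            break
        baseline = float(x[sel].mean())
        sigma = float(x[sel].std())
    return baseline, sigma


def detect_events(
    trace,
    baseline: float,
    sigma: float | None = None,
    k: float = 5.0,
    min_duration_samples: int = 3,
    sample_rate: float | None = None,
    cutoff_hz: float | None = None,
) -> EventTable:
    """Threshold-with-hysteresis event detector.

    An event opens at a crossing below ``baseline - k*sigma`` and closes at
    recovery above ``baseline - (k/2)*sigma``.  Events shorter than
    ``min_duration_samples`` are discarded; events still open at either
    trace boundary are censored (dropped from the table, their span still
    removed from the unoccupied time).
    """
    if k <= 0:
        raise ValueError("threshold multiplier k must be positive")
    x = _as_samples(trace)
    if isinstance(trace, CurrentTrace):
        sample_rate = sample_rate or trace.sample_rate
        cutoff_hz = cutoff_hz or trace.acquisition.cutoff_hz
    if sample_rate is None:
        raise ValueError("sample_rate required for plain-array traces")
    if sigma is None:
        _, sigma = estimate_baseline_sigma(x)

    t_deep = baseline - k * sigma
    t_exit = baseline - 0.5 * k * sigma
    deep = x < t_deep
    above_exit = x > t_exit
    # candidate openings: crossings into the deep region
    entries = np.nonzero(deep[1:] & ~deep[:-1])[0] + 1
    if deep[0]:
        entries = np.concatenate([[0], entries])
    exit_idx = np.nonzero(above_exit)[0]

    starts, ends = [], []
    n_censored = 0
    censored_span = 0
    pos = 0
    while True:
        i = np.searchsorted(entries, pos)
        if i >= len(entries):
            break
        start = entries[i]
        j = np.searchsorted(exit_idx, start)
        if j >= len(exit_idx):
            n_censored += 1
            censored_span += len(x) - start
            break
        end = exit_idx[j]
        if start == 0 and not above_exit[:start + 1].any():
            # event already open at trace start: censored
            n_censored += 1
            censored_span += end
        elif end - start >= min_duration_samples:
            starts.append(start)
            ends.append(end)
        pos = end + 1

    starts = np.asarray(starts, dtype=int)
    ends = np.asarray(ends, dtype=int)
    dwell = (ends - starts) / sample_rate
    mean_amp = np.array([x[s:e].mean() for s, e in zip(starts, ends)])
    blockade = np.clip(1.0 - mean_amp / baseline, 0.0, 1.0) if baseline != 0 else np.zeros_like(mean_amp)
    if cutoff_hz:
        rise = 0.34 / cutoff_hz  # 10-90% rise time of a ~4-pole Bessel
        reliable = dwell >= 3.0 * rise
    else:
        reliable = np.ones_like(dwell, dtype=bool)

    events = pd.DataFrame(
        {
            "start": starts,
            "end": ends,
            "dwell_s": dwell,
            "mean_pA": mean_amp,
            "blockade": blockade,
            "reliable": reliable,
        }
    )
    total_time = len(x) / sample_rate
    occupied = dwell.sum() + censored_span / sample_rate
    return EventTable(
        events=events,
        sample_rate=sample_rate,
        baseline=baseline,
        sigma=float(sigma),
        total_time=total_time,
        unoccupied_time=max(total_time - occupied, 0.0),
        n_censored=n_censored,
    )


def fit_dwell_exponential(dwells: Sequence[float], bootstrap: int = 0, seed: int = 0) -> DwellFit:
    """Exponential MLE of the dwell-time constant: tau-hat = mean(dwells).

    The sample mean is the exact maximum-likelihood estimator for the
    exponential model; ``rate = 1/tau`` is the escape rate.  With
    ``bootstrap`` > 0 the SD of tau-hat over that many resamples is
    attached (0 otherwise).
    """
    d = np.asarray(list(dwells), dtype=float)
    if d.size == 0:
        raise ValueError("no dwell times to fit")
    if np.any(d <= 0):
        raise ValueError("dwell times must be positive")
    tau = float(d.mean())
    sd = bootstrap_sd(d, np.mean, B=bootstrap, seed=seed) if bootstrap else 0.0
    return DwellFit(tau=tau, rate=1.0 / tau, sd_tau=sd, n=d.size)


def bootstrap_sd(
    data: Sequence[float],
    estimator: Callable[[np.ndarray], float],
    B: int = 1000,
    seed: int = 0,
) -> float:
    """SD of ``estimator`` over B resamples (with replacement) of the data."""
    d = np.asarray(list(data), dtype=float)
    if d.size < 2:
        raise ValueError("bootstrap needs at least two observations")
    if B < 100:
        raise ValueError("use at least 100 bootstrap resamples")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, d.size, size=(B, d.size))
    stats = np.array([estimator(d[row]) for row in idx])
    return float(stats.std(ddof=1))


def capture_rate(table: EventTable, bootstrap: int = 1000, seed: int = 0) -> RateEstimates:
    """Capture and escape rates from an event table.

    Capture rate = (number of events) / (total unoccupied time), the
    waiting-time interpretation of events per second; escape rate is the
    inverse MLE dwell-time constant.  Bootstrap SDs resample the
    inter-event waiting times and the dwell times respectively.
    """
    n = len(table)
    if n == 0:
        raise ValueError("no events")
    if table.unoccupied_time <= 0:
        raise ValueError("zero unoccupied time")
    cap = n / table.unoccupied_time
    fit = fit_dwell_exponential(table.dwells, bootstrap=bootstrap, seed=seed)
    esc_sd = fit.sd_tau / fit.tau**2 if fit.sd_tau else 0.0
    if n >= 2 and bootstrap:
        waits = table.waiting_times()
        cap_sd = bootstrap_sd(waits, lambda w: 1.0 / max(w.mean(), 1e-300), B=bootstrap, seed=seed + 1)
    else:
        cap_sd = np.sqrt(n) / table.unoccupied_time
    return RateEstimates(
        capture=cap, capture_sd=cap_sd, escape=fit.rate, escape_sd=esc_sd, n_events=n
    )


def event_scatter(table: EventTable) -> pd.DataFrame:
    """Per-event (dwell_s, blockade) points with the reliability flag."""
    if len(table) == 0:
        raise ValueError("no events")
    return table.events[["dwell_s", "blockade", "reliable"]].copy()
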
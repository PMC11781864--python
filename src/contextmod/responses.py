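"""Instantaneous firing rates, response-latency detection, response windows.

The instantaneous rate is the trial-averaged convolution of the spike train
with a Gaussian kernel (σ = 10 ms, truncated where its amplitude falls below
1% of the peak), normalized so each spike contributes unit area — the trace
integrates to the mean spike count per trial.

The response latency is the earliest upward crossing of the instantaneous
rate over a threshold that persists for at least 90 ms, with sub-threshold
dips shorter than 20 ms bridged. The threshold is the pooled baseline mean
plus 4 SD (baseline: 900 to 100 ms before onset, across all stimuli), with a
5 Hz floor for units with low baseline firing.

The response window is the 500 ms following the latency onset when one is
found, and a fixed 200-700 ms window otherwise; response strength is the
median spike count across trials within the window. Recall responses use a
fixed [-1.5, +0.5] s window around vocalization onset and a gate requiring
the median in-window rate to exceed the baseline mean plus one SD, with a
3 Hz floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import AnalysisConfig


class InsufficientTrialsError(ValueError):
    """Too few (correct) trials to run the analysis."""


@dataclass
class RateTrace:
    """Trial-averaged instantaneous firing rate on a uniform time grid."""

    times: np.ndarray        # bin centers, s relative to the alignment event
    rate: np.ndarray         # Hz
    n_trials: int
    kernel_sigma: float

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0]) if self.times.size > 1 else np.nan


@dataclass
class ResponseProfile:
    """Latency, window, and per-trial counts of one unit for one condition."""

    unit_id: int
    task: str
    identity: int
    story: int
    latency: float | None
    window: tuple[float, float]
    counts: np.ndarray               # spikes per trial inside the window
    threshold_used: float | None = None
    gate_passed: bool | None = None  # recall responsiveness gate

    @property
    def strength(self) -> float:
        """Median spike count across trials in the response window."""
        return float(np.median(self.counts))

    @property
    def window_rate(self) -> float:
        """Mean firing rate in the window, Hz."""
        w0, w1 = self.window
        return float(np.mean(self.counts)) / (w1 - w0)


# ---------------------------------------------------------------------------
# alignment and rate estimation
# ---------------------------------------------------------------------------

def align_spikes(spike_times: np.ndarray, onsets: np.ndarray,
                 window: tuple[float, float]) -> list[np.ndarray]:
    """Per-trial spike times relative to each onset, clipped to ``window``."""
    t = np.asarray(spike_times, dtype=float)
    out = []
    for onset in np.asarray(onsets, dtype=float):
        rel = t[(t >= onset + window[0]) & (t < onset + window[1])] - onset
        out.append(rel)
    return out


def gaussian_kernel(sigma: float, dt: float, truncate_frac: float = 0.01) -> np.ndarray:
    """Discrete Gaussian kernel, truncated below ``truncate_frac`` of its peak,
    normalized to unit area (sum x dt = 1)."""
    if sigma <= 0 or dt <= 0:
        raise ValueError("sigma and dt must be > 0")
    half_width = sigma * np.sqrt(2.0 * np.log(1.0 / truncate_frac))
    n_half = int(np.ceil(half_width / dt))
    x = np.arange(-n_half, n_half + 1) * dt
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / (k.sum() * dt)


def instantaneous_rate(trial_spikes: list[np.ndarray],
                       window: tuple[float, float],
                       sigma: float = 0.010, dt: float = 0.001,
                       truncate_frac: float = 0.01) -> RateTrace:
    """Trial-averaged instantaneous firing rate over ``window``.

    ``trial_spikes`` holds per-trial spike times relative to the alignment
    event. Kernel mass falling outside the window is lost at the edges.
    """
    if len(trial_spikes) == 0:
        raise ValueError("need at least one trial")
    t0, t1 = window
    n_bins = int(round((t1 - t0) / dt))
    edges = t0 + np.arange(n_bins + 1) * dt
    counts = np.zeros(n_bins)
    for spikes in trial_spikes:
        s = np.asarray(spikes, dtype=float)
        s = s[(s >= t0) & (s < edges[-1])]
        if s.size:
            counts += np.histogram(s, bins=edges)[0]
    kernel = gaussian_kernel(sigma, dt, truncate_frac)
    rate = np.convolve(counts, kernel, mode="same") / len(trial_spikes)
    times = (edges[:-1] + edges[1:]) / 2.0
    return RateTrace(times=times, rate=rate, n_trials=len(trial_spikes),
                     kernel_sigma=sigma)


# ---------------------------------------------------------------------------
# threshold and latency
# ---------------------------------------------------------------------------

def detection_threshold(traces: list[RateTrace],
                        config: AnalysisConfig | None = None) -> float:
    """Latency-detection threshold from pooled pre-onset baseline samples.

    max(mean + 4 SD of the baseline rate samples pooled across all stimuli,
    5 Hz). The SD is over the pooled trial-averaged rate samples.
    """
    cfg = config or AnalysisConfig()
    b0, b1 = cfg.baseline_window
    pooled = []
    for tr in traces:
        mask = (tr.times >= b0) & (tr.times <= b1)
        if not mask.any():
            raise ValueError("trace has no samples in the baseline window")
        pooled.append(tr.rate[mask])
    samples = np.concatenate(pooled)
    thr = samples.mean() + cfg.threshold_n_sd * samples.std(ddof=0)
    return float(max(thr, cfg.threshold_floor_hz))


def detect_latency(trace: RateTrace, threshold: float,
                   config: AnalysisConfig | None = None) -> float | None:
    """Earliest sustained upward threshold crossing of the rate trace.

    The supra-threshold state must persist for at least ``min_run_s``, with
    sub-threshold dips shorter than ``max_gap_s`` bridged. A run already in
    progress at the start of the search window is not an onset: the crossing
    itself must happen inside the window. Returns None when no crossing
    qualifies.
    """
    cfg = config or AnalysisConfig()
    s0, s1 = cfg.latency_search
    dt = trace.dt
    in_search = (trace.times >= s0) & (trace.times <= s1)
    if not in_search.any():
        return None
    above = trace.rate > threshold

    # bridge sub-threshold gaps shorter than max_gap_s (interior gaps only)
    bridged = above.copy()
    i = 0
    n = above.size
    while i < n:
        if not bridged[i]:
            j = i
            while j < n and not bridged[j]:
                j += 1
            gap = (j - i) * dt
            if i > 0 and j < n and gap < cfg.max_gap_s:
                bridged[i:j] = True
            i = j
        else:
            i += 1

    # earliest qualifying run starting inside the search window
    idx_search = np.flatnonzero(in_search)
    i = 0
    while i < n:
        if bridged[i]:
            j = i
            while j < n and bridged[j]:
                j += 1
            run_start_t = trace.times[i]
            run_len = (j - i) * dt
            is_crossing = (i == 0) or (not bridged[i - 1])
            if (is_crossing and run_len >= cfg.min_run_s - 1e-12
                    and idx_search[0] <= i <= idx_search[-1]
                    and run_start_t >= s0):
                return float(run_start_t)
            i = j
        else:
            i += 1
    return None


# ---------------------------------------------------------------------------
# response profiles
# ---------------------------------------------------------------------------

def window_counts(spike_times: np.ndarray, onsets: np.ndarray,
                  window: tuple[float, float]) -> np.ndarray:
    """Spike counts per trial inside ``window`` relative to each onset."""
    t = np.asarray(spike_times, dtype=float)
    w0, w1 = window
    onsets = np.asarray(onsets, dtype=float)
    lo = np.searchsorted(t, onsets + w0, side="left")
    hi = np.searchsorted(t, onsets + w1, side="left")
    return (hi - lo).astype(int)


def encoding_response(spike_times: np.ndarray, onsets: np.ndarray,
                      threshold: float, unit_id: int = 0, task: str = "encoding",
                      identity: int = 0, story: int = 0,
                      config: AnalysisConfig | None = None) -> ResponseProfile:
    """Latency-anchored (or fixed-fallback) response profile for one condition.

    The latency is detected on the trial-averaged instantaneous rate of this
    condition's trials against the supplied threshold; the window is the
    500 ms after it, or the fixed 200-700 ms window when no latency is found.
    """
    cfg = config or AnalysisConfig()
    epoch = (-max(abs(cfg.baseline_window[0]), 1.0) - 0.1,
             cfg.latency_search[1] + cfg.window_length + 0.1)
    trials = align_spikes(spike_times, onsets, epoch)
    trace = instantaneous_rate(trials, epoch, cfg.kernel_sigma, cfg.rate_dt,
                               cfg.kernel_truncate_frac)
    latency = detect_latency(trace, threshold, cfg)
    if latency is not None:
        window = (latency, latency + cfg.window_length)
    else:
        window = cfg.fixed_window
    counts = window_counts(spike_times, onsets, window)
    return ResponseProfile(unit_id=unit_id, task=task, identity=identity,
                           story=story, latency=latency, window=window,
                           counts=counts, threshold_used=threshold)


def recall_gate_threshold(baseline_mean: float, baseline_sd: float,
                          config: AnalysisConfig | None = None) -> float:
    """Minimum median in-window rate for recall responsiveness:
    max(baseline mean + 1 SD, 3 Hz)."""
    cfg = config or AnalysisConfig()
    return float(max(baseline_mean + cfg.recall_baseline_n_sd * baseline_sd,
                     cfg.recall_floor_hz))


def recall_response(spike_times: np.ndarray, onsets: np.ndarray,
                    baseline_mean: float, baseline_sd: float,
                    unit_id: int = 0, identity: int = 0, story: int = 0,
                    config: AnalysisConfig | None = None) -> ResponseProfile:
    """Recall-phase response in the fixed window around vocalization onset.

    ``onsets`` should already be restricted to the trials being analyzed
    (by default, correct recalls only). The gate flag records whether the
    median in-window rate clears the recall threshold.
    """
    cfg = config or AnalysisConfig()
    window = cfg.recall_window
    counts = window_counts(spike_times, onsets, window)
    wlen = window[1] - window[0]
    median_rate = float(np.median(counts)) / wlen
    gate = median_rate > recall_gate_threshold(baseline_mean, baseline_sd, cfg)
    return ResponseProfile(unit_id=unit_id, task="recall", identity=identity,
                           story=story, latency=None, window=window,
                           counts=counts, gate_passed=bool(gate))


def check_recall_usable(events: pd.DataFrame,
                        config: AnalysisConfig | None = None) -> bool:
    """Whether the session has enough correct recall trials per identity."""
    cfg = config or AnalysisConfig()
    recalls = events[events.task == "recall"]
    if recalls.empty:
        return False
    for ident, grp in recalls.groupby("identity"):
        if int(grp.correct.sum()) < cfg.min_correct_recall:
            return False
    return True
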
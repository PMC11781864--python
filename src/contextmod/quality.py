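"""Unit quality metrics and single/multi-unit classification.

For each isolated unit we compute waveform signal-to-noise ratios, the
modified coefficient of variation of the inter-spike intervals, the fraction
of refractory-period violations, and the session-wide firing rate, and apply
the inclusion and single-/multi-unit rules:

* units firing below 0.1 Hz over the session are excluded;
* single units require a peak SNR above ~5 and under ~1% of inter-spike
  intervals shorter than 3 ms; everything else is a multi-unit.

``SNR_peak = |W̄(peak)| / σ_W`` where ``W̄`` is the mean waveform, ``peak`` the
sample where ``|W̄|`` is maximal, and ``σ_W`` the across-spike standard
deviation of the first epoched sample (a pre-spike sample carrying noise
only). ``SNR_whole`` is the RMS of the pointwise ratio ``W̄(i)/σ_W(i)`` over
all 64 samples. ``CV2`` is the mean over consecutive interval pairs of
``|ΔISI| / (mean ISI of the pair)`` and lies in [0, 2]: 0 for a perfectly
regular train, ~1 for a Poisson train.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AnalysisConfig


@dataclass
class UnitQuality:
    unit_id: int
    snr_peak: float          # NaN when undefined (zero noise SD)
    snr_whole: float
    cv2: float               # NaN when fewer than 2 ISIs
    isi_lt3ms_pct: float
    mean_rate: float         # Hz across the whole session
    n_spikes: int
    unit_class: str          # "single" | "multi" | "excluded"


def snr_peak(waveforms: np.ndarray, sigma_sample: str = "first") -> float:
    """Peak signal-to-noise ratio of a spike waveform matrix (n x 64).

    ``sigma_sample`` selects the noise estimate: the across-spike SD at the
    "first" epoched sample (default), or at the "peak" sample itself.
    Returns NaN (undefined, flagged) when that SD is zero.
    """
    w = np.asarray(waveforms, dtype=float)
    if w.ndim != 2 or w.shape[0] < 2:
        raise ValueError("need a 2-D waveform matrix with at least 2 spikes")
    mean_w = w.mean(axis=0)
    peak = int(np.argmax(np.abs(mean_w)))
    if sigma_sample == "first":
        sd = w[:, 0].std(ddof=1)
    elif sigma_sample == "peak":
        sd = w[:, peak].std(ddof=1)
    else:
        raise ValueError(f"sigma_sample must be 'first' or 'peak', got {sigma_sample!r}")
    if sd == 0:
        return float("nan")
    return float(np.abs(mean_w[peak]) / sd)


def snr_whole(waveforms: np.ndarray) -> float:
    """RMS of the pointwise mean-waveform / SD-waveform ratio over all samples."""
    w = np.asarray(waveforms, dtype=float)
    if w.ndim != 2 or w.shape[0] < 2:
        raise ValueError("need a 2-D waveform matrix with at least 2 spikes")
    mean_w = w.mean(axis=0)
    sd_w = w.std(axis=0, ddof=1)
    if np.any(sd_w == 0):
        return float("nan")
    return float(np.sqrt(np.mean((mean_w / sd_w) ** 2)))


def cv2(isis: np.ndarray) -> float:
    """Modified coefficient of variation over consecutive ISI pairs.

    mean over i of |ISI(i+1) - ISI(i)| / ((ISI(i+1) + ISI(i)) / 2);
    NaN (flagged undefined) with fewer than two intervals.
    """
    isi = np.asarray(isis, dtype=float)
    if isi.ndim != 1 or np.any(isi <= 0):
        raise ValueError("ISIs must be a 1-D array of positive durations")
    if isi.size < 2:
        return float("nan")
    num = np.abs(np.diff(isi))
    den = (isi[1:] + isi[:-1]) / 2.0
    return float(np.mean(num / den))


def isi_violation_pct(spike_times: np.ndarray, refractory_s: float = 0.003) -> float:
    """Percent of inter-spike intervals shorter than the refractory bound."""
    t = np.asarray(spike_times, dtype=float)
    if t.size < 2:
        return 0.0
    isi = np.diff(t)
    return float(100.0 * np.mean(isi < refractory_s))


def classify_unit(snr_peak_value: float, isi_lt3ms_pct: float, mean_rate: float,
                  config: AnalysisConfig | None = None) -> str:
    """Apply the exclusion and SU/MU rules.

    Excluded below 0.1 Hz; single when SNR_peak exceeds the single-unit bound
    AND refractory violations stay under the allowed percentage; multi
    otherwise. An undefined SNR (NaN) cannot support a single-unit call.
    """
    cfg = config or AnalysisConfig()
    if mean_rate < cfg.min_rate_hz:
        return "excluded"
    if (np.isfinite(snr_peak_value) and snr_peak_value > cfg.snr_single
            and isi_lt3ms_pct < cfg.isi_pct_single):
        return "single"
    return "multi"


def unit_quality(unit_id: int, spike_times: np.ndarray, waveforms: np.ndarray,
                 session_duration: float,
                 config: AnalysisConfig | None = None) -> UnitQuality:
    """All quality metrics plus the class label for one unit."""
    cfg = config or AnalysisConfig()
    t = np.asarray(spike_times, dtype=float)
    if session_duration <= 0:
        raise ValueError("session_duration must be > 0")
    rate = t.size / session_duration
    isi = np.diff(t)
    isi = isi[isi > 0]
    q_cv2 = cv2(isi) if isi.size >= 2 else float("nan")
    pct = isi_violation_pct(t, cfg.isi_refractory_s)
    w = np.atleast_2d(np.asarray(waveforms, dtype=float))
    if w.shape[0] >= 2 and w.shape[1] > 0:
        sp = snr_peak(w, cfg.snr_sigma_sample)
        sw = snr_whole(w)
    else:
        sp = sw = float("nan")
    return UnitQuality(unit_id=unit_id, snr_peak=sp, snr_whole=sw, cv2=q_cv2,
                       isi_lt3ms_pct=pct, mean_rate=rate, n_spikes=int(t.size),
                       unit_class=classify_unit(sp, pct, rate, cfg))


def quality_table(spike_trains: list[np.ndarray], waveforms: list[np.ndarray],
                  session_duration: float,
                  config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Per-unit quality table for a whole session."""
    rows = [unit_quality(u, t, w, session_duration, config)
            for u, (t, w) in enumerate(zip(spike_trains, waveforms))]
    return pd.DataFrame([r.__dict__ for r in rows])
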
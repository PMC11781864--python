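"""Rate estimation, detection threshold, latency, and response windows."""

import numpy as np
import pytest

from contextmod import (AnalysisConfig, detect_latency, detection_threshold,
                        encoding_response, instantaneous_rate,
                        recall_gate_threshold, recall_response, window_counts)
from contextmod.responses import (RateTrace, align_spikes, check_recall_usable,
                                  gaussian_kernel)
from conftest import step_trace
from oracles import brute_force_latency


def random_trace(cfg, rng, span=(-1.0, 1.2)):
    """Random smooth-ish trace for oracle comparisons."""
    dt = cfg.rate_dt
    n = int(round((span[1] - span[0]) / dt))
    times = span[0] + (np.arange(n) + 0.5) * dt
    # random piecewise-constant rate with segment lengths 5-120 ms
    rate = np.empty(n)
    i = 0
    while i < n:
        seg = rng.integers(5, 120)
        rate[i:i + seg] = rng.uniform(0, 15)
        i += seg
    return RateTrace(times=times, rate=rate, n_trials=1,
                     kernel_sigma=cfg.kernel_sigma)


# ---------------------------------------------------------------------------
# instantaneous rate
# ---------------------------------------------------------------------------

def test_rate_zero_without_spikes():
    tr = instantaneous_rate([np.array([])] * 5, (-1.0, 1.0))
    assert np.all(tr.rate == 0)


def test_rate_recovers_homogeneous_poisson(rng):
    trials = [np.sort(rng.uniform(-1, 1, rng.poisson(40))) for _ in range(200)]
    tr = instantaneous_rate(trials, (-1.0, 1.0))
    interior = (tr.times > -0.9) & (tr.times < 0.9)  # avoid edge loss
    assert np.mean(tr.rate[interior]) == pytest.approx(20.0, rel=0.1)


def test_rate_integrates_to_mean_count(rng):
    trials = [np.sort(rng.uniform(-0.5, 0.5, rng.poisson(12))) for _ in range(50)]
    tr = instantaneous_rate(trials, (-1.0, 1.0))
    mean_count = np.mean([t.size for t in trials])
    assert np.sum(tr.rate) * 0.001 == pytest.approx(mean_count, rel=0.02)


def test_kernel_unit_area_and_truncation():
    k = gaussian_kernel(0.010, 0.001, 0.01)
    assert k.sum() * 0.001 == pytest.approx(1.0)
    # truncated at 1% of peak: half-width ~= 3.03 sigma
    assert k.size == 2 * int(np.ceil(0.010 * np.sqrt(2 * np.log(100)) / 0.001)) + 1


# ---------------------------------------------------------------------------
# detection threshold
# ---------------------------------------------------------------------------

def test_threshold_floor_for_silent_unit(cfg):
    tr = step_trace(cfg, [], high=0.0, low=0.0)
    assert detection_threshold([tr], cfg) == 5.0


def test_threshold_constant_baseline(cfg):
    tr = step_trace(cfg, [], low=10.0)
    assert detection_threshold([tr], cfg) == 10.0


def test_threshold_mean_plus_4sd(cfg):
    tr = step_trace(cfg, [], low=3.0)
    # alternate baseline samples 3 and 7: mean 5, population SD 2 -> 13 Hz
    mask = (tr.times >= -0.9) & (tr.times <= -0.1)
    idx = np.flatnonzero(mask)
    tr.rate[idx[::2]] = 7.0
    assert detection_threshold([tr], cfg) == pytest.approx(13.0, abs=0.02)


# ---------------------------------------------------------------------------
# latency detection
# ---------------------------------------------------------------------------

def test_latency_none_below_threshold(cfg):
    tr = step_trace(cfg, [], low=1.0)
    assert detect_latency(tr, 5.0, cfg) is None


def test_latency_bridges_short_dip(cfg):
    tr = step_trace(cfg, [(0.30, 0.345), (0.360, 0.50)])
    assert detect_latency(tr, 5.0, cfg) == pytest.approx(0.30, abs=0.002)


def test_latency_rejects_short_run(cfg):
    tr = step_trace(cfg, [(0.30, 0.35)])
    assert detect_latency(tr, 5.0, cfg) is None


def test_latency_rejects_run_in_progress_at_zero(cfg):
    """A response already above threshold at t=0 has no upward crossing."""
    tr = step_trace(cfg, [(-0.2, 0.5)])
    assert detect_latency(tr, 5.0, cfg) is None


def test_latency_exact_90ms_run_accepted(cfg):
    tr = step_trace(cfg, [(0.40, 0.49)])
    assert detect_latency(tr, 5.0, cfg) == pytest.approx(0.40, abs=0.002)


def test_latency_matches_brute_force_oracle(cfg, rng):
    """Fast scanner agrees with the brute-force run-length oracle."""
    mismatches = 0
    for _ in range(300):
        tr = random_trace(cfg, rng)
        thr = rng.uniform(2, 12)
        got = detect_latency(tr, thr, cfg)
        want = brute_force_latency(tr.times, tr.rate, thr,
                                   cfg.min_run_s, cfg.max_gap_s,
                                   cfg.latency_search)
        if got != want and (got is None or want is None
                            or abs(got - want) > 1e-9):
            mismatches += 1
    assert mismatches == 0


def test_latency_monotone_in_threshold(cfg, rng):
    """Raising the threshold never yields an earlier latency.

    Traces start at the search origin: for a run already in progress at the
    edge of the search window the crossing rule can legitimately move the
    onset either way as the threshold changes.
    """
    for _ in range(100):
        tr = random_trace(cfg, rng, span=(0.0, 1.2))
        lats = []
        for thr in (3.0, 6.0, 9.0):
            lat = detect_latency(tr, thr, cfg)
            lats.append(np.inf if lat is None else lat)
        assert lats[0] <= lats[1] <= lats[2]


# ---------------------------------------------------------------------------
# response profiles
# ---------------------------------------------------------------------------

def test_encoding_window_from_latency(cfg, rng):
    # strong step response at 0.31 s on every trial
    onsets = np.arange(10.0, 10.0 + 15 * 6, 6.0)
    spikes = np.sort(np.concatenate(
        [o + np.sort(rng.uniform(0.31, 0.81, 25)) for o in onsets]))
    prof = encoding_response(spikes, onsets, threshold=5.0, config=cfg)
    assert prof.latency == pytest.approx(0.31, abs=0.03)
    assert prof.window[1] - prof.window[0] == pytest.approx(0.5)
    assert prof.window[0] == prof.latency


def test_encoding_fixed_window_fallback(cfg):
    onsets = np.arange(10.0, 100.0, 6.0)
    spikes = np.array([5.0])  # essentially silent
    prof = encoding_response(spikes, onsets, threshold=5.0, config=cfg)
    assert prof.latency is None
    assert prof.window == (0.2, 0.7)


def test_strength_is_median_of_counts(cfg):
    onsets = np.array([10.0, 20.0, 30.0, 40.0, 50.0])
    counts = [3, 5, 4, 6, 4]
    spikes = np.sort(np.concatenate(
        [o + np.linspace(0.25, 0.65, c) for o, c in zip(onsets, counts)]))
    prof = encoding_response(spikes, onsets, threshold=100.0, config=cfg)
    assert prof.window == (0.2, 0.7)
    np.testing.assert_array_equal(np.sort(prof.counts), np.sort(counts))
    assert prof.strength == 4.0


def test_window_counts_half_open(cfg):
    spikes = np.array([0.2, 0.45, 0.7])
    counts = window_counts(spikes, np.array([0.0]), (0.2, 0.7))
    assert counts[0] == 2  # [0.2, 0.7): includes left edge, excludes right


def test_recall_gate_threshold_floor(cfg):
    assert recall_gate_threshold(0.0, 0.0, cfg) == 3.0
    assert recall_gate_threshold(10.0, 2.0, cfg) == 12.0


def test_recall_gate_fails_below_floor(cfg, rng):
    # ~2 Hz in the recall window, baseline stats 0.5 +/- 0.5 -> floor binds
    onsets = np.arange(20.0, 20.0 + 12 * 10, 10.0)
    spikes = np.sort(np.concatenate(
        [o + np.sort(rng.uniform(-1.5, 0.5, 4)) for o in onsets]))
    prof = recall_response(spikes, onsets, baseline_mean=0.5, baseline_sd=0.5,
                           config=cfg)
    assert prof.window == (-1.5, 0.5)
    assert prof.gate_passed is False


def test_recall_gate_passes_strong_response(cfg, rng):
    onsets = np.arange(20.0, 20.0 + 12 * 10, 10.0)
    spikes = np.sort(np.concatenate(
        [o + np.sort(rng.uniform(-1.5, 0.5, 20)) for o in onsets]))  # 10 Hz
    prof = recall_response(spikes, onsets, baseline_mean=1.0, baseline_sd=1.0,
                           config=cfg)
    assert prof.gate_passed is True


def test_too_few_correct_recalls_flags_session(cfg):
    import pandas as pd
    rows = []
    for ident in (1, 2):
        for k in range(12):
            rows.append(dict(task="recall", trial=k, identity=ident, story=1,
                             onset_s=100.0 + 20 * k,
                             correct=(k < 8 if ident == 1 else True)))
    events = pd.DataFrame(rows)
    assert check_recall_usable(events, cfg) is False  # identity 1: 8 < 10
    events["correct"] = True
    assert check_recall_usable(events, cfg) is True
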
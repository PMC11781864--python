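"""Population summaries: normalized rate traces, activity measures, correlations.

Each responsive unit's trial-averaged rate is normalized by subtracting its
baseline mean and dividing by the encoding-phase peak of its responsive
stories, so the responsive encoding trace peaks at 1. The same factor is
reused for VP traces (which may therefore exceed 1); recall traces use the
recall-phase peak. The per-unit activity measure is the mean-rate difference
between responsive and non-responsive stimuli in a task-specific window
(0.1-0.8 s post-onset for encoding/VP, -2.5 to 0.75 s around vocalization
for recall), and context invariance at the population level shows up as a
strong story-1 vs story-2 correlation of these activities across units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import AnalysisConfig
from .responses import RateTrace


@dataclass
class NormalizedTrace:
    unit_id: int
    task: str
    identity: int
    story: int
    times: np.ndarray
    rate: np.ndarray          # normalized, responsive encoding peak = 1


class DegenerateUnitError(ValueError):
    """Unit cannot be normalized (no peak above its baseline)."""


def normalization_factor(trace: RateTrace, baseline_mean: float,
                         window: tuple[float, float] | None = None,
                         normalize_to_one: bool = True) -> float:
    """Per-unit divisor from the responsive-story trace of the anchor task.

    Default: peak minus baseline mean, so the anchor trace peaks at exactly 1
    after baseline subtraction. ``normalize_to_one=False`` divides by the raw
    peak instead (the anchor peak then lands below 1).
    """
    rate = trace.rate
    if window is not None:
        mask = (trace.times >= window[0]) & (trace.times <= window[1])
        rate = rate[mask]
    peak = float(rate.max()) if rate.size else 0.0
    factor = (peak - baseline_mean) if normalize_to_one else peak
    if factor <= 0:
        raise DegenerateUnitError("no peak above baseline; unit excluded "
                                  "from the population summary")
    return factor


def normalize_trace(trace: RateTrace, baseline_mean: float, factor: float,
                    unit_id: int = 0, task: str = "encoding",
                    identity: int = 0, story: int = 0) -> NormalizedTrace:
    """(rate - baseline mean) / factor on the trace's own grid."""
    if factor <= 0:
        raise DegenerateUnitError("normalization factor must be > 0")
    return NormalizedTrace(unit_id=unit_id, task=task, identity=identity,
                           story=story, times=trace.times,
                           rate=(trace.rate - baseline_mean) / factor)


def activity_measure(rate_responsive: RateTrace, rate_nonresponsive: RateTrace,
                     task: str, config: AnalysisConfig | None = None) -> float:
    """Mean rate difference (responsive - non-responsive stimuli), Hz,
    inside the task's activity window."""
    cfg = config or AnalysisConfig()
    if task in ("encoding", "vp"):
        w = cfg.activity_window_encoding
    elif task == "recall":
        w = cfg.activity_window_recall
    else:
        raise ValueError(f"unknown task {task!r}")

    def mean_in(tr: RateTrace) -> float:
        mask = (tr.times >= w[0]) & (tr.times <= w[1])
        if not mask.any():
            raise ValueError(f"trace does not cover the {task} activity window {w}")
        return float(tr.rate[mask].mean())

    return mean_in(rate_responsive) - mean_in(rate_nonresponsive)


def story_task_correlations(activity: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations of per-unit activity across stories and tasks.

    ``activity`` needs columns unit_id, task, story, activity (one row per
    unit x task x story; VP rows may carry story 0). Reported comparisons:
    story1-vs-story2 within encoding and recall, and between-task pairs on
    per-unit story-mean activity.
    """
    req = {"unit_id", "task", "story", "activity"}
    if not req.issubset(activity.columns):
        raise ValueError(f"activity table needs columns {sorted(req)}")
    rows = []

    def corr(x: np.ndarray, y: np.ndarray, label: str) -> None:
        if len(x) < 3:
            return
        if np.std(x) == 0 or np.std(y) == 0:
            rows.append(dict(comparison=label, r=float("nan"), p=float("nan"),
                             n=len(x)))
            return
        r, p = sps.pearsonr(x, y)
        rows.append(dict(comparison=label, r=float(r), p=float(p), n=len(x)))

    # story 1 vs story 2 within a task
    for task in ("encoding", "recall"):
        sub = activity[activity.task == task]
        wide = sub.pivot_table(index="unit_id", columns="story",
                               values="activity")
        if {1, 2}.issubset(wide.columns):
            both = wide[[1, 2]].dropna()
            corr(both[1].to_numpy(), both[2].to_numpy(), f"{task}_story1_vs_story2")

    # task vs task on per-unit mean activity
    mean_act = (activity.groupby(["unit_id", "task"])["activity"]
                .mean().unstack("task"))
    for a, b in (("encoding", "vp"), ("recall", "vp"), ("encoding", "recall")):
        if a in mean_act.columns and b in mean_act.columns:
            both = mean_act[[a, b]].dropna()
            corr(both[a].to_numpy(), both[b].to_numpy(), f"{a}_vs_{b}")

    return pd.DataFrame(rows, columns=["comparison", "r", "p", "n"])


def latency_sort(unit_latencies: dict[int, list[float | None]]) -> list[int]:
    """Unit ordering by mean latency over responsive stories.

    ``unit_latencies[u]`` holds the latencies of unit ``u``'s responsive
    stories (None entries ignored). Units with no defined latency go last;
    the sort is stable, so ties keep input order.
    """
    keys = []
    for u, lats in unit_latencies.items():
        vals = [l for l in lats if l is not None]
        keys.append((u, np.mean(vals) if vals else np.inf))
    order = sorted(range(len(keys)), key=lambda i: keys[i][1])
    return [keys[i][0] for i in order]
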
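"""Analysis configuration: every threshold of the pipeline as a named field.

Keeping all criteria in one serializable object makes robustness re-runs
(different significance levels, different windows) a one-flag change and lets
every report record exactly the parameters it was produced with.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field


@dataclass
class AnalysisConfig:
    """Thresholds and parameters for a full session analysis.

    Units are seconds and Hz throughout unless noted.
    """

    # -- significance ------------------------------------------------------
    alpha: float = 0.01                 # two-sided level for all verdicts

    # -- unit quality ------------------------------------------------------
    min_rate_hz: float = 0.1            # units below this are excluded
    snr_single: float = 5.0             # SNR_peak bound for single units
    isi_pct_single: float = 1.0         # % ISIs < 3 ms allowed for single units
    isi_refractory_s: float = 0.003
    snr_sigma_sample: str = "first"     # denominator of SNR_peak: SD at "first"
                                        # epoched sample, or at the "peak" sample

    # -- instantaneous rate ------------------------------------------------
    kernel_sigma: float = 0.010         # Gaussian kernel width
    kernel_truncate_frac: float = 0.01  # truncate kernel below 1% of its peak
    rate_dt: float = 0.001              # time grid step

    # -- latency detection -------------------------------------------------
    baseline_window: tuple[float, float] = (-0.9, -0.1)
    threshold_n_sd: float = 4.0
    threshold_floor_hz: float = 5.0
    min_run_s: float = 0.090            # supra-threshold persistence
    max_gap_s: float = 0.020            # sub-threshold dips bridged
    latency_search: tuple[float, float] = (0.0, 1.0)

    # -- response windows --------------------------------------------------
    window_length: float = 0.5          # latency-anchored window
    fixed_window: tuple[float, float] = (0.2, 0.7)   # fallback, no latency
    recall_window: tuple[float, float] = (-1.5, 0.5)
    recall_floor_hz: float = 3.0
    recall_baseline_n_sd: float = 1.0
    recall_correct_only: bool = True
    min_correct_recall: int = 10        # per identity; else recall unusable

    # -- permutation / equivalence -----------------------------------------
    n_perm: int = 1000                  # strength & latency permutations
    tost_alpha: float = 0.05
    tost_beta: float = 0.05

    # -- decoding ----------------------------------------------------------
    n_shuffles: int = 10_000            # decoder label shuffles
    nb_pseudocount: float = 0.5         # spikes added per window (smoothing)
    nb_likelihood: str = "poisson"      # or "gaussian"
    nb_priors: str = "uniform"          # or "empirical" (from training fold)
    sliding_step: float = 0.025
    sliding_width_encoding: float = 0.25
    sliding_width_recall: float = 1.0
    cluster_alpha: float = 0.01
    cluster_min_duration: float = 0.100
    n_perm_cluster: int = 1000

    # -- population --------------------------------------------------------
    activity_window_encoding: tuple[float, float] = (0.1, 0.8)
    activity_window_recall: tuple[float, float] = (-2.5, 0.75)
    normalize_to_one: bool = True       # divide by (peak - baseline mean)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, default=list)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        kwargs = {}
        for k, v in d.items():
            if k not in fields:
                raise ValueError(f"unknown config field: {k!r}")
            kwargs[k] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)

    @classmethod
    def from_json(cls, text: str) -> "AnalysisConfig":
        return cls.from_dict(json.loads(text))
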
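"""Identity/context statistics: ANOVAs, permutation tests, TOST equivalence.

Responsiveness and context modulation are assessed with

* a two-way fixed-effects ANOVA of the per-trial spike count with factors
  identity and context (story), including their interaction — a unit is
  story-modulated when the context factor or the interaction is significant;
* permutation tests comparing the absolute difference in response strength
  (median count) and in response latency between the two stories of an
  identity against 1000 label-shuffled surrogates;
* a TOST (two one-sided tests) equivalence procedure with Welch t statistics
  and symmetric standardized bounds ±d0, where
  d0 = sqrt(2 (z_alpha + z_{beta/2})^2 / min(n1, n2)) — the bound at which a
  test with type-I error alpha attains power 1 - beta against a true zero
  difference, under the normal approximation.

All permutation p-values use the (k + 1) / (N + 1) convention, so the
smallest reportable p with 1000 surrogates is 1/1001 < 0.001, attained
exactly when the observed statistic exceeds every surrogate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .config import AnalysisConfig
from .responses import RateTrace, detect_latency, instantaneous_rate


@dataclass
class AnovaResult:
    f_identity: float
    f_context: float
    f_interaction: float
    p_identity: float
    p_context: float
    p_interaction: float
    total_df: int


@dataclass
class EquivResult:
    t_l: float
    t_u: float
    d0: float
    delta_l: float
    delta_u: float
    df: float
    t_crit: float
    alpha: float
    beta: float
    verdict: str              # "equivalent" | "inconclusive"
    degenerate: bool = False

    @property
    def equivalent(self) -> bool:
        return self.verdict == "equivalent"


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------

def anova_two_way(counts: np.ndarray, identity: np.ndarray,
                  story: np.ndarray, ss_type: int = 2) -> AnovaResult:
    """Two-factor fixed-effects ANOVA with interaction on per-trial counts.

    Type II sums of squares by default (identical to Type I on balanced
    designs; appropriate when discarding incorrect trials unbalances cells).
    Zero overall variance is reported explicitly as p = 1, F undefined.
    """
    counts = np.asarray(counts, dtype=float)
    identity = np.asarray(identity)
    story = np.asarray(story)
    if counts.shape != identity.shape or counts.shape != story.shape:
        raise ValueError("counts, identity, story must have equal length")
    df_total = counts.size - 1
    cells = pd.crosstab(identity, story)
    if (cells.values < 2).any() or cells.size < 4:
        raise ValueError("need >= 2 trials in every identity x story cell")
    if np.ptp(counts) == 0:
        nan = float("nan")
        return AnovaResult(nan, nan, nan, 1.0, 1.0, 1.0, df_total)
    data = pd.DataFrame({"count": counts, "identity": identity, "story": story})
    model = smf.ols("count ~ C(identity) * C(story)", data=data).fit()
    table = sm.stats.anova_lm(model, typ=ss_type)
    def row(name):
        return table.loc[name, "F"], table.loc[name, "PR(>F)"]
    f_i, p_i = row("C(identity)")
    f_c, p_c = row("C(story)")
    f_x, p_x = row("C(identity):C(story)")
    return AnovaResult(float(f_i), float(f_c), float(f_x),
                       float(p_i), float(p_c), float(p_x), df_total)


def anova_one_way(counts: np.ndarray, stimulus: np.ndarray) -> tuple[float, float, int]:
    """One-factor fixed-effects ANOVA across stimuli; (F, p, total_df)."""
    counts = np.asarray(counts, dtype=float)
    stimulus = np.asarray(stimulus)
    groups = [counts[stimulus == s] for s in np.unique(stimulus)]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 stimuli with >= 2 trials each")
    if np.ptp(counts) == 0:
        return float("nan"), 1.0, counts.size - 1
    f, p = sps.f_oneway(*groups)
    return float(f), float(p), counts.size - 1


def story_modulation_verdict(a: AnovaResult, alpha: float = 0.01) -> bool:
    """Story modulation is significant when context OR interaction is (strict <)."""
    return bool(a.p_context < alpha or a.p_interaction < alpha)


# ---------------------------------------------------------------------------
# permutation tests
# ---------------------------------------------------------------------------

def permutation_pvalue(observed: float, surrogates: np.ndarray) -> float:
    """(k + 1) / (N + 1) with k = #{surrogates >= observed}."""
    surrogates = np.asarray(surrogates, dtype=float)
    k = int(np.sum(surrogates >= observed))
    return (k + 1) / (surrogates.size + 1)


def permutation_strength(counts_a: np.ndarray, counts_b: np.ndarray,
                         n_perm: int = 1000,
                         rng: np.random.Generator | int | None = None) -> float:
    """Permutation p for the absolute difference in response strength.

    Strength is the median per-trial count; trial labels are shuffled
    between the two conditions.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    rng = np.random.default_rng(rng)
    observed = abs(np.median(a) - np.median(b))
    pooled = np.concatenate([a, b])
    n_a = a.size
    # all n_perm permutations at once: rows of random ranks
    idx = np.argsort(rng.random((n_perm, pooled.size)), axis=1)
    perm = pooled[idx]
    surr = np.abs(np.median(perm[:, :n_a], axis=1)
                  - np.median(perm[:, n_a:], axis=1))
    return permutation_pvalue(observed, surr)


def _latency_of_trials(trials: list[np.ndarray], epoch: tuple[float, float],
                       threshold: float, cfg: AnalysisConfig) -> float | None:
    trace = instantaneous_rate(trials, epoch, cfg.kernel_sigma, cfg.rate_dt,
                               cfg.kernel_truncate_frac)
    return detect_latency(trace, threshold, cfg)


def permutation_latency(trials_a: list[np.ndarray], trials_b: list[np.ndarray],
                        threshold: float, n_perm: int = 1000,
                        rng: np.random.Generator | int | None = None,
                        config: AnalysisConfig | None = None,
                        undefined_policy: str = "inf") -> float:
    """Permutation p for the absolute latency difference between two conditions.

    Each latency is recomputed from the trial-averaged rate of the permuted
    trial sets. Surrogates on which a latency cannot be defined contribute
    +inf (counting against significance) under the default policy, or are
    discarded under ``undefined_policy="discard"``.

    Raises when a latency is undefined on the observed data (the test is
    then not applicable).
    """
    cfg = config or AnalysisConfig()
    if undefined_policy not in ("inf", "discard"):
        raise ValueError("undefined_policy must be 'inf' or 'discard'")
    rng = np.random.default_rng(rng)
    epoch = (cfg.baseline_window[0] - 0.1,
             cfg.latency_search[1] + cfg.window_length + 0.1)
    lat_a = _latency_of_trials(trials_a, epoch, threshold, cfg)
    lat_b = _latency_of_trials(trials_b, epoch, threshold, cfg)
    if lat_a is None or lat_b is None:
        raise ValueError("latency undefined on observed data; test not applicable")
    observed = abs(lat_a - lat_b)
    pooled = list(trials_a) + list(trials_b)
    n_a = len(trials_a)
    surr = []
    for _ in range(n_perm):
        idx = rng.permutation(len(pooled))
        perm_a = [pooled[i] for i in idx[:n_a]]
        perm_b = [pooled[i] for i in idx[n_a:]]
        la = _latency_of_trials(perm_a, epoch, threshold, cfg)
        lb = _latency_of_trials(perm_b, epoch, threshold, cfg)
        if la is None or lb is None:
            if undefined_policy == "inf":
                surr.append(np.inf)
            continue
        surr.append(abs(la - lb))
    return permutation_pvalue(observed, np.asarray(surr))


# ---------------------------------------------------------------------------
# TOST equivalence
# ---------------------------------------------------------------------------

def tost_bound_d0(n1: int, n2: int, alpha: float = 0.05, beta: float = 0.05) -> float:
    """Standardized symmetric equivalence bound d0.

    Normal-approximation bound at which the TOST with per-test level alpha
    reaches power 1 - beta against a truly zero difference:
    d0 = sqrt(2 (z_alpha + z_{beta/2})^2 / min(n1, n2)).
    """
    z = sps.norm.ppf
    return float(np.sqrt(2.0 * (z(1 - alpha) + z(1 - beta / 2.0)) ** 2
                         / min(n1, n2)))


def tost_equivalence(counts_a: np.ndarray, counts_b: np.ndarray,
                     alpha: float = 0.05, beta: float = 0.05) -> EquivResult:
    """TOST equivalence of two trial-count samples with Welch t statistics.

    Bounds are ±d0 x pooled SD; both one-sided nulls (difference beyond a
    bound) must be rejected at level alpha with Welch-Satterthwaite degrees
    of freedom for an "equivalent" verdict; otherwise "inconclusive".
    Identical constant samples are degenerate-equivalent.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 trials per sample")
    m1, m2 = a.mean(), b.mean()
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    d0 = tost_bound_d0(n1, n2, alpha, beta)
    pooled_sd = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
    delta_u = d0 * pooled_sd
    delta_l = -delta_u
    if pooled_sd == 0:
        verdict = "equivalent" if m1 == m2 else "inconclusive"
        return EquivResult(t_l=float("nan"), t_u=float("nan"), d0=d0,
                           delta_l=delta_l, delta_u=delta_u,
                           df=float(n1 + n2 - 2), t_crit=float("nan"),
                           alpha=alpha, beta=beta, verdict=verdict,
                           degenerate=True)
    se2 = v1 / n1 + v2 / n2
    se = np.sqrt(se2)
    df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    t_l = (m1 - m2 - delta_l) / se
    t_u = (m1 - m2 - delta_u) / se
    t_crit = float(sps.t.ppf(1 - alpha, df))
    verdict = "equivalent" if (t_l > t_crit and t_u < -t_crit) else "inconclusive"
    return EquivResult(t_l=float(t_l), t_u=float(t_u), d0=d0,
                       delta_l=float(delta_l), delta_u=float(delta_u),
                       df=float(df), t_crit=t_crit, alpha=alpha, beta=beta,
                       verdict=verdict)
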
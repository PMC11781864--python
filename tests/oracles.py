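"""Independent brute-force oracles used to validate the fast implementations.

Each oracle is written as plainly as possible (explicit loops, library pmf
calls, textbook formulas) and deliberately shares no code with the package
paths it checks.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps


def brute_force_latency(times: np.ndarray, rate: np.ndarray, threshold: float,
                        min_run: float = 0.090, max_gap: float = 0.020,
                        search: tuple[float, float] = (0.0, 1.0)) -> float | None:
    """Run-length scan for the earliest sustained threshold crossing.

    Walks every candidate onset sample and simulates forward, tracking the
    consecutive sub-threshold time; dips shorter than ``max_gap`` are
    forgiven, a dip reaching ``max_gap`` (or the end of the trace) ends the
    run. The onset must be a genuine upward crossing inside ``search`` and
    its run must last at least ``min_run``.
    """
    dt = times[1] - times[0]
    n = len(times)
    for i in range(n):
        if not (search[0] <= times[i] <= search[1]):
            continue
        if rate[i] <= threshold:
            continue
        if i > 0 and rate[i - 1] > threshold:
            continue  # already above: not a crossing
        # a forgivable (< max_gap) dip attaching to an earlier above-segment
        # makes this a run continuation, not an onset
        k = i - 1
        below = 0.0
        while k >= 0 and rate[k] <= threshold:
            below += dt
            k -= 1
        if k >= 0 and below < max_gap:
            continue
        run = 0.0
        gap = 0.0
        j = i
        while j < n:
            if rate[j] > threshold:
                run += (gap + dt)  # forgiven dip counts toward persistence
                gap = 0.0
            else:
                gap += dt
                if gap >= max_gap:
                    break
            j += 1
        if run >= min_run - 1e-12:
            return float(times[i])
    return None


def brute_force_nb_loocv(X: np.ndarray, y: np.ndarray, pseudocount: float = 0.5,
                         priors: str = "uniform") -> np.ndarray:
    """Leave-one-out Poisson naive-Bayes by explicit per-fold enumeration."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    n = len(y)
    pred = np.empty(n, dtype=y.dtype)
    for i in range(n):
        train = [j for j in range(n) if j != i]
        scores = []
        for c in classes:
            rows = [j for j in train if y[j] == c]
            score = 0.0
            for u in range(X.shape[1]):
                lam = np.mean([X[j, u] for j in rows]) + pseudocount
                score += sps.poisson.logpmf(X[i, u], lam)
            if priors == "empirical":
                score += np.log(len(rows) / len(train))
            scores.append(score)
        pred[i] = classes[int(np.argmax(scores))]
    return pred


def anova_2x2_hand(cells: dict[tuple[int, int], np.ndarray]) -> dict:
    """Balanced 2x2 fixed-effects ANOVA from textbook sums of squares.

    ``cells[(a, b)]`` holds the n replicate values of cell (a, b); all cells
    must have equal n. Returns F and p for factor A, factor B and the
    interaction, plus the total df.
    """
    ns = {len(v) for v in cells.values()}
    assert len(ns) == 1, "balanced design required"
    n = ns.pop()
    a_levels = sorted({a for a, _ in cells})
    b_levels = sorted({b for _, b in cells})
    all_vals = np.concatenate([np.asarray(v, float) for v in cells.values()])
    grand = all_vals.mean()
    n_total = all_vals.size
    mean_a = {a: np.mean(np.concatenate([cells[(a, b)] for b in b_levels]))
              for a in a_levels}
    mean_b = {b: np.mean(np.concatenate([cells[(a, b)] for a in a_levels]))
              for b in b_levels}
    ss_a = n * len(b_levels) * sum((mean_a[a] - grand) ** 2 for a in a_levels)
    ss_b = n * len(a_levels) * sum((mean_b[b] - grand) ** 2 for b in b_levels)
    ss_cells = n * sum((np.mean(cells[(a, b)]) - grand) ** 2
                       for a in a_levels for b in b_levels)
    ss_ab = ss_cells - ss_a - ss_b
    ss_err = sum(((np.asarray(cells[(a, b)], float)
                   - np.mean(cells[(a, b)])) ** 2).sum()
                 for a in a_levels for b in b_levels)
    df_a = len(a_levels) - 1
    df_b = len(b_levels) - 1
    df_ab = df_a * df_b
    df_err = n_total - len(a_levels) * len(b_levels)
    ms_err = ss_err / df_err
    out = {}
    for name, ss, df in (("a", ss_a, df_a), ("b", ss_b, df_b),
                         ("ab", ss_ab, df_ab)):
        f = (ss / df) / ms_err
        out[f"f_{name}"] = f
        out[f"p_{name}"] = float(sps.f.sf(f, df, df_err))
    out["total_df"] = n_total - 1
    return out


def sorted_by_latency(unit_ids: list[int], latencies: list[float | None]) -> list[int]:
    """Stable latency sort by exhaustive selection (None last)."""
    remaining = list(range(len(unit_ids)))
    order = []
    while remaining:
        best = None
        for idx in remaining:
            key = latencies[idx] if latencies[idx] is not None else float("inf")
            if best is None or key < (latencies[best] if latencies[best] is not None
                                      else float("inf")):
                best = idx
        order.append(unit_ids[best])
        remaining.remove(best)
    return order
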
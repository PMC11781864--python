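"""Full-session orchestration: quality -> responses -> statistics -> decoding.

``run_session`` sequences the whole analysis for one session and returns a
:class:`SessionReport` whose summary counts (responsive units, story-modulated
units, equivalence verdicts, recall-responsive units) are all aggregations of
the persisted row-level tables. ``summarize_cohort`` pools reports across
sessions.

Responsiveness follows the study's criteria: a unit is responsive for
identity during encoding when the two-way ANOVA identity factor is
significant (p < 0.01) and a latency onset is defined for at least one
story; story modulation requires a significant context factor or
interaction; recall responsiveness additionally requires the median-rate
gate. Decoding always uses all recorded units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from . import quality as qm
from . import responses as resp
from . import stats as st
from . import decoding as dec
from .synthetic import SessionData, IDENTITIES, STORIES

logger = logging.getLogger(__name__)


@dataclass
class SessionReport:
    quality: pd.DataFrame         # one row per unit
    responses: pd.DataFrame       # one row per unit x task x condition
    verdicts: pd.DataFrame        # one row per unit: tests and flags
    decoding: dict                # {(task, mode): DecodeResult}
    summary: dict
    config: AnalysisConfig
    rng_seed: int
    recall_usable: bool = True


def _encoding_profiles(session: SessionData, unit: int,
                       cfg: AnalysisConfig) -> tuple[list[resp.ResponseProfile], float]:
    """Per-story encoding response profiles plus the detection threshold."""
    spikes = session.spike_trains[unit]
    events = session.events
    enc = events[events.task == "encoding"]
    epoch = (cfg.baseline_window[0] - 0.1,
             cfg.latency_search[1] + cfg.window_length + 0.1)
    traces = []
    conds = [(i, s) for i in IDENTITIES for s in STORIES]
    for ident, story in conds:
        onsets = enc[(enc.identity == ident) & (enc.story == story)].onset_s.to_numpy()
        trials = resp.align_spikes(spikes, onsets, epoch)
        traces.append(resp.instantaneous_rate(trials, epoch, cfg.kernel_sigma,
                                              cfg.rate_dt, cfg.kernel_truncate_frac))
    threshold = resp.detection_threshold(traces, cfg)
    profiles = []
    for ident, story in conds:
        onsets = enc[(enc.identity == ident) & (enc.story == story)].onset_s.to_numpy()
        profiles.append(resp.encoding_response(spikes, onsets, threshold,
                                               unit_id=unit, identity=ident,
                                               story=story, config=cfg))
    return profiles, threshold


def _baseline_trial_rates(session: SessionData, unit: int,
                          cfg: AnalysisConfig) -> np.ndarray:
    """Per-trial pre-onset baseline rates (Hz) over encoding trials."""
    enc = session.events[session.events.task == "encoding"]
    b0, b1 = cfg.baseline_window
    counts = resp.window_counts(session.spike_trains[unit],
                                enc.onset_s.to_numpy(), (b0, b1))
    return counts / (b1 - b0)


def run_session(session: SessionData, config: AnalysisConfig | None = None,
                rng_seed: int = 0, n_shuffles: int | None = None) -> SessionReport:
    """Analyze one session end to end. Deterministic given ``rng_seed``."""
    cfg = config or AnalysisConfig()
    rng = np.random.default_rng(rng_seed)
    n_shuffles = cfg.n_shuffles if n_shuffles is None else n_shuffles
    events = session.events
    n_units = session.n_units
    logger.info("run_session: %d units, alpha=%g, kernel sigma=%g s",
                n_units, cfg.alpha, cfg.kernel_sigma)

    quality = qm.quality_table(session.spike_trains, session.waveforms,
                               session.duration, cfg)

    recall_ok = resp.check_recall_usable(events, cfg)
    response_rows = []
    verdict_rows = []
    enc_windows: list[tuple[float, float]] = []

    for u in range(n_units):
        spikes = session.spike_trains[u]
        profiles, threshold = _encoding_profiles(session, u, cfg)
        for p in profiles:
            response_rows.append(dict(
                unit_id=u, task="encoding", identity=p.identity, story=p.story,
                latency=p.latency, window_start=p.window[0],
                window_end=p.window[1], strength=p.strength,
                window_rate=p.window_rate, threshold=threshold,
                n_trials=len(p.counts)))

        counts = np.concatenate([p.counts for p in profiles])
        ident_lab = np.concatenate([[p.identity] * len(p.counts) for p in profiles])
        story_lab = np.concatenate([[p.story] * len(p.counts) for p in profiles])
        anova = st.anova_two_way(counts, ident_lab, story_lab)
        has_latency = any(p.latency is not None for p in profiles)
        responsive = anova.p_identity < cfg.alpha and has_latency
        modulated = st.story_modulation_verdict(anova, cfg.alpha)

        # preferred identity: larger summed response strength
        strength_by_ident = {i: sum(p.strength for p in profiles if p.identity == i)
                             for i in IDENTITIES}
        pref = max(IDENTITIES, key=lambda i: strength_by_ident[i])
        pair = [p for p in profiles if p.identity == pref]
        p_strength = st.permutation_strength(pair[0].counts, pair[1].counts,
                                             cfg.n_perm, rng)
        tost = st.tost_equivalence(pair[0].counts, pair[1].counts,
                                   cfg.tost_alpha, cfg.tost_beta)

        # decoding window for this unit: strongest story's window
        best = max(profiles, key=lambda p: (p.latency is not None, p.strength))
        enc_windows.append(best.window)

        row = dict(unit_id=u, threshold=threshold,
                   p_identity=anova.p_identity, p_context=anova.p_context,
                   p_interaction=anova.p_interaction, total_df=anova.total_df,
                   has_latency=has_latency, responsive_encoding=responsive,
                   story_modulated=bool(responsive and modulated),
                   preferred_identity=pref, p_perm_strength=p_strength,
                   tost_verdict=tost.verdict, tost_d0=tost.d0,
                   equivalent=bool(tost.equivalent))

        # recall phase
        if recall_ok:
            rec = events[events.task == "recall"]
            if cfg.recall_correct_only:
                rec = rec[rec.correct]
            base_rates = _baseline_trial_rates(session, u, cfg)
            b_mean, b_sd = float(base_rates.mean()), float(base_rates.std(ddof=1))
            rec_profiles = []
            for ident in IDENTITIES:
                for story in STORIES:
                    onsets = rec[(rec.identity == ident)
                                 & (rec.story == story)].onset_s.to_numpy()
                    rp = resp.recall_response(spikes, onsets, b_mean, b_sd,
                                              unit_id=u, identity=ident,
                                              story=story, config=cfg)
                    rec_profiles.append(rp)
                    response_rows.append(dict(
                        unit_id=u, task="recall", identity=ident, story=story,
                        latency=None, window_start=rp.window[0],
                        window_end=rp.window[1], strength=rp.strength,
                        window_rate=rp.window_rate, threshold=np.nan,
                        n_trials=len(rp.counts)))
            gate_any = any(rp.gate_passed for rp in rec_profiles)
            r_counts = np.concatenate([rp.counts for rp in rec_profiles])
            r_ident = np.concatenate([[rp.identity] * len(rp.counts)
                                      for rp in rec_profiles])
            r_story = np.concatenate([[rp.story] * len(rp.counts)
                                      for rp in rec_profiles])
            try:
                r_anova = st.anova_two_way(r_counts, r_ident, r_story)
                row.update(recall_p_identity=r_anova.p_identity,
                           recall_p_context=r_anova.p_context,
                           recall_p_interaction=r_anova.p_interaction)
                recall_responsive = gate_any and r_anova.p_identity < cfg.alpha
            except ValueError:
                recall_responsive = False
            row.update(recall_gate=gate_any,
                       responsive_recall=bool(recall_responsive))
        verdict_rows.append(row)

    responses = pd.DataFrame(response_rows)
    verdicts = pd.DataFrame(verdict_rows)

    # ---- population decoding (all units, per-unit encoding windows) -------
    enc = events[events.task == "encoding"]
    X_enc = dec.trial_count_matrix(session.spike_trains,
                                   enc.onset_s.to_numpy(), enc_windows)
    decoding: dict = {}
    for mode in dec.MODES:
        acc, p, _ = dec.shuffle_significance(
            X_enc, enc.identity.to_numpy(), enc.story.to_numpy(), mode,
            n_shuffles=n_shuffles, rng=rng, config=cfg)
        result = dec.nb_loocv(X_enc, enc.identity.to_numpy(),
                              enc.story.to_numpy(), mode, task="encoding",
                              config=cfg)
        result.p_shuffle = p
        result.n_surrogates = n_shuffles
        decoding[("encoding", mode)] = result
    if recall_ok:
        rec = events[events.task == "recall"]
        if cfg.recall_correct_only:
            rec = rec[rec.correct]
        rec_windows = [cfg.recall_window] * n_units
        X_rec = dec.trial_count_matrix(session.spike_trains,
                                       rec.onset_s.to_numpy(), rec_windows)
        for mode in dec.MODES:
            acc, p, _ = dec.shuffle_significance(
                X_rec, rec.identity.to_numpy(), rec.story.to_numpy(), mode,
                n_shuffles=n_shuffles, rng=rng, config=cfg)
            result = dec.nb_loocv(X_rec, rec.identity.to_numpy(),
                                  rec.story.to_numpy(), mode, task="recall",
                                  config=cfg)
            result.p_shuffle = p
            result.n_surrogates = n_shuffles
            decoding[("recall", mode)] = result

    summary = dict(
        n_units=int(n_units),
        n_excluded=int((quality.unit_class == "excluded").sum()),
        n_single=int((quality.unit_class == "single").sum()),
        n_multi=int((quality.unit_class == "multi").sum()),
        n_responsive_encoding=int(verdicts.responsive_encoding.sum()),
        n_story_modulated=int(verdicts.story_modulated.sum()),
        n_equivalent=int(verdicts.equivalent.sum()),
        n_recall_responsive=int(verdicts.responsive_recall.sum())
        if "responsive_recall" in verdicts else 0,
        recall_usable=bool(recall_ok),
        rng_seed=int(rng_seed),
    )
    return SessionReport(quality=quality, responses=responses,
                         verdicts=verdicts, decoding=decoding, summary=summary,
                         config=cfg, rng_seed=rng_seed, recall_usable=recall_ok)


def summarize_cohort(reports: list[SessionReport]) -> dict:
    """Pooled counts and mean decoding accuracies across session reports."""
    if not reports:
        raise ValueError("need at least one report")
    count_keys = ["n_units", "n_excluded", "n_single", "n_multi",
                  "n_responsive_encoding", "n_story_modulated",
                  "n_equivalent", "n_recall_responsive"]
    pooled = {k: int(sum(r.summary[k] for r in reports)) for k in count_keys}
    pooled["n_sessions"] = len(reports)
    for task_mode in {key for r in reports for key in r.decoding}:
        accs = [r.decoding[task_mode].accuracy for r in reports
                if task_mode in r.decoding]
        pooled[f"mean_accuracy_{task_mode[0]}_{task_mode[1]}"] = float(np.mean(accs))
    return pooled


def write_report(report: SessionReport, out_dir: str | Path) -> Path:
    """Persist all row-level tables and the summary of one report."""
    import json
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.quality.to_csv(out / "quality.csv", index=False)
    report.responses.to_csv(out / "responses.csv", index=False)
    report.verdicts.to_csv(out / "verdicts.csv", index=False)
    decode_rows = []
    for (task, mode), res in report.decoding.items():
        decode_rows.append(dict(task=task, mode=mode, accuracy=res.accuracy,
                                p_shuffle=res.p_shuffle,
                                n_surrogates=res.n_surrogates,
                                confusion=res.confusion.tolist()))
    (out / "decoding.json").write_text(json.dumps(decode_rows, indent=2))
    payload = dict(summary=report.summary, config=report.config.to_dict())
    (out / "summary.json").write_text(json.dumps(payload, indent=2, default=list))
    return out
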
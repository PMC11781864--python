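"""Synthetic session generator for the context-modulation paradigm.

Emulates sessions of the episodic-memory task: two stimulus identities, each
embedded in two narrative stories (four stories total), with three phases —
passive visual presentation (VP) of each stimulus, encoding of the stories as
picture sequences, and cued verbal recall aligned to vocalization onset.

Spike trains are drawn from inhomogeneous Poisson processes with known
ground-truth tuning, so every downstream stage (quality metrics, latency
detection, identity/context statistics, decoding) can be validated against
the parameters that generated the data.

Rate model per unit:

* baseline everywhere, at ``baseline_rate``;
* for tuned units, a rectangular step to ``evoked_rate`` (times
  ``context_gain`` for story 2) from ``latency_true`` after stimulus onset,
  lasting ``response_duration``, on VP and encoding trials of the tuned
  identity;
* during correct recall of tuned-identity stories, a linear ramp from
  baseline up to ``recall_rate`` starting ``recall_ramp_start`` before the
  labeled vocalization onset, held until 0.5 s after it;
* incorrect recall trials fire at baseline only and are flagged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

N_WAVEFORM_SAMPLES = 64
IDENTITIES = (1, 2)
STORIES = (1, 2)

EVENT_COLUMNS = ["task", "trial", "identity", "story", "onset_s", "correct"]


class ConfigurationError(ValueError):
    """Invalid generator configuration (negative rates, spec/unit mismatch...)."""


@dataclass
class SessionConfig:
    """Trial structure of one synthetic session.

    Defaults follow the paradigm: pictures shown for 1 s, 10-15 encoding/recall
    repetitions per story, 15-30 VP presentations per stimulus, inter-picture
    intervals in [2.65, 2.9] s and inter-story blanks in [5, 5.1] s.
    """

    n_units: int = 1
    n_trials_encoding: int = 15       # per story
    n_trials_vp: int = 30             # per stimulus
    n_trials_recall: int = 12         # per story
    stim_duration: float = 1.0
    inter_picture_interval: tuple[float, float] = (2.65, 2.9)
    inter_story_blank: tuple[float, float] = (5.0, 5.1)
    pre_onset_record: float = 1.0
    post_onset_record: float = 2.0
    recall_pre: float = 3.0           # recorded window before recall onset
    recall_post: float = 1.0
    incorrect_recall_frac: float = 0.10   # early trials, decaying linearly to 0
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_units < 1:
            raise ConfigurationError("n_units must be >= 1")
        for name in ("n_trials_encoding", "n_trials_vp", "n_trials_recall"):
            if getattr(self, name) not in (0,) and getattr(self, name) < 2:
                raise ConfigurationError(f"{name} must be 0 or >= 2")
        for name in ("stim_duration", "pre_onset_record", "post_onset_record",
                     "recall_pre", "recall_post"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if not 0.0 <= self.incorrect_recall_frac <= 1.0:
            raise ConfigurationError("incorrect_recall_frac must be in [0, 1]")


@dataclass
class NeuronSpec:
    """Ground-truth tuning of one simulated unit.

    ``tuned_identity`` is ``None`` for untuned units. ``context_gain``
    multiplies the evoked rate in story 2; 1.0 means context-invariant.
    ``recall_rate`` defaults to 0.6 x evoked rate (recall responses are
    weaker than encoding ones; the factor is unconstrained and configurable).
    """

    baseline_rate: float = 5.0
    tuned_identity: int | None = None
    evoked_rate: float = 30.0
    latency_true: float = 0.3
    response_duration: float = 0.5
    context_gain: float = 1.0
    recall_ramp_start: float = 2.5
    recall_rate: float | None = None          # default 0.6 * evoked_rate
    recall_hold: float = 0.5                  # hold after vocalization onset
    waveform_amplitude: float = 100.0
    waveform_noise_sd: float = 10.0

    def __post_init__(self) -> None:
        if self.recall_rate is None:
            self.recall_rate = 0.6 * self.evoked_rate
        if self.baseline_rate < 0:
            raise ConfigurationError("baseline_rate must be >= 0")
        if self.context_gain <= 0:
            raise ConfigurationError("context_gain must be > 0")
        if self.tuned_identity is not None:
            if self.tuned_identity not in IDENTITIES:
                raise ConfigurationError(
                    f"tuned_identity must be one of {IDENTITIES} or None")
            if self.evoked_rate < self.baseline_rate:
                raise ConfigurationError(
                    "evoked_rate must be >= baseline_rate for tuned units")
        if self.waveform_noise_sd < 0:
            raise ConfigurationError("waveform_noise_sd must be >= 0")


@dataclass
class SessionData:
    """One generated session: spikes, events, and the specs that made them."""

    spike_trains: list[np.ndarray]
    waveforms: list[np.ndarray]
    events: pd.DataFrame
    ground_truth: list[NeuronSpec]
    config: SessionConfig
    duration: float

    @property
    def n_units(self) -> int:
        return len(self.spike_trains)


# ---------------------------------------------------------------------------
# waveforms
# ---------------------------------------------------------------------------

def spike_template(n_samples: int = N_WAVEFORM_SAMPLES) -> np.ndarray:
    """Canonical extracellular spike shape, 64 samples, peak magnitude 1.

    A negative-going trough followed by a slower positive after-potential,
    the typical shape of a filtered extracellular action potential. The
    global extremum (the trough) has absolute value exactly 1 and sits away
    from the first sample, so the first sample carries noise only.
    """
    t = np.arange(n_samples, dtype=float)
    trough = np.exp(-0.5 * ((t - 20.0) / 3.0) ** 2)
    after = 0.35 * np.exp(-0.5 * ((t - 32.0) / 7.0) ** 2)
    w = -trough + after
    return w / np.max(np.abs(w))


def generate_waveforms(spec: NeuronSpec, n_spikes: int,
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw an (n_spikes, 64) waveform matrix: scaled template plus i.i.d. noise."""
    if n_spikes < 1:
        raise ConfigurationError("n_spikes must be >= 1")
    rng = np.random.default_rng(rng)
    template = spec.waveform_amplitude * spike_template()
    noise = rng.normal(0.0, spec.waveform_noise_sd,
                       size=(n_spikes, N_WAVEFORM_SAMPLES))
    return template[None, :] + noise


# ---------------------------------------------------------------------------
# inhomogeneous Poisson sampling
# ---------------------------------------------------------------------------

def _sample_constant(rate: float, t0: float, t1: float,
                     rng: np.random.Generator) -> np.ndarray:
    if rate <= 0 or t1 <= t0:
        return np.empty(0)
    n = rng.poisson(rate * (t1 - t0))
    return np.sort(rng.uniform(t0, t1, size=n))


def _sample_linear(r0: float, r1: float, t0: float, t1: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Spikes of a Poisson process with rate linear from r0 at t0 to r1 at t1.

    Thinning against the segment's maximum rate.
    """
    rmax = max(r0, r1)
    if rmax <= 0 or t1 <= t0:
        return np.empty(0)
    cand = _sample_constant(rmax, t0, t1, rng)
    if cand.size == 0:
        return cand
    rate_at = r0 + (r1 - r0) * (cand - t0) / (t1 - t0)
    keep = rng.uniform(0.0, rmax, size=cand.size) < rate_at
    return cand[keep]


@dataclass
class _Segment:
    t0: float
    t1: float
    r0: float
    r1: float


def sample_piecewise_rate(segments: list[_Segment],
                          rng: np.random.Generator) -> np.ndarray:
    """Sample one realization of a piecewise-linear-rate Poisson process."""
    parts = []
    for s in segments:
        if s.r0 == s.r1:
            parts.append(_sample_constant(s.r0, s.t0, s.t1, rng))
        else:
            parts.append(_sample_linear(s.r0, s.r1, s.t0, s.t1, rng))
    if not parts:
        return np.empty(0)
    spikes = np.sort(np.concatenate(parts))
    # strictly increasing timestamps (duplicate draws have measure zero, but
    # guard against float ties anyway)
    if spikes.size > 1:
        spikes = spikes[np.concatenate(([True], np.diff(spikes) > 0))]
    return spikes


# ---------------------------------------------------------------------------
# event layout
# ---------------------------------------------------------------------------

def _layout_events(config: SessionConfig, rng: np.random.Generator) -> tuple[pd.DataFrame, float]:
    """Lay the three task blocks on a single session timeline.

    Each encoding/recall event's onset is the analysis alignment point (the
    identity picture during encoding; the vocalization onset during recall);
    the surrounding when/where/what pictures are absorbed into the
    inter-trial spacing rather than modeled individually.
    """
    rows: list[dict] = []
    t = config.pre_onset_record  # leave room for the first trial's baseline

    def ipi() -> float:
        lo, hi = config.inter_picture_interval
        return rng.uniform(lo, hi)

    def blank() -> float:
        lo, hi = config.inter_story_blank
        return rng.uniform(lo, hi)

    # --- VP block: pseudorandom interleaving of the two stimuli -----------
    if config.n_trials_vp:
        order = np.repeat(IDENTITIES, config.n_trials_vp)
        rng.shuffle(order)
        counters = {i: 0 for i in IDENTITIES}
        for ident in order:
            rows.append(dict(task="vp", trial=counters[ident], identity=int(ident),
                             story=0, onset_s=t, correct=True))
            counters[ident] += 1
            t += config.stim_duration + ipi() + config.post_onset_record
        t += blank()

    # --- encoding block: repetitions of the 4 stories in pseudorandom order
    story_labels = [(i, s) for i in IDENTITIES for s in STORIES]
    if config.n_trials_encoding:
        for rep in range(config.n_trials_encoding):
            order = list(story_labels)
            rng.shuffle(order)
            for ident, story in order:
                # two context pictures precede the identity picture
                t += 2 * (config.stim_duration + ipi())
                rows.append(dict(task="encoding", trial=rep, identity=ident,
                                 story=story, onset_s=t, correct=True))
                # identity + closing picture, then the inter-story blank
                t += 2 * (config.stim_duration + ipi()) + blank()

    # --- recall block: cued retrieval, onset = vocalization time ----------
    if config.n_trials_recall:
        n_rep = config.n_trials_recall
        for rep in range(n_rep):
            order = list(story_labels)
            rng.shuffle(order)
            # incorrect-recall probability decays linearly across repetitions
            p_inc = config.incorrect_recall_frac * max(0.0, 1.0 - rep / max(n_rep - 1, 1))
            for ident, story in order:
                t += config.recall_pre
                correct = bool(rng.uniform() >= p_inc)
                rows.append(dict(task="recall", trial=rep, identity=ident,
                                 story=story, onset_s=t, correct=correct))
                t += config.recall_post + blank()

    duration = t + config.post_onset_record
    events = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    return events, duration


# ---------------------------------------------------------------------------
# session generation
# ---------------------------------------------------------------------------

def _unit_segments(spec: NeuronSpec, events: pd.DataFrame,
                   duration: float) -> list[_Segment]:
    """Piecewise rate profile of one unit over the whole session."""
    base = spec.baseline_rate
    # (t_start, t_end, r_start, r_end) response insertions, non-overlapping
    resp: list[tuple[float, float, float, float]] = []
    if spec.tuned_identity is not None:
        for ev in events.itertuples():
            if ev.identity != spec.tuned_identity:
                continue
            if ev.task in ("vp", "encoding"):
                gain = spec.context_gain if (ev.task == "encoding" and ev.story == 2) else 1.0
                r = spec.evoked_rate * gain
                t0 = ev.onset_s + spec.latency_true
                resp.append((t0, t0 + spec.response_duration, r, r))
            elif ev.task == "recall" and ev.correct:
                t0 = ev.onset_s - spec.recall_ramp_start
                resp.append((t0, ev.onset_s, base, spec.recall_rate))
                resp.append((ev.onset_s, ev.onset_s + spec.recall_hold,
                             spec.recall_rate, spec.recall_rate))
    resp.sort()
    segments: list[_Segment] = []
    t = 0.0
    for t0, t1, r0, r1 in resp:
        t0, t1 = max(t0, 0.0), min(t1, duration)
        if t1 <= t0:
            continue
        if t0 > t:
            segments.append(_Segment(t, t0, base, base))
        segments.append(_Segment(t0, t1, r0, r1))
        t = t1
    if t < duration:
        segments.append(_Segment(t, duration, base, base))
    return segments


def generate_session(config: SessionConfig,
                     specs: list[NeuronSpec] | None = None,
                     with_waveforms: bool = True) -> SessionData:
    """Generate one full synthetic session.

    ``specs`` must have length ``config.n_units``; if omitted, alternating
    tuned (context-invariant) and untuned default specs are used.
    ``with_waveforms=False`` skips waveform synthesis (large rate-only
    simulations do not need it).
    """
    config.validate()
    if specs is None:
        specs = [NeuronSpec(tuned_identity=IDENTITIES[u % 2]) if u % 2 == 0
                 else NeuronSpec(tuned_identity=None)
                 for u in range(config.n_units)]
    if len(specs) != config.n_units:
        raise ConfigurationError(
            f"got {len(specs)} neuron specs for {config.n_units} units")

    rng = np.random.default_rng(config.rng_seed)
    events, duration = _layout_events(config, rng)

    spike_trains: list[np.ndarray] = []
    waveforms: list[np.ndarray] = []
    for spec in specs:
        segments = _unit_segments(spec, events, duration)
        spikes = sample_piecewise_rate(segments, rng)
        spike_trains.append(spikes)
        if with_waveforms:
            waveforms.append(generate_waveforms(spec, max(len(spikes), 1), rng))
        else:
            waveforms.append(np.empty((0, N_WAVEFORM_SAMPLES)))

    return SessionData(spike_trains=spike_trains, waveforms=waveforms,
                       events=events, ground_truth=specs, config=config,
                       duration=duration)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def exemplar_spec(context_gain: float = 1.0, **overrides) -> NeuronSpec:
    """The exemplar tuned unit: ~5 Hz baseline rising to ~30 Hz for its identity."""
    kwargs = dict(baseline_rate=5.0, tuned_identity=1, evoked_rate=30.0,
                  latency_true=0.3, response_duration=0.5,
                  context_gain=context_gain)
    kwargs.update(overrides)
    return NeuronSpec(**kwargs)


def untuned_spec(baseline_rate: float = 5.0, **overrides) -> NeuronSpec:
    return NeuronSpec(baseline_rate=baseline_rate, tuned_identity=None, **overrides)


# ---------------------------------------------------------------------------
# session bundle I/O
# ---------------------------------------------------------------------------

def write_bundle(session: SessionData, out_dir: str | Path) -> Path:
    """Write a session bundle: events.csv, spikes.csv, per-unit waveform CSVs,
    and a manifest JSON with the config, specs, and seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    session.events.to_csv(out / "events.csv", index=False)
    spike_rows = [(u, t) for u, train in enumerate(session.spike_trains) for t in train]
    pd.DataFrame(spike_rows, columns=["unit_id", "timestamp_s"]).to_csv(
        out / "spikes.csv", index=False)
    for u, w in enumerate(session.waveforms):
        np.savetxt(out / f"waveforms_unit{u:03d}.csv", w, delimiter=",")
    manifest = dict(
        n_units=session.n_units,
        duration_s=session.duration,
        config=asdict(session.config),
        ground_truth=[asdict(s) for s in session.ground_truth],
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def read_bundle(bundle_dir: str | Path) -> SessionData:
    """Read a session bundle written by :func:`write_bundle`."""
    d = Path(bundle_dir)
    try:
        manifest = json.loads((d / "manifest.json").read_text())
        events = pd.read_csv(d / "events.csv")
        spikes = pd.read_csv(d / "spikes.csv")
    except FileNotFoundError as e:
        raise ValueError(f"malformed session bundle {d}: missing {e.filename}") from e
    missing = set(EVENT_COLUMNS) - set(events.columns)
    if missing:
        raise ValueError(f"malformed events.csv: missing columns {sorted(missing)}")
    for col in ("unit_id", "timestamp_s"):
        if col not in spikes.columns:
            raise ValueError(f"malformed spikes.csv: missing column {col!r}")
    n_units = int(manifest["n_units"])
    trains = [np.sort(spikes.loc[spikes.unit_id == u, "timestamp_s"].to_numpy())
              for u in range(n_units)]
    waveforms = []
    for u in range(n_units):
        path = d / f"waveforms_unit{u:03d}.csv"
        if path.exists():
            w = np.loadtxt(path, delimiter=",")
            waveforms.append(np.atleast_2d(w))
        else:
            waveforms.append(np.empty((0, N_WAVEFORM_SAMPLES)))
    cfg_d = manifest["config"]
    for key in ("inter_picture_interval", "inter_story_blank"):
        cfg_d[key] = tuple(cfg_d[key])
    config = SessionConfig(**cfg_d)
    specs = []
    for s in manifest.get("ground_truth", []):
        spec = NeuronSpec(**s)
        specs.append(spec)
    return SessionData(spike_trains=trains, waveforms=waveforms, events=events,
                       ground_truth=specs, config=config,
                       duration=float(manifest["duration_s"]))
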
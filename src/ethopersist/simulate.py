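"""Synthetic cohort generator with stimulus-triggered persistent latent states.

The generator emulates the statistical structure of an opto-thermocycler
trial: each animal occupies a latent behavioral state (rest, global
search, local search, engorge).  A stimulus pulse (fictive CO2 via
light, or heat) pushes an animal into a target state with some entry
probability; the triggered state persists with an exponential dwell time
parameterized by its half-life (decay rate ln 2 / t_half per second) and
then relaxes back to baseline.  Within a state, behaviors are emitted as
alternating bouts — a behavior is drawn from the state's emission
distribution, then held for a geometrically distributed number of frames
matching its mean bout length — so bout counts and transition rates are
meaningful features.  Centroid tracks follow a heading-correlated random
walk whose step size matches the per-behavior mean speed.  The
engorgement outcome is drawn from a logistic model on the fraction of a
stated pre-heat window the animal spent in local search; engorged
animals enter the engorge state shortly after the heat pulse.

Everything is driven by one :class:`numpy.random.Generator` seeded from
the config, so a fixed seed reproduces a cohort bit-for-bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .core import (
    BEHAVIORS,
    CohortDataset,
    Ethogram,
    Pulse,
    StimulusSeries,
)

EMISSION_CATEGORIES: tuple[str, ...] = BEHAVIORS + ("none",)


@dataclass(frozen=True)
class StateSpec:
    """Emission model for one latent state.

    ``emission`` gives the probability of drawing each behavior category
    for the next bout; ``bout_s`` the mean bout length per behavior in
    seconds; ``speed`` the mean centroid speed per behavior in pixels/s.
    ``probe_walk_frac`` is the fraction of probe bouts emitted with the
    walk flag also set (probing while walking co-occurs in real data).
    """

    name: str
    emission: Mapping[str, float]
    bout_s: Mapping[str, float]
    speed: Mapping[str, float]
    probe_walk_frac: float = 0.0

    def __post_init__(self) -> None:
        for b, p in self.emission.items():
            if b not in EMISSION_CATEGORIES:
                raise ValueError(f"state {self.name!r}: unknown behavior {b!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"state {self.name!r}: emission p({b}) = {p} not in [0,1]")
        total = sum(self.emission.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"state {self.name!r}: emission sums to {total}, not 1")
        for b, d in self.bout_s.items():
            if d <= 0:
                raise ValueError(f"state {self.name!r}: bout_s[{b}] = {d} must be > 0")
        if not 0.0 <= self.probe_walk_frac <= 1.0:
            raise ValueError(f"state {self.name!r}: probe_walk_frac not in [0,1]")


@dataclass(frozen=True)
class TriggerSpec:
    """A stimulus channel pushing animals into a target latent state.

    On each pulse onset of ``channel``, an animal enters ``target_state``
    with probability ``p_entry``; the dwell is exponential with
    ``half_life_s`` (mean dwell = half_life_s / ln 2).
    """

    channel: str
    target_state: str
    p_entry: float
    half_life_s: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_entry <= 1.0:
            raise ValueError(f"trigger p_entry = {self.p_entry} not in [0,1]")
        if not self.half_life_s > 0:
            raise ValueError(f"trigger half_life_s = {self.half_life_s} must be > 0")


@dataclass(frozen=True)
class FeedingModel:
    """Logistic engorgement model on pre-heat local-search occupancy.

    P(engorged) = expit(intercept + coef * occupancy) where occupancy is
    the fraction of ``window_s`` (relative to pulse ``pulse`` of
    ``channel``) the animal's latent state equals ``search_state``.
    Engorged animals switch to ``engorge_state`` ``latency_s`` seconds
    after that pulse onset and stay there until the record ends.
    """

    intercept: float = -2.0
    coef: float = 3.5
    channel: str = "heat"
    pulse: int = 0
    window_s: tuple[float, float] = (-120.0, 0.0)
    search_state: str = "local_search"
    engorge_state: str | None = "engorge"
    latency_s: float = 60.0


@dataclass(frozen=True)
class GeneratorConfig:
    """Full parameterization of a synthetic cohort.

    Defaults describe the reference trial: 70 females, a 20 min record
    at 30 frames/s, a 5 s light pulse at 300 s (fictive CO2) and a 5 s
    heat pulse at 420 s, probing persistence half-life 234 s (3.9 min)
    for the light-triggered local-search state.
    """

    n_animals: int = 70
    fps: float = 30.0
    duration_s: float = 1200.0
    seed: int = 0
    states: tuple[StateSpec, ...] = ()
    baseline_state: str = "rest"
    triggers: tuple[TriggerSpec, ...] = ()
    stimuli: tuple[tuple[str, tuple[Pulse, ...]], ...] = ()
    feeding: FeedingModel = field(default_factory=FeedingModel)

    def __post_init__(self) -> None:
        if self.n_animals < 0:
            raise ValueError("n_animals must be >= 0")
        if self.fps <= 0 or self.duration_s <= 0:
            raise ValueError("fps and duration_s must be > 0")
        names = {s.name for s in self.states}
        if self.states and self.baseline_state not in names:
            raise ValueError(f"baseline state {self.baseline_state!r} not defined")
        for t in self.triggers:
            if t.target_state not in names:
                raise ValueError(f"trigger target {t.target_state!r} not defined")

    def state(self, name: str) -> StateSpec:
        for s in self.states:
            if s.name == name:
                return s
        raise KeyError(name)

    def stimulus_series(self) -> StimulusSeries:
        return StimulusSeries(channels={ch: list(pulses) for ch, pulses in self.stimuli})


@dataclass
class LatentTrace:
    """Ground-truth per-frame latent state names for one simulated animal."""

    animal_id: str
    states: np.ndarray  # (n_frames,) of str

    def window_label(self, start_frame: int, end_frame: int) -> str:
        """Majority latent state within a half-open frame span."""
        vals, counts = np.unique(self.states[start_frame:end_frame], return_counts=True)
        return str(vals[np.argmax(counts)])


def default_config(seed: int = 0) -> GeneratorConfig:
    """Reference four-state configuration (rest, global/local search, engorge).

    Per-state emission probabilities are a modeling choice made to give
    the four states distinct, realistic behavior compositions; the
    trigger half-lives follow the reported probing decay (3.9 min for
    the light-triggered search state, 0.4 min for heat).
    """
    states = (
        StateSpec(
            "rest",
            emission={"groom": 0.15, "walk": 0.05, "probe": 0.02, "fly": 0.01, "none": 0.77},
            bout_s={"groom": 2.0, "walk": 1.5, "probe": 1.0, "fly": 0.5, "none": 4.0},
            speed={"groom": 1.0, "walk": 6.0, "probe": 2.0, "fly": 60.0, "none": 0.3},
            probe_walk_frac=0.1,
        ),
        StateSpec(
            "global_search",
            emission={"groom": 0.02, "walk": 0.30, "probe": 0.08, "fly": 0.35, "none": 0.25},
            bout_s={"groom": 1.0, "walk": 2.0, "probe": 1.0, "fly": 1.5, "none": 1.5},
            speed={"groom": 1.0, "walk": 12.0, "probe": 3.0, "fly": 80.0, "none": 0.5},
            probe_walk_frac=0.2,
        ),
        StateSpec(
            "local_search",
            emission={"groom": 0.02, "walk": 0.25, "probe": 0.45, "fly": 0.03, "none": 0.25},
            bout_s={"groom": 1.0, "walk": 2.0, "probe": 2.5, "fly": 0.5, "none": 1.5},
            speed={"groom": 1.0, "walk": 8.0, "probe": 3.0, "fly": 60.0, "none": 0.5},
            probe_walk_frac=0.5,
        ),
        StateSpec(
            "engorge",
            emission={"groom": 0.02, "walk": 0.02, "probe": 0.55, "fly": 0.0, "none": 0.41},
            bout_s={"groom": 1.0, "walk": 1.0, "probe": 8.0, "fly": 0.5, "none": 4.0},
            speed={"groom": 0.5, "walk": 2.0, "probe": 0.5, "fly": 60.0, "none": 0.2},
            probe_walk_frac=0.0,
        ),
    )
    triggers = (
        TriggerSpec("light", "local_search", p_entry=0.5, half_life_s=234.0),
        TriggerSpec("light", "global_search", p_entry=0.3, half_life_s=120.0),
        TriggerSpec("heat", "local_search", p_entry=0.4, half_life_s=24.0),
    )
    stimuli = (
        ("light", (Pulse(300.0, 305.0, 1.0),)),
        ("heat", (Pulse(420.0, 425.0, 35.0),)),
    )
    return GeneratorConfig(
        n_animals=70,
        fps=30.0,
        duration_s=1200.0,
        seed=seed,
        states=states,
        baseline_state="rest",
        triggers=triggers,
        stimuli=stimuli,
        feeding=FeedingModel(),
    )


def decay_recovery_config(
    tau_half_s: float, n_animals: int = 500, seed: int = 0, p_entry: float = 0.7
) -> GeneratorConfig:
    """Single light trigger into local search with the given half-life.

    Used for half-life parameter-recovery runs: no heat channel, no
    feeding-driven engorge entries, so post-pulse excess probing decays
    with the one configured half-life.
    """
    cfg = default_config(seed=seed)
    return dataclasses.replace(
        cfg,
        n_animals=n_animals,
        triggers=(TriggerSpec("light", "local_search", p_entry, tau_half_s),),
        stimuli=(("light", (Pulse(300.0, 305.0, 1.0),)),),
        feeding=dataclasses.replace(cfg.feeding, engorge_state=None, coef=0.0),
    )


# ---------------------------------------------------------------------------
# simulation


def _latent_segments(
    cfg: GeneratorConfig, rng: np.random.Generator
) -> list[tuple[float, float, str]]:
    """One animal's latent timeline as (start_s, end_s, state) segments."""
    events: list[tuple[float, str, float]] = []  # (onset, state, dwell)
    for trig in cfg.triggers:
        pulses = dict(cfg.stimuli).get(trig.channel, ())
        for p in pulses:
            u = rng.random()
            dwell = rng.exponential(trig.half_life_s / np.log(2))
            if u < trig.p_entry:
                events.append((p.onset_s, trig.target_state, dwell))
    events.sort(key=lambda e: e[0])
    segments: list[tuple[float, float, str]] = []
    cur_state, cur_until = cfg.baseline_state, np.inf
    t = 0.0
    for onset, state, dwell in events:
        onset = min(onset, cfg.duration_s)
        if cur_state != cfg.baseline_state and cur_until < onset:
            segments.append((t, cur_until, cur_state))
            segments.append((cur_until, onset, cfg.baseline_state))
        else:
            segments.append((t, onset, cur_state))
        cur_state, cur_until = state, onset + dwell
        t = onset
    if cur_state != cfg.baseline_state and cur_until < cfg.duration_s:
        segments.append((t, cur_until, cur_state))
        segments.append((cur_until, cfg.duration_s, cfg.baseline_state))
    else:
        segments.append((t, cfg.duration_s, cur_state))
    return [(a, b, s) for a, b, s in segments if b > a]


def _emit_frames(
    cfg: GeneratorConfig,
    segments: list[tuple[float, float, str]],
    rng: np.random.Generator,
    n_frames: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Emit flags (n,4), per-frame speed (n,), latent names (n,) from segments."""
    flags = np.zeros((n_frames, len(BEHAVIORS)), dtype=bool)
    speed = np.zeros(n_frames)
    latent = np.empty(n_frames, dtype=object)
    cat_idx = {b: i for i, b in enumerate(BEHAVIORS)}
    for start_s, end_s, state_name in segments:
        spec = cfg.state(state_name)
        f0 = int(round(start_s * cfg.fps))
        f1 = min(int(round(end_s * cfg.fps)), n_frames)
        latent[f0:f1] = state_name
        cats = list(spec.emission.keys())
        cum = np.cumsum([spec.emission[c] for c in cats])
        pos = f0
        while pos < f1:
            cat = cats[int(np.searchsorted(cum, rng.random() * cum[-1]))]
            mean_frames = max(spec.bout_s.get(cat, 1.0) * cfg.fps, 1.0)
            length = int(rng.geometric(1.0 / mean_frames))
            end = min(pos + length, f1)
            if cat != "none":
                flags[pos:end, cat_idx[cat]] = True
                if cat == "probe" and rng.random() < spec.probe_walk_frac:
                    flags[pos:end, cat_idx["walk"]] = True
            speed[pos:end] = spec.speed.get(cat, 0.0)
            pos = end
    return flags, speed, latent


def _random_walk(
    speed: np.ndarray, fps: float, rng: np.random.Generator
) -> np.ndarray:
    """Heading-correlated random walk with per-frame step = speed / fps."""
    n = speed.size
    headings = np.cumsum(rng.normal(0.0, 0.6, size=n))
    steps = speed / fps
    dx = steps * np.cos(headings)
    dy = steps * np.sin(headings)
    pos = np.empty((n, 2))
    pos[:, 0] = np.cumsum(dx)
    pos[:, 1] = np.cumsum(dy)
    pos += rng.uniform(0, 500, size=2)
    return pos


def simulate_cohort(cfg: GeneratorConfig) -> tuple[CohortDataset, list[LatentTrace]]:
    """Simulate a cohort and its ground-truth latent traces.

    Returns a :class:`CohortDataset` (flags, tracks, stimuli, metadata
    with the engorged outcome) plus one :class:`LatentTrace` per animal.
    """
    rng = np.random.default_rng(cfg.seed)
    n_frames = int(round(cfg.duration_s * cfg.fps))
    stimuli = cfg.stimulus_series()
    fm = cfg.feeding
    try:
        heat_onset = stimuli.pulse(fm.channel, fm.pulse).onset_s
    except (KeyError, IndexError):
        heat_onset = None

    ethograms: list[Ethogram] = []
    traces: list[LatentTrace] = []
    engorged = np.zeros(cfg.n_animals, dtype=bool)
    for i in range(cfg.n_animals):
        animal_id = f"m{i:04d}"
        segments = _latent_segments(cfg, rng)
        # feeding outcome from latent occupancy of the pre-heat window
        if heat_onset is not None:
            w0, w1 = heat_onset + fm.window_s[0], heat_onset + fm.window_s[1]
            occ = 0.0
            for a, b, s in segments:
                if s == fm.search_state:
                    occ += max(0.0, min(b, w1) - max(a, w0))
            occ /= max(w1 - w0, 1e-12)
            p_fed = expit(fm.intercept + fm.coef * occ)
        else:
            p_fed = expit(fm.intercept)
        fed = rng.random() < p_fed
        engorged[i] = fed
        if fed and heat_onset is not None and fm.engorge_state is not None:
            t_eng = heat_onset + fm.latency_s
            clipped = []
            for a, b, s in segments:
                if b <= t_eng:
                    clipped.append((a, b, s))
                elif a < t_eng:
                    clipped.append((a, t_eng, s))
            clipped.append((t_eng, cfg.duration_s, fm.engorge_state))
            segments = clipped
        flags, speed, latent = _emit_frames(cfg, segments, rng, n_frames)
        track = _random_walk(speed, cfg.fps, rng)
        ethograms.append(Ethogram(animal_id, flags, fps=cfg.fps, track=track))
        traces.append(LatentTrace(animal_id, latent))

    meta = pd.DataFrame(
        {
            "animal_id": [e.animal_id for e in ethograms],
            "sex": "F",
            "condition": "default",
            "engorged": pd.array(engorged.astype(int)),
        }
    )
    cohort = CohortDataset(ethograms, stimuli, meta)
    return cohort, traces


def config_to_dict(cfg: GeneratorConfig) -> dict:
    """Plain-dict form of a config (YAML/JSON friendly)."""
    return {
        "n_animals": cfg.n_animals,
        "fps": cfg.fps,
        "duration_s": cfg.duration_s,
        "seed": cfg.seed,
        "baseline_state": cfg.baseline_state,
        "states": [
            {
                "name": s.name,
                "emission": dict(s.emission),
                "bout_s": dict(s.bout_s),
                "speed": dict(s.speed),
                "probe_walk_frac": s.probe_walk_frac,
            }
            for s in cfg.states
        ],
        "triggers": [
            {
                "channel": t.channel,
                "target_state": t.target_state,
                "p_entry": t.p_entry,
                "half_life_s": t.half_life_s,
            }
            for t in cfg.triggers
        ],
        "stimuli": {
            ch: [
                {"onset_s": p.onset_s, "offset_s": p.offset_s, "magnitude": p.magnitude}
                for p in pulses
            ]
            for ch, pulses in cfg.stimuli
        },
        "feeding": {
            "intercept": cfg.feeding.intercept,
            "coef": cfg.feeding.coef,
            "channel": cfg.feeding.channel,
            "pulse": cfg.feeding.pulse,
            "window_s": list(cfg.feeding.window_s),
            "search_state": cfg.feeding.search_state,
            "engorge_state": cfg.feeding.engorge_state,
            "latency_s": cfg.feeding.latency_s,
        },
    }


def config_from_dict(d: dict) -> GeneratorConfig:
    """Inverse of :func:`config_to_dict`."""
    fd = d.get("feeding", {})
    return GeneratorConfig(
        n_animals=int(d.get("n_animals", 70)),
        fps=float(d.get("fps", 30.0)),
        duration_s=float(d.get("duration_s", 1200.0)),
        seed=int(d.get("seed", 0)),
        baseline_state=d.get("baseline_state", "rest"),
        states=tuple(
            StateSpec(
                s["name"],
                emission=s["emission"],
                bout_s=s["bout_s"],
                speed=s["speed"],
                probe_walk_frac=float(s.get("probe_walk_frac", 0.0)),
            )
            for s in d.get("states", [])
        ),
        triggers=tuple(
            TriggerSpec(
                t["channel"], t["target_state"], float(t["p_entry"]), float(t["half_life_s"])
            )
            for t in d.get("triggers", [])
        ),
        stimuli=tuple(
            (ch, tuple(Pulse(p["onset_s"], p["offset_s"], p.get("magnitude", 1.0)) for p in ps))
            for ch, ps in d.get("stimuli", {}).items()
        ),
        feeding=FeedingModel(
            intercept=float(fd.get("intercept", -2.0)),
            coef=float(fd.get("coef", 3.5)),
            channel=fd.get("channel", "heat"),
            pulse=int(fd.get("pulse", 0)),
            window_s=tuple(fd.get("window_s", (-120.0, 0.0))),
            search_state=fd.get("search_state", "local_search"),
            engorge_state=fd.get("engorge_state", "engorge"),
            latency_s=float(fd.get("latency_s", 60.0)),
        ),
    )


def write_latent_traces(traces: list[LatentTrace], path) -> None:
    """Write ground-truth latent traces as a long CSV (animal_id, frame, state)."""
    import csv
    from pathlib import Path

    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["animal_id", "frame", "state"])
        for tr in traces:
            for f, s in enumerate(tr.states):
                w.writerow([tr.animal_id, f, s])


# ---------------------------------------------------------------------------
# constructed fixtures


def make_decay_curve(
    baseline: float,
    peak: float,
    tau_half_s: float,
    duration_s: float = 900.0,
    bin_s: float = 0.5,
    pre_s: float = 120.0,
):
    """Noiseless response curve: constant baseline for t < 0, then
    ``baseline + (peak - baseline) * 2**(-t / tau_half_s)`` for t >= 0."""
    from .response import ResponseCurve

    if not 0.0 <= baseline <= peak <= 1.0:
        raise ValueError(f"need 0 <= baseline <= peak <= 1, got {baseline}, {peak}")
    if tau_half_s <= 0:
        raise ValueError("tau_half_s must be > 0")
    times = np.arange(-round(pre_s / bin_s), round(duration_s / bin_s)) * bin_s
    values = np.where(
        times < 0, baseline, baseline + (peak - baseline) * 2.0 ** (-times / tau_half_s)
    )
    return ResponseCurve(times_s=times, values=values, behavior="probe", n=0)


def make_additivity_scenario(
    mode: str = "additive",
    n_per_condition: int = 40,
    fps: float = 30.0,
    response_window_s: float = 15.0,
    seed: int = 0,
) -> CohortDataset:
    """Three-condition cohort (A, B, A+B) with additivity known by construction.

    Animals in conditions A and B probe for exact per-animal fractions
    of the post-onset response window (cohort means 0.2 and 0.3).  Every
    combined-condition animal probes for ``factor * (mean_A + mean_B)``
    of the window, where factor is 1 (additive), 0.5 (suppressive) or
    1.5 (enhanced), so the cohort median percent additivity is exactly
    100, 50 or 150.
    """
    factors = {"additive": 1.0, "suppressive": 0.5, "enhanced": 1.5}
    if mode not in factors:
        raise ValueError(f"mode must be one of {sorted(factors)}, got {mode!r}")
    factor = factors[mode]

    onset_s = 120.0
    duration_s = onset_s + 2 * response_window_s
    n_frames = int(round(duration_s * fps))
    w0 = int(round(onset_s * fps))
    w_frames = int(round(response_window_s * fps))

    # exact per-animal probing frame counts; means chosen so that
    # factor * (mean_A + mean_B) is an integer for all three modes
    def spread(k_mean: int, n: int) -> np.ndarray:
        out = np.full(n, k_mean)
        half = n // 2
        out[:half] += 16
        out[n - half:] -= 16
        return out

    k_a = int(round(0.2 * w_frames))
    k_b = int(round(0.3 * w_frames))
    k_b -= (k_a + k_b) % 2  # even sum => 0.5x and 1.5x are whole frames
    rng = np.random.default_rng(seed)
    ka = rng.permutation(spread(k_a, n_per_condition))
    kb = rng.permutation(spread(k_b, n_per_condition))
    k_combined = int(round(factor * (ka.mean() + kb.mean())))
    assert abs(factor * (ka.mean() + kb.mean()) - k_combined) < 1e-9

    ethograms, conditions = [], []
    counts = {"A": ka, "B": kb, "A+B": np.full(n_per_condition, k_combined)}
    for cond, ks in counts.items():
        for j, k in enumerate(ks):
            flags = np.zeros((n_frames, len(BEHAVIORS)), dtype=bool)
            flags[w0 : w0 + int(k), BEHAVIORS.index("probe")] = True
            ethograms.append(Ethogram(f"{cond}-{j:03d}", flags, fps=fps))
            conditions.append(cond)
    meta = pd.DataFrame(
        {
            "animal_id": [e.animal_id for e in ethograms],
            "sex": "F",
            "condition": conditions,
            "engorged": pd.array([pd.NA] * len(ethograms)),
        }
    )
    stimuli = StimulusSeries(
        channels={"light": [Pulse(onset_s, onset_s + 5.0, 1.0)]}
    )
    return CohortDataset(ethograms, stimuli, meta)
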
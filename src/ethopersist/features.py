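"""Sliding-window behavioral feature extraction (the 38-parameter vector).

Each animal's track is split into 30 s windows at a 10 s step and a
fixed-order vector of 38 features is computed per window:

* 8 proportions of window time: groom, walk, probe, fly (raw flags,
  which may co-occur), no behavior, probing-and-walking,
  probing-not-walking, walking-not-probing;
* 5 bout counts over the exclusive per-frame categories obtained by
  precedence resolution (fly > probe > walk > groom > none);
* 5 velocities: overall mean speed and mean speed during each behavior;
* 20 outgoing transition rates per second between the five exclusive
  categories.

A behavior whose raw-flag window proportion falls below its cutoff
(0.04 fly, 0.2 walk, 0.2 probe, 0.3 groom) is treated as too rare to
interpret: its bout count, per-behavior velocity, and every transition
rate into or out of it are set to zero for that window.  The window
itself is kept so the window grid stays uniform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    BEHAVIORS,
    EXCLUSIVE_LABELS,
    LABEL_CODES,
    CohortDataset,
    Ethogram,
    compute_velocity,
    count_runs,
    resolve_precedence_frames,
)

#: Canonical fixed order of the 38 features.
FEATURE_NAMES: tuple[str, ...] = (
    # (a) 8 time proportions (raw flags; probe/walk co-occurrence explicit)
    "prop_groom",
    "prop_walk",
    "prop_probe",
    "prop_fly",
    "prop_none",
    "prop_probe_walk",
    "prop_probe_not_walk",
    "prop_walk_not_probe",
    # (b) 5 bout counts on exclusive categories
    "bouts_groom",
    "bouts_walk",
    "bouts_probe",
    "bouts_fly",
    "bouts_none",
    # (c) 5 velocities (pixels/s)
    "vel_mean",
    "vel_groom",
    "vel_walk",
    "vel_probe",
    "vel_fly",
    # (d) 20 outgoing transition rates (per second), precedence order
) + tuple(
    f"rate_{a}_to_{b}"
    for a in EXCLUSIVE_LABELS
    for b in EXCLUSIVE_LABELS
    if a != b
)

assert len(FEATURE_NAMES) == 38


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry: 30 s windows advancing in 10 s steps."""

    length_s: float = 30.0
    step_s: float = 10.0

    def __post_init__(self) -> None:
        if not (0 < self.step_s <= self.length_s):
            raise ValueError("need 0 < step_s <= length_s")


@dataclass(frozen=True)
class CutoffSet:
    """Minimum window proportion below which a behavior is excluded."""

    fly: float = 0.04
    walk: float = 0.2
    probe: float = 0.2
    groom: float = 0.3

    def for_behavior(self, behavior: str) -> float:
        return getattr(self, behavior)


@dataclass
class WindowFeatures:
    """One (animal, window) feature vector in :data:`FEATURE_NAMES` order."""

    animal_id: str
    start_s: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(FEATURE_NAMES),):
            raise ValueError(f"feature vector must have length {len(FEATURE_NAMES)}")

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(FEATURE_NAMES), name=self.animal_id)

    def __getitem__(self, name: str) -> float:
        return float(self.values[FEATURE_NAMES.index(name)])


def make_windows(ethogram: Ethogram, spec: WindowSpec = WindowSpec()) -> list[range]:
    """Half-open frame spans [k*step, k*step + length); a final partial window is dropped."""
    length_f = int(round(spec.length_s * ethogram.fps))
    step_f = int(round(spec.step_s * ethogram.fps))
    n = ethogram.n_frames
    if length_f > n:
        raise ValueError(
            f"record of {n} frames is shorter than one {length_f}-frame window"
        )
    n_windows = (n - length_f) // step_f + 1
    return [range(k * step_f, k * step_f + length_f) for k in range(n_windows)]


def transition_rates(
    labels: np.ndarray, span: range | None = None, fps: float = 30.0
) -> dict[tuple[str, str], float]:
    """Outgoing transition rates per second between exclusive categories.

    rate(a -> b) = (# consecutive-frame label changes a -> b within the
    span) / (seconds spent in a within the span); zero when no time was
    spent in a.
    """
    labels = np.asarray(labels)
    if span is not None:
        labels = labels[span.start : span.stop]
    rates: dict[tuple[str, str], float] = {}
    src = labels[:-1]
    dst = labels[1:]
    changed = src != dst
    for a in EXCLUSIVE_LABELS:
        ca = LABEL_CODES[a]
        time_in_a = np.count_nonzero(labels == ca) / fps
        from_a = changed & (src == ca)
        for b in EXCLUSIVE_LABELS:
            if a == b:
                continue
            if time_in_a == 0:
                rates[(a, b)] = 0.0
            else:
                n_ab = int(np.count_nonzero(from_a & (dst == LABEL_CODES[b])))
                rates[(a, b)] = n_ab / time_in_a
    return rates


def extract_features(
    ethogram: Ethogram,
    span: range,
    cutoffs: CutoffSet = CutoffSet(),
    velocity: np.ndarray | None = None,
    velocity_interval_s: float = 0.1,
) -> WindowFeatures:
    """Compute the 38-feature vector for one window of one animal.

    ``velocity`` may be the precomputed full-record speed series from
    :func:`compute_velocity` (it is computed on the fly otherwise); when
    the ethogram has no track, the five velocity features are NaN.
    """
    n = ethogram.n_frames
    if not (0 <= span.start < span.stop <= n):
        raise ValueError(f"span [{span.start}, {span.stop}) outside record of {n} frames")
    fps = ethogram.fps
    flags = ethogram.flags[span.start : span.stop]
    n_f = flags.shape[0]
    groom, walk, probe, fly = (flags[:, BEHAVIORS.index(b)] for b in BEHAVIORS)

    props = {
        "prop_groom": groom.mean(),
        "prop_walk": walk.mean(),
        "prop_probe": probe.mean(),
        "prop_fly": fly.mean(),
        "prop_none": (~flags.any(axis=1)).mean(),
        "prop_probe_walk": (probe & walk).mean(),
        "prop_probe_not_walk": (probe & ~walk).mean(),
        "prop_walk_not_probe": (walk & ~probe).mean(),
    }

    excluded = {
        b for b in BEHAVIORS if props[f"prop_{b}"] < cutoffs.for_behavior(b)
    }

    labels = resolve_precedence_frames(flags)
    bouts = {
        f"bouts_{name}": float(count_runs(labels, LABEL_CODES[name]))
        for name in EXCLUSIVE_LABELS
    }

    # velocity samples whose [start, end] frames lie inside the window
    if ethogram.track is None:
        vel = {k: np.nan for k in ("vel_mean", "vel_groom", "vel_walk", "vel_probe", "vel_fly")}
    else:
        if velocity is None:
            velocity = compute_velocity(ethogram, velocity_interval_s)
        step = int(round(velocity_interval_s * fps))
        k0 = -(-span.start // step)  # first sample starting inside the span
        k1 = (span.stop - 1 - step) // step  # last sample ending inside the span
        ks = np.arange(k0, min(k1, velocity.size - 1) + 1)
        speeds = velocity[ks] if ks.size else np.array([])
        sample_start = ks * step

        def mean_speed(mask_frames: np.ndarray | None) -> float:
            if speeds.size == 0:
                return 0.0
            if mask_frames is None:
                sel = np.ones(speeds.size, dtype=bool)
            else:
                sel = mask_frames[sample_start - span.start]
            vals = speeds[sel]
            vals = vals[~np.isnan(vals)]
            return float(vals.mean()) if vals.size else 0.0

        vel = {
            "vel_mean": mean_speed(None),
            "vel_groom": mean_speed(groom),
            "vel_walk": mean_speed(walk),
            "vel_probe": mean_speed(probe),
            "vel_fly": mean_speed(fly),
        }

    rates = transition_rates(labels, fps=fps)

    # cutoff exclusion: zero conditional features of too-rare behaviors
    for b in excluded:
        bouts[f"bouts_{b}"] = 0.0
        if not np.isnan(vel[f"vel_{b}"]):
            vel[f"vel_{b}"] = 0.0
        for a, c in list(rates):
            if a == b or c == b:
                rates[(a, c)] = 0.0

    valuemap: dict[str, float] = {**props, **bouts, **vel}
    for (a, b), r in rates.items():
        valuemap[f"rate_{a}_to_{b}"] = r
    values = np.array([valuemap[name] for name in FEATURE_NAMES], dtype=float)
    return WindowFeatures(ethogram.animal_id, span.start / fps, values)


def features_table(
    cohort: CohortDataset,
    spec: WindowSpec = WindowSpec(),
    cutoffs: CutoffSet = CutoffSet(),
) -> pd.DataFrame:
    """All (animal, window) feature vectors of a cohort as one DataFrame.

    Columns: ``animal_id``, ``start_s`` (window start relative to the
    cohort time origin), then the 38 features in canonical order.
    """
    rows = []
    for e in cohort.ethograms:
        velocity = compute_velocity(e) if e.track is not None else None
        for span in make_windows(e, spec):
            wf = extract_features(e, span, cutoffs, velocity=velocity)
            rows.append(
                (e.animal_id, wf.start_s - cohort.time_origin_s, *wf.values)
            )
    return pd.DataFrame(rows, columns=["animal_id", "start_s", *FEATURE_NAMES])


def feature_schema() -> dict:
    """Machine-readable description of the canonical feature order and units."""
    units = {}
    for name in FEATURE_NAMES:
        if name.startswith("prop_"):
            units[name] = "fraction of window time"
        elif name.startswith("bouts_"):
            units[name] = "count per window"
        elif name.startswith("vel_"):
            units[name] = "pixels/s"
        else:
            units[name] = "transitions per second in source behavior"
    return {
        "n_features": len(FEATURE_NAMES),
        "order": list(FEATURE_NAMES),
        "units": units,
        "window": {"length_s": 30.0, "step_s": 10.0},
        "cutoffs": {"fly": 0.04, "walk": 0.2, "probe": 0.2, "groom": 0.3},
    }
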
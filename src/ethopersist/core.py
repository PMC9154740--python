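"""Core data model for ethogram analysis.

An *ethogram* is a per-frame record of which behaviors one animal is
exhibiting.  Behaviors here are the four machine-classified mosquito
behaviors — grooming, walking, probing, flying — stored as raw boolean
flags that may co-occur (probing while walking is biologically real),
plus an optional x–y centroid track.  A cohort bundles the ethograms of
all animals in one trial together with the stimulus timeline (light and
heat pulse channels) and per-animal metadata (sex, condition, and the
engorgement outcome).

Frames are 0-based and all intervals are half-open ``[start, end)``.
Times are in seconds; the time of frame ``i`` is ``i / fps -
time_origin_s``, so re-aligning a cohort to a stimulus onset is a pure
change of time origin.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

#: Raw behavior flag order used by every flags matrix in the package.
BEHAVIORS: tuple[str, ...] = ("groom", "walk", "probe", "fly")

#: Exclusive categories in precedence order (highest first):
#: flying > probing > walking > grooming > no behavior.
EXCLUSIVE_LABELS: tuple[str, ...] = ("fly", "probe", "walk", "groom", "none")

LABEL_CODES: dict[str, int] = {name: i for i, name in enumerate(EXCLUSIVE_LABELS)}

_ETHOGRAM_HEADER = "frame,time_s,groom,walk,probe,fly,x,y"


class EthogramError(ValueError):
    """Raised when ethogram/cohort data violate a structural invariant."""


class Pulse(NamedTuple):
    """One stimulus pulse: half-open interval [onset_s, offset_s) with a magnitude."""

    onset_s: float
    offset_s: float
    magnitude: float = 1.0


@dataclass(frozen=True)
class Bout:
    """Maximal run of consecutive frames of one behavior, half-open in frames."""

    behavior: str
    start_frame: int
    end_frame: int

    def __post_init__(self) -> None:
        if self.end_frame <= self.start_frame:
            raise EthogramError(
                f"bout must have end > start, got [{self.start_frame}, {self.end_frame})"
            )

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame


@dataclass
class Ethogram:
    """Per-frame behavior flags (and optional centroid track) for one animal.

    Parameters
    ----------
    animal_id : str
        Identifier matching the cohort's metadata table.
    flags : ndarray of bool, shape (n_frames, 4)
        Raw behavior flags in :data:`BEHAVIORS` order.  Flags may co-occur.
    fps : float
        Frame rate in frames per second (video standard here is 30).
    track : ndarray of float, shape (n_frames, 2), optional
        x–y centroid positions in pixels; NaN rows mark tracking gaps.
    """

    animal_id: str
    flags: np.ndarray
    fps: float = 30.0
    track: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)
        if self.flags.ndim != 2 or self.flags.shape[1] != len(BEHAVIORS):
            raise EthogramError(
                f"animal {self.animal_id!r}: flags must be (n_frames, "
                f"{len(BEHAVIORS)}), got {self.flags.shape}"
            )
        if not self.fps > 0:
            raise EthogramError(f"animal {self.animal_id!r}: fps must be > 0")
        if self.track is not None:
            self.track = np.asarray(self.track, dtype=float)
            if self.track.shape != (self.flags.shape[0], 2):
                raise EthogramError(
                    f"animal {self.animal_id!r}: track has {self.track.shape[0]} "
                    f"frames but flags have {self.flags.shape[0]}"
                )

    @property
    def n_frames(self) -> int:
        return self.flags.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    def flag(self, behavior: str) -> np.ndarray:
        """Boolean series of one raw behavior flag."""
        return self.flags[:, BEHAVIORS.index(behavior)]

    def exclusive_labels(self) -> np.ndarray:
        """Per-frame exclusive category codes (see :func:`resolve_precedence_frames`)."""
        return resolve_precedence_frames(self.flags)


@dataclass
class StimulusSeries:
    """Named stimulus channels, each a sorted list of non-overlapping pulses."""

    channels: dict[str, list[Pulse]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, pulses in self.channels.items():
            self.channels[name] = norm = [Pulse(*p) for p in pulses]
            prev_off = -np.inf
            for p in norm:
                if not (0 <= p.onset_s < p.offset_s):
                    raise EthogramError(
                        f"channel {name!r}: pulse must satisfy 0 <= onset < offset, got {p}"
                    )
                if p.onset_s < prev_off:
                    raise EthogramError(
                        f"channel {name!r}: pulses overlap or are unsorted at {p}"
                    )
                prev_off = p.offset_s

    def pulse(self, channel: str, which: int = 0) -> Pulse:
        if channel not in self.channels:
            raise KeyError(f"unknown stimulus channel {channel!r}")
        pulses = self.channels[channel]
        if not -len(pulses) <= which < len(pulses):
            raise IndexError(
                f"channel {channel!r} has {len(pulses)} pulse(s), no index {which}"
            )
        return pulses[which]


@dataclass
class CohortDataset:
    """Ethograms + shared stimulus timeline + per-animal metadata.

    ``meta`` has one row per ethogram with columns ``animal_id, sex,
    condition, engorged`` (engorged may be missing).  ``time_origin_s``
    is the recording time mapped to t = 0; stimulus pulse times are
    stored in recording time.
    """

    ethograms: list[Ethogram]
    stimuli: StimulusSeries = field(default_factory=StimulusSeries)
    meta: pd.DataFrame | None = None
    time_origin_s: float = 0.0

    def __post_init__(self) -> None:
        if self.meta is None:
            self.meta = pd.DataFrame(
                {
                    "animal_id": [e.animal_id for e in self.ethograms],
                    "sex": "F",
                    "condition": "",
                    "engorged": pd.array([pd.NA] * len(self.ethograms)),
                }
            )
        self.meta = self.meta.reset_index(drop=True)
        if len(self.meta) != len(self.ethograms):
            raise EthogramError(
                f"{len(self.meta)} metadata rows for {len(self.ethograms)} ethograms"
            )
        ids = [e.animal_id for e in self.ethograms]
        if list(self.meta["animal_id"]) != ids:
            raise EthogramError("meta animal_id order does not match ethograms")
        if self.ethograms:
            fps0 = self.ethograms[0].fps
            for e in self.ethograms:
                if e.fps != fps0:
                    raise EthogramError(
                        f"animal {e.animal_id!r}: fps {e.fps} differs from cohort fps {fps0}"
                    )

    @property
    def fps(self) -> float:
        if not self.ethograms:
            raise EthogramError("empty cohort has no fps")
        return self.ethograms[0].fps

    @property
    def n_animals(self) -> int:
        return len(self.ethograms)

    def times_s(self) -> np.ndarray:
        """Frame times (s) relative to the current time origin."""
        n = self.ethograms[0].n_frames
        return np.arange(n) / self.fps - self.time_origin_s

    def frame_at(self, t_s: float) -> int:
        """Frame index whose time is ``t_s`` relative to the origin."""
        return int(round((t_s + self.time_origin_s) * self.fps))

    def subset(self, mask: Sequence[bool]) -> "CohortDataset":
        mask = np.asarray(mask, dtype=bool)
        eth = [e for e, m in zip(self.ethograms, mask) if m]
        return CohortDataset(
            ethograms=eth,
            stimuli=self.stimuli,
            meta=self.meta.loc[mask].reset_index(drop=True),
            time_origin_s=self.time_origin_s,
        )


# ---------------------------------------------------------------------------
# precedence resolution


def resolve_precedence(flags: Iterable[str]) -> str:
    """Collapse a set of co-occurring raw flags to one exclusive category.

    Precedence is flying > probing > walking > grooming; an empty set
    resolves to ``"none"``.
    """
    flagset = set(flags)
    unknown = flagset - set(BEHAVIORS)
    if unknown:
        raise EthogramError(f"unknown behavior flag(s): {sorted(unknown)}")
    for label in EXCLUSIVE_LABELS[:-1]:
        if label in flagset:
            return label
    return "none"


def resolve_precedence_frames(flags: np.ndarray) -> np.ndarray:
    """Vectorized precedence resolution over a (n_frames, 4) flags matrix.

    Returns int8 codes indexing :data:`EXCLUSIVE_LABELS`.
    """
    flags = np.asarray(flags, dtype=bool)
    out = np.full(flags.shape[0], LABEL_CODES["none"], dtype=np.int8)
    # assign lowest precedence first so higher precedence overwrites
    for label in reversed(EXCLUSIVE_LABELS[:-1]):
        out[flags[:, BEHAVIORS.index(label)]] = LABEL_CODES[label]
    return out


# ---------------------------------------------------------------------------
# bouts and velocity


def find_bouts(series: np.ndarray, behavior: str = "behavior") -> list[Bout]:
    """Maximal runs of consecutive True frames as half-open :class:`Bout` spans."""
    series = np.asarray(series, dtype=bool)
    if series.size == 0:
        return []
    padded = np.concatenate(([False], series, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return [Bout(behavior, int(s), int(e)) for s, e in zip(starts, ends)]


def count_runs(labels: np.ndarray, code: int) -> int:
    """Number of maximal runs of ``code`` in an integer label series."""
    is_code = np.asarray(labels) == code
    if is_code.size == 0:
        return 0
    return int(is_code[0]) + int(np.count_nonzero(~is_code[:-1] & is_code[1:]))


def compute_velocity(ethogram: Ethogram, interval_s: float = 0.1) -> np.ndarray:
    """Centroid speed sampled at ``interval_s`` (default 100 ms, i.e. 3 frames at 30 fps).

    Sample ``k`` is the Euclidean displacement between the positions at
    frames ``k*step`` and ``(k+1)*step`` divided by ``interval_s``
    (pixels/s).  Samples whose endpoint frame is beyond the record or
    falls in a tracking gap are NaN; callers exclude NaN from averages.
    """
    if ethogram.track is None:
        raise EthogramError(f"animal {ethogram.animal_id!r} has no track")
    step_f = interval_s * ethogram.fps
    step = int(round(step_f))
    if step < 1 or abs(step - step_f) > 1e-9:
        raise EthogramError(
            f"interval_s={interval_s} is not a positive multiple of 1/fps"
        )
    n = ethogram.n_frames
    n_samples = n // step
    speeds = np.full(n_samples, np.nan)
    idx0 = np.arange(n_samples) * step
    idx1 = idx0 + step
    ok = idx1 <= n - 1
    d = ethogram.track[idx1[ok]] - ethogram.track[idx0[ok]]
    speeds[ok] = np.hypot(d[:, 0], d[:, 1]) / interval_s
    return speeds


# ---------------------------------------------------------------------------
# stimulus alignment


def align_to_stimulus(
    cohort: CohortDataset, channel: str, which_pulse: int = 0
) -> CohortDataset:
    """Re-index cohort time so t = 0 is the onset of the given pulse.

    Only the time origin changes; frames and stimulus pulses (stored in
    recording time) are untouched, so alignment is exactly invertible.
    """
    onset = cohort.stimuli.pulse(channel, which_pulse).onset_s
    return dataclasses.replace(cohort, time_origin_s=onset)


def shift_time_origin(cohort: CohortDataset, origin_s: float) -> CohortDataset:
    """Return the cohort with an explicit time origin (s, recording time)."""
    return dataclasses.replace(cohort, time_origin_s=origin_s)


# ---------------------------------------------------------------------------
# I/O: cohort directory of per-animal CSVs, or a single JSON file

def _fmt(x: float | None) -> str:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return ""
    return repr(float(x))


def _ethogram_to_csv(e: Ethogram, time_origin_s: float) -> str:
    lines = [_ETHOGRAM_HEADER]
    times = np.arange(e.n_frames) / e.fps - time_origin_s
    has_track = e.track is not None
    for i in range(e.n_frames):
        g, w, p, f = (int(v) for v in e.flags[i])
        if has_track:
            x, y = _fmt(e.track[i, 0]), _fmt(e.track[i, 1])
        else:
            x = y = ""
        lines.append(f"{i},{_fmt(times[i])},{g},{w},{p},{f},{x},{y}")
    return "\n".join(lines) + "\n"


def _ethogram_from_csv(path: Path, animal_id: str, fps: float) -> tuple[Ethogram, float]:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - message path
        raise EthogramError(f"{path}: cannot parse ({exc})") from exc
    expected = _ETHOGRAM_HEADER.split(",")
    if list(df.columns) != expected:
        raise EthogramError(
            f"{path}: malformed header {list(df.columns)}, expected {expected}"
        )
    frames = df["frame"].to_numpy()
    if not np.array_equal(frames, np.arange(len(df))):
        bad = int(np.flatnonzero(frames != np.arange(len(df)))[0])
        raise EthogramError(f"{path}: line {bad + 2}: frame index not consecutive")
    for col in BEHAVIORS:
        vals = df[col].to_numpy()
        if not np.isin(vals, (0, 1)).all():
            bad = int(np.flatnonzero(~np.isin(vals, (0, 1)))[0])
            raise EthogramError(f"{path}: line {bad + 2}: flag {col!r} not 0/1")
    flags = df[list(BEHAVIORS)].to_numpy(dtype=bool)
    if df["x"].notna().any() or df["y"].notna().any():
        track = df[["x", "y"]].to_numpy(dtype=float)
    else:
        track = None
    origin = -float(df["time_s"].iloc[0]) if len(df) else 0.0
    return Ethogram(animal_id, flags, fps=fps, track=track), origin


def _stimuli_to_dict(stimuli: StimulusSeries) -> dict:
    return {
        "channels": [
            {
                "name": name,
                "pulses": [
                    {"onset_s": p.onset_s, "offset_s": p.offset_s, "magnitude": p.magnitude}
                    for p in pulses
                ],
            }
            for name, pulses in stimuli.channels.items()
        ]
    }


def _stimuli_from_dict(d: dict) -> StimulusSeries:
    return StimulusSeries(
        channels={
            ch["name"]: [
                Pulse(p["onset_s"], p["offset_s"], p.get("magnitude", 1.0))
                for p in ch["pulses"]
            ]
            for ch in d.get("channels", [])
        }
    )


def _meta_records(meta: pd.DataFrame) -> list[dict]:
    recs = []
    for _, row in meta.iterrows():
        eng = row.get("engorged")
        recs.append(
            {
                "animal_id": str(row["animal_id"]),
                "sex": str(row.get("sex", "")),
                "condition": str(row.get("condition", "")),
                "engorged": None if pd.isna(eng) else int(eng),
            }
        )
    return recs


def _meta_frame(recs: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "animal_id": [r["animal_id"] for r in recs],
            "sex": [r["sex"] for r in recs],
            "condition": [r["condition"] for r in recs],
            "engorged": pd.array(
                [pd.NA if r["engorged"] is None else int(r["engorged"]) for r in recs]
            ),
        }
    )


def write_cohort(cohort: CohortDataset, path: str | Path, format: str = "csv_dir") -> None:
    """Write a cohort in the canonical on-disk dialect.

    ``csv_dir``: a directory holding one ``<animal_id>.csv`` per animal
    (header ``frame,time_s,groom,walk,probe,fly,x,y``), a ``meta.csv``
    and a ``stimuli.json``.  ``json``: everything in one JSON file.
    Output is canonical: writing what :func:`read_cohort` read is
    byte-identical.
    """
    path = Path(path)
    if format == "csv_dir":
        path.mkdir(parents=True, exist_ok=True)
        for e in cohort.ethograms:
            (path / f"{e.animal_id}.csv").write_text(
                _ethogram_to_csv(e, cohort.time_origin_s)
            )
        meta_lines = ["animal_id,sex,condition,engorged"]
        for r in _meta_records(cohort.meta):
            eng = "" if r["engorged"] is None else str(r["engorged"])
            meta_lines.append(f"{r['animal_id']},{r['sex']},{r['condition']},{eng}")
        (path / "meta.csv").write_text("\n".join(meta_lines) + "\n")
        stim = _stimuli_to_dict(cohort.stimuli)
        stim["fps"] = cohort.fps if cohort.ethograms else 30.0
        stim["time_origin_s"] = cohort.time_origin_s
        (path / "stimuli.json").write_text(
            json.dumps(stim, indent=2, sort_keys=True) + "\n"
        )
    elif format == "json":
        doc = {
            "fps": cohort.fps if cohort.ethograms else 30.0,
            "time_origin_s": cohort.time_origin_s,
            "stimuli": _stimuli_to_dict(cohort.stimuli),
            "meta": _meta_records(cohort.meta),
            "ethograms": [
                {
                    "animal_id": e.animal_id,
                    "flags": e.flags.astype(int).tolist(),
                    "track": None if e.track is None else e.track.tolist(),
                }
                for e in cohort.ethograms
            ],
        }
        Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_cohort(path: str | Path, format: str = "csv_dir") -> CohortDataset:
    """Read a cohort written by :func:`write_cohort`; all invariants are checked."""
    path = Path(path)
    if format == "csv_dir":
        stim_doc = json.loads((path / "stimuli.json").read_text())
        fps = float(stim_doc.get("fps", 30.0))
        stimuli = _stimuli_from_dict(stim_doc)
        meta_df = pd.read_csv(
            path / "meta.csv", dtype={"animal_id": str}, keep_default_na=True
        )
        if list(meta_df.columns) != ["animal_id", "sex", "condition", "engorged"]:
            raise EthogramError(f"{path / 'meta.csv'}: malformed header")
        meta = _meta_frame(
            [
                {
                    "animal_id": row["animal_id"],
                    "sex": "" if pd.isna(row["sex"]) else str(row["sex"]),
                    "condition": "" if pd.isna(row["condition"]) else str(row["condition"]),
                    "engorged": None if pd.isna(row["engorged"]) else int(row["engorged"]),
                }
                for _, row in meta_df.iterrows()
            ]
        )
        ethograms, origins = [], []
        for animal_id in meta["animal_id"]:
            f = path / f"{animal_id}.csv"
            if not f.exists():
                raise EthogramError(f"{path}: missing ethogram file for animal {animal_id!r}")
            e, origin = _ethogram_from_csv(f, animal_id, fps)
            ethograms.append(e)
            origins.append(origin)
        origin = float(stim_doc.get("time_origin_s", origins[0] if origins else 0.0))
        return CohortDataset(ethograms, stimuli, meta, time_origin_s=origin)
    elif format == "json":
        doc = json.loads(Path(path).read_text())
        fps = float(doc["fps"])
        meta = _meta_frame(doc["meta"])
        ethograms = []
        for rec in doc["ethograms"]:
            try:
                ethograms.append(
                    Ethogram(
                        rec["animal_id"],
                        np.asarray(rec["flags"], dtype=bool),
                        fps=fps,
                        track=None if rec["track"] is None else np.asarray(rec["track"]),
                    )
                )
            except EthogramError as exc:
                raise EthogramError(f"{path}: {exc}") from exc
        return CohortDataset(
            ethograms,
            _stimuli_from_dict(doc["stimuli"]),
            meta,
            time_origin_s=float(doc.get("time_origin_s", 0.0)),
        )
    else:
        raise ValueError(f"unknown format {format!r}")


def validate_cohort(cohort: CohortDataset) -> list[str]:
    """Run all structural checks, returning a list of problem strings (empty = valid)."""
    problems: list[str] = []
    try:
        CohortDataset(
            cohort.ethograms, cohort.stimuli, cohort.meta, cohort.time_origin_s
        )
    except EthogramError as exc:
        problems.append(str(exc))
    if cohort.ethograms:
        n0 = cohort.ethograms[0].n_frames
        for e in cohort.ethograms:
            if e.n_frames != n0:
                problems.append(
                    f"animal {e.animal_id!r}: {e.n_frames} frames, cohort expects {n0}"
                )
    return problems
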
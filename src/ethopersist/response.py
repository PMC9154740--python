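"""Stimulus-aligned population response curves and summary statistics.

The population response to a stimulus is the fraction of animals
exhibiting a behavior as a function of time relative to stimulus onset.
Three derived statistics are implemented:

* **half-life** (t1/2): baseline is the mean response over the 2 min
  before onset; the response is smoothed with a 15 s sliding window
  starting at onset; the maximum response is the largest windowed value
  after onset; t1/2 is the first window at or after the maximum whose
  value has returned halfway from the maximum to baseline.  Reported in
  minutes, or censored when there is no response or the record ends
  before the halfway crossing.
* **percent additivity**: 100 x (response to the combined stimulus) /
  (sum of the cohort-average responses to the individual stimuli),
  evaluated per animal over the first 15 s after onset and summarized
  by the cohort median.  100% is exact additivity, 0% no response.
* time-resolved additivity is smoothed over 4.5 s around each 500 ms
  bin (a centered 9-bin moving average with truncated edges).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import BEHAVIORS, CohortDataset


@dataclass
class ResponseCurve:
    """Fraction of animals (or of time) exhibiting a behavior vs time from onset."""

    times_s: np.ndarray
    values: np.ndarray
    behavior: str = "probe"
    n: int = 0

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times_s.shape != self.values.shape:
            raise ValueError("times and values must have the same shape")
        if self.times_s.size >= 2:
            dt = np.diff(self.times_s)
            if not (dt > 0).all() or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("times must be a strictly increasing uniform grid")
        if ((self.values < -1e-9) | (self.values > 1 + 1e-9)).any():
            raise ValueError("response values must lie in [0, 1]")

    @property
    def dt(self) -> float:
        return float(self.times_s[1] - self.times_s[0])

    def truncate(self, t_min: float = -np.inf, t_max: float = np.inf) -> "ResponseCurve":
        m = (self.times_s >= t_min) & (self.times_s < t_max)
        return ResponseCurve(self.times_s[m], self.values[m], self.behavior, self.n)

    def plot(self, ax=None, **kwargs):
        """Plot the curve (percent on the y axis) against minutes from onset."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.times_s / 60.0, 100.0 * self.values, **kwargs)
        ax.set_xlabel("time from stimulus onset (min)")
        ax.set_ylabel(f"% exhibiting {self.behavior}")
        return ax


@dataclass
class HalfLifeResult:
    """Baseline, maximum windowed response, and the decay half-life in minutes."""

    baseline: float
    max_response: float
    argmax_time_s: float | None = None
    t_half_min: float | None = None
    censored: str | None = None  # "no response" | "right-censored" | None

    def __post_init__(self) -> None:
        if self.t_half_min is not None and self.censored is not None:
            raise ValueError("a censored result carries no t_half")


@dataclass
class AdditivityResult:
    """Per-animal percent additivity and its cohort median."""

    per_animal: np.ndarray
    median: float
    predicted: float
    behavior: str = "probe"
    series: np.ndarray | None = None  # optional time-resolved additivity
    series_times_s: np.ndarray | None = None


# ---------------------------------------------------------------------------


def fraction_exhibiting(
    cohort: CohortDataset,
    behavior: str,
    bin_s: float | None = None,
    per_animal_time: bool = False,
) -> ResponseCurve:
    """Population response curve for one raw behavior flag.

    At each time bin the value is the fraction of animals whose flag is
    on at any frame of the bin (the plotted "% individuals" convention).
    With ``per_animal_time=True`` it is instead the mean over animals of
    the fraction of the bin's frames with the flag on.
    """
    if not cohort.ethograms:
        raise ValueError("empty cohort")
    if behavior not in BEHAVIORS:
        raise ValueError(f"unknown behavior {behavior!r}")
    fps = cohort.fps
    bin_s = 1.0 / fps if bin_s is None else bin_s
    bin_f = int(round(bin_s * fps))
    if bin_f < 1:
        raise ValueError("bin_s must be at least one frame")
    n_frames = cohort.ethograms[0].n_frames
    n_bins = n_frames // bin_f
    col = BEHAVIORS.index(behavior)
    stack = np.stack(
        [e.flags[: n_bins * bin_f, col].reshape(n_bins, bin_f) for e in cohort.ethograms]
    )  # (animals, bins, frames/bin)
    if per_animal_time:
        values = stack.mean(axis=(0, 2))
    else:
        values = stack.any(axis=2).mean(axis=0)
    times = np.arange(n_bins) * bin_s - cohort.time_origin_s
    return ResponseCurve(times, values, behavior=behavior, n=cohort.n_animals)


def sliding_window_response(curve: ResponseCurve, window_s: float = 15.0) -> ResponseCurve:
    """Forward-looking sliding mean over [t, t + window_s) for every sample t >= 0.

    Windows truncated by the end of the record are dropped.
    """
    dt = curve.dt
    w = int(round(window_s / dt))
    post = curve.times_s >= -dt / 2  # t >= 0 samples
    t_post = curve.times_s[post]
    v_post = curve.values[post]
    if w < 1 or w > v_post.size:
        raise ValueError("window longer than the post-onset record")
    kernel_sums = np.convolve(v_post, np.ones(w), mode="valid")
    return ResponseCurve(t_post[: v_post.size - w + 1], kernel_sums / w, curve.behavior, curve.n)


def half_life(
    curve: ResponseCurve,
    baseline_window_s: float = 120.0,
    window_s: float = 15.0,
) -> HalfLifeResult:
    """Decay half-life of a stimulus-aligned response curve (minutes).

    Baseline is the mean of the raw curve over ``[-baseline_window_s, 0)``;
    the search for the halfway crossing starts at the earliest maximum of
    the windowed post-onset curve (the rising phase also crosses the
    halfway level, so "first window" is read on the decay).
    """
    pre = (curve.times_s >= -baseline_window_s) & (curve.times_s < 0)
    if not pre.any():
        raise ValueError("curve does not cover the pre-stimulus baseline window")
    baseline = float(curve.values[pre].mean())
    windowed = sliding_window_response(curve, window_s=window_s)
    i_max = int(np.argmax(windowed.values))  # earliest maximum wins
    max_response = float(windowed.values[i_max])
    if max_response <= baseline:
        return HalfLifeResult(baseline, max_response, censored="no response")
    halfway = baseline + (max_response - baseline) / 2.0
    tail = windowed.values[i_max:]
    below = np.flatnonzero(tail <= halfway)
    argmax_t = float(windowed.times_s[i_max])
    if below.size == 0:
        return HalfLifeResult(
            baseline, max_response, argmax_time_s=argmax_t, censored="right-censored"
        )
    t_half_s = float(windowed.times_s[i_max + below[0]])
    return HalfLifeResult(
        baseline, max_response, argmax_time_s=argmax_t, t_half_min=t_half_s / 60.0
    )


# ---------------------------------------------------------------------------
# multimodal additivity


def predicted_additive(resp_a, resp_b):
    """Predicted additive response: the sum of the two individual responses."""
    if isinstance(resp_a, ResponseCurve) and isinstance(resp_b, ResponseCurve):
        if resp_a.times_s.shape != resp_b.times_s.shape or not np.allclose(
            resp_a.times_s, resp_b.times_s
        ):
            raise ValueError("response curves are on different time grids")
        return resp_a.values + resp_b.values
    return resp_a + resp_b


def percent_additivity(combined_response, predicted: float):
    """100 x combined / predicted, per animal; NaN-free scalar or array.

    ``predicted`` must be positive; a non-positive predicted response
    makes the ratio undefined and raises.
    """
    if predicted <= 0:
        raise ValueError("predicted additive response must be > 0")
    return 100.0 * np.asarray(combined_response, dtype=float) / predicted


def mean_response(
    cohort: CohortDataset, behavior: str, window_s: float = 15.0
) -> np.ndarray:
    """Per-animal mean raw-flag response over the first ``window_s`` after t = 0."""
    f0 = cohort.frame_at(0.0)
    f1 = f0 + int(round(window_s * cohort.fps))
    col = BEHAVIORS.index(behavior)
    return np.array([e.flags[f0:f1, col].mean() for e in cohort.ethograms])


def additivity_from_cohort(
    cohort: CohortDataset,
    behavior: str = "probe",
    conditions: tuple[str, str, str] = ("A", "B", "A+B"),
    window_s: float = 15.0,
    baseline_subtract: bool = False,
    baseline_window_s: float = 120.0,
    time_resolved: bool = False,
) -> AdditivityResult:
    """Percent additivity of a three-condition cohort (A alone, B alone, A+B).

    The predicted additive response is the sum of the cohort-average
    responses to A and B over the first ``window_s`` after onset; each
    combined-condition animal's response over the same window is divided
    by it.  Optionally responses are baseline-subtracted using the mean
    response over the pre-onset baseline window.  With
    ``time_resolved=True`` the result also carries a 500 ms-binned
    additivity series smoothed over 4.5 s (bins with no predicted
    response are NaN, and NaN spreads into the smoothing window).
    """
    cond_a, cond_b, cond_ab = conditions
    parts = {}
    subsets = {}
    for cond in conditions:
        sub = cohort.subset(cohort.meta["condition"] == cond)
        if sub.n_animals == 0:
            raise ValueError(f"no animals in condition {cond!r}")
        resp = mean_response(sub, behavior, window_s)
        if baseline_subtract:
            f1 = sub.frame_at(0.0)
            f0 = max(f1 - int(round(baseline_window_s * sub.fps)), 0)
            col = BEHAVIORS.index(behavior)
            base = np.array([e.flags[f0:f1, col].mean() for e in sub.ethograms])
            resp = resp - base
        parts[cond] = resp
        subsets[cond] = sub
    predicted = float(parts[cond_a].mean() + parts[cond_b].mean())
    if predicted <= 0:
        warnings.warn(
            f"predicted additive response for {behavior!r} is not positive; "
            "additivity undefined"
        )
        raise ValueError("predicted additive response must be > 0")
    per_animal = percent_additivity(parts[cond_ab], predicted)
    result = AdditivityResult(
        per_animal=per_animal,
        median=float(np.median(per_animal)),
        predicted=predicted,
        behavior=behavior,
    )
    if time_resolved:
        bin_s = 0.5
        curves = {
            cond: fraction_exhibiting(sub, behavior, bin_s=bin_s, per_animal_time=True)
            for cond, sub in subsets.items()
        }
        post = {c: k.truncate(0.0, np.inf) for c, k in curves.items()}
        n = min(k.values.size for k in post.values())
        pred = post[cond_a].values[:n] + post[cond_b].values[:n]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(pred > 0, 100.0 * post[cond_ab].values[:n] / pred, np.nan)
        result.series = smooth_additivity(ratio, bin_s=bin_s)
        result.series_times_s = post[cond_ab].times_s[:n]
    return result


def smooth_additivity(series: np.ndarray, bin_s: float = 0.5, span_s: float = 4.5) -> np.ndarray:
    """Centered moving average over ``span_s`` (9 bins at 500 ms); edges use available bins."""
    series = np.asarray(series, dtype=float)
    w = int(round(span_s / bin_s))
    if w % 2 == 0:
        w += 1  # centered window
    kernel = np.ones(w)
    sums = np.convolve(series, kernel, mode="same")
    counts = np.convolve(np.ones_like(series), kernel, mode="same")
    return sums / counts
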
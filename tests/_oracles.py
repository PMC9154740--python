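"""Independent brute-force oracles used to verify the library.

Everything here is written as a direct frame-by-frame transcription of
the feature definitions, deliberately ignoring the library's vectorized
implementations, so that agreement is a meaningful check.
"""

from __future__ import annotations

import math


BEHAVIORS = ("groom", "walk", "probe", "fly")
ORDER = ("fly", "probe", "walk", "groom", "none")  # precedence, high to low


def exclusive_label(flag_row) -> str:
    on = {b for b, v in zip(BEHAVIORS, flag_row) if v}
    for name in ORDER[:-1]:
        if name in on:
            return name
    return "none"


def bout_count(series) -> int:
    count = 0
    prev = False
    for v in series:
        if v and not prev:
            count += 1
        prev = bool(v)
    return count


def bout_spans(series) -> list[tuple[int, int]]:
    spans = []
    start = None
    for i, v in enumerate(series):
        if v and start is None:
            start = i
        elif not v and start is not None:
            spans.append((start, i))
            start = None
    if start is not None:
        spans.append((start, len(series)))
    return spans


def velocity_series(track, fps, interval_s=0.1) -> list[float]:
    step = round(interval_s * fps)
    n = len(track)
    out = []
    for k in range(n // step):
        i0, i1 = k * step, (k + 1) * step
        if i1 > n - 1:
            out.append(float("nan"))
            continue
        dx = track[i1][0] - track[i0][0]
        dy = track[i1][1] - track[i0][1]
        if math.isnan(dx) or math.isnan(dy):
            out.append(float("nan"))
        else:
            out.append(math.hypot(dx, dy) / interval_s)
    return out


def window_features(flags, track, fps, start, stop, cutoffs) -> dict[str, float]:
    """All 38 features for one window, by direct frame scans."""
    fl = flags[start:stop]
    n = len(fl)
    cols = {b: [bool(r[i]) for r in fl] for i, b in enumerate(BEHAVIORS)}
    feats: dict[str, float] = {}
    for b in BEHAVIORS:
        feats[f"prop_{b}"] = sum(cols[b]) / n
    feats["prop_none"] = sum(1 for r in fl if not any(r)) / n
    feats["prop_probe_walk"] = sum(
        1 for p, w in zip(cols["probe"], cols["walk"]) if p and w
    ) / n
    feats["prop_probe_not_walk"] = sum(
        1 for p, w in zip(cols["probe"], cols["walk"]) if p and not w
    ) / n
    feats["prop_walk_not_probe"] = sum(
        1 for p, w in zip(cols["probe"], cols["walk"]) if w and not p
    ) / n

    labels = [exclusive_label(r) for r in fl]
    for name in ORDER:
        feats[f"bouts_{name}"] = float(bout_count([l == name for l in labels]))

    # velocity: samples [k*step, (k+1)*step] fully inside the window
    if track is None:
        for key in ("vel_mean", "vel_groom", "vel_walk", "vel_probe", "vel_fly"):
            feats[key] = float("nan")
    else:
        step = round(0.1 * fps)
        full = velocity_series(track, fps)
        samples = []  # (sample_start_frame, speed)
        for k, v in enumerate(full):
            i0, i1 = k * step, (k + 1) * step
            if i0 >= start and i1 <= stop - 1:
                samples.append((i0, v))

        def msel(pred):
            vals = [v for i0, v in samples if pred(i0) and not math.isnan(v)]
            return sum(vals) / len(vals) if vals else 0.0

        feats["vel_mean"] = msel(lambda i: True)
        for b in BEHAVIORS:
            feats[f"vel_{b}"] = msel(lambda i, b=b: cols[b][i - start])

    for a in ORDER:
        time_a = sum(1 for l in labels if l == a) / fps
        for b in ORDER:
            if a == b:
                continue
            if time_a == 0:
                feats[f"rate_{a}_to_{b}"] = 0.0
            else:
                nab = sum(
                    1
                    for x, y in zip(labels[:-1], labels[1:])
                    if x == a and y == b
                )
                feats[f"rate_{a}_to_{b}"] = nab / time_a

    # cutoffs zero conditional features of too-rare behaviors
    for b in BEHAVIORS:
        if feats[f"prop_{b}"] < cutoffs[b]:
            feats[f"bouts_{b}"] = 0.0
            if not math.isnan(feats[f"vel_{b}"]):
                feats[f"vel_{b}"] = 0.0
            for a in ORDER:
                for c in ORDER:
                    if a != c and (a == b or c == b):
                        feats[f"rate_{a}_to_{c}"] = 0.0
    return feats


def fraction_curve(flag_stack, bin_f) -> list[float]:
    """Fraction of animals with the flag on at any frame of each bin."""
    n_animals, n_frames = len(flag_stack), len(flag_stack[0])
    out = []
    for b in range(n_frames // bin_f):
        hit = 0
        for a in range(n_animals):
            if any(flag_stack[a][b * bin_f : (b + 1) * bin_f]):
                hit += 1
        out.append(hit / n_animals)
    return out


def sliding_mean(values, w) -> list[float]:
    return [sum(values[i : i + w]) / w for i in range(len(values) - w + 1)]


def windowed_decay_halflife(baseline, peak, tau_s, window_s=15.0, dt=0.5) -> float:
    """Half-life of the analytic decay curve after 15 s forward-window
    averaging, by numeric integration of the curve over each window."""

    def windowed(t):
        m = 200
        xs = [t + window_s * (i + 0.5) / m for i in range(m)]
        return sum(baseline + (peak - baseline) * 2 ** (-x / tau_s) for x in xs) / m

    wmax = windowed(0.0)
    half = baseline + (wmax - baseline) / 2
    t = 0.0
    while windowed(t) > half:
        t += dt
    return t


def occupancy_counts(labels) -> dict[str, float]:
    total = len(labels)
    return {u: labels.count(u) / total for u in set(labels)}
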
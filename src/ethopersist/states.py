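"""Behavioral-state inference from window features.

Window feature vectors are z-scored, embedded into two dimensions with
tSNE (perplexity = n/100 by default, learning rate 200, 1000
iterations), and segmented into clusters.  The reference analysis
segmented the embedding by hand; the default here is an automatic
density-peaks segmentation (cluster centers are points of locally
maximal density that are far from any denser point), with a k-means
option and a manual-polygon override path so a hand segmentation
remains expressible.  Windows of very low local density are left
``unassigned`` (the analysis equivalent of the white, no-state windows).

Clusters are mapped onto the four canonical state names — ``rest``,
``global_search``, ``local_search``, ``engorge`` — by matching each
cluster's behavior composition (flight-dominated and fast: global
search; probe-rich and mobile: local search; probe-rich and immobile:
engorge; inactive/grooming: rest).  When segmentation yields more than
four clusters, extras are merged into the state they best match (the
engorge cluster in particular is known to split).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE

from .core import BEHAVIORS, CohortDataset
from .features import FEATURE_NAMES, WindowSpec

STATE_NAMES: tuple[str, ...] = ("rest", "global_search", "local_search", "engorge")
UNASSIGNED = "unassigned"


@dataclass
class StateMap:
    """Per-window embedding coordinates and state labels.

    ``cluster_ids`` are raw cluster indices (-1 = unassigned);
    ``labels`` are state names (or ``unassigned``).  ``animal_ids`` and
    ``start_s`` identify the windows; provenance records the method and
    parameters that produced the map.
    """

    animal_ids: np.ndarray
    start_s: np.ndarray
    coords: np.ndarray
    cluster_ids: np.ndarray
    labels: np.ndarray
    window: WindowSpec = field(default_factory=WindowSpec)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.animal_ids)
        if not (len(self.start_s) == len(self.coords) == len(self.cluster_ids) == len(self.labels) == n):
            raise ValueError("all StateMap arrays must have one entry per window")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal_id": self.animal_ids,
                "start_s": self.start_s,
                "tsne_1": self.coords[:, 0],
                "tsne_2": self.coords[:, 1],
                "cluster": self.cluster_ids,
                "state": self.labels,
            }
        )


@dataclass
class StateEthogram:
    """Per-state behavior composition, inter-state transition rates, travel."""

    composition: pd.DataFrame  # state x {groom,walk,probe,fly,none}
    transition_rates: pd.DataFrame  # state x state, per second
    distance: pd.Series  # mean pixels traveled per window, per state


# ---------------------------------------------------------------------------
# embedding


def embed_features(
    features: pd.DataFrame,
    perplexity: float | None = None,
    seed: int = 0,
    standardize: bool = True,
) -> np.ndarray:
    """2-D tSNE embedding of a window-feature table.

    ``perplexity`` defaults to n/100 (clipped to at least 2, hence the
    n >= 200 precondition).  Features are z-scored per column and
    zero-variance columns dropped with a warning.
    """
    X = features[list(FEATURE_NAMES)].to_numpy(dtype=float)
    n = X.shape[0]
    if n < 200:
        raise ValueError(f"need at least 200 windows for embedding, got {n}")
    if np.isnan(X).any():
        raise ValueError("feature table contains NaN (missing velocities?)")
    if standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        keep = sd > 0
        if not keep.all():
            dropped = [FEATURE_NAMES[i] for i in np.flatnonzero(~keep)]
            warnings.warn(f"dropping zero-variance features: {dropped}")
        if not keep.any():
            raise ValueError("all features are constant")
        X = (X[:, keep] - mu[keep]) / sd[keep]
    if perplexity is None:
        perplexity = max(n / 100.0, 2.0)
    perplexity = min(perplexity, (n - 1) / 3.0)
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        learning_rate=200.0,
        max_iter=1000,
        init="pca",
        random_state=seed,
        method="barnes_hut",
    )
    return tsne.fit_transform(X)


# ---------------------------------------------------------------------------
# clustering


def _density_peaks(
    coords: np.ndarray,
    n_clusters: int | None,
    density_percentile: float,
    max_clusters: int = 16,
) -> np.ndarray:
    """Density-peaks segmentation of a 2-D point cloud.

    For each point, rho is a Gaussian-kernel local density and delta the
    distance to the nearest point of higher density.  Unless a cluster
    count is given, centers are the points that are simultaneously dense
    (rho above 35% of the peak) and isolated (delta above 8% of the
    embedding diameter).  Points are assigned by inheriting the label of
    their nearest denser neighbor; cluster pairs separated only by a
    shallow density valley are merged (see
    :func:`_merge_shallow_borders`); points below the
    ``density_percentile`` of rho are unassigned (-1).
    """
    n = coords.shape[0]
    if n == 1:
        return np.zeros(1, dtype=int)
    rng = np.random.default_rng(0)
    sample = coords[rng.choice(n, size=min(n, 1000), replace=False)]
    d_sample = np.sqrt(
        ((sample[:, None, :] - sample[None, :, :]) ** 2).sum(-1)
    )
    tri = d_sample[np.triu_indices_from(d_sample, k=1)]
    d_c = max(np.quantile(tri, 0.02), 1e-12)

    # local density, chunked
    rho = np.zeros(n)
    chunk = 512
    for i0 in range(0, n, chunk):
        block = coords[i0 : i0 + chunk]
        d2 = ((block[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
        rho[i0 : i0 + chunk] = np.exp(-d2 / d_c**2).sum(axis=1) - 1.0

    order = np.argsort(-rho, kind="stable")
    sorted_pts = coords[order]
    delta = np.empty(n)
    nneigh = np.empty(n, dtype=int)  # index (in sorted order) of nearest denser point
    delta[0] = np.inf
    nneigh[0] = 0
    for i0 in range(1, n, chunk):
        i1 = min(i0 + chunk, n)
        d2 = ((sorted_pts[i0:i1, None, :] - sorted_pts[None, : i1 - 1, :]) ** 2).sum(-1)
        # point j (sorted) may only look at strictly earlier points
        for j in range(i0, i1):
            row = d2[j - i0, :j]
            k = int(np.argmin(row))
            nneigh[j] = k
            delta[j] = np.sqrt(row[k])
    delta[0] = delta[1:].max() * 1.01 if n > 1 else 1.0

    # rho, delta, gamma all in sorted (descending-density) order
    rs = rho[order]
    gamma = rs * delta
    g_order = np.argsort(-gamma, kind="stable")
    if n_clusters is None:
        # centers: dense points far from any denser point (delta above a
        # twelfth of the embedding diameter, density above 35% of the peak)
        diam = float(np.sqrt(((coords.max(0) - coords.min(0)) ** 2).sum()))
        cand = (delta > 0.08 * diam) & (rs > 0.35 * rs.max())
        n_clusters = int(np.clip(np.count_nonzero(cand), 1, max_clusters))
        g_order = np.argsort(-np.where(cand, gamma, -np.inf), kind="stable")
        if not cand.any():
            g_order = np.argsort(-gamma, kind="stable")
    center_rank = {int(j): i for i, j in enumerate(g_order[:n_clusters])}

    labels_sorted = np.full(n, -1, dtype=int)
    for j in range(n):  # descending density
        if j in center_rank:
            labels_sorted[j] = center_rank[j]
        else:
            labels_sorted[j] = labels_sorted[nneigh[j]]
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted

    labels = _merge_shallow_borders(coords, rho, labels, d_c)

    if density_percentile > 0:
        thresh = np.percentile(rho, density_percentile)
        labels[rho < thresh] = -1
    return labels


def _merge_shallow_borders(
    coords: np.ndarray,
    rho: np.ndarray,
    labels: np.ndarray,
    d_c: float,
    ratio: float = 0.65,
) -> np.ndarray:
    """Merge cluster pairs whose border is nearly as dense as their peaks.

    The border density of a pair is the largest mean density of two
    points from different clusters lying within d_c of each other.  A
    border denser than ``ratio`` of the smaller peak means the two
    clusters sit on one density hill split by estimation noise, and they
    are merged.  Genuinely separated clusters have near-empty borders.
    """
    ids = [int(c) for c in np.unique(labels) if c >= 0]
    if len(ids) <= 1:
        return labels
    peak = {c: float(rho[labels == c].max()) for c in ids}
    border: dict[tuple[int, int], float] = {}
    n = coords.shape[0]
    chunk = 512
    for i0 in range(0, n, chunk):
        i1 = min(i0 + chunk, n)
        d2 = ((coords[i0:i1, None, :] - coords[None, :, :]) ** 2).sum(-1)
        close = d2 < d_c**2
        la = labels[i0:i1]
        for r in range(i1 - i0):
            if la[r] < 0:
                continue
            js = np.flatnonzero(close[r] & (labels != la[r]) & (labels >= 0))
            for j in js:
                lb = labels[j]
                key = (min(la[r], lb), max(la[r], lb))
                dens = 0.5 * (rho[i0 + r] + rho[j])
                if dens > border.get(key, 0.0):
                    border[key] = dens
    # union-find over mergeable pairs
    parent = {c: c for c in ids}

    def find(c: int) -> int:
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    for (a, b), dens in border.items():
        if dens > ratio * min(peak[a], peak[b]):
            parent[find(a)] = find(b)
    roots = sorted({find(c) for c in ids})
    remap = {c: roots.index(find(c)) for c in ids}
    out = labels.copy()
    for c in ids:
        out[labels == c] = remap[c]
    return out


def cluster_states(
    coords: np.ndarray,
    method: str = "density_peaks",
    n_clusters: int | None = None,
    density_percentile: float = 5.0,
    polygons: list[tuple[str, object]] | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Segment embedding coordinates into clusters.

    Returns (cluster_ids, provenance).  ``method`` is one of
    ``density_peaks`` (default, automatic), ``kmeans_k`` (requires
    ``n_clusters``), or ``manual_polygons`` (``polygons`` is a list of
    (state_name, shapely-Polygon-like) pairs in embedding coordinates;
    points outside every polygon are unassigned).
    """
    coords = np.asarray(coords, dtype=float)
    prov = {"method": method, "seed": seed}
    if method == "density_peaks":
        ids = _density_peaks(coords, n_clusters, density_percentile)
        prov["density_percentile"] = density_percentile
    elif method == "kmeans_k":
        if n_clusters is None:
            raise ValueError("kmeans_k requires n_clusters")
        from sklearn.cluster import KMeans

        ids = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed).fit_predict(coords)
        prov["n_clusters"] = n_clusters
    elif method == "manual_polygons":
        if not polygons:
            raise ValueError("manual_polygons requires polygons")
        from shapely.geometry import Point, shape

        ids = np.full(coords.shape[0], -1, dtype=int)
        names = []
        for idx, (name, poly) in enumerate(polygons):
            geom = poly if hasattr(poly, "contains") else shape(poly)
            inside = np.array([geom.contains(Point(x, y)) for x, y in coords])
            if not inside.any():
                warnings.warn(f"polygon {name!r} contains no embedded points")
            ids[inside] = idx
            names.append(name)
        prov["polygon_names"] = names
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    return ids, prov


def name_states(
    cluster_ids: np.ndarray, features: pd.DataFrame
) -> dict[int, str]:
    """Map cluster indices to canonical state names by behavior composition.

    Each cluster is summarized by its (groom, walk, probe, fly, none)
    mean proportions and matched to a prototype composition of the four
    states by nearest Euclidean distance: flight-rich clusters map to
    global search, probe-rich mobile (walking) clusters to local search,
    probe-rich immobile clusters to engorge, inactive/grooming clusters
    to rest.  With more than four clusters several may share a name (the
    engorge-merge case).
    """
    prototypes = {
        "rest": np.array([0.20, 0.05, 0.02, 0.01, 0.75]),
        "global_search": np.array([0.02, 0.30, 0.10, 0.35, 0.25]),
        "local_search": np.array([0.02, 0.30, 0.45, 0.03, 0.25]),
        "engorge": np.array([0.02, 0.02, 0.55, 0.00, 0.40]),
    }
    cols = ["prop_groom", "prop_walk", "prop_probe", "prop_fly", "prop_none"]
    uniq = [c for c in np.unique(cluster_ids) if c >= 0]
    mapping: dict[int, str] = {}
    for c in uniq:
        vec = features.loc[cluster_ids == c, cols].mean().to_numpy()
        dists = {name: float(np.linalg.norm(vec - p)) for name, p in prototypes.items()}
        mapping[int(c)] = min(dists, key=dists.get)
    return mapping


def infer_states(
    features: pd.DataFrame,
    perplexity: float | None = None,
    seed: int = 0,
    method: str = "density_peaks",
    n_clusters: int | None = None,
    density_percentile: float = 5.0,
    polygons: list | None = None,
    window: WindowSpec = WindowSpec(),
) -> StateMap:
    """Full pipeline: embed a feature table, cluster, and name the states."""
    coords = embed_features(features, perplexity=perplexity, seed=seed)
    ids, prov = cluster_states(
        coords,
        method=method,
        n_clusters=n_clusters,
        density_percentile=density_percentile,
        polygons=polygons,
        seed=seed,
    )
    if method == "manual_polygons":
        names = {i: n for i, (n, _) in enumerate(polygons)}
    else:
        names = name_states(ids, features)
    labels = np.array([names.get(int(c), UNASSIGNED) if c >= 0 else UNASSIGNED for c in ids])
    prov["state_names"] = {int(k): v for k, v in names.items()}
    return StateMap(
        animal_ids=features["animal_id"].to_numpy(),
        start_s=features["start_s"].to_numpy(dtype=float),
        coords=coords,
        cluster_ids=ids,
        labels=labels,
        window=window,
        provenance=prov,
    )


# ---------------------------------------------------------------------------
# occupancy and state ethograms


def state_occupancy(
    state_map: StateMap, animal_id: str, period: tuple[float, float]
) -> pd.Series:
    """Per-state fraction of an animal's windows overlapping [t0, t1).

    Includes ``unassigned``; the fractions sum to 1.
    """
    t0, t1 = period
    sel = state_map.animal_ids == animal_id
    starts = state_map.start_s[sel]
    ends = starts + state_map.window.length_s
    overlap = (starts < t1) & (ends > t0)
    if not overlap.any():
        raise ValueError(
            f"no windows of animal {animal_id!r} overlap [{t0}, {t1})"
        )
    labels = state_map.labels[sel][overlap]
    order = list(STATE_NAMES) + [UNASSIGNED]
    counts = pd.Series(
        {name: float(np.count_nonzero(labels == name)) for name in order}
    )
    return counts / counts.sum()


def state_ethograms(state_map: StateMap, cohort: CohortDataset) -> StateEthogram:
    """Per-state behavior composition, inter-state transition rates, travel.

    Composition is the mean raw-flag proportion of each behavior (plus
    no-behavior) over the frames of all windows labeled with the state.
    Transition rates come from consecutive-window label changes per
    animal, normalized per second of time in the source state.  Distance
    is the mean within-window path length of the centroid (pixels).
    States with no windows are omitted with a warning.
    """
    eth_by_id = {e.animal_id: e for e in cohort.ethograms}
    fps = cohort.fps
    length_f = int(round(state_map.window.length_s * fps))
    present = [s for s in STATE_NAMES if (state_map.labels == s).any()]
    for s in STATE_NAMES:
        if s not in present:
            warnings.warn(f"state {s!r} has no windows; omitted")

    comp_rows, dist = {}, {}
    for s in present:
        sel = state_map.labels == s
        sums = np.zeros(len(BEHAVIORS) + 1)
        n_frames_total = 0
        path = []
        for aid, start in zip(state_map.animal_ids[sel], state_map.start_s[sel]):
            e = eth_by_id[aid]
            f0 = int(round((start + cohort.time_origin_s) * fps))
            f1 = min(f0 + length_f, e.n_frames)
            fl = e.flags[f0:f1]
            sums[: len(BEHAVIORS)] += fl.sum(axis=0)
            sums[-1] += np.count_nonzero(~fl.any(axis=1))
            n_frames_total += f1 - f0
            if e.track is not None:
                seg = e.track[f0:f1]
                steps = np.hypot(*np.diff(seg, axis=0).T)
                path.append(float(np.nansum(steps)))
        comp_rows[s] = sums / max(n_frames_total, 1)
        dist[s] = float(np.mean(path)) if path else np.nan

    composition = pd.DataFrame(
        comp_rows, index=list(BEHAVIORS) + ["none"]
    ).T

    # transition rates from consecutive windows per animal
    step_s = state_map.window.step_s
    counts = pd.DataFrame(0.0, index=present, columns=present)
    time_in = {s: 0.0 for s in present}
    df = state_map.to_frame().sort_values(["animal_id", "start_s"])
    for _, grp in df.groupby("animal_id", sort=False):
        lab = grp["state"].to_numpy()
        for s in present:
            time_in[s] += np.count_nonzero(lab == s) * step_s
        for a, b in zip(lab[:-1], lab[1:]):
            if a != b and a in present and b in present:
                counts.loc[a, b] += 1
    rates = counts.copy()
    for s in present:
        rates.loc[s] = counts.loc[s] / time_in[s] if time_in[s] > 0 else 0.0
    return StateEthogram(
        composition=composition,
        transition_rates=rates,
        distance=pd.Series(dist),
    )


def window_size_robustness(
    cohort: CohortDataset,
    lengths_s: tuple[float, ...] = (10.0, 20.0, 30.0, 45.0, 60.0),
    step_s: float = 10.0,
    seed: int = 0,
    method: str = "density_peaks",
    reference_length_s: float = 30.0,
) -> pd.DataFrame:
    """Re-run the state-inference pipeline at several window lengths.

    For each window length the feature table is recomputed, embedded,
    clustered and named; windows are then matched to the reference
    length's windows by animal and window midpoint, and the adjusted
    Rand index between the two labelings is reported.  Stable behavioral
    states should yield high agreement across a several-fold range of
    window lengths.

    Returns a DataFrame with columns ``length_s``, ``n_windows``,
    ``n_states``, ``ari_vs_reference``.
    """
    from sklearn.metrics import adjusted_rand_score

    from .features import features_table

    def run(length: float):
        table = features_table(cohort, WindowSpec(length, step_s))
        smap = infer_states(
            table, seed=seed, method=method, window=WindowSpec(length, step_s)
        )
        mids = smap.start_s + length / 2.0
        keys = {
            (a, round(m / step_s)): lab
            for a, m, lab in zip(smap.animal_ids, mids, smap.labels)
        }
        return smap, keys

    ref_map, ref_keys = run(reference_length_s)
    rows = []
    for length in lengths_s:
        if length == reference_length_s:
            smap, keys = ref_map, ref_keys
        else:
            smap, keys = run(length)
        shared = sorted(set(keys) & set(ref_keys))
        ari = adjusted_rand_score(
            [ref_keys[k] for k in shared], [keys[k] for k in shared]
        ) if shared else np.nan
        rows.append(
            {
                "length_s": length,
                "n_windows": len(smap.labels),
                "n_states": len(set(smap.labels) - {UNASSIGNED}),
                "ari_vs_reference": float(ari),
            }
        )
    return pd.DataFrame(rows)
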
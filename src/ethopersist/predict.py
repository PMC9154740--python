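"""Predicting engorgement from pre-stimulus behavior.

A class-weight-balanced, L2-penalized logistic regression predicts the
binary engorgement outcome from the proportions of time an animal spent
grooming, walking, probing, and flying during a stated 2 min window
(typically the 2 min after the fictive-CO2 light pulse, i.e. the
pre-heat period).  Significance is assessed by resampling:

* **bootstrap** — resample animals with replacement, refit, score; the
  spread of the resampled performances describes the stability of the
  model (single-class resamples are redrawn);
* **shuffle null** — permute the outcome column, refit, score; the
  observed performance is compared to this null with a z-test
  (z = (obs - mean(null)) / sd(null), one-sided normal p) and with the
  empirical permutation percentile.

The performance statistic is balanced accuracy at threshold 0.5
(accuracy and AUROC are reported alongside); leave-one-out
cross-validation measures overfitting.  Observed and resampled models
are scored the same way (in-sample on their training rows), which makes
the shuffle comparison a valid permutation test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import balanced_accuracy_score, roc_auc_score

from .core import BEHAVIORS, CohortDataset

PREDICTORS: tuple[str, ...] = BEHAVIORS  # groom, walk, probe, fly proportions


def build_predictor_table(
    cohort: CohortDataset,
    window: tuple[float, float] = (0.0, 120.0),
    channel: str = "light",
    which_pulse: int = 0,
) -> pd.DataFrame:
    """Per-animal behavior proportions over a window relative to a pulse onset.

    ``window`` is (t0, t1) in seconds relative to the onset of the given
    pulse.  Returns a DataFrame with columns ``animal_id``, the four
    raw-flag time proportions, and ``engorged``; animals with a missing
    outcome are dropped with a warning.
    """
    onset = cohort.stimuli.pulse(channel, which_pulse).onset_s
    fps = cohort.fps
    f0 = int(round((onset + window[0]) * fps))
    f1 = int(round((onset + window[1]) * fps))
    n = cohort.ethograms[0].n_frames if cohort.ethograms else 0
    if not (0 <= f0 < f1 <= n):
        raise ValueError(
            f"window [{window[0]}, {window[1]}) s relative to {channel!r} onset "
            f"maps to frames [{f0}, {f1}) outside the record of {n} frames"
        )
    rows = []
    for e, (_, m) in zip(cohort.ethograms, cohort.meta.iterrows()):
        if pd.isna(m["engorged"]):
            warnings.warn(f"animal {e.animal_id!r} has no engorgement outcome; dropped")
            continue
        props = e.flags[f0:f1].mean(axis=0)
        rows.append((e.animal_id, *props, int(m["engorged"])))
    return pd.DataFrame(rows, columns=["animal_id", *PREDICTORS, "engorged"])


def _fit(X: np.ndarray, y: np.ndarray, seed: int = 0) -> LogisticRegression:
    return LogisticRegression(
        C=1.0,  # L2 penalty at the common default strength
        solver="liblinear",
        class_weight="balanced",
        random_state=seed,
    ).fit(X, y)


def _score(model: LogisticRegression, X: np.ndarray, y: np.ndarray) -> float:
    return float(balanced_accuracy_score(y, model.predict(X)))


def _xy(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    X = table[list(PREDICTORS)].to_numpy(dtype=float)
    y = table["engorged"].to_numpy(dtype=int)
    return X, y


def fit_and_score(table: pd.DataFrame, seed: int = 0) -> tuple[np.ndarray, float]:
    """Fit the logistic model; return (coefficients incl. intercept, LOO balanced accuracy).

    Leave-one-out cross-validation refits the model n times, predicting
    each held-out animal at threshold 0.5.
    """
    X, y = _xy(table)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    model = _fit(X, y, seed)
    coefs = np.concatenate([model.intercept_, model.coef_.ravel()])
    n = len(y)
    preds = np.empty(n, dtype=int)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        m = _fit(X[mask], y[mask], seed)
        preds[i] = int(m.predict(X[i : i + 1])[0])
        mask[i] = True
    loo = float(balanced_accuracy_score(y, preds))
    return coefs, loo


def observed_performance(table: pd.DataFrame, seed: int = 0) -> dict[str, float]:
    """Full-data model performance: balanced accuracy, accuracy, AUROC."""
    X, y = _xy(table)
    model = _fit(X, y, seed)
    pred = model.predict(X)
    return {
        "balanced_accuracy": float(balanced_accuracy_score(y, pred)),
        "accuracy": float((pred == y).mean()),
        "auroc": float(roc_auc_score(y, model.decision_function(X))),
    }


def bootstrap_performance(
    table: pd.DataFrame, B: int = 10_000, seed: int = 0
) -> np.ndarray:
    """Balanced accuracy of B bootstrap-refit models (rows resampled with replacement).

    Resamples containing a single outcome class are redrawn.
    """
    X, y = _xy(table)
    n = len(y)
    rng = np.random.default_rng(seed)
    out = np.empty(B)
    for b in range(B):
        while True:
            idx = rng.integers(0, n, size=n)
            if len(np.unique(y[idx])) == 2:
                break
        m = _fit(X[idx], y[idx], seed)
        out[b] = _score(m, X[idx], y[idx])
    return out


def shuffle_null(table: pd.DataFrame, S: int = 10_000, seed: int = 0) -> np.ndarray:
    """Balanced accuracy of S models refit on permuted outcome labels."""
    X, y = _xy(table)
    rng = np.random.default_rng(seed)
    out = np.empty(S)
    for s in range(S):
        yp = rng.permutation(y)
        m = _fit(X, yp, seed)
        out[s] = _score(m, X, yp)
    return out


def significance(
    observed: float,
    null_distribution: np.ndarray,
    bootstrap_distribution: np.ndarray | None = None,
) -> dict[str, float]:
    """z-test of the observed performance against the shuffle null.

    Returns z = (observed - mean(null)) / sd(null), the one-sided normal
    upper-tail p, and the empirical permutation p-value
    (1 + #{null >= observed}) / (1 + S).  If a bootstrap distribution is
    supplied, an alternative distribution-vs-distribution statistic is
    added: z_distribution = (mean(boot) - mean(null)) /
    sqrt(var(boot) + var(null)), with its one-sided normal p.
    """
    null = np.asarray(null_distribution, dtype=float)
    if np.unique(null).size < 2:
        raise ValueError("null distribution has no variance")
    mu, sd = float(null.mean()), float(null.std(ddof=1))
    z = (observed - mu) / sd
    p_normal = float(stats.norm.sf(z))
    p_emp = float((1 + np.count_nonzero(null >= observed)) / (1 + null.size))
    out = {"z": float(z), "p": p_normal, "p_empirical": p_emp}
    if bootstrap_distribution is not None:
        boot = np.asarray(bootstrap_distribution, dtype=float)
        zd = (boot.mean() - mu) / np.sqrt(boot.var(ddof=1) + sd**2)
        out["z_distribution"] = float(zd)
        out["p_distribution"] = float(stats.norm.sf(zd))
    return out


# ---------------------------------------------------------------------------
# model-object surface


@dataclass
class FeedingClassifierResults:
    """Fitted feeding-prediction results with resampling diagnostics."""

    table: pd.DataFrame
    coefficients: np.ndarray
    observed: dict[str, float]
    loo_balanced_accuracy: float
    seed: int = 0
    bootstrap: np.ndarray | None = None
    null: np.ndarray | None = None
    test: dict[str, float] | None = None

    def run_bootstrap(self, B: int = 10_000) -> np.ndarray:
        self.bootstrap = bootstrap_performance(self.table, B=B, seed=self.seed)
        return self.bootstrap

    def run_shuffle_null(self, S: int = 10_000) -> np.ndarray:
        self.null = shuffle_null(self.table, S=S, seed=self.seed + 1)
        self.test = significance(self.observed["balanced_accuracy"], self.null)
        return self.null

    def summary(self) -> str:
        names = ["intercept", *PREDICTORS]
        lines = [
            "Feeding outcome ~ pre-stimulus behavior proportions",
            f"n = {len(self.table)} animals "
            f"({int(self.table['engorged'].sum())} engorged)",
            "",
            "coefficients (log-odds):",
        ]
        for name, c in zip(names, self.coefficients):
            lines.append(f"  {name:>10s}  {c:+.4f}")
        lines += [
            "",
            f"balanced accuracy (in-sample): {self.observed['balanced_accuracy']:.3f}",
            f"balanced accuracy (LOO CV):    {self.loo_balanced_accuracy:.3f}",
            f"accuracy: {self.observed['accuracy']:.3f}   "
            f"AUROC: {self.observed['auroc']:.3f}",
        ]
        if self.test is not None:
            lines.append(
                f"shuffle null (S={len(self.null)}): z = {self.test['z']:.2f}, "
                f"p = {self.test['p']:.2e} (empirical p = {self.test['p_empirical']:.4f})"
            )
        return "\n".join(lines)


@dataclass
class FeedingClassifier:
    """Model object over a predictor table; ``fit()`` returns results."""

    table: pd.DataFrame
    seed: int = 0

    @classmethod
    def from_cohort(
        cls,
        cohort: CohortDataset,
        window: tuple[float, float] = (0.0, 120.0),
        channel: str = "light",
        which_pulse: int = 0,
        seed: int = 0,
    ) -> "FeedingClassifier":
        return cls(build_predictor_table(cohort, window, channel, which_pulse), seed=seed)

    def fit(self) -> FeedingClassifierResults:
        coefs, loo = fit_and_score(self.table, seed=self.seed)
        obs = observed_performance(self.table, seed=self.seed)
        return FeedingClassifierResults(
            table=self.table,
            coefficients=coefs,
            observed=obs,
            loo_balanced_accuracy=loo,
            seed=self.seed,
        )
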
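"""Movement-strategy phenotyping by weighted k-means.

Each participant is summarised by two late-trial features computed from
the last five trials of every biased block: the mean absolute lateral
offset before the guard appeared (how far they deviated from a straight
path, regardless of direction) and the mean offset toward the likely
open side (how well the deviation matched the regularity).  k-means with
k = 4 on (|offset|, weight x correct-offset) separates four strategies:

* **Waiter** — near-midline, commits only after seeing the guard;
* **Moderate Learner** — small but aligned anticipatory shifts;
* **Super Learner** — large, accurate anticipatory shifts;
* **Random Walker** — large lateral movement unaligned with the bias.

The correct-direction feature is weighted (default 2.0) because it
carries the strategic signal; features are raw meters, unstandardized,
matching the weighting's intent (a standardization flag exists).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

LABELS = ("Waiter", "Moderate Learner", "Super Learner", "Random Walker")


def compute_features(trial_table: pd.DataFrame, last_n: int = 5,
                     per_block_mean: bool = False) -> pd.DataFrame:
    """Per-participant late-trial movement features.

    Uses trials with ``trial_in_block`` in the last ``last_n`` of each
    biased block (block length taken from the data).  ``mean_abs_offset``
    averages |last pre-guard x| and ``mean_correct_offset`` averages the
    normalized (sign-corrected) last x.  By default trials are pooled
    across blocks; ``per_block_mean`` averages per block first.
    Participants without any eligible trial are excluded and logged.
    """
    req = {"participant_id", "block_index", "trial_in_block", "condition",
           "last_x", "normalized_x"}
    missing = req - set(trial_table.columns)
    if missing:
        raise ValueError(f"trial table lacks columns {sorted(missing)}")
    d = trial_table[trial_table["condition"] != "control"].copy()
    block_len = d.groupby(["participant_id", "block_index"])["trial_in_block"] \
        .transform("max")
    d = d[d["trial_in_block"] > block_len - last_n]
    d = d.dropna(subset=["last_x", "normalized_x"])
    if d.empty:
        raise ValueError("no eligible biased-block trials")
    d["abs_x"] = d["last_x"].abs()
    if per_block_mean:
        per_block = d.groupby(["participant_id", "block_index"])[
            ["abs_x", "normalized_x"]].mean().reset_index()
        agg = per_block.groupby("participant_id")[["abs_x", "normalized_x"]].mean()
        counts = d.groupby("participant_id").size()
    else:
        agg = d.groupby("participant_id")[["abs_x", "normalized_x"]].mean()
        counts = d.groupby("participant_id").size()
    out = agg.rename(columns={"abs_x": "mean_abs_offset",
                              "normalized_x": "mean_correct_offset"})
    out["n_trials_used"] = counts
    dropped = set(trial_table["participant_id"].unique()) - set(out.index)
    for p in sorted(dropped):
        logger.warning("participant %s excluded from clustering: no eligible trials", p)
    return out.reset_index()


@dataclass
class ClusterResult:
    assignments: pd.DataFrame       # participant_id, features, cluster, label
    centroids: np.ndarray           # (k, 2) in unweighted feature space
    weight: float
    k: int
    inertia: float


def _label_centroids(centroids: np.ndarray) -> dict[int, str]:
    """Assign strategy names to centroids by their feature semantics.

    Waiter = centroid closest to the origin (low offset, low alignment);
    Super Learner = highest combined offset + alignment among the rest;
    of the remaining two, Random Walker has the lower (or negative)
    correct-direction coordinate and Moderate Learner the higher.
    Permutation-invariant in the cluster indices.
    """
    k = centroids.shape[0]
    idx = list(range(k))
    labels = {}
    waiter = min(idx, key=lambda i: np.hypot(*centroids[i]))
    labels[waiter] = "Waiter"
    rest = [i for i in idx if i != waiter]
    superl = max(rest, key=lambda i: centroids[i, 0] + centroids[i, 1])
    labels[superl] = "Super Learner"
    rest = [i for i in rest if i != superl]
    if len(rest) == 2:
        walker = min(rest, key=lambda i: centroids[i, 1])
        labels[walker] = "Random Walker"
        labels[[i for i in rest if i != walker][0]] = "Moderate Learner"
    elif rest:  # k != 4 fallback: rank remaining by alignment
        order = sorted(rest, key=lambda i: centroids[i, 1])
        labels[order[0]] = "Random Walker"
        for i in order[1:]:
            labels[i] = "Moderate Learner"
    return labels


def cluster_participants(features: pd.DataFrame, weight: float = 2.0, k: int = 4,
                         seed: int = 0, n_restarts: int = 25,
                         standardize: bool = False) -> ClusterResult:
    """Weighted k-means partition of participants into strategy groups.

    Clusters on (mean_abs_offset, weight x mean_correct_offset) with
    ``n_restarts`` seeded restarts (best squared-Euclidean objective
    kept), then names each cluster from its centroid semantics.
    """
    if len(features) < k:
        raise ValueError(f"need at least k={k} participants, got {len(features)}")
    X = features[["mean_abs_offset", "mean_correct_offset"]].to_numpy(dtype=float)
    if np.allclose(X, X[0]):
        raise ValueError("all participants identical: degenerate clustering")
    scale = np.ones(2)
    if standardize:
        scale = X.std(axis=0, ddof=0)
        scale[scale == 0] = 1.0
    Xw = (X / scale) * np.array([1.0, weight])
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    cluster = km.fit_predict(Xw)
    centroids = km.cluster_centers_ / np.array([1.0, weight]) * scale
    names = _label_centroids(centroids)
    out = features.copy()
    out["cluster"] = cluster
    out["label"] = [names[c] for c in cluster]
    return ClusterResult(assignments=out, centroids=centroids, weight=weight,
                         k=k, inertia=float(km.inertia_))
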
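"""Fuzzy c-means clustering of parcel lifespan trajectories.

Soft clustering with a deliberately high fuzzifier (default 5) so parcels
can share membership between trajectory families; the cluster count is
selected by the mean silhouette of winner-take-all labels over candidate
counts 2-15, and cluster-to-network correspondence is summarized by the
normalized sum of dot products between RSN probability maps and cluster
memberships.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score

DEFAULT_FUZZIFIER = 5.0
DEFAULT_MAX_ITER = 10000
DEFAULT_TOL = 1e-5
DEFAULT_CANDIDATES = tuple(range(2, 16))


@dataclass
class Membership:
    u: np.ndarray                 # parcels x clusters, rows sum to 1
    labels: np.ndarray            # winner-take-all cluster index (0-based)
    tie_flags: np.ndarray
    objective_trace: np.ndarray   # objective per iteration, non-increasing
    centers: np.ndarray
    n_iter: int


@dataclass
class ClusterSelection:
    candidate_n: tuple
    silhouette: np.ndarray
    chosen_n: int
    memberships: dict = field(default_factory=dict)


def fuzzy_cmeans(
    X: np.ndarray,
    n_clusters: int,
    fuzzifier: float = DEFAULT_FUZZIFIER,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    seed: int = 0,
) -> Membership:
    """Standard fuzzy c-means with Euclidean distance.

    Alternates center updates (membership^fuzzifier-weighted means) and
    membership updates (inverse-distance ratios with exponent
    2/(fuzzifier-1)) from a random row-stochastic initial membership;
    stops when the objective improves by less than ``tol`` or after
    ``max_iter`` iterations.  A point at zero distance from one or more
    centers splits its membership evenly over those centers (so a unique
    coincident center receives membership 1).

    Clusters are canonically reordered by descending winner-take-all size
    on output, so cluster 0 is the majority family.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (parcels x grid)")
    n, _ = X.shape
    if n_clusters < 2:
        raise ValueError(f"n_clusters must be >= 2, got {n_clusters}")
    if n < n_clusters:
        raise ValueError(f"need at least {n_clusters} rows, got {n}")
    if fuzzifier <= 1:
        raise ValueError("fuzzifier must be > 1")

    rng = np.random.default_rng(seed)
    u = rng.random((n, n_clusters))
    u /= u.sum(axis=1, keepdims=True)

    expo = 2.0 / (fuzzifier - 1.0)
    trace: list[float] = []
    prev = np.inf
    for it in range(max_iter):
        w = u**fuzzifier
        centers = (w.T @ X) / w.sum(axis=0)[:, None]
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        obj = float((w * d2).sum())
        trace.append(obj)
        d2s = np.maximum(d2, 0.0)
        zero = d2s <= 0.0
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = d2s ** (-expo / 2.0)
            u_new = inv / inv.sum(axis=1, keepdims=True)
        # coincident point/center: split mass evenly over zero-distance centers
        rows = np.flatnonzero(zero.any(axis=1))
        for r in rows:
            u_new[r] = zero[r] / zero[r].sum()
        u = u_new
        if prev - obj < tol:
            break
        prev = obj

    labels, ties = winner_take_all(u)
    # canonical order: descending cluster size, stable
    counts = np.bincount(labels, minlength=n_clusters)
    order = np.argsort(-counts, kind="stable")
    u = u[:, order]
    centers = centers[order]
    labels, ties = winner_take_all(u)
    return Membership(
        u=u,
        labels=labels,
        tie_flags=ties,
        objective_trace=np.asarray(trace),
        centers=centers,
        n_iter=len(trace),
    )


def winner_take_all(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hard labels from memberships: row argmax, ties to the lowest index."""
    u = np.asarray(u, dtype=float)
    labels = u.argmax(axis=1)
    row_max = u.max(axis=1)
    ties = (u == row_max[:, None]).sum(axis=1) > 1
    return labels, ties


def silhouette_select(
    X: np.ndarray,
    candidates: tuple = DEFAULT_CANDIDATES,
    seed: int = 0,
    **fcm_kwargs,
) -> ClusterSelection:
    """Choose the cluster count maximizing mean silhouette of hard labels.

    Candidates yielding a single non-empty cluster get score -1 (silhouette
    undefined there).
    """
    X = np.asarray(X, dtype=float)
    if all(n_c > X.shape[0] for n_c in candidates):
        raise ValueError("no candidate cluster count is feasible for this few rows")
    scores = np.empty(len(candidates))
    memberships = {}
    for i, n_c in enumerate(candidates):
        if n_c > X.shape[0]:
            scores[i] = -1.0  # infeasible: more clusters than trajectories
            continue
        m = fuzzy_cmeans(X, n_c, seed=seed, **fcm_kwargs)
        memberships[n_c] = m
        n_labels = len(np.unique(m.labels))
        if n_labels < 2 or n_labels >= X.shape[0]:
            scores[i] = -1.0  # silhouette undefined
        else:
            scores[i] = float(silhouette_score(X, m.labels, metric="euclidean"))
    chosen = candidates[int(np.argmax(scores))]
    return ClusterSelection(
        candidate_n=tuple(candidates),
        silhouette=scores,
        chosen_n=int(chosen),
        memberships=memberships,
    )


def rsn_correspondence_index(
    membership: Membership | np.ndarray, rsn_probs: pd.DataFrame
) -> pd.DataFrame:
    """Normalized sum of dot products between RSN maps and memberships.

    raw(r, c) = sum_p rsn_prob_r(p) * u_c(p), normalized within each
    cluster so indices sum to 1 across RSNs (comparable between clusters
    of different sizes).  ``rsn_probs`` rows must align with membership
    rows; columns are RSN names (``rsn_`` prefixes are stripped).
    """
    u = membership.u if isinstance(membership, Membership) else np.asarray(membership)
    probs = rsn_probs.to_numpy(dtype=float)
    if probs.shape[0] != u.shape[0]:
        raise ValueError("rsn_probs rows must match membership rows")
    if not probs.any():
        raise ValueError("all-zero RSN probabilities")
    raw = probs.T @ u  # RSNs x clusters
    totals = raw.sum(axis=0, keepdims=True)
    if np.any(totals <= 0):
        raise ValueError("cluster with zero total membership mass")
    names = [c.removeprefix("rsn_") for c in rsn_probs.columns]
    return pd.DataFrame(
        raw / totals,
        index=pd.Index(names, name="rsn"),
        columns=[f"cluster{c + 1}" for c in range(u.shape[1])],
    )
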
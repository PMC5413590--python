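"""Fuzzy c-means clustering.

Alternates the membership and centroid updates of the fuzzified
within-cluster sum-of-squares objective until the membership matrix
stabilizes. Centroids are initialized from distinct data points drawn
without replacement under a caller-supplied seed, so runs are repeatable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FuzzyPartition", "fcm_fit"]


@dataclass(frozen=True)
class FuzzyPartition:
    """Converged fuzzy partition.

    ``memberships`` is ``c x p`` with columns summing to one; ``centroids``
    is ``c x d``. ``objective_trace`` records the objective after every
    full update and is non-increasing.
    """

    memberships: np.ndarray
    centroids: np.ndarray
    objective_trace: np.ndarray
    fuzzifier: float
    n_clusters: int

    @property
    def objective(self) -> float:
        return float(self.objective_trace[-1])

    def hard_labels(self) -> np.ndarray:
        """Maximum-membership cluster index per point."""
        return np.argmax(self.memberships, axis=0)


def _sq_distances(points: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances, shape (c, p)."""
    diff = centroids[:, None, :] - points[None, :, :]
    return np.einsum("ijk,ijk->ij", diff, diff)


def _memberships(d2: np.ndarray, m: float) -> np.ndarray:
    """Membership update from squared distances; columns sum to 1.

    Where a point coincides with one or more centroids the update is
    undefined; membership 1 is split equally over the coincident centroids.
    """
    if d2.min() <= 0.0:
        c, p = d2.shape
        u = np.zeros((c, p))
        zero_cols = np.any(d2 <= 0.0, axis=0)
        hits = d2[:, zero_cols] <= 0.0
        u[:, zero_cols] = hits / hits.sum(axis=0)
        ok = ~zero_cols
        if np.any(ok):
            inv = d2[:, ok] ** (-1.0 / (m - 1.0))
            u[:, ok] = inv / inv.sum(axis=0)
        return u
    inv = 1.0 / d2 if m == 2.0 else d2 ** (-1.0 / (m - 1.0))
    return inv / inv.sum(axis=0)


def _objective(
    d2: np.ndarray, u: np.ndarray, m: float, w: np.ndarray | None
) -> float:
    um = u * u if m == 2.0 else u**m
    if w is not None:
        um = um * w
    return float(np.sum(um * d2))


def fcm_fit(
    points: np.ndarray,
    c: int,
    m: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 300,
    seed: int = 0,
    weights: np.ndarray | None = None,
) -> FuzzyPartition:
    """Cluster ``points`` (``p x d``) into ``c`` fuzzy clusters.

    Requires ``1 < c < p`` and fuzzifier ``m > 1``. Iteration stops when
    the maximum absolute membership change falls below ``tol`` or after
    ``max_iter`` full updates. Optional non-negative per-point ``weights``
    scale each point's contribution to the objective and centroid update
    (membership updates are per-point and unaffected).
    """
    x = np.asarray(points, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    p = x.shape[0]
    if not (1 < c < p):
        raise ValueError(f"need 1 < c < p, got c={c}, p={p}")
    if not (m > 1):
        raise ValueError(f"fuzzifier must exceed 1, got {m}")
    if not (tol > 0):
        raise ValueError(f"tol must be positive, got {tol}")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    w: np.ndarray | None = None
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if w.shape != (p,):
            raise ValueError("weights must be one value per point")
        if np.any(w < 0) or not np.any(w > 0):
            raise ValueError("weights must be non-negative with positive sum")

    rng = np.random.default_rng(seed)
    unique_rows = np.unique(x, axis=0)
    if unique_rows.shape[0] >= c:
        idx = rng.choice(unique_rows.shape[0], size=c, replace=False)
        centroids = unique_rows[idx].copy()
    else:  # not enough distinct points; permit coincident centroids
        idx = rng.choice(p, size=c, replace=False)
        centroids = x[idx].copy()

    u = _memberships(_sq_distances(x, centroids), m)
    trace = []
    for _ in range(max_iter):
        um = u * u if m == 2.0 else u**m
        if w is not None:
            um = um * w
        denom = um.sum(axis=1, keepdims=True)
        alive = denom[:, 0] > 0
        updated = (um[alive] @ x) / denom[alive]
        centroids = centroids.copy()
        centroids[alive] = updated  # dead clusters keep their centroid
        d2 = _sq_distances(x, centroids)
        u_new = _memberships(d2, m)
        trace.append(_objective(d2, u_new, m, w))
        delta = float(np.max(np.abs(u_new - u)))
        u = u_new
        if delta < tol:
            break

    return FuzzyPartition(
        memberships=u,
        centroids=centroids,
        objective_trace=np.asarray(trace),
        fuzzifier=float(m),
        n_clusters=int(c),
    )
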
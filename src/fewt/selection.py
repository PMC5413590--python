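"""Multivariate filter feature-selection criteria and greedy forward search.

Three subset criteria are provided: the Bhattacharyya/Chernoff distance
between two Gaussian class summaries, the between/within scatter trace
ratio, and the coefficient of determination of a linear fit of the class
label on the subset. ``forward_select`` adds features one by one, keeping
at each step the candidate that maximizes the criterion on the enlarged
subset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ClassStatistics",
    "SelectionResult",
    "class_statistics",
    "chernoff_distance",
    "bhattacharyya_distance",
    "scatter_ratio",
    "lr_criterion",
    "forward_select",
    "CRITERIA",
]

_SINGULAR_COND = 1e12


@dataclass(frozen=True)
class ClassStatistics:
    """Per-class Gaussian summaries of a feature subset."""

    classes: np.ndarray
    means: np.ndarray  # (c, d)
    covariances: np.ndarray  # (c, d, d), unbiased
    priors: np.ndarray  # (c,)
    global_mean: np.ndarray  # (d,)

    @property
    def n_classes(self) -> int:
        return self.classes.size


def class_statistics(features: np.ndarray, labels: np.ndarray) -> ClassStatistics:
    """Sample means, unbiased covariances, empirical priors and global mean."""
    x = np.atleast_2d(np.asarray(features, dtype=float))
    if x.shape[0] == 1 and np.asarray(labels).size != 1:
        x = x.T
    y = np.asarray(labels)
    if x.shape[0] != y.size:
        raise ValueError("features and labels disagree in sample count")
    classes, counts = np.unique(y, return_counts=True)
    if np.any(counts < 2):
        small = classes[counts < 2]
        raise ValueError(f"classes {small} have fewer than 2 samples")
    means = np.stack([x[y == cls].mean(axis=0) for cls in classes])
    covs = np.stack(
        [np.atleast_2d(np.cov(x[y == cls], rowvar=False)) for cls in classes]
    )
    priors = counts / counts.sum()
    return ClassStatistics(
        classes=classes,
        means=means,
        covariances=covs,
        priors=priors,
        global_mean=x.mean(axis=0),
    )


def _default_ridge(cov1: np.ndarray, cov2: np.ndarray) -> float:
    scale = np.mean(np.diagonal(cov1) + np.diagonal(cov2)) / 2.0
    return 1e-6 * max(scale, 1e-12)


def chernoff_distance(
    stats: ClassStatistics, beta: float, ridge: float | None = None
) -> float:
    """Chernoff separability of two Gaussian class summaries.

    The pooled covariance ``(1-beta) S1 + beta S2`` is inverted; when it is
    numerically singular a ridge is added to each class covariance first
    (the log-determinant term requires proper determinants, ruling out a
    pseudo-inverse).
    """
    if stats.n_classes != 2:
        raise ValueError(
            f"Chernoff distance needs exactly 2 classes, got {stats.n_classes}"
        )
    if not (0.0 < beta < 1.0):
        raise ValueError(f"beta must lie in (0, 1), got {beta}")
    cov1, cov2 = stats.covariances
    pooled = (1.0 - beta) * cov1 + beta * cov2
    if np.linalg.cond(pooled) > _SINGULAR_COND:
        eps = ridge if ridge is not None else _default_ridge(cov1, cov2)
        eye = np.eye(pooled.shape[0])
        logger.info("pooled covariance near-singular; adding ridge %.3g", eps)
        cov1 = cov1 + eps * eye
        cov2 = cov2 + eps * eye
        pooled = (1.0 - beta) * cov1 + beta * cov2
        if np.linalg.cond(pooled) > _SINGULAR_COND:
            raise ValueError("pooled covariance singular even after ridge")

    dmu = stats.means[1] - stats.means[0]
    quad = 0.5 * beta * (1.0 - beta) * float(dmu @ np.linalg.solve(pooled, dmu))
    sign_p, logdet_p = np.linalg.slogdet(pooled)
    sign_1, logdet_1 = np.linalg.slogdet(cov1)
    sign_2, logdet_2 = np.linalg.slogdet(cov2)
    if sign_p <= 0 or sign_1 <= 0 or sign_2 <= 0:
        raise ValueError("non-positive covariance determinant")
    logterm = 0.5 * (logdet_p - (1.0 - beta) * logdet_1 - beta * logdet_2)
    return quad + logterm


def bhattacharyya_distance(
    stats: ClassStatistics, ridge: float | None = None
) -> float:
    """Chernoff distance at ``beta = 1/2``."""
    return chernoff_distance(stats, beta=0.5, ridge=ridge)


def scatter_ratio(features: np.ndarray, labels: np.ndarray) -> float:
    """Trace ratio of between-class to within-class scatter.

    Scatter matrices use population (per-class) expectations of squared
    deviations, weighted by the empirical class priors.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("scatter ratio needs at least 2 classes")
    priors = counts / counts.sum()
    mu0 = x.mean(axis=0)
    trace_w = 0.0
    trace_b = 0.0
    for cls, prior in zip(classes, priors):
        grp = x[y == cls]
        mu = grp.mean(axis=0)
        trace_w += prior * float(np.mean(np.sum((grp - mu) ** 2, axis=1)))
        trace_b += prior * float(np.sum((mu - mu0) ** 2))
    if trace_w <= 0.0:
        raise ValueError("zero within-class scatter: every point equals its class mean")
    return trace_b / trace_w


def lr_criterion(features: np.ndarray, targets: np.ndarray) -> float:
    """Coefficient of determination of a least-squares fit with intercept."""
    x = np.asarray(features, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(targets, dtype=float)
    n, k = x.shape
    if y.size != n:
        raise ValueError("features and targets disagree in sample count")
    if n <= k + 1:
        raise ValueError(f"need more than {k + 1} samples to fit {k} features")
    ssto = float(np.sum((y - y.mean()) ** 2))
    if ssto <= 0.0:
        raise ValueError("constant target: total sum of squares is zero")
    design = np.column_stack([np.ones(n), x])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        logger.info("rank-deficient design; minimum-norm least squares used")
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    sse = float(np.sum((y - design @ coef) ** 2))
    return float(np.clip(1.0 - sse / ssto, 0.0, 1.0))


def _as_numeric_targets(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels)
    if np.issubdtype(y.dtype, np.number):
        return y.astype(float)
    classes = np.unique(y)
    codes = {cls: i for i, cls in enumerate(classes)}
    return np.array([codes[v] for v in y], dtype=float)


def _criterion_value(
    name: str,
    features: np.ndarray,
    labels: np.ndarray,
    ridge: float | None,
) -> float:
    if name == "bd":
        return bhattacharyya_distance(class_statistics(features, labels), ridge)
    if name == "sr":
        return scatter_ratio(features, labels)
    if name == "lr":
        return lr_criterion(features, _as_numeric_targets(labels))
    raise ValueError(f"unknown criterion {name!r}; expected 'bd', 'sr' or 'lr'")


CRITERIA = ("bd", "sr", "lr")


@dataclass(frozen=True)
class SelectionResult:
    """Ranked feature indices with the criterion value after each inclusion."""

    ranked_indices: list[int]
    criterion_trace: list[float]
    criterion_name: str
    k: int


def forward_select(
    features: np.ndarray,
    labels: np.ndarray,
    criterion_name: str = "lr",
    k: int = 25,
    ridge: float | None = None,
) -> SelectionResult:
    """Greedy forward inclusion of ``k`` features under one criterion.

    At every step the candidate maximizing the criterion on the enlarged
    subset is added (ties go to the lower column index). Candidates on
    which the criterion fails are skipped; if none remain, the partial
    ranking is returned with a logged reason.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim != 2:
        raise ValueError("features must be 2-D (samples x columns)")
    y = np.asarray(labels)
    n_cols = x.shape[1]
    if not (1 <= k <= n_cols):
        raise ValueError(f"k={k} outside 1..{n_cols}")
    if criterion_name not in CRITERIA:
        raise ValueError(f"unknown criterion {criterion_name!r}")

    selected: list[int] = []
    trace: list[float] = []
    remaining = list(range(n_cols))
    for _ in range(k):
        best_col = None
        best_val = -np.inf
        for col in remaining:
            subset = x[:, selected + [col]]
            try:
                val = _criterion_value(criterion_name, subset, y, ridge)
            except (ValueError, np.linalg.LinAlgError):
                continue
            if val > best_val:
                best_val = val
                best_col = col
        if best_col is None:
            logger.warning(
                "criterion %s failed on every remaining candidate after "
                "%d inclusions; returning partial ranking",
                criterion_name,
                len(selected),
            )
            break
        selected.append(best_col)
        trace.append(best_val)
        remaining.remove(best_col)

    return SelectionResult(
        ranked_indices=selected,
        criterion_trace=trace,
        criterion_name=criterion_name,
        k=len(selected),
    )
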
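"""Trial windowing, cross-validated classification, and method comparison.

Windows are cut contiguously from the start of each trial; every window is
encoded into one feature row. Classification accuracy is measured with a
stratified k-fold support-vector classifier whose RBF hyper-parameters are
grid-searched inside each training fold (no information leak from the test
fold). Method combinations are then compared by percentage gain over a
baseline family and by the Friedman rank test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import EncodeConfig, FeatureMatrix, encode_window
from .selection import SelectionResult

logger = logging.getLogger(__name__)

__all__ = [
    "Trial",
    "TrialSet",
    "Window",
    "segment_trials",
    "encode_trials",
    "CVResult",
    "crossval_classify",
    "RankingTable",
    "percentage_gain_rank",
    "FriedmanResult",
    "friedman_rank",
]

DEFAULT_C_GRID = tuple(10.0**e for e in range(-2, 4))
DEFAULT_GAMMA_GRID = tuple(10.0**e for e in range(-4, 2))


@dataclass(frozen=True)
class Trial:
    """One multi-channel recording with its task label and subject id."""

    samples: np.ndarray  # (n_samples, n_channels)
    label: str
    subject: str = "s1"

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 2:
            raise ValueError("trial samples must be 2-D (samples x channels)")
        object.__setattr__(self, "samples", samples)


@dataclass(frozen=True)
class TrialSet:
    """A homogeneous collection of trials (same rate and channel count)."""

    trials: tuple[Trial, ...]
    rate: float

    def __post_init__(self) -> None:
        if not self.trials:
            raise ValueError("empty trial set")
        channels = {t.samples.shape[1] for t in self.trials}
        if len(channels) != 1:
            raise ValueError(f"inconsistent channel counts across trials: {channels}")
        if not (self.rate > 0):
            raise ValueError("rate must be positive")
        object.__setattr__(self, "trials", tuple(self.trials))

    @property
    def n_channels(self) -> int:
        return self.trials[0].samples.shape[1]

    @property
    def labels(self) -> list[str]:
        return [t.label for t in self.trials]


@dataclass(frozen=True)
class Window:
    samples: np.ndarray
    label: str
    subject: str
    trial_index: int
    window_index: int


def segment_trials(ts: TrialSet, window_seconds: float) -> list[Window]:
    """Cut every trial into non-overlapping windows from its start.

    A trailing remainder shorter than one window is dropped (logged once
    per trial). A window longer than any trial is rejected.
    """
    if not (window_seconds > 0):
        raise ValueError("window_seconds must be positive")
    w = int(round(window_seconds * ts.rate))
    if w < 8:
        raise ValueError(f"window of {w} samples is below the minimum of 8")
    windows: list[Window] = []
    for t_idx, trial in enumerate(ts.trials):
        n = trial.samples.shape[0]
        if n < w:
            raise ValueError(
                f"trial {t_idx} has {n} samples, shorter than the "
                f"{w}-sample window"
            )
        n_windows = n // w
        dropped = n - n_windows * w
        if dropped:
            logger.debug("trial %d: dropping %d trailing samples", t_idx, dropped)
        for k in range(n_windows):
            windows.append(
                Window(
                    samples=trial.samples[k * w : (k + 1) * w],
                    label=trial.label,
                    subject=trial.subject,
                    trial_index=t_idx,
                    window_index=k,
                )
            )
    return windows


def encode_trials(
    ts: TrialSet,
    window_seconds: float = 0.5,
    config: EncodeConfig | None = None,
) -> FeatureMatrix:
    """Window every trial and encode each window into one feature row."""
    config = config or EncodeConfig()
    windows = segment_trials(ts, window_seconds)
    rows = []
    names: list[str] | None = None
    for win in windows:
        row, cols = encode_window(win.samples, ts.rate, config)
        if names is None:
            names = cols
        rows.append(row)
    return FeatureMatrix(
        values=np.vstack(rows),
        column_names=names or [],
        labels=np.array([w.label for w in windows]),
        subjects=np.array([w.subject for w in windows]),
    )


@dataclass(frozen=True)
class CVResult:
    """Accuracy (in %) over the incremental feature-count curve."""

    ks: list[int]
    accuracies: list[float]

    @property
    def best_accuracy(self) -> float:
        return max(self.accuracies)

    @property
    def best_k(self) -> int:
        return self.ks[int(np.argmax(self.accuracies))]


def _cv_accuracy(
    x: np.ndarray,
    y: np.ndarray,
    folds: int,
    seed: int,
    c_grid: tuple[float, ...],
    gamma_grid: tuple[float, ...],
    inner_folds: int,
) -> float:
    outer = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = []
    for train, test in outer.split(x, y):
        search = GridSearchCV(
            Pipeline([("scale", StandardScaler()), ("svc", SVC(kernel="rbf"))]),
            param_grid={"svc__C": list(c_grid), "svc__gamma": list(gamma_grid)},
            cv=StratifiedKFold(inner_folds, shuffle=True, random_state=seed),
            n_jobs=None,
        )
        search.fit(x[train], y[train])
        scores.append(search.score(x[test], y[test]))
    return 100.0 * float(np.mean(scores))


def crossval_classify(
    features: FeatureMatrix,
    ranked: SelectionResult | None = None,
    folds: int = 10,
    seed: int = 0,
    c_grid: tuple[float, ...] = DEFAULT_C_GRID,
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID,
    inner_folds: int = 3,
    ks: list[int] | None = None,
) -> CVResult:
    """Accuracy of an RBF support-vector classifier over a feature ranking.

    With a ranking, the top-``k`` subsets for ``k = 1 .. |ranking|`` (or the
    provided ``ks``) are each scored by stratified ``folds``-fold
    cross-validation with in-fold grid search; without one, the full
    feature set is scored once (the no-selection condition).
    """
    x = features.values
    y = features.labels
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError(
            f"stratified {folds}-fold impossible with class counts "
            f"{counts.tolist()}"
        )
    if ranked is None:
        acc = _cv_accuracy(x, y, folds, seed, c_grid, gamma_grid, inner_folds)
        return CVResult(ks=[x.shape[1]], accuracies=[acc])

    k_values = ks if ks is not None else list(range(1, len(ranked.ranked_indices) + 1))
    accuracies = []
    for k in k_values:
        cols = ranked.ranked_indices[:k]
        acc = _cv_accuracy(
            x[:, cols], y, folds, seed, c_grid, gamma_grid, inner_folds
        )
        accuracies.append(acc)
    return CVResult(ks=list(k_values), accuracies=accuracies)


@dataclass(frozen=True)
class RankingTable:
    """Percentage gains over the baseline family, with ranks."""

    table: pd.DataFrame  # columns: combination, gain, rank

    def gain(self, combination: str) -> float:
        row = self.table.loc[self.table["combination"] == combination]
        return float(row["gain"].iloc[0])


def _family_of(combination: str) -> str:
    return combination.rsplit("_", 1)[-1]


def percentage_gain_rank(
    acc: pd.DataFrame,
    baseline_family: str = "EWT",
    test_family: str = "FEWT",
) -> RankingTable:
    """Rank test-family combinations by mean percentage gain in accuracy.

    ``acc`` must carry columns ``task_pair``, ``combination`` and
    ``accuracy`` (a ``subject`` column, if present, is averaged out).
    Combination ids end in their family name, e.g. ``LR_FEWT``. For each
    task pair the baseline is the maximum accuracy over all
    baseline-family combinations; gains are averaged over task pairs and
    ranked so that a larger gain never receives a larger rank (equal gains
    share a rank).
    """
    required = {"task_pair", "combination", "accuracy"}
    if not required.issubset(acc.columns):
        raise ValueError(f"accuracy table needs columns {sorted(required)}")
    mean_acc = (
        acc.groupby(["task_pair", "combination"], as_index=False)["accuracy"].mean()
    )
    pivot = mean_acc.pivot(index="task_pair", columns="combination", values="accuracy")
    if pivot.isna().any().any():
        raise ValueError("every (task_pair, combination) cell must be present")
    base_cols = [c for c in pivot.columns if _family_of(c) == baseline_family]
    test_cols = [c for c in pivot.columns if _family_of(c) == test_family]
    if not base_cols or not test_cols:
        raise ValueError(
            f"missing combinations for family {baseline_family!r} or {test_family!r}"
        )
    base_max = pivot[base_cols].max(axis=1)
    if (base_max <= 0).any():
        raise ValueError("baseline maximum accuracy of 0 makes the gain undefined")
    gains = {
        comb: float(((pivot[comb] - base_max) / base_max * 100.0).mean())
        for comb in test_cols
    }
    table = pd.DataFrame(
        {"combination": list(gains.keys()), "gain": list(gains.values())}
    )
    table["rank"] = sps.rankdata(-table["gain"].to_numpy(), method="min")
    table = table.sort_values("rank", kind="stable").reset_index(drop=True)
    return RankingTable(table)


@dataclass(frozen=True)
class FriedmanResult:
    """Friedman test over blocks (rows) and method combinations (columns)."""

    combinations: list[str]
    mean_ranks: np.ndarray
    statistic: float
    pvalue: float
    reject: bool
    alpha: float = 0.05
    note: str = ""


def _block_ranks(block_matrix: np.ndarray) -> np.ndarray:
    """Within-block ranks, best (largest accuracy) = rank 1, ties averaged."""
    return np.vstack([sps.rankdata(-row) for row in block_matrix])


def friedman_rank(
    acc: pd.DataFrame | np.ndarray,
    combinations: list[str] | None = None,
    alpha: float = 0.05,
) -> FriedmanResult:
    """Mean ranks per combination and the Friedman test decision.

    Accepts either a blocks-by-combinations matrix or a long-format frame
    with columns ``block``, ``combination``, ``accuracy``. If accuracies
    are constant within every block the statistic is undefined and the
    null is retained with a diagnostic note.
    """
    if isinstance(acc, pd.DataFrame):
        required = {"block", "combination", "accuracy"}
        if not required.issubset(acc.columns):
            raise ValueError(f"long-format frame needs columns {sorted(required)}")
        pivot = acc.pivot(index="block", columns="combination", values="accuracy")
        if pivot.isna().any().any():
            raise ValueError("every (block, combination) cell must be present")
        matrix = pivot.to_numpy(dtype=float)
        combinations = list(pivot.columns)
    else:
        matrix = np.asarray(acc, dtype=float)
        if combinations is None:
            combinations = [f"m{j + 1}" for j in range(matrix.shape[1])]
    n_blocks, k = matrix.shape
    if k < 2 or n_blocks < 2:
        raise ValueError("need at least 2 combinations and 2 blocks")

    ranks = _block_ranks(matrix)
    mean_ranks = ranks.mean(axis=0)
    if np.all(np.ptp(matrix, axis=1) == 0):
        return FriedmanResult(
            combinations=combinations,
            mean_ranks=mean_ranks,
            statistic=float("nan"),
            pvalue=1.0,
            reject=False,
            alpha=alpha,
            note="constant accuracies within every block; statistic undefined",
        )
    rank_sums = ranks.sum(axis=0)
    chi2 = (
        12.0 / (n_blocks * k * (k + 1)) * float(np.sum(rank_sums**2))
        - 3.0 * n_blocks * (k + 1)
    )
    ties = 0.0
    for row in matrix:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts**3 - counts))
    correction = 1.0 - ties / (n_blocks * k * (k**2 - 1))
    statistic = chi2 / correction
    pvalue = float(sps.chi2.sf(statistic, df=k - 1))
    return FriedmanResult(
        combinations=combinations,
        mean_ranks=mean_ranks,
        statistic=float(statistic),
        pvalue=float(pvalue),
        reject=bool(pvalue < alpha),
        alpha=alpha,
    )
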
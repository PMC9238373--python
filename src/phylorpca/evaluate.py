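"""Benchmark harness: PERMANOVA pseudo-F and KNN cross-validated AUCs.

Distance matrices are scored with the PERMANOVA pseudo-F statistic
(permutation p-value, add-one estimator); ordinations with k-nearest-
neighbor classification over repeated stratified train/test splits,
reporting macro one-vs-rest average precision (PR-AUC) and ROC-AUC on the
first three components.  ``benchmark`` sweeps sequencing depth x tip-shuffle
proportion x replicate seed for RPCA and phylo-RPCA on the block simulation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as _skbio_permanova
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import label_binarize

from .factor import rpca
from .simulate import SimulationConfig, simulate

logger = logging.getLogger("phylorpca")

__all__ = ["BenchmarkResult", "permanova", "knn_cv", "benchmark"]


@dataclass
class BenchmarkResult:
    """One method x simulation-cell evaluation."""

    method: str
    depth: int
    shuffle_proportion: float
    seed: int
    f_statistic: float
    permanova_p: float
    pr_auc: float
    roc_auc: float


def _as_grouping(d: DistanceMatrix, grouping) -> pd.Series:
    if isinstance(grouping, dict):
        grouping = pd.Series(grouping)
    if isinstance(grouping, pd.Series):
        missing = set(d.ids) - set(grouping.index)
        if missing:
            raise ValueError(f"unlabeled samples: {sorted(missing)[:5]}")
        grouping = grouping.loc[list(d.ids)]
    else:
        grouping = pd.Series(list(grouping), index=list(d.ids))
    return grouping.astype(str)


def permanova(
    d: DistanceMatrix,
    grouping,
    permutations: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """PERMANOVA pseudo-F of a grouping on a distance matrix.

    The pseudo-F is computed from among/within sums of squared distances;
    the p-value is the add-one permutation estimator
    ``(1 + #{F_perm >= F}) / (1 + permutations)`` under seeded label
    permutations.  Requires at least two groups with two samples each.
    """
    grouping = _as_grouping(d, grouping)
    counts = grouping.value_counts()
    if len(counts) < 2:
        raise ValueError("grouping must contain at least two groups")
    if (counts < 2).any():
        raise ValueError("every group needs at least two samples")
    res = _skbio_permanova(
        d, grouping.to_numpy(), permutations=permutations, seed=seed
    )
    return float(res["test statistic"]), float(res["p-value"])


def knn_cv(
    scores: pd.DataFrame,
    labels,
    k: int = 3,
    folds: int = 10,
    split: float = 0.5,
    seed: int = 0,
) -> tuple[float, float]:
    """KNN cross-validated PR-AUC and ROC-AUC of ordination scores.

    Uses the first min(r, 3) score columns; ``folds`` repeated seeded
    stratified random splits at train fraction ``split``; per fold the
    one-vs-rest average precision and ROC-AUC are macro-averaged over
    classes, then averaged over folds.
    """
    if isinstance(labels, dict):
        labels = pd.Series(labels)
    if isinstance(labels, pd.Series):
        labels = labels.loc[scores.index]
    y = np.asarray(labels).astype(str)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    x = scores.iloc[:, : min(scores.shape[1], 3)].to_numpy(dtype=float)

    splitter = StratifiedShuffleSplit(
        n_splits=folds, train_size=split, random_state=seed
    )
    pr_aucs, roc_aucs = [], []
    for train, test in splitter.split(x, y):
        min_class = pd.Series(y[train]).value_counts().min()
        k_fold = k
        if k_fold > min_class:
            warnings.warn(
                f"k={k} exceeds smallest training class ({min_class}); clamped",
                RuntimeWarning,
                stacklevel=2,
            )
            k_fold = int(min_class)
        clf = KNeighborsClassifier(n_neighbors=k_fold)
        clf.fit(x[train], y[train])
        proba = clf.predict_proba(x[test])
        y_bin = label_binarize(y[test], classes=classes)
        if y_bin.shape[1] == 1:  # two classes: binarize gives one column
            y_bin = np.hstack([1 - y_bin, y_bin])
        # macro one-vs-rest, skipping classes absent from the test split
        present = y_bin.sum(axis=0) > 0
        both = present & (y_bin.sum(axis=0) < len(test))
        pr_aucs.append(
            float(
                np.mean(
                    [
                        average_precision_score(y_bin[:, c], proba[:, c])
                        for c in np.where(present)[0]
                    ]
                )
            )
        )
        if both.any():
            roc_aucs.append(
                float(
                    np.mean(
                        [
                            roc_auc_score(y_bin[:, c], proba[:, c])
                            for c in np.where(both)[0]
                        ]
                    )
                )
            )
    return float(np.mean(pr_aucs)), float(np.mean(roc_aucs)) if roc_aucs else float("nan")


def _evaluate_method(
    dataset, tree, method: str, rank: int, seed: int, permutations: int, knn_kwargs
) -> BenchmarkResult:
    ordination, dm = rpca(dataset.counts, tree=tree, rank=rank, seed=seed)
    f, p = permanova(dm, dataset.sample_labels, permutations=permutations, seed=seed)
    pr, roc = knn_cv(ordination.samples, dataset.sample_labels, seed=seed, **knn_kwargs)
    return BenchmarkResult(
        method=method,
        depth=dataset.config.depth,
        shuffle_proportion=dataset.config.shuffle_proportion,
        seed=dataset.config.seed,
        f_statistic=f,
        permanova_p=p,
        pr_auc=pr,
        roc_auc=roc,
    )


def benchmark(
    depths=(200, 2_000_000),
    shuffle_proportions=(0.0, 0.25, 0.75, 1.0),
    seeds=range(10),
    methods=("rpca", "phylo_rpca"),
    base_config: SimulationConfig | None = None,
    rank: int = 3,
    permutations: int = 999,
    knn_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Sweep depth x shuffle x seed, evaluating RPCA and phylo-RPCA.

    Returns one row per (cell, method) with PERMANOVA F/p and KNN AUCs.
    """
    base = base_config or SimulationConfig()
    knn_kwargs = knn_kwargs or {}
    rows: list[BenchmarkResult] = []
    for depth in depths:
        for q in shuffle_proportions:
            for seed in seeds:
                cfg = SimulationConfig(
                    **{
                        **base.__dict__,
                        "depth": int(depth),
                        "shuffle_proportion": float(q),
                        "seed": int(seed),
                    }
                )
                dataset = simulate(cfg)
                for method in methods:
                    tree = dataset.tree if method == "phylo_rpca" else None
                    rows.append(
                        _evaluate_method(
                            dataset, tree, method, rank, int(seed), permutations, knn_kwargs
                        )
                    )
    return pd.DataFrame([r.__dict__ for r in rows])
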
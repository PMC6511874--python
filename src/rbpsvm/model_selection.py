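"""Stratified splitting, cross-validated grid search and the balanced
bootstrap alternative to class weighting.

The selection criterion everywhere is balanced accuracy (BACC), the mean of
sensitivity and specificity, which is insensitive to the heavy RBP/non-RBP
class imbalance. The hyperparameter search is a grid over (k, C) in 10-fold
stratified CV; the class weights (W+, W-) are tuned in a separate outer
loop at fixed (k, C). As an alternative to weighting, ``bootstrap_balanced``
trains on all positives plus an equally sized random negative subsample,
repeated ``reps`` times.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from .exceptions import TrainingError
from .kernel import KernelConfig, featurize_csr, maybe_normalize
from .metrics import confusion, scalar_metrics
from .svm import (
    TrainedModel,
    _check_labels,
    decision_values,
    fit_svc_precomputed,
    train,
)

logger = logging.getLogger(__name__)

#: default hyperparameter grids; they bracket the selected optimum k=3, C=1
DEFAULT_K_GRID = (1, 2, 3, 4)
DEFAULT_C_GRID = (0.01, 0.1, 1.0, 10.0)
#: default class-weight grid (includes the tuned pairs (1.8, 0.2) and (1.0, 0.1))
DEFAULT_W_PLUS = (1.0, 1.4, 1.8, 2.2)
DEFAULT_W_MINUS = (0.05, 0.1, 0.2, 0.5, 1.0)


@dataclass(frozen=True)
class SplitSpec:
    """Held-out fraction, CV fold count and the seed driving both."""

    test_fraction: float = 0.10
    n_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise TrainingError("test_fraction must lie in (0, 1)")
        if self.n_folds < 2:
            raise TrainingError("n_folds must be >= 2")


@dataclass
class GridResult:
    """Cross-validation results, one row per hyperparameter combination."""

    frame: pd.DataFrame
    best_index: int

    @property
    def best(self) -> pd.Series:
        return self.frame.loc[self.best_index]

    def to_tsv(self, path) -> None:
        out = self.frame.copy()
        out["per_fold_bacc"] = out["per_fold_bacc"].map(
            lambda folds: ",".join(f"{b:.6g}" for b in folds)
        )
        out["selected"] = out.index == self.best_index
        out.to_csv(path, sep="\t", index=False)


def stratified_split(records, spec: SplitSpec) -> Tuple[list, list]:
    """Disjoint, exhaustive train/test partition preserving the class ratio.

    Deterministic given ``spec.seed``.
    """
    y = _check_labels([r.label for r in records])
    if int(min((y == 1).sum(), (y == 0).sum())) < 2:
        raise TrainingError("each class needs >= 2 members to stratify a split")
    idx = np.arange(len(records))
    train_idx, test_idx = train_test_split(
        idx, test_size=spec.test_fraction, stratify=y, random_state=spec.seed
    )
    train_set = [records[i] for i in np.sort(train_idx)]
    test_set = [records[i] for i in np.sort(test_idx)]
    logger.info(
        "split %d records into train=%d (pos=%d) / test=%d (pos=%d)",
        len(records),
        len(train_set),
        sum(r.label for r in train_set),
        len(test_set),
        sum(r.label for r in test_set),
    )
    return train_set, test_set


def _cv_bacc(
    gram_by_k: Dict[int, np.ndarray],
    y: np.ndarray,
    folds,
    k: int,
    cost: float,
    weights: Tuple[float, float],
) -> Tuple[List[float], bool]:
    """Per-fold balanced accuracy at decision cutoff 0; NaN marks a failed fold.

    Fits run on the precomputed Gram matrix (identical weighted dual as the
    explicit-feature solver, but the kernel is evaluated once per k).
    """
    per_fold: List[float] = []
    failed = False
    gram = gram_by_k[k]
    for train_idx, test_idx in folds:
        try:
            svc = fit_svc_precomputed(
                gram[np.ix_(train_idx, train_idx)], y[train_idx], cost, weights
            )
            scores = svc.decision_function(gram[np.ix_(test_idx, train_idx)])
            per_fold.append(scalar_metrics(confusion(scores, y[test_idx], 0.0))["bacc"])
        except TrainingError as exc:
            logger.warning("fold failed for k=%d C=%g W=%s: %s", k, cost, weights, exc)
            per_fold.append(float("nan"))
            failed = True
    return per_fold, failed


def _prepare(records, ks: Sequence[int], spec: SplitSpec, normalized: bool):
    y = _check_labels([r.label for r in records])
    if int(min((y == 1).sum(), (y == 0).sum())) < spec.n_folds:
        raise TrainingError(
            f"each class needs >= n_folds={spec.n_folds} members for stratified CV"
        )
    sequences = [r.sequence for r in records]
    gram_by_k = {}
    for k in sorted(set(ks)):
        config = KernelConfig(k=k, normalized=normalized)
        X = maybe_normalize(featurize_csr(sequences, config), config)
        gram_by_k[k] = np.asarray((X @ X.T).todense())
    splitter = StratifiedKFold(n_splits=spec.n_folds, shuffle=True, random_state=spec.seed)
    folds = list(splitter.split(np.zeros(len(y)), y))
    return gram_by_k, y, folds


def _build_result(rows: List[dict], sort_key) -> GridResult:
    frame = pd.DataFrame(rows)
    order = sorted(frame.index, key=lambda i: sort_key(frame.loc[i]))
    return GridResult(frame=frame, best_index=order[0])


def grid_search(
    records,
    ks: Sequence[int] = DEFAULT_K_GRID,
    costs: Sequence[float] = DEFAULT_C_GRID,
    weights: Tuple[float, float] = (1.0, 1.0),
    spec: SplitSpec = SplitSpec(),
    normalized: bool = True,
) -> GridResult:
    """n-fold CV over the (k, C) grid at fixed class weights.

    The best row maximizes mean BACC; ties break toward the simpler model
    (smaller k, then smaller C). Deterministic given ``spec.seed``.
    """
    if not ks or not costs:
        raise TrainingError("grid must be non-empty")
    gram_by_k, y, folds = _prepare(records, ks, spec, normalized)
    rows = []
    for k, cost in product(ks, costs):
        per_fold, failed = _cv_bacc(gram_by_k, y, folds, k, cost, weights)
        clean = [b for b in per_fold if not np.isnan(b)]
        rows.append(
            {
                "k": k,
                "C": cost,
                "w_plus": weights[0],
                "w_minus": weights[1],
                "mean_bacc": float(np.mean(clean)) if clean else float("nan"),
                "sd_bacc": float(np.std(clean, ddof=1)) if len(clean) > 1 else 0.0,
                "per_fold_bacc": per_fold,
                "failed_folds": int(sum(np.isnan(per_fold))),
            }
        )
    result = _build_result(
        rows, lambda r: (-(r["mean_bacc"] if np.isfinite(r["mean_bacc"]) else -np.inf), r["k"], r["C"])
    )
    best = result.best
    logger.info(
        "grid search best: k=%d C=%g mean BACC=%.4f", best["k"], best["C"], best["mean_bacc"]
    )
    return result


def class_weight_search(
    records,
    k: int = 3,
    cost: float = 1.0,
    weight_grid: Optional[Sequence[Tuple[float, float]]] = None,
    spec: SplitSpec = SplitSpec(),
    normalized: bool = True,
) -> GridResult:
    """Outer loop over (W+, W-) at fixed (k, C).

    Ties break toward the least aggressive weighting (smaller W+, then
    larger W-).
    """
    if weight_grid is None:
        weight_grid = list(product(DEFAULT_W_PLUS, DEFAULT_W_MINUS))
    if not weight_grid:
        raise TrainingError("weight grid must be non-empty")
    gram_by_k, y, folds = _prepare(records, [k], spec, normalized)
    rows = []
    for w_plus, w_minus in weight_grid:
        per_fold, _ = _cv_bacc(gram_by_k, y, folds, k, cost, (w_plus, w_minus))
        clean = [b for b in per_fold if not np.isnan(b)]
        rows.append(
            {
                "k": k,
                "C": cost,
                "w_plus": w_plus,
                "w_minus": w_minus,
                "mean_bacc": float(np.mean(clean)) if clean else float("nan"),
                "sd_bacc": float(np.std(clean, ddof=1)) if len(clean) > 1 else 0.0,
                "per_fold_bacc": per_fold,
                "failed_folds": int(sum(np.isnan(per_fold))),
            }
        )
    result = _build_result(
        rows,
        lambda r: (
            -(r["mean_bacc"] if np.isfinite(r["mean_bacc"]) else -np.inf),
            r["w_plus"],
            -r["w_minus"],
        ),
    )
    best = result.best
    logger.info(
        "class-weight search best: W+=%g W-=%g mean BACC=%.4f",
        best["w_plus"],
        best["w_minus"],
        best["mean_bacc"],
    )
    return result


@dataclass
class BootstrapResult:
    """Per-replicate balanced-subsample models and their test metrics."""

    replicates: List[Tuple[TrainedModel, Dict[str, object]]]

    @property
    def mean_bacc(self) -> float:
        return float(np.mean([m["bacc"] for _, m in self.replicates]))

    def summary(self) -> pd.DataFrame:
        rows = [
            {"rep": i, **{k: v for k, v in m.items() if k != "flags"}}
            for i, (_, m) in enumerate(self.replicates)
        ]
        return pd.DataFrame(rows)


def bootstrap_balanced(
    train_records,
    test_records,
    k: int = 3,
    cost: float = 1.0,
    reps: int = 10,
    seed: int = 0,
    normalized: bool = True,
) -> BootstrapResult:
    """Train ``reps`` unweighted models on balanced negative subsamples.

    Each replicate uses all positives plus a without-replacement negative
    subsample of equal size; metrics are measured on ``test_records`` at
    decision cutoff 0. Requires at least as many negatives as positives.
    """
    positives = [r for r in train_records if r.label == 1]
    negatives = [r for r in train_records if r.label == 0]
    if not positives:
        raise TrainingError("no positive examples in the training set")
    if len(negatives) < len(positives):
        raise TrainingError(
            f"balanced subsampling needs negatives >= positives "
            f"({len(negatives)} < {len(positives)})"
        )
    config = KernelConfig(k=k, normalized=normalized)
    test_sequences = [r.sequence for r in test_records]
    test_labels = np.asarray([r.label for r in test_records], dtype=int)
    replicates = []
    for rep in range(reps):
        rng = np.random.default_rng([seed, rep])
        chosen = rng.choice(len(negatives), size=len(positives), replace=False)
        subset = positives + [negatives[i] for i in np.sort(chosen)]
        model = train(subset, config=config, cost=cost, weights=(1.0, 1.0), seed=seed)
        scores = decision_values(model, test_sequences)
        replicates.append((model, scalar_metrics(confusion(scores, test_labels, 0.0))))
    result = BootstrapResult(replicates=replicates)
    logger.info("balanced bootstrap: %d reps, mean test BACC=%.4f", reps, result.mean_bacc)
    return result
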
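"""Class-weighted soft-margin SVM over the spectrum feature space.

Training solves the usual soft-margin SVM whose per-class box constraints
are scaled by class weights: dual coefficients of positive support vectors
are bounded by C*W+ and those of negatives by C*W-. Because the spectrum
kernel is linear in the (possibly L2-normalized) k-mer count space, the
primal weight vector

    w = sum_i alpha_i y_i Phi(x_i)

is recoverable exactly from the support vectors, giving a per-k-mer
importance score: the sign tells which class a k-mer pulls toward, the
magnitude how strongly. The decision function is f(x) = <w, Phi(x)> + b.

The optimization is delegated to libsvm (sklearn.svm.SVC) with a linear
kernel on the explicit sparse 20^k feature matrix; the class-weighted dual
box constraints and the equality constraint sum_i alpha_i y_i = 0 are
asserted on every returned model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.sparse as sp
import scipy.special
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .exceptions import CalibrationError, TrainingError
from .kernel import (
    KernelConfig,
    SpectrumVector,
    featurize_csr,
    index_to_kmer,
    maybe_normalize,
    vectors_to_csr,
)

logger = logging.getLogger(__name__)

#: solver settings (documented contract: tolerance 1e-6, iteration cap 1e5)
SOLVER_TOL = 1e-6
SOLVER_MAX_ITER = 100_000

#: published operating-point presets on the calibrated-probability scale
PRESET_CUTOFFS = {"human": 0.68, "salmonella": 0.28, "ecoli": 0.3}


@dataclass
class TrainedModel:
    """A trained spectrum-kernel SVM.

    ``dual_coefs[i]`` equals alpha_i * y_i (y_i in {-1, +1}) for support
    vector i, so positives have positive entries. ``calibration`` holds
    Platt sigmoid parameters (A, B) with P(RBP | f) = 1 / (1 + exp(A f + B)).
    """

    support_vectors: List[SpectrumVector]
    dual_coefs: np.ndarray
    bias: float
    config: KernelConfig
    cost: float
    class_weights: Tuple[float, float]
    calibration: Optional[Tuple[float, float]] = None
    _sv_cache: Optional[sp.csr_matrix] = field(
        default=None, init=False, repr=False, compare=False
    )

    @property
    def sv_matrix(self) -> sp.csr_matrix:
        """Support vectors as a (possibly normalized) sparse feature matrix."""
        if self._sv_cache is None:
            raw = vectors_to_csr(self.support_vectors, self.config)
            self._sv_cache = maybe_normalize(raw, self.config)
        return self._sv_cache


@dataclass
class FeatureWeights:
    """Per-k-mer weights w of the linear decision function (absent = 0)."""

    weights: Dict[str, float]
    dense: np.ndarray
    config: KernelConfig

    def value(self, kmer: str) -> float:
        return self.weights.get(kmer, 0.0)

    def as_array(self) -> np.ndarray:
        return self.dense

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            sorted(self.weights.items()), columns=["kmer", "weight"]
        )
        frame["abs_weight"] = frame["weight"].abs()
        return frame.sort_values(
            "abs_weight", ascending=False, kind="mergesort"
        ).reset_index(drop=True)

    def top_positive(self, n: int) -> List[str]:
        positive = [(w, m) for m, w in self.weights.items() if w > 0]
        positive.sort(key=lambda t: (-t[0], t[1]))
        return [m for _, m in positive[:n]]

    def top_by_abs(self, n: int) -> List[str]:
        ranked = sorted(self.weights.items(), key=lambda t: (-abs(t[1]), t[0]))
        return [m for m, _ in ranked[:n]]


def _check_labels(labels: Sequence[Optional[int]]) -> np.ndarray:
    arr = np.asarray(labels)
    if any(label is None for label in labels):
        raise TrainingError("all training records must carry a binary label")
    arr = arr.astype(int)
    if not set(np.unique(arr)) <= {0, 1}:
        raise TrainingError("labels must be binary (1 = RBP, 0 = non-RBP)")
    if len(np.unique(arr)) < 2:
        raise TrainingError("training requires at least one example of each class")
    return arr


def fit_svc(
    X: sp.csr_matrix,
    y: np.ndarray,
    cost: float,
    weights: Tuple[float, float],
    seed: int = 0,
) -> SVC:
    """Fit libsvm on a prepared (already normalized) feature matrix."""
    w_plus, w_minus = weights
    if cost <= 0 or w_plus <= 0 or w_minus <= 0:
        raise TrainingError("cost and class weights must be positive")
    svc = SVC(
        kernel="linear",
        C=cost,
        class_weight={1: w_plus, 0: w_minus},
        tol=SOLVER_TOL,
        max_iter=SOLVER_MAX_ITER,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            svc.fit(X, y)
        except ConvergenceWarning as exc:
            raise TrainingError(
                f"solver did not converge within {SOLVER_MAX_ITER} iterations "
                f"(tol={SOLVER_TOL}): {exc}"
            ) from exc
    return svc


def fit_svc_precomputed(
    gram_train: np.ndarray,
    y: np.ndarray,
    cost: float,
    weights: Tuple[float, float],
) -> SVC:
    """Fit libsvm on a precomputed Gram submatrix.

    Solves the identical weighted dual as :func:`fit_svc`; used where the
    same dataset is refit many times (cross-validation, calibration), since
    the kernel matrix then only has to be computed once.
    """
    w_plus, w_minus = weights
    if cost <= 0 or w_plus <= 0 or w_minus <= 0:
        raise TrainingError("cost and class weights must be positive")
    svc = SVC(
        kernel="precomputed",
        C=cost,
        class_weight={1: w_plus, 0: w_minus},
        tol=SOLVER_TOL,
        max_iter=SOLVER_MAX_ITER,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            svc.fit(gram_train, y)
        except ConvergenceWarning as exc:
            raise TrainingError(
                f"solver did not converge within {SOLVER_MAX_ITER} iterations "
                f"(tol={SOLVER_TOL}): {exc}"
            ) from exc
    return svc


def oof_decision_values(
    X: sp.csr_matrix,
    y: np.ndarray,
    cost: float = 1.0,
    weights: Tuple[float, float] = (1.0, 1.0),
    n_folds: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Pooled out-of-fold decision values from stratified k-fold refits.

    Every example is scored by a model that never saw it; the pooled scores
    give an unbiased held-out performance estimate on the full dataset.
    """
    gram = np.asarray((X @ X.T).todense())
    oof = np.empty(len(y), dtype=float)
    splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for train_idx, test_idx in splitter.split(np.zeros(len(y)), y):
        svc = fit_svc_precomputed(gram[np.ix_(train_idx, train_idx)], y[train_idx], cost, weights)
        oof[test_idx] = svc.decision_function(gram[np.ix_(test_idx, train_idx)])
    return oof


def _row_to_vector(raw: sp.csr_matrix, row: int, config: KernelConfig) -> SpectrumVector:
    start, stop = raw.indptr[row], raw.indptr[row + 1]
    return SpectrumVector(
        {
            index_to_kmer(int(raw.indices[j]), config): int(raw.data[j])
            for j in range(start, stop)
        },
        config.k,
    )


def _check_dual(model: TrainedModel, sv_labels: np.ndarray) -> None:
    bounds = np.where(
        sv_labels == 1,
        model.cost * model.class_weights[0],
        model.cost * model.class_weights[1],
    )
    if np.any(np.abs(model.dual_coefs) > bounds * (1 + 1e-9) + 1e-12):
        raise TrainingError("dual coefficients violate the class-weighted box constraint")
    if abs(float(np.sum(model.dual_coefs))) > 1e-6:
        raise TrainingError("dual equality constraint sum(alpha_i y_i) = 0 violated")


def train(
    records,
    config: Optional[KernelConfig] = None,
    cost: float = 1.0,
    weights: Tuple[float, float] = (1.0, 1.0),
    seed: int = 0,
) -> TrainedModel:
    """Train a class-weighted spectrum-kernel SVM on labeled protein records.

    Deterministic given the record order and seed. Raises TrainingError on
    single-class data, invalid hyperparameters or solver non-convergence.
    """
    config = config or KernelConfig()
    y = _check_labels([r.label for r in records])
    raw = featurize_csr([r.sequence for r in records], config)
    X = maybe_normalize(raw, config)
    svc = fit_svc(X, y, cost, weights, seed)
    support = svc.support_
    dual = svc.dual_coef_
    if sp.issparse(dual):  # libsvm returns a sparse matrix for sparse X
        dual = dual.toarray()
    model = TrainedModel(
        support_vectors=[_row_to_vector(raw, int(i), config) for i in support],
        dual_coefs=np.asarray(dual, dtype=float).ravel(),
        bias=float(svc.intercept_[0]),
        config=config,
        cost=float(cost),
        class_weights=(float(weights[0]), float(weights[1])),
    )
    _check_dual(model, y[support])
    logger.info(
        "trained SVM: n=%d (pos=%d), support vectors=%d, C=%g, W=(%g, %g)",
        len(records),
        int(y.sum()),
        len(support),
        cost,
        weights[0],
        weights[1],
    )
    return model


def decision_values(model: TrainedModel, sequences: Sequence[str]) -> np.ndarray:
    """f(x) = sum_i dual_coef_i K(x_i, x) + b for each sequence.

    All-ambiguity or too-short sequences have an empty spectrum and score
    exactly the bias.
    """
    phi = maybe_normalize(featurize_csr(sequences, model.config), model.config)
    gram = phi @ model.sv_matrix.T
    return np.asarray(gram @ model.dual_coefs).ravel() + model.bias


def decision_value(model: TrainedModel, sequence: str) -> float:
    return float(decision_values(model, [sequence])[0])


def feature_weights(model: TrainedModel) -> FeatureWeights:
    """Per-k-mer weight vector w = sum_i dual_coef_i Phi(x_i).

    Phi here is the same (possibly normalized) feature map the model was
    trained with, so <w, Phi(x)> + b reproduces the decision function
    exactly (linearity of the spectrum kernel).
    """
    dense = np.asarray(model.sv_matrix.T @ model.dual_coefs).ravel()
    nonzero = np.flatnonzero(dense)
    weights = {index_to_kmer(int(i), model.config): float(dense[i]) for i in nonzero}
    return FeatureWeights(weights=weights, dense=dense, config=model.config)


def _sigmoid(calibration: Tuple[float, float], scores: np.ndarray) -> np.ndarray:
    a, b = calibration
    z = a * np.asarray(scores, dtype=float) + b
    return 1.0 / (1.0 + np.exp(z))


def probabilities(model: TrainedModel, sequences: Sequence[str]) -> np.ndarray:
    if model.calibration is None:
        raise CalibrationError("model carries no calibration parameters")
    return _sigmoid(model.calibration, decision_values(model, sequences))


def predict(
    model: TrainedModel,
    records,
    cutoff: float,
    scale: str = "decision",
) -> pd.DataFrame:
    """Score records and call RBPs at ``score >= cutoff``.

    ``scale`` selects whether the cutoff applies to raw decision values or
    to calibrated probabilities (requires a calibrated model).
    """
    if scale not in ("decision", "probability"):
        raise ValueError(f"unknown scale {scale!r}")
    scores = decision_values(model, [r.sequence for r in records])
    probs: Optional[np.ndarray] = None
    if model.calibration is not None:
        probs = _sigmoid(model.calibration, scores)
    if scale == "probability":
        if probs is None:
            raise CalibrationError(
                "probability cutoff requested but model is not calibrated"
            )
        called = probs >= cutoff
    else:
        called = scores >= cutoff
    return pd.DataFrame(
        {
            "protein_id": [r.id for r in records],
            "decision_value": scores,
            "probability": probs if probs is not None else [None] * len(records),
            "predicted_label": called.astype(int),
        }
    )


def _platt_fit(scores: np.ndarray, labels: np.ndarray) -> Tuple[float, float]:
    """Platt's sigmoid fit with the standard smoothed targets."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    targets = np.where(
        labels == 1, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0)
    )

    def nll_and_grad(params):
        a, b = params
        z = a * scores + b
        # P(y=1) = sigmoid(-z); NLL written with logaddexp for stability
        nll = float(np.sum(np.logaddexp(0.0, z) - (1.0 - targets) * z))
        dz = scipy.special.expit(z) - (1.0 - targets)
        return nll, np.array([float(dz @ scores), float(dz.sum())])

    x0 = np.array([0.0, np.log((n_neg + 1.0) / (n_pos + 1.0))])
    result = scipy.optimize.minimize(nll_and_grad, x0, jac=True, method="BFGS")
    if not np.all(np.isfinite(result.x)):
        raise CalibrationError("sigmoid fit diverged")
    return float(result.x[0]), float(result.x[1])


def calibrate(
    model: TrainedModel,
    records,
    n_folds: int = 5,
    seed: int = 0,
) -> TrainedModel:
    """Fit Platt sigmoid parameters on out-of-fold decision values.

    Refits the model's hyperparameters on k-1 folds and scores the held-out
    fold, so the sigmoid never sees in-sample (optimistic) decision values.
    Returns a copy of the model carrying (A, B).
    """
    y = _check_labels([r.label for r in records])
    min_class = int(min((y == 1).sum(), (y == 0).sum()))
    if min_class < 2:
        raise CalibrationError("calibration needs at least 2 examples per class")
    folds = min(n_folds, min_class)
    raw = featurize_csr([r.sequence for r in records], model.config)
    X = maybe_normalize(raw, model.config)
    oof = oof_decision_values(
        X, y, cost=model.cost, weights=model.class_weights, n_folds=folds, seed=seed
    )
    a, b = _platt_fit(oof, y)
    if a >= 0:
        logger.warning(
            "Platt slope A=%g is non-negative: probabilities decrease with the "
            "decision value (degenerate calibration data)",
            a,
        )
    return replace(model, calibration=(a, b))
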
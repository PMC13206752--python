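"""Cross-validated non-negative least-squares reweighting of RDM predictors.

Each subject's behavioral RDM is one predictor; NNLS assigns every predictor
a nonnegative weight expressing its relative fit to the training
dissimilarities of a target RDM (a searchlight brain RDM or a model RDM).
Stimuli — not dissimilarities — are split into train and test sets: training
uses only pairs whose two items are both in the train set, evaluation uses
only pairs fully inside the test set, and pairs spanning the two sets are
discarded so no test-item geometry leaks into the fit.  The fitted weights
predict held-out dissimilarities by a plain dot product, the prediction is
scored with Pearson correlation on the test pairs, and scores are averaged
over folds.

A "fold" here is one independent seeded random 70:30 item split; ten of
them make the default plan.  (Ten disjoint 30% test sets cannot tile 100
stimuli, so repeated random splits are the only consistent reading of a
70:30 ten-fold scheme.)

Variance partitioning compares the joint model (visual and linguistic
predictor stacks entered simultaneously) against each single-modality model
in R² space, where R² is the squared fold-averaged correlation: the unique
linguistic contribution is R²_joint − R²_visual and the unique visual
contribution is R²_joint − R²_linguistic.  Cross-validated differences can
be negative and are reported as-is.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import nnls as _scipy_nnls

from ._pairs import n_pairs
from .exceptions import InvalidArgumentError, UndefinedCorrelationError
from .rdm import RDMStack, validate_rdm, vectorize
from .searchlight import BrainRDMField

__all__ = [
    "SplitPlan",
    "ReweightResult",
    "VariancePartition",
    "make_folds",
    "pair_partition",
    "nnls_fit",
    "predict_and_score",
    "crossval_reweight",
    "field_reweight",
    "variance_partition",
]


@dataclass
class SplitPlan:
    """Seeded train/test item splits shared across every fit of an analysis."""

    n_items: int
    folds: list  # list of (train item array, test item array)
    train_frac: float
    seed: int


@dataclass
class ReweightResult:
    """Per-fold NNLS weights and test-set Pearson fits for one target."""

    weights: np.ndarray  # folds x predictors
    fold_r: np.ndarray
    mean_r: float


@dataclass
class VariancePartition:
    """Joint vs single-modality cross-validated R² decomposition."""

    r2_joint: float
    r2_visual: float
    r2_linguistic: float

    @property
    def unique_linguistic(self) -> float:
        return self.r2_joint - self.r2_visual

    @property
    def unique_visual(self) -> float:
        return self.r2_joint - self.r2_linguistic


def make_folds(
    n_items: int,
    train_frac: float = 0.7,
    n_folds: int = 10,
    seed: int = 0,
) -> SplitPlan:
    """``n_folds`` independent seeded random train/test item splits."""
    if not (0 < train_frac < 1):
        raise InvalidArgumentError("train_frac must be in (0, 1)")
    if n_folds < 1:
        raise InvalidArgumentError("n_folds must be >= 1")
    n_train = int(round(train_frac * n_items))
    if n_train < 2 or n_items - n_train < 2:
        raise InvalidArgumentError(
            f"split {n_train}/{n_items - n_train} leaves fewer than 2 items on one side"
        )
    rng = np.random.default_rng(seed)
    folds = []
    for _ in range(n_folds):
        perm = rng.permutation(n_items)
        folds.append((np.sort(perm[:n_train]), np.sort(perm[n_train:])))
    return SplitPlan(n_items=n_items, folds=folds, train_frac=train_frac, seed=seed)


def pair_partition(fold, n_items: int) -> tuple[np.ndarray, np.ndarray]:
    """Indices of train pairs (both items in train) and test pairs (both in
    test) in the canonical pair vector; mixed pairs belong to neither."""
    train_items, test_items = fold
    in_train = np.zeros(n_items, dtype=bool)
    in_train[np.asarray(train_items)] = True
    in_test = np.zeros(n_items, dtype=bool)
    in_test[np.asarray(test_items)] = True
    ii, jj = np.triu_indices(n_items, k=1)
    train_pairs = np.flatnonzero(in_train[ii] & in_train[jj])
    test_pairs = np.flatnonzero(in_test[ii] & in_test[jj])
    return train_pairs, test_pairs


def nnls_fit(predictors: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Nonnegative weights minimizing ||predictors @ w - target||²."""
    predictors = np.asarray(predictors, dtype=float)
    target = np.asarray(target, dtype=float)
    if predictors.ndim != 2 or predictors.shape[1] < 1:
        raise InvalidArgumentError("predictors must be pairs x P with P >= 1")
    if predictors.shape[0] != target.shape[0]:
        raise InvalidArgumentError("predictor rows and target length differ")
    if not (np.all(np.isfinite(predictors)) and np.all(np.isfinite(target))):
        raise InvalidArgumentError("non-finite entries in NNLS inputs")
    weights, _ = _scipy_nnls(predictors, target)
    return weights


def predict_and_score(
    weights: np.ndarray,
    test_predictors: np.ndarray,
    test_target: np.ndarray,
) -> float:
    """Pearson r between the dot-product prediction and the held-out target."""
    test_target = np.asarray(test_target, dtype=float)
    if test_target.size < 3:
        raise InvalidArgumentError("need >= 3 test pairs to score")
    pred = np.asarray(test_predictors, dtype=float) @ np.asarray(weights, dtype=float)
    if np.ptp(pred) == 0 or np.ptp(test_target) == 0:
        raise UndefinedCorrelationError("constant prediction or target on test pairs")
    r, _ = stats.pearsonr(pred, test_target)
    return float(r)


def _plan_partitions(plan: SplitPlan):
    return [pair_partition(f, plan.n_items) for f in plan.folds]


def crossval_reweight(
    stack: RDMStack,
    target: np.ndarray,
    plan: SplitPlan,
) -> ReweightResult:
    """Fit NNLS weights on train pairs, score on test pairs, per fold.

    ``target`` may be a square RDM or an already-vectorized pair vector.
    """
    target = np.asarray(target, dtype=float)
    if target.ndim == 2:
        target = vectorize(validate_rdm(target))
    if stack.n_items != plan.n_items or target.size != n_pairs(plan.n_items):
        raise InvalidArgumentError("stack, target and plan cover different item sets")
    predictors = stack.vectors.T  # pairs x P
    weights, fold_r = [], []
    for k, (train_pairs, test_pairs) in enumerate(_plan_partitions(plan)):
        try:
            w = nnls_fit(predictors[train_pairs], target[train_pairs])
            r = predict_and_score(w, predictors[test_pairs], target[test_pairs])
        except (InvalidArgumentError, UndefinedCorrelationError) as err:
            raise type(err)(f"fold {k}: {err}") from err
        weights.append(w)
        fold_r.append(r)
    weights = np.array(weights)
    fold_r = np.array(fold_r)
    return ReweightResult(weights=weights, fold_r=fold_r, mean_r=float(fold_r.mean()))


def field_reweight(
    stack: RDMStack,
    field: BrainRDMField,
    plan: SplitPlan,
) -> tuple[np.ndarray, list]:
    """Fold-averaged fit at every searchlight center (NaN where degenerate).

    Applies :func:`crossval_reweight` independently per center, preserving
    center order.  Centers with constant test targets in some fold are
    skipped leniently: their map value is NaN and they are listed in the
    returned report.
    """
    if stack.n_items != field.n_items:
        raise InvalidArgumentError("stack and field cover different item sets")
    predictors = stack.vectors.T
    partitions = _plan_partitions(plan)
    train_preds = [predictors[tr] for tr, _ in partitions]
    test_preds = [predictors[te] for _, te in partitions]
    out = np.full(field.vectors.shape[0], np.nan)
    skipped = []
    for c in range(field.vectors.shape[0]):
        target = field.vectors[c]
        rs = np.empty(len(partitions))
        try:
            for k, (train_pairs, test_pairs) in enumerate(partitions):
                w = nnls_fit(train_preds[k], target[train_pairs])
                rs[k] = predict_and_score(w, test_preds[k], target[test_pairs])
        except UndefinedCorrelationError:
            skipped.append(tuple(field.centers[c]))
            continue
        out[c] = rs.mean()
    return out, skipped


def variance_partition(
    visual: RDMStack,
    linguistic: RDMStack,
    target: np.ndarray,
    plan: SplitPlan,
) -> VariancePartition:
    """Joint and single-modality cross-validated fits in R² space."""
    if visual.n_items != linguistic.n_items:
        raise InvalidArgumentError("modality stacks cover different item sets")
    joint = RDMStack(
        n_items=visual.n_items,
        vectors=np.vstack([visual.vectors, linguistic.vectors]),
        labels=[f"vis:{l}" for l in visual.labels] + [f"lin:{l}" for l in linguistic.labels],
    )
    r_joint = crossval_reweight(joint, target, plan).mean_r
    r_vis = crossval_reweight(visual, target, plan).mean_r
    r_lin = crossval_reweight(linguistic, target, plan).mean_r
    return VariancePartition(
        r2_joint=r_joint**2, r2_visual=r_vis**2, r2_linguistic=r_lin**2
    )
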
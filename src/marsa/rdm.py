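"""Core RDM algebra.

A representational dissimilarity matrix (RDM) is the universal currency of
this package: a square symmetric matrix of pairwise dissimilarities between
stimuli with an exactly-zero diagonal.  Square matrices are plain
``numpy.ndarray`` s; collections of subject (or predictor) RDMs live in
:class:`RDMStack`, which stores one vectorized RDM per row in the canonical
upper-triangle order (see :mod:`marsa._pairs`).

Besides construction and (de)vectorization this module implements the two
group-comparison styles used for behavioral similarity data:

* fixed-effects RSA — average the per-subject RDMs of each stack, then take
  one Spearman correlation between the two averages;
* random-effects RSA — average the Spearman correlation over every
  cross-stack subject pair, with significance from an item-relabeling
  permutation null.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._pairs import n_items_from_pairs, n_pairs, permute_pair_order
from .exceptions import (
    DegeneratePatternError,
    InvalidArgumentError,
    UndefinedCorrelationError,
)

__all__ = [
    "RDMStack",
    "validate_rdm",
    "corrdist_rdm",
    "vectorize",
    "devectorize",
    "rank_transform",
    "average_stack",
    "fixed_effects_rsa",
    "random_effects_rsa",
    "within_modality_consistency",
]


def validate_rdm(values: np.ndarray, *, atol: float = 1e-10) -> np.ndarray:
    """Check RDM invariants (square, symmetric, zero diagonal, finite, >= 0)."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise InvalidArgumentError(f"RDM must be square, got shape {values.shape}")
    if not np.all(np.isfinite(values)):
        raise InvalidArgumentError("RDM contains non-finite entries")
    if not np.allclose(values, values.T, atol=atol):
        raise InvalidArgumentError("RDM is not symmetric")
    if np.any(np.abs(np.diag(values)) > atol):
        raise InvalidArgumentError("RDM diagonal is not zero")
    if np.any(values < -atol):
        raise InvalidArgumentError("RDM has negative dissimilarities")
    return values


@dataclass
class RDMStack:
    """A set of vectorized RDMs over the same items (one row per subject).

    ``vectors`` has shape (n_rows, n_items*(n_items-1)/2) in canonical pair
    order.  ``labels`` identifies each row (subject id, predictor name, ...).
    """

    n_items: int
    vectors: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.vectors = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        m = n_pairs(self.n_items)
        if self.vectors.shape[1] != m:
            raise InvalidArgumentError(
                f"expected {m} pairs for {self.n_items} items, "
                f"got {self.vectors.shape[1]}"
            )
        if not np.all(np.isfinite(self.vectors)):
            raise InvalidArgumentError("stack contains non-finite dissimilarities")
        if np.any(self.vectors < 0):
            raise InvalidArgumentError("stack contains negative dissimilarities")
        if not self.labels:
            self.labels = [f"row{i}" for i in range(self.vectors.shape[0])]
        if len(self.labels) != self.vectors.shape[0]:
            raise InvalidArgumentError("labels length does not match rows")

    @property
    def n_rows(self) -> int:
        return self.vectors.shape[0]

    @classmethod
    def from_matrices(cls, matrices, labels=None) -> "RDMStack":
        matrices = [validate_rdm(m) for m in matrices]
        n = matrices[0].shape[0]
        vecs = np.stack([vectorize(m) for m in matrices])
        return cls(n_items=n, vectors=vecs, labels=list(labels) if labels else [])


def corrdist_rdm(patterns: np.ndarray) -> np.ndarray:
    """Correlation-distance RDM of an items x features pattern matrix.

    Entry (i, j) is 1 minus the Pearson correlation between the feature
    vectors of items i and j; the range is [0, 2].
    """
    patterns = np.asarray(patterns, dtype=float)
    if patterns.ndim != 2 or patterns.shape[1] < 2:
        raise InvalidArgumentError("patterns must be items x features with >= 2 features")
    if not np.all(np.isfinite(patterns)):
        raise InvalidArgumentError("patterns contain non-finite values")
    sd = patterns.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise DegeneratePatternError(bad)
    d = 1.0 - np.corrcoef(patterns)
    d = np.clip(d, 0.0, 2.0)
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    return d


def vectorize(rdm: np.ndarray) -> np.ndarray:
    """Upper-triangle vector of an RDM in canonical pair order."""
    rdm = validate_rdm(rdm)
    iu = np.triu_indices(rdm.shape[0], k=1)
    return rdm[iu].copy()


def devectorize(vector: np.ndarray, n_items: int | None = None) -> np.ndarray:
    """Rebuild the square symmetric RDM from its canonical pair vector."""
    vector = np.asarray(vector, dtype=float).ravel()
    n = n_items_from_pairs(vector.size) if n_items is None else int(n_items)
    if n_pairs(n) != vector.size:
        raise InvalidArgumentError(
            f"vector of length {vector.size} does not match {n} items"
        )
    out = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    out[iu] = vector
    out += out.T
    return out


def rank_transform(vector: np.ndarray) -> np.ndarray:
    """Ranks 1..m with average ranks for ties (Spearman = Pearson of ranks)."""
    vector = np.asarray(vector, dtype=float)
    if not np.all(np.isfinite(vector)):
        raise InvalidArgumentError("cannot rank non-finite values")
    return stats.rankdata(vector)


def average_stack(stack: RDMStack) -> np.ndarray:
    """Elementwise mean RDM of a stack, returned as a square matrix."""
    if stack.n_rows < 1:
        raise InvalidArgumentError("cannot average an empty stack")
    return devectorize(stack.vectors.mean(axis=0), stack.n_items)


def _check_items(a: RDMStack, b: RDMStack) -> None:
    if a.n_items != b.n_items:
        raise InvalidArgumentError(
            f"stacks cover different item sets ({a.n_items} vs {b.n_items})"
        )


def fixed_effects_rsa(stack_a: RDMStack, stack_b: RDMStack) -> float:
    """Spearman correlation between the two subject-averaged RDM vectors."""
    _check_items(stack_a, stack_b)
    va = stack_a.vectors.mean(axis=0)
    vb = stack_b.vectors.mean(axis=0)
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        raise UndefinedCorrelationError("subject-averaged RDM is constant")
    rho, _ = stats.spearmanr(va, vb)
    return float(rho)


def _standardized_ranks(vectors: np.ndarray) -> np.ndarray:
    """Row-wise rank transform, then z-score each row (constant rows error)."""
    ranks = np.apply_along_axis(stats.rankdata, 1, vectors)
    sd = ranks.std(axis=1)
    if np.any(sd == 0):
        raise UndefinedCorrelationError("a subject RDM is constant")
    return (ranks - ranks.mean(axis=1, keepdims=True)) / sd[:, None]


def random_effects_rsa(
    stack_a: RDMStack,
    stack_b: RDMStack,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Mean cross-stack pairwise Spearman and a permutation p-value.

    The statistic averages Spearman(subject a, subject b) over all subject
    pairs with a in stack_a and b in stack_b.  The null relabels items: the
    same random item permutation is applied to every RDM of stack_b, and the
    statistic recomputed, ``n_perm`` times.  One-sided
    p = (1 + #{null >= observed}) / (1 + n_perm).
    """
    _check_items(stack_a, stack_b)
    if stack_a.n_rows < 2 or stack_b.n_rows < 2:
        raise InvalidArgumentError("random-effects RSA needs >= 2 subjects per stack")
    if n_perm < 1:
        raise InvalidArgumentError("n_perm must be >= 1")
    m = stack_a.vectors.shape[1]
    za = _standardized_ranks(stack_a.vectors)
    zb = _standardized_ranks(stack_b.vectors)
    # mean over all (a, b) of z_a . z_b / m  ==  (mean z_a) . (mean z_b) / m
    za_bar = za.mean(axis=0)
    zb_bar = zb.mean(axis=0)
    observed = float(za_bar @ zb_bar / m)
    rng = np.random.default_rng(seed)
    exceed = 0
    n = stack_a.n_items
    for _ in range(n_perm):
        order = permute_pair_order(rng.permutation(n))
        if float(za_bar @ zb_bar[order] / m) >= observed:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return observed, float(p)


def within_modality_consistency(stack: RDMStack) -> float:
    """Mean pairwise Spearman over all unordered subject pairs of one stack."""
    if stack.n_rows < 2:
        raise InvalidArgumentError("consistency needs >= 2 subjects")
    z = _standardized_ranks(stack.vectors)
    m = z.shape[1]
    g = z @ z.T / m
    iu = np.triu_indices(stack.n_rows, k=1)
    return float(g[iu].mean())
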
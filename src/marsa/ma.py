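"""Multiple-arrangement (MA) RDM estimation by evidence-weighted averaging.

In an MA session a participant repeatedly drags subsets of items inside a
circular arena so that on-screen distance expresses perceived dissimilarity.
A full dissimilarity matrix is assembled across trials: each trial's
pairwise distances are scaled to unit RMS (arena distances are only
meaningful up to scale), then folded into a running per-pair estimate
weighted by per-trial evidence.  The evidence a trial contributes to a pair
is the squared scaled on-screen distance — larger separations are measured
with better relative precision, so they count for more.  Subsequent trials
target the subsets of items whose pairs currently have the weakest
accumulated evidence.

:func:`estimate_rdm` adds a second, refinement phase: each trial is
re-scaled by the least-squares scalar aligning it to the current estimate on
its own pairs, the weighted average is recomputed, and this repeats until
the estimate stabilizes.  This removes the residual scale mismatch between
trials that arranged tight versus spread-out item subsets.

:func:`run_ma_session` simulates whole sessions against a known geometry so
the estimator can be validated by parameter recovery.
"""
from __future__ import annotations

from dataclasses import dataclass
import numpy as np
from scipy.spatial.distance import pdist

from ._pairs import n_pairs, pair_indices
from .exceptions import (
    DegenerateTrialError,
    IncompleteEvidenceError,
    InvalidArgumentError,
)
from .rdm import devectorize
from .synthetic import GroundTruth, simulate_arrangement_positions

__all__ = [
    "ArrangementTrial",
    "EvidenceState",
    "trial_distances",
    "scale_trial",
    "update_estimate",
    "select_next_subset",
    "estimate_rdm",
    "run_ma_session",
]


@dataclass
class ArrangementTrial:
    """One arena arrangement: which items, where they were placed."""

    item_ids: np.ndarray
    positions: np.ndarray  # per-item 2-D coordinates, same order as item_ids
    arena_radius: float

    def __post_init__(self):
        self.item_ids = np.asarray(self.item_ids, dtype=int)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.item_ids.size < 2:
            raise InvalidArgumentError("a trial needs >= 2 items")
        if np.unique(self.item_ids).size != self.item_ids.size:
            raise InvalidArgumentError("trial item_ids must be unique")
        if self.positions.shape != (self.item_ids.size, 2):
            raise InvalidArgumentError("positions must be (n_items, 2)")
        radii = np.linalg.norm(self.positions, axis=1)
        if np.any(radii > self.arena_radius * (1 + 1e-9)):
            raise InvalidArgumentError("positions fall outside the arena disk")


@dataclass
class EvidenceState:
    """Running per-pair dissimilarity estimate and accumulated evidence.

    ``estimate`` is NaN wherever ``evidence`` is zero (no measurement yet).
    """

    n_items: int
    estimate: np.ndarray
    evidence: np.ndarray

    @classmethod
    def empty(cls, n_items: int) -> "EvidenceState":
        m = n_pairs(n_items)
        return cls(n_items=n_items, estimate=np.full(m, np.nan), evidence=np.zeros(m))

    def copy(self) -> "EvidenceState":
        return EvidenceState(self.n_items, self.estimate.copy(), self.evidence.copy())


def trial_distances(trial: ArrangementTrial) -> np.ndarray:
    """Pairwise Euclidean on-screen distances, in upper-triangle order of the
    trial's sorted item ids."""
    order = np.argsort(trial.item_ids)
    return pdist(trial.positions[order])


def scale_trial(distances: np.ndarray) -> np.ndarray:
    """Divide a distance vector by its root-mean-square (output RMS = 1)."""
    distances = np.asarray(distances, dtype=float)
    rms = np.sqrt(np.mean(distances**2))
    if rms == 0:
        raise DegenerateTrialError("all trial distances are zero")
    return distances / rms


def _trial_pairs_and_scaled(trial: ArrangementTrial, n_items: int):
    if trial.item_ids.max() >= n_items or trial.item_ids.min() < 0:
        raise InvalidArgumentError("trial items outside the state's item range")
    idx = pair_indices(trial.item_ids, n_items)
    d = scale_trial(trial_distances(trial))
    return idx, d


def update_estimate(state: EvidenceState, trial: ArrangementTrial) -> EvidenceState:
    """Fold one trial into the running weighted-average estimate.

    For each trial pair with scaled distance d, the trial contributes
    evidence w = d**2, and the pair's estimate moves to the evidence-weighted
    mean of the old estimate and d.  Pairs not in the trial are untouched.
    """
    idx, d = _trial_pairs_and_scaled(trial, state.n_items)
    new = state.copy()
    w = d**2
    old_e = new.evidence[idx]
    old_est = np.where(old_e > 0, new.estimate[idx], 0.0)
    tot = old_e + w
    upd = tot > 0
    new.estimate[idx[upd]] = (old_e[upd] * old_est[upd] + w[upd] * d[upd]) / tot[upd]
    new.evidence[idx] = tot
    return new


def select_next_subset(
    state: EvidenceState,
    subset_size: int,
    threshold: float = 1.0,
) -> np.ndarray:
    """Choose the item subset whose pairs most need more evidence.

    Greedy construction: seed with the two items of the globally
    weakest-evidence pair, then repeatedly add the item that maximizes the
    summed evidence deficit (threshold - evidence, floored at zero) over the
    pairs it newly covers.  Ties break toward the lowest item index, so the
    selection is deterministic.
    """
    n = state.n_items
    if not (3 <= subset_size <= n):
        raise InvalidArgumentError("subset_size must be in [3, n_items]")
    ii, jj = np.triu_indices(n, k=1)
    weakest = int(np.argmin(state.evidence))  # argmin takes the first = lowest pair
    chosen = [int(ii[weakest]), int(jj[weakest])]
    deficit = np.maximum(threshold - state.evidence, 0.0)
    # deficit as a symmetric matrix for fast row gathers
    dmat = devectorize_unchecked(deficit, n)
    remaining = np.setdiff1d(np.arange(n), chosen)
    while len(chosen) < subset_size:
        gains = dmat[np.ix_(remaining, chosen)].sum(axis=1)
        best = int(remaining[np.argmax(gains)])  # argmax takes first = lowest index
        chosen.append(best)
        remaining = remaining[remaining != best]
    return np.array(sorted(chosen))


def devectorize_unchecked(vector: np.ndarray, n: int) -> np.ndarray:
    """Symmetric matrix from a pair vector without RDM validation (internal)."""
    out = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    out[iu] = vector
    return out + out.T


def estimate_rdm(
    trials: list[ArrangementTrial],
    n_items: int,
    align_iters: int = 50,
    tol: float = 1e-6,
) -> np.ndarray:
    """Estimate a full RDM from a list of arrangement trials.

    Phase 1 folds every trial through :func:`update_estimate`.  Phase 2
    iteratively refines: each trial is rescaled by the least-squares scalar
    aligning its scaled distances to the current estimate on its own pairs,
    the evidence-weighted average is recomputed from the rescaled trials,
    and the estimate is renormalized to unit off-diagonal RMS; iteration
    stops when the estimate moves by less than ``tol`` in RMS or after
    ``align_iters`` rounds.  Raises :class:`IncompleteEvidenceError` if any
    pair was never measured with positive evidence.
    """
    if not trials:
        raise InvalidArgumentError("no trials given")
    m = n_pairs(n_items)
    per_trial = [_trial_pairs_and_scaled(t, n_items) for t in trials]

    evidence = np.zeros(m)
    for idx, d in per_trial:
        evidence[idx] += d**2
    if np.any(evidence == 0):
        ii, jj = np.triu_indices(n_items, k=1)
        missing = np.flatnonzero(evidence == 0)
        raise IncompleteEvidenceError(list(zip(ii[missing], jj[missing])))

    def weighted_average(scales: np.ndarray) -> np.ndarray:
        num = np.zeros(m)
        den = np.zeros(m)
        for s, (idx, d) in zip(scales, per_trial):
            ds = s * d
            w = ds**2
            np.add.at(num, idx, w * ds)
            np.add.at(den, idx, w)
        return num / den

    scales = np.ones(len(per_trial))
    est = weighted_average(scales)
    est /= np.sqrt(np.mean(est**2))
    for _ in range(align_iters):
        for k, (idx, d) in enumerate(per_trial):
            target = est[idx]
            scales[k] = float(d @ target / (d @ d))
        new = weighted_average(scales)
        new /= np.sqrt(np.mean(new**2))
        delta = np.sqrt(np.mean((new - est) ** 2))
        est = new
        if delta < tol:
            break
    return devectorize(est, n_items)


def run_ma_session(
    gt,
    first_trial_all_items: bool = True,
    subset_size: int = 8,
    evidence_threshold: float = 0.5,
    max_trials: int = 20,
    placement_noise: float = 0.0,
    seed: int = 0,
    arena_radius: float = 1.0,
) -> tuple[list[ArrangementTrial], np.ndarray]:
    """Simulate one whole MA session against a target geometry.

    ``gt`` may be a :class:`~marsa.synthetic.GroundTruth` or a bare RDM.
    The first trial presents every item; later trials present the
    weakest-evidence subsets, with arena positions generated by classical
    scaling of the target dissimilarities plus placement jitter.  The
    session stops once every pair's evidence reaches ``evidence_threshold``
    or after ``max_trials`` trials, and returns the trials together with the
    refined estimate.
    """
    if max_trials < 1:
        raise InvalidArgumentError("max_trials must be >= 1")
    target = gt.true_rdm if isinstance(gt, GroundTruth) else np.asarray(gt, dtype=float)
    n = target.shape[0]
    if not first_trial_all_items:
        raise InvalidArgumentError(
            "sessions must start with a full-set trial to guarantee pair coverage"
        )
    rng = np.random.default_rng(seed)
    state = EvidenceState.empty(n)
    trials: list[ArrangementTrial] = []
    subset = np.arange(n)
    while True:
        sub_rdm = target[np.ix_(subset, subset)]
        trial_seed = int(rng.integers(2**31))
        pos = simulate_arrangement_positions(
            sub_rdm, arena_radius, placement_noise, seed=trial_seed
        )
        trial = ArrangementTrial(item_ids=subset, positions=pos, arena_radius=arena_radius)
        trials.append(trial)
        state = update_estimate(state, trial)
        if state.evidence.min() >= evidence_threshold or len(trials) >= max_trials:
            break
        subset = select_next_subset(state, min(subset_size, n), evidence_threshold)
    return trials, estimate_rdm(trials, n)
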
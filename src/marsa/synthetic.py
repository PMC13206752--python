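"""Synthetic ground truths, behavioral cohorts, arrangement trials, and brains.

The generator plays the role of the unavailable experimental data.  It plants
known representational structure at every level of the pipeline so each stage
can be validated by parameter recovery:

* a latent item geometry (:class:`GroundTruth`) whose pairwise Euclidean
  distances define the true RDM, optionally organized into semantic
  categories;
* per-subject behavioral RDMs that mix the shared true geometry with
  subject-specific idiosyncratic geometry plus noise (:func:`simulate_subject_rdm`);
* two-modality cohorts (visual / linguistic) whose RDMs share a common source
  and carry controlled modality-unique sources (:func:`simulate_two_modalities`);
* 2-D arrangement positions consistent with a dissimilarity structure, for
  driving the multiple-arrangement estimator (:func:`simulate_arrangement_positions`);
* volumetric "brains" with representational geometry planted in designated
  voxel regions (:func:`simulate_brain`).

All source RDMs are rescaled to unit root-mean-square (off-diagonal) before
mixing, so mixture weights are directly comparable.  Noise on dissimilarities
is additive Gaussian truncated at zero and symmetrized, which preserves the
RDM invariants.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .exceptions import InvalidArgumentError
from .rdm import RDMStack

__all__ = [
    "GroundTruth",
    "CohortSpec",
    "TwoModalitySpec",
    "RegionSpec",
    "SyntheticBrain",
    "make_ground_truth",
    "unit_rms",
    "simulate_subject_rdm",
    "simulate_cohort",
    "simulate_two_modalities",
    "simulate_arrangement_positions",
    "classical_scaling",
    "ball_region",
    "simulate_brain",
]


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class GroundTruth:
    """A latent item geometry and its derived true RDM."""

    n_items: int
    coords: np.ndarray  # items x d
    categories: np.ndarray  # per-item integer label
    true_rdm: np.ndarray  # pairwise Euclidean distances of coords


def make_ground_truth(
    n_items: int,
    n_dims: int,
    n_categories: int = 1,
    cat_separation: float = 0.0,
    seed: int = 0,
    within_sd: float = 1.0,
) -> GroundTruth:
    """Sample item coordinates around category centroids.

    Centroids are drawn at random directions and rescaled so their mean
    pairwise distance equals ``cat_separation``; items are assigned to
    categories round-robin and jittered around their centroid with standard
    deviation ``within_sd``.  The true RDM is the pairwise Euclidean distance
    matrix of the coordinates.
    """
    if n_items < 3:
        raise InvalidArgumentError("n_items must be >= 3")
    if n_dims < 1:
        raise InvalidArgumentError("n_dims must be >= 1")
    if not (1 <= n_categories <= n_items):
        raise InvalidArgumentError("n_categories must be in [1, n_items]")
    if cat_separation < 0:
        raise InvalidArgumentError("cat_separation must be >= 0")
    rng = np.random.default_rng(seed)
    centroids = rng.normal(size=(n_categories, n_dims))
    if n_categories > 1 and cat_separation > 0:
        mean_sep = pdist(centroids).mean()
        centroids *= cat_separation / mean_sep
    else:
        centroids[:] = 0.0
    categories = np.arange(n_items) % n_categories
    coords = centroids[categories] + within_sd * rng.normal(size=(n_items, n_dims))
    true_rdm = squareform(pdist(coords))
    return GroundTruth(n_items=n_items, coords=coords, categories=categories, true_rdm=true_rdm)


def unit_rms(rdm: np.ndarray) -> np.ndarray:
    """Rescale so the off-diagonal entries have root-mean-square 1."""
    rdm = np.asarray(rdm, dtype=float)
    iu = np.triu_indices(rdm.shape[0], k=1)
    rms = np.sqrt(np.mean(rdm[iu] ** 2))
    if rms == 0:
        raise InvalidArgumentError("cannot rescale an all-zero RDM")
    return rdm / rms


def _random_geometry_rdm(n_items: int, n_dims: int, rng: np.random.Generator) -> np.ndarray:
    coords = rng.normal(size=(n_items, n_dims))
    return squareform(pdist(coords))


def _add_truncated_noise(rdm: np.ndarray, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Additive Gaussian noise on the upper triangle, floored at zero, symmetrized."""
    n = rdm.shape[0]
    iu = np.triu_indices(n, k=1)
    vec = rdm[iu]
    if noise_sd > 0:
        vec = np.maximum(vec + noise_sd * rng.normal(size=vec.size), 0.0)
    out = np.zeros_like(rdm)
    out[iu] = vec
    return out + out.T


# ---------------------------------------------------------------------------
# behavioral cohorts


@dataclass
class CohortSpec:
    """How to generate one cohort of per-subject behavioral RDMs."""

    n_subjects: int
    shared_w: float = 1.0
    idio_w: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise InvalidArgumentError("n_subjects must be >= 1")
        if self.shared_w < 0 or self.idio_w < 0:
            raise InvalidArgumentError("mixture weights must be >= 0")
        if self.shared_w + self.idio_w <= 0:
            raise InvalidArgumentError("shared_w + idio_w must be > 0")
        if self.noise_sd < 0:
            raise InvalidArgumentError("noise_sd must be >= 0")


def simulate_subject_rdm(gt: GroundTruth, spec: CohortSpec, subject_index: int) -> np.ndarray:
    """One subject's behavioral RDM: shared + idiosyncratic mixture plus noise.

    The subject-specific geometry is an independent random configuration in
    the ground truth's latent dimensionality; both sources are rescaled to
    unit RMS before mixing so the weights are comparable.
    """
    if not (0 <= subject_index < spec.n_subjects):
        raise InvalidArgumentError("subject_index out of range")
    rng = np.random.default_rng([spec.seed, subject_index])
    mix = spec.shared_w * unit_rms(gt.true_rdm)
    if spec.idio_w > 0:
        idio = _random_geometry_rdm(gt.n_items, gt.coords.shape[1], rng)
        mix = mix + spec.idio_w * unit_rms(idio)
    else:
        rng.normal(size=(gt.n_items, gt.coords.shape[1]))  # keep stream aligned
    return _add_truncated_noise(mix, spec.noise_sd, rng)


def simulate_cohort(gt: GroundTruth, spec: CohortSpec) -> RDMStack:
    """Stack of all subjects' RDMs for one cohort."""
    mats = [simulate_subject_rdm(gt, spec, s) for s in range(spec.n_subjects)]
    return RDMStack.from_matrices(mats, labels=[f"sub{s:02d}" for s in range(spec.n_subjects)])


# ---------------------------------------------------------------------------
# two modalities with shared and unique sources


@dataclass
class TwoModalitySpec:
    """Mixture weights for a visual + linguistic cohort with planted overlap."""

    shared_w: float = 1.0
    unique_visual_w: float = 0.0
    unique_linguistic_w: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for w in (self.shared_w, self.unique_visual_w, self.unique_linguistic_w):
            if w < 0:
                raise InvalidArgumentError("weights must be >= 0")
        if self.shared_w + self.unique_visual_w + self.unique_linguistic_w <= 0:
            raise InvalidArgumentError("at least one mixture weight must be > 0")
        if self.noise_sd < 0:
            raise InvalidArgumentError("noise_sd must be >= 0")


def simulate_two_modalities(
    gt: GroundTruth,
    spec: TwoModalitySpec,
    n_subjects: int,
) -> tuple[RDMStack, RDMStack, dict[str, np.ndarray]]:
    """Visual and linguistic RDM stacks with controlled shared/unique structure.

    The shared source is the ground-truth RDM; the two unique sources are
    independent random geometries (independent of each other and of the
    shared source).  Every subject of a modality mixes the same sources with
    the spec's weights; subjects differ only through the truncated additive
    noise.  The sources are returned so recovery tests can compare against
    them.
    """
    if n_subjects < 2:
        raise InvalidArgumentError("n_subjects must be >= 2")
    d = gt.coords.shape[1]
    shared = unit_rms(gt.true_rdm)
    uv_rng = np.random.default_rng([spec.seed, 101])
    ul_rng = np.random.default_rng([spec.seed, 102])
    unique_visual = unit_rms(_random_geometry_rdm(gt.n_items, d, uv_rng))
    unique_linguistic = unit_rms(_random_geometry_rdm(gt.n_items, d, ul_rng))
    sources = {
        "shared": shared,
        "unique_visual": unique_visual,
        "unique_linguistic": unique_linguistic,
    }

    def _stack(unique_rdm: np.ndarray, unique_w: float, code: int) -> RDMStack:
        mats = []
        for s in range(n_subjects):
            rng = np.random.default_rng([spec.seed, code, s])
            mix = spec.shared_w * shared + unique_w * unique_rdm
            mats.append(_add_truncated_noise(mix, spec.noise_sd, rng))
        return RDMStack.from_matrices(mats, labels=[f"sub{s:02d}" for s in range(n_subjects)])

    visual = _stack(unique_visual, spec.unique_visual_w, 1)
    linguistic = _stack(unique_linguistic, spec.unique_linguistic_w, 2)
    return visual, linguistic, sources


# ---------------------------------------------------------------------------
# arrangement positions


def classical_scaling(rdm: np.ndarray, n_dims: int) -> np.ndarray:
    """Classical (Torgerson) scaling: embed an RDM in ``n_dims`` dimensions.

    Double-centers the squared dissimilarities and keeps the top eigenpairs;
    dimensions with non-positive eigenvalues contribute zero coordinates.
    For a Euclidean-embeddable RDM of intrinsic dimension <= n_dims the
    embedding reproduces the distances exactly.
    """
    d = np.asarray(rdm, dtype=float)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:n_dims]
    vals = np.clip(vals[order], 0.0, None)
    coords = vecs[:, order] * np.sqrt(vals)
    if coords.shape[1] < n_dims:
        coords = np.pad(coords, ((0, 0), (0, n_dims - coords.shape[1])))
    return coords


def simulate_arrangement_positions(
    d_subset: np.ndarray,
    arena_radius: float,
    placement_noise: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """2-D arena positions whose distances reflect the given dissimilarities.

    The subset RDM is embedded with classical scaling (top 2 dimensions),
    rescaled so the maximum pairwise distance equals 0.9 of the arena
    diameter, jittered isotropically with scale ``placement_noise``, and
    clipped to the arena disk.
    """
    d_subset = np.asarray(d_subset, dtype=float)
    if d_subset.shape[0] < 2:
        raise InvalidArgumentError("need >= 2 items to arrange")
    if arena_radius <= 0:
        raise InvalidArgumentError("arena_radius must be > 0")
    if placement_noise < 0:
        raise InvalidArgumentError("placement_noise must be >= 0")
    pos = classical_scaling(d_subset, 2)
    dists = pdist(pos)
    max_d = dists.max() if dists.size else 0.0
    if max_d > 0:
        pos *= 0.9 * (2 * arena_radius) / max_d
    # a skewed configuration can reach past the arena even after the diameter
    # rule; shrink uniformly (preserves proportionality) rather than clip it
    max_r = np.linalg.norm(pos, axis=1).max()
    if max_r > arena_radius:
        pos *= arena_radius / max_r
    if placement_noise > 0:
        rng = np.random.default_rng(seed)
        pos = pos + placement_noise * rng.normal(size=pos.shape)
    radii = np.linalg.norm(pos, axis=1)
    over = radii > arena_radius
    if np.any(over):
        pos[over] *= (arena_radius / radii[over])[:, None]
    return pos


# ---------------------------------------------------------------------------
# synthetic brains


@dataclass
class RegionSpec:
    """A planted region: voxel coordinates, source-geometry index, amplitude."""

    voxels: np.ndarray  # (m, 3) integer coordinates
    source: int
    amplitude: float = 1.0

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=int)
        if self.voxels.ndim != 2 or self.voxels.shape[1] != 3:
            raise InvalidArgumentError("region voxels must be an (m, 3) array")


@dataclass
class SyntheticBrain:
    """One subject's synthetic volume: mask, item x voxel patterns, plants."""

    mask: np.ndarray  # 3-D boolean
    patterns: np.ndarray  # items x n_in_mask_voxels
    planted_regions: list = field(default_factory=list)


def ball_region(center, radius: float, shape) -> np.ndarray:
    """All integer voxel coordinates within Euclidean ``radius`` of ``center``."""
    center = np.asarray(center)
    grids = np.mgrid[0 : shape[0], 0 : shape[1], 0 : shape[2]]
    coords = np.stack([g.ravel() for g in grids], axis=1)
    keep = ((coords - center) ** 2).sum(axis=1) <= radius**2
    return coords[keep]


def _sphere_lift(source_rdm: np.ndarray, max_dims: int) -> np.ndarray:
    """Embed a source RDM and lift the configuration onto a sphere.

    Classical scaling recovers coordinates whose Euclidean distances match
    the source; an extra norm-equalizing coordinate places every item on a
    common sphere of radius well above the configuration spread.  On the
    sphere, cosine (hence correlation) distance is monotone in chord
    distance, so the correlation-distance RDM of the planted patterns tracks
    the source RDM's rank order.
    """
    n = source_rdm.shape[0]
    coords = classical_scaling(source_rdm, min(n - 1, max_dims))
    # drop all-zero trailing dimensions
    keep = np.flatnonzero(np.abs(coords).max(axis=0) > 1e-12)
    coords = coords[:, keep] if keep.size else coords[:, :1]
    norms2 = (coords**2).sum(axis=1)
    big = 9.0 * max(norms2.max(), 1e-12)
    lift = np.sqrt(big - norms2)
    return np.column_stack([coords, lift])


def simulate_brain(
    sources: list[np.ndarray],
    mask_shape: tuple[int, int, int],
    region_specs: list[RegionSpec],
    noise_sd: float,
    n_subjects: int,
    seed: int = 0,
    n_items: int | None = None,
) -> list[SyntheticBrain]:
    """Per-subject volumes with source geometry planted in designated regions.

    Within a planted region, item patterns are the sphere-lifted embedding of
    the source RDM projected through a random orthonormal, zero-column-sum
    voxel loading (so pattern correlations equal latent cosines exactly),
    scaled to unit RMS times the region amplitude, plus Gaussian noise of
    scale ``noise_sd``.  Outside regions the volume is pure noise.
    """
    if n_subjects < 1:
        raise InvalidArgumentError("n_subjects must be >= 1")
    if noise_sd < 0:
        raise InvalidArgumentError("noise_sd must be >= 0")
    mask = np.ones(mask_shape, dtype=bool)
    n_vox = int(mask.sum())
    # linear index of each voxel in the canonical in-mask ordering
    lin = -np.ones(mask_shape, dtype=int)
    lin[mask] = np.arange(n_vox)

    seen = set()
    for rs in region_specs:
        for v in map(tuple, rs.voxels):
            if any(c < 0 for c in v) or any(c >= s for c, s in zip(v, mask_shape)):
                raise InvalidArgumentError(f"region voxel {v} outside the grid")
            if v in seen:
                raise InvalidArgumentError(f"regions overlap at voxel {v}")
            seen.add(v)
        if rs.source < 0 or rs.source >= len(sources):
            raise InvalidArgumentError(f"region references unknown source {rs.source}")

    if n_items is None:
        if not sources:
            raise InvalidArgumentError("n_items required when no sources are given")
        n_items = sources[0].shape[0]
    for s in sources:
        if s.shape[0] != n_items:
            raise InvalidArgumentError("all sources must cover the same items")

    brains = []
    for subj in range(n_subjects):
        rng = np.random.default_rng([seed, subj])
        patterns = noise_sd * rng.normal(size=(n_items, n_vox))
        planted = []
        for rs in region_specs:
            cols = lin[rs.voxels[:, 0], rs.voxels[:, 1], rs.voxels[:, 2]]
            m = cols.size
            z = _sphere_lift(sources[rs.source], max_dims=m - 2)
            k = z.shape[1]
            if k + 1 > m:
                raise InvalidArgumentError(
                    f"region of {m} voxels too small for a {k}-dimensional plant"
                )
            # random loading with orthonormal, zero-sum columns
            raw = rng.normal(size=(m, k))
            raw -= raw.mean(axis=0, keepdims=True)
            q, _ = np.linalg.qr(raw)
            signal = z @ q.T
            signal *= rs.amplitude / np.sqrt(np.mean(signal**2))
            patterns[:, cols] += signal
            planted.append((rs.voxels, sources[rs.source], rs.amplitude))
        brains.append(SyntheticBrain(mask=mask, patterns=patterns, planted_regions=planted))
    return brains
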
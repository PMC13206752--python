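"""Spherical searchlight neighborhoods and per-center correlation-distance RDMs.

A searchlight sweeps a sphere of voxels over the brain volume; at every
in-mask center the correlation-distance RDM of the item activity patterns
within the sphere characterizes the local representational geometry.  The
radius is measured in voxel units on an isotropic grid with an inclusive
boundary (offsets with squared norm <= radius**2 belong to the sphere).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._pairs import n_pairs
from .exceptions import DegeneratePatternError, InvalidArgumentError
from .rdm import corrdist_rdm, vectorize

__all__ = [
    "VoxelMask",
    "SearchlightIndex",
    "BrainRDMField",
    "sphere_offsets",
    "build_index",
    "field_rdms",
]


@dataclass
class VoxelMask:
    """3-D boolean grid of voxels included in the analysis."""

    inside: np.ndarray

    def __post_init__(self):
        self.inside = np.asarray(self.inside, dtype=bool)
        if self.inside.ndim != 3:
            raise InvalidArgumentError("mask must be 3-D")
        if not self.inside.any():
            raise InvalidArgumentError("mask has no in-mask voxels")

    @property
    def shape(self):
        return self.inside.shape

    @property
    def n_voxels(self) -> int:
        return int(self.inside.sum())


@dataclass
class SearchlightIndex:
    """Per-center spherical neighborhoods, as in-mask linear voxel indices.

    The in-mask linear ordering is the C-order scan of the mask (the order
    of ``np.argwhere(mask)``), the same ordering used for pattern columns.
    """

    radius: float
    centers: np.ndarray  # (n_centers, 3) voxel coordinates
    neighborhoods: list  # per-center int arrays
    dropped: np.ndarray = field(default_factory=lambda: np.empty((0, 3), dtype=int))


@dataclass
class BrainRDMField:
    """One vectorized RDM per searchlight center."""

    n_items: int
    centers: np.ndarray
    vectors: np.ndarray  # (n_centers, n_pairs)
    skipped: list = field(default_factory=list)

    def __post_init__(self):
        if self.vectors.shape[1] != n_pairs(self.n_items):
            raise InvalidArgumentError("field vectors do not match n_items")


def sphere_offsets(radius: float) -> np.ndarray:
    """All integer 3-D offsets within Euclidean ``radius`` of the origin."""
    if radius < 0:
        raise InvalidArgumentError("radius must be >= 0")
    r = int(np.floor(radius))
    rng = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(rng, rng, rng, indexing="ij")
    offsets = np.stack([dx.ravel(), dy.ravel(), dz.ravel()], axis=1)
    keep = (offsets**2).sum(axis=1) <= radius**2
    return offsets[keep]


def build_index(mask: VoxelMask, radius: float, min_voxels: int = 10) -> SearchlightIndex:
    """One neighborhood per in-mask voxel; small neighborhoods are dropped.

    Centers whose in-mask neighborhood has fewer than ``min_voxels`` members
    are excluded from ``centers`` and reported in ``dropped``.
    """
    if radius < 1:
        raise InvalidArgumentError("radius must be >= 1")
    offsets = sphere_offsets(radius)
    shape = mask.shape
    lin = -np.ones(shape, dtype=int)
    coords = np.argwhere(mask.inside)
    lin[mask.inside] = np.arange(coords.shape[0])
    centers, neighborhoods, dropped = [], [], []
    for c in coords:
        pts = c + offsets
        ok = np.all((pts >= 0) & (pts < np.asarray(shape)), axis=1)
        pts = pts[ok]
        members = lin[pts[:, 0], pts[:, 1], pts[:, 2]]
        members = members[members >= 0]
        if members.size < min_voxels:
            dropped.append(c)
            continue
        centers.append(c)
        neighborhoods.append(np.sort(members))
    if not centers:
        import warnings

        warnings.warn("no searchlight center meets min_voxels; index is empty")
    return SearchlightIndex(
        radius=radius,
        centers=np.array(centers, dtype=int).reshape(-1, 3),
        neighborhoods=neighborhoods,
        dropped=np.array(dropped, dtype=int).reshape(-1, 3),
    )


def field_rdms(
    patterns: np.ndarray,
    index: SearchlightIndex,
    policy: str = "strict",
) -> BrainRDMField:
    """Correlation-distance RDM at every searchlight center.

    ``patterns`` is items x in-mask-voxels, with columns in the index's
    in-mask linear order.  Under ``policy="strict"`` a zero-variance item
    pattern within any neighborhood raises; under ``"lenient"`` the affected
    centers are dropped and reported in ``skipped``.
    """
    patterns = np.asarray(patterns, dtype=float)
    if policy not in ("strict", "lenient"):
        raise InvalidArgumentError("policy must be 'strict' or 'lenient'")
    n_items = patterns.shape[0]
    kept_centers, rows, skipped = [], [], []
    for center, nb in zip(index.centers, index.neighborhoods):
        sub = patterns[:, nb]
        try:
            rows.append(vectorize(corrdist_rdm(sub)))
            kept_centers.append(center)
        except DegeneratePatternError:
            if policy == "strict":
                raise
            skipped.append(tuple(center))
    vectors = (
        np.array(rows) if rows else np.empty((0, n_pairs(n_items)))
    )
    return BrainRDMField(
        n_items=n_items,
        centers=np.array(kept_centers, dtype=int).reshape(-1, 3),
        vectors=vectors,
        skipped=skipped,
    )
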
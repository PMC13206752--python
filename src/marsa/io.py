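"""Standard-format I/O: TSV matrices and logs, RDM stacks, NIfTI volumes."""
from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .exceptions import InvalidArgumentError
from .ma import ArrangementTrial
from .rdm import RDMStack, devectorize, validate_rdm, vectorize

__all__ = [
    "write_rdm_tsv",
    "read_rdm_tsv",
    "write_stack",
    "read_stack",
    "write_trials_tsv",
    "read_trials_tsv",
    "save_patterns_nifti",
    "load_patterns_nifti",
    "save_map_nifti",
]


def write_rdm_tsv(rdm: np.ndarray, path, item_ids=None) -> None:
    """Square-matrix TSV with an item-id header row and column."""
    rdm = validate_rdm(rdm)
    n = rdm.shape[0]
    ids = list(item_ids) if item_ids is not None else [f"item{i:03d}" for i in range(n)]
    pd.DataFrame(rdm, index=ids, columns=ids).to_csv(path, sep="\t", float_format="%.10g")


def read_rdm_tsv(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return validate_rdm(df.to_numpy(dtype=float))


def write_stack(stack: RDMStack, directory) -> None:
    """One TSV square matrix per row plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = []
    for label, vec in zip(stack.labels, stack.vectors):
        fname = f"{label}.tsv"
        write_rdm_tsv(devectorize(vec, stack.n_items), directory / fname)
        files.append(fname)
    manifest = {"n_items": stack.n_items, "labels": stack.labels, "files": files}
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def read_stack(directory) -> RDMStack:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    vectors = [vectorize(read_rdm_tsv(directory / f)) for f in manifest["files"]]
    return RDMStack(
        n_items=manifest["n_items"], vectors=np.stack(vectors), labels=manifest["labels"]
    )


def write_trials_tsv(trials: list[ArrangementTrial], path) -> None:
    """Arrangement log with columns trial, item_id, x, y."""
    rows = []
    for t, trial in enumerate(trials):
        for item, (x, y) in zip(trial.item_ids, trial.positions):
            rows.append({"trial": t, "item_id": int(item), "x": x, "y": y})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_trials_tsv(path, arena_radius: float | None = None) -> list[ArrangementTrial]:
    """Rebuild trials from an arrangement log.

    If ``arena_radius`` is not given, each trial's radius is taken as the
    largest item distance from the arena center within that trial.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"trial", "item_id", "x", "y"}
    if not required.issubset(df.columns):
        raise InvalidArgumentError(f"trials TSV must have columns {sorted(required)}")
    trials = []
    for _, grp in df.groupby("trial", sort=True):
        pos = grp[["x", "y"]].to_numpy(dtype=float)
        radius = arena_radius
        if radius is None:
            radius = float(np.linalg.norm(pos, axis=1).max())
        trials.append(
            ArrangementTrial(
                item_ids=grp["item_id"].to_numpy(dtype=int),
                positions=pos,
                arena_radius=radius,
            )
        )
    return trials


def save_patterns_nifti(patterns: np.ndarray, mask: np.ndarray, vol_path, mask_path) -> None:
    """Items x voxels patterns as a 4-D NIfTI (items on the 4th axis) + mask."""
    mask = np.asarray(mask, dtype=bool)
    n_items = patterns.shape[0]
    vol = np.zeros(mask.shape + (n_items,), dtype=np.float64)
    vol[mask, :] = patterns.T
    affine = np.eye(4)
    nib.save(nib.Nifti1Image(vol, affine), str(vol_path))
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), str(mask_path))


def load_patterns_nifti(vol_path, mask_path) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`save_patterns_nifti` (canonical in-mask voxel order)."""
    mask = np.asarray(nib.load(str(mask_path)).get_fdata()) > 0
    vol = np.asarray(nib.load(str(vol_path)).get_fdata())
    if vol.shape[:3] != mask.shape:
        raise InvalidArgumentError("volume and mask shapes differ")
    return vol[mask, :].T, mask


def save_map_nifti(values: np.ndarray, centers: np.ndarray, mask_shape, path) -> None:
    """Per-center statistic written back into a 3-D volume (NaN elsewhere)."""
    vol = np.full(mask_shape, np.nan, dtype=np.float64)
    centers = np.asarray(centers, dtype=int)
    vol[centers[:, 0], centers[:, 1], centers[:, 2]] = values
    nib.save(nib.Nifti1Image(vol, np.eye(4)), str(path))
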
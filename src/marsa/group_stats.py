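"""Group-level inference over per-subject fit maps and model-comparison tables.

Per-center fits (fold-averaged Pearson correlations) are tested across
subjects with a one-sample t-test against zero — one-sided by default, since
the question is whether behavior predicts the local geometry at all — and
corrected over all centers jointly with Benjamini–Hochberg FDR.  Model
comparisons (e.g. two network variants across training seeds) use paired
differences per cell with the same machinery.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import DegenerateTestError, InvalidArgumentError

__all__ = [
    "GroupMap",
    "ComparisonTable",
    "one_sided_t",
    "fdr_bh",
    "group_map",
    "paired_difference_test",
    "comparison_table",
]


@dataclass
class GroupMap:
    """Per-center group statistics for a cohort of subject fit maps."""

    centers: np.ndarray
    fits: np.ndarray  # centers x subjects
    mean_map: np.ndarray
    t_map: np.ndarray
    p_map: np.ndarray
    fdr_mask: np.ndarray
    q: float


@dataclass
class ComparisonTable:
    """Cell-wise paired model comparison with FDR across cells."""

    cells: list  # (layer, timestep) keys
    mean_diff: np.ndarray
    sem_a: np.ndarray
    sem_b: np.ndarray
    t: np.ndarray
    p: np.ndarray
    q_reject: np.ndarray
    sidedness: str

    def to_dataframe(self) -> pd.DataFrame:
        layers, steps = zip(*self.cells)
        return pd.DataFrame(
            {
                "layer": layers,
                "timestep": steps,
                "mean_diff": self.mean_diff,
                "sem_a": self.sem_a,
                "sem_b": self.sem_b,
                "t": self.t,
                "p": self.p,
                "q_reject": self.q_reject,
            }
        )


def one_sided_t(values: np.ndarray, null_value: float = 0.0) -> tuple[float, float]:
    """One-sample t against ``null_value`` with an upper-tail p-value."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise DegenerateTestError("need >= 2 values for a t-test")
    if np.ptp(values) == 0:
        raise DegenerateTestError("zero variance across values")
    res = stats.ttest_1samp(values, null_value, alternative="greater")
    return float(res.statistic), float(res.pvalue)


def fdr_bh(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini–Hochberg step-up rejection mask at level ``q``."""
    p_values = np.asarray(p_values, dtype=float)
    if p_values.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any(p_values <= 0) or np.any(p_values > 1):
        raise InvalidArgumentError("p-values must lie in (0, 1]")
    reject, *_ = multipletests(p_values, alpha=q, method="fdr_bh")
    return reject


def group_map(
    fit_maps: list[np.ndarray],
    centers: np.ndarray,
    q: float = 0.05,
) -> GroupMap:
    """Mean map plus per-center one-sided t, p, and joint FDR mask.

    ``fit_maps`` holds one per-center fit array per subject; all must be
    aligned to the same ``centers``.
    """
    if len(fit_maps) < 2:
        raise DegenerateTestError("group statistics need >= 2 subjects")
    lengths = {np.asarray(m).shape for m in fit_maps}
    if len(lengths) != 1:
        raise InvalidArgumentError("subject maps are misaligned (different centers)")
    fits = np.column_stack([np.asarray(m, dtype=float) for m in fit_maps])
    if fits.shape[0] != np.asarray(centers).shape[0]:
        raise InvalidArgumentError("centers do not match map length")
    if not np.all(np.isfinite(fits)):
        raise InvalidArgumentError("non-finite fits; drop degenerate centers first")
    t_map = np.empty(fits.shape[0])
    p_map = np.empty(fits.shape[0])
    for c in range(fits.shape[0]):
        t_map[c], p_map[c] = one_sided_t(fits[c])
    return GroupMap(
        centers=np.asarray(centers),
        fits=fits,
        mean_map=fits.mean(axis=1),
        t_map=t_map,
        p_map=p_map,
        fdr_mask=fdr_bh(p_map, q),
        q=q,
    )


def paired_difference_test(
    fits_a: np.ndarray,
    fits_b: np.ndarray,
    sidedness: str = "one",
) -> tuple[float, float, float]:
    """Mean difference, t, and p for paired fits A - B against zero."""
    fits_a = np.asarray(fits_a, dtype=float)
    fits_b = np.asarray(fits_b, dtype=float)
    if fits_a.shape != fits_b.shape or fits_a.size < 2:
        raise InvalidArgumentError("paired fits must have equal length >= 2")
    if sidedness not in ("one", "two"):
        raise InvalidArgumentError("sidedness must be 'one' or 'two'")
    diff = fits_a - fits_b
    if np.ptp(diff) == 0:
        if diff[0] == 0:  # identical fits: t = 0 is well defined
            return 0.0, 0.0, 0.5 if sidedness == "one" else 1.0
        raise DegenerateTestError("zero variance in paired differences")
    alt = "greater" if sidedness == "one" else "two-sided"
    res = stats.ttest_1samp(diff, 0.0, alternative=alt)
    return float(diff.mean()), float(res.statistic), float(res.pvalue)


def comparison_table(
    fits_a: dict,
    fits_b: dict,
    q: float = 0.05,
    sidedness: str = "one",
) -> ComparisonTable:
    """Per-cell paired tests with FDR across all (layer, timestep) cells.

    ``fits_a`` and ``fits_b`` map (layer, timestep) keys to per-seed fit
    arrays; seeds must be matched across models within each cell.
    """
    if set(fits_a) != set(fits_b):
        raise InvalidArgumentError("models have different cells")
    cells = sorted(fits_a)
    mean_diff, sem_a, sem_b, ts, ps = [], [], [], [], []
    for cell in cells:
        a = np.asarray(fits_a[cell], dtype=float)
        b = np.asarray(fits_b[cell], dtype=float)
        if a.shape != b.shape:
            raise InvalidArgumentError(f"cell {cell}: unmatched seed counts")
        d, t, p = paired_difference_test(a, b, sidedness)
        mean_diff.append(d)
        ts.append(t)
        ps.append(p)
        sem_a.append(stats.sem(a))
        sem_b.append(stats.sem(b))
    ps = np.array(ps)
    return ComparisonTable(
        cells=cells,
        mean_diff=np.array(mean_diff),
        sem_a=np.array(sem_a),
        sem_b=np.array(sem_b),
        t=np.array(ts),
        p=ps,
        q_reject=fdr_bh(ps, q),
        sidedness=sidedness,
    )
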
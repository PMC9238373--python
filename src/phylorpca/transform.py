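"""Compositional transforms: closure, robust clr, and the phylogenetic rclr.

The robust centered log-ratio (rclr) takes the log of each count and centers
it by the log geometric mean over the *observed* (nonzero) entries of the
sample, leaving zeros as missing rather than imputing them.  The phylogenetic
variant first expands the table to every tree node, closes each sample to
proportions, and weights each node column by its branch length before the
rclr — so a node's value is log(branch-length x aggregated proportion) minus
the sample's observed log-mean.  All logs are natural.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phylo import ExpandedTable, Phylogeny, expand_table

logger = logging.getLogger("phylorpca")

__all__ = ["MaskedLogMatrix", "closure", "rclr", "double_center", "phylo_rclr"]


@dataclass
class MaskedLogMatrix:
    """Real matrix defined only on observed entries.

    ``values`` holds NaN wherever ``mask`` is False; ``mask`` is True exactly
    where the underlying (weighted) count was positive.
    """

    values: pd.DataFrame
    mask: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        vals = self.values.to_numpy()
        msk = self.mask.to_numpy(dtype=bool)
        if np.isnan(vals[msk]).any():
            raise ValueError("NaN value at an observed (masked-in) entry")

    @classmethod
    def from_values(cls, values: pd.DataFrame) -> "MaskedLogMatrix":
        return cls(values, ~values.isna())

    def copy(self) -> "MaskedLogMatrix":
        return MaskedLogMatrix(self.values.copy(), self.mask.copy())

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def closure(matrix: pd.DataFrame) -> pd.DataFrame:
    """Close each sample (row) to proportions summing to one."""
    vals = matrix.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("negative entries")
    totals = vals.sum(axis=1)
    if (totals == 0).any():
        bad = list(matrix.index[totals == 0])
        raise ValueError(f"empty sample (all-zero row): {bad[:5]}")
    return pd.DataFrame(
        vals / totals[:, None], index=matrix.index, columns=matrix.columns
    )


def rclr(matrix: pd.DataFrame) -> MaskedLogMatrix:
    """Robust clr: log counts centered by the observed-entry log mean per row.

    Zeros become missing (masked out).  On a dense row this is the classic
    clr; it is invariant to per-sample rescaling.
    """
    vals = matrix.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("negative entries")
    observed = vals > 0
    if (~observed).all(axis=1).any():
        raise ValueError("sample with no observed entries")
    logs = np.full(vals.shape, np.nan)
    np.log(vals, out=logs, where=observed)
    row_means = np.nanmean(np.where(observed, logs, np.nan), axis=1)
    out = np.where(observed, logs - row_means[:, None], np.nan)
    values = pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    mask = pd.DataFrame(observed, index=matrix.index, columns=matrix.columns)
    return MaskedLogMatrix(values, mask)


def double_center(
    m: MaskedLogMatrix, tol: float = 1e-8, max_iter: int = 100
) -> MaskedLogMatrix:
    """Remove row and column means over observed entries, alternating.

    On masked data simultaneous row+column centering has no one-pass
    solution, so row and column means are removed in turn until every
    observed-entry row and column mean is below ``tol`` in absolute value.
    Masked entries stay untouched (NaN).
    """
    vals = m.values.to_numpy(dtype=float).copy()
    msk = m.mask.to_numpy(dtype=bool)
    work = np.where(msk, vals, np.nan)
    for _ in range(max_iter):
        row_means = np.nanmean(work, axis=1)
        work = work - row_means[:, None]
        col_means = np.nanmean(work, axis=0)
        work = work - col_means[None, :]
        resid = max(
            np.nanmax(np.abs(np.nanmean(work, axis=1))),
            np.nanmax(np.abs(np.nanmean(work, axis=0))),
        )
        if resid < tol:
            break
    else:
        warnings.warn(
            f"double centering did not reach tol={tol:g} in {max_iter} "
            f"iterations (residual {resid:.3g}); returning best iterate",
            RuntimeWarning,
            stacklevel=2,
        )
    values = pd.DataFrame(work, index=m.values.index, columns=m.values.columns)
    return MaskedLogMatrix(values, m.mask.copy())


def phylo_rclr(
    table: pd.DataFrame, tree: Phylogeny
) -> tuple[MaskedLogMatrix, ExpandedTable, pd.Series]:
    """Phylogenetic rclr of a samples x features count table.

    Pipeline: expand the table to all non-root tree nodes, close each sample
    to proportions, multiply each node column by its branch-length weight,
    then apply the rclr.  An entry is observed iff the node's aggregated
    count is positive (zero-weight nodes were already dropped by expansion).
    """
    expanded, weights = expand_table(table, tree)
    closed = closure(expanded.counts)
    weighted = closed * weights.to_numpy()[None, :]
    return rclr(weighted), expanded, weights
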
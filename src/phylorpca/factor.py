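"""Masked low-rank factorization of (phylo-)rclr matrices.

RPCA here means: double-center the rclr matrix over its observed entries,
fit a rank-r factorization by alternating least squares restricted to the
observed mask (a matrix-completion fit), and read the ordination off the
SVD of the completed low-rank reconstruction.  Sample scores are the
singular-value-scaled left vectors; feature loadings (tips and internal
nodes in the phylogenetic case) are the right vectors; the beta-diversity
distance between two samples is the Euclidean distance between their scores.

CTF extends this to repeated measures: samples are arranged into a
subject x node x state tensor (missing cells masked) and fitted by a masked
CP decomposition; subject scores come from the SVD of the subject-mode
unfolding of the reconstruction, so a one-state tensor reduces exactly to
RPCA.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, OrdinationResults

from .phylo import Phylogeny
from .transform import MaskedLogMatrix, double_center, phylo_rclr, rclr

logger = logging.getLogger("phylorpca")

__all__ = ["FactorizationResult", "masked_factorize", "rpca", "ctf", "rank_loadings"]

_RIDGE = 1e-12  # tiny Tikhonov term keeping the batched normal equations SPD


@dataclass
class FactorizationResult:
    """Orthonormal factors of a masked low-rank fit.

    Iterating yields ``(u, s, v)`` so the result unpacks like a thin SVD.
    ``objective`` records the masked sum of squared residuals per ALS sweep
    (nonincreasing).
    """

    u: np.ndarray
    s: np.ndarray
    v: np.ndarray
    objective: list[float] = field(default_factory=list)
    converged: bool = True

    def __iter__(self):
        return iter((self.u, self.s, self.v))


def _batched_solve(mask: np.ndarray, target: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """Row-wise masked least squares: for each row i solve
    min ||mask_i * (target_i - x_i @ basis.T)||^2."""
    r = basis.shape[1]
    # normal matrices: A_i = basis[obs_i].T @ basis[obs_i]
    gram = np.einsum("jk,jl->jkl", basis, basis)  # (p, r, r)
    a = np.tensordot(mask, gram, axes=(1, 0))  # (n, r, r)
    # ridge scaled to each normal matrix so sparse rows stay solvable
    scale = np.trace(a, axis1=1, axis2=2) / r
    a += (_RIDGE * (scale[:, None, None] + 1.0)) * np.eye(r)[None, :, :]
    b = (mask * target) @ basis  # (n, r)
    return np.linalg.solve(a, b[:, :, None])[:, :, 0]


def masked_factorize(
    m: MaskedLogMatrix,
    rank: int,
    max_iter: int = 1000,
    tol: float = 1e-8,
    seed: int = 0,
    center: bool = True,
) -> FactorizationResult:
    """Rank-``rank`` completion of a masked matrix by alternating least squares.

    The matrix is double-centered over its observed entries first (disable
    with ``center=False`` to complete a raw masked matrix).  Factors
    are initialized from a seeded uniform(-0.5, 0.5)/sqrt(rank) draw; sweeps
    alternate exact row and column least-squares updates (each sweep cannot
    increase the masked residual), stopping when the relative objective
    change drops below ``tol``.  The returned factors are the thin SVD of
    the completed reconstruction, so ``u`` and ``v`` are orthonormal and
    ``s`` is nonincreasing.
    """
    n, p = m.shape
    if rank < 1 or rank > min(n, p):
        raise ValueError(f"rank {rank} outside [1, min(n, p)={min(n, p)}]")
    msk = m.mask.to_numpy(dtype=bool)
    if (~msk).all(axis=1).any():
        raise ValueError("row with no observed entries")
    if (~msk).all(axis=0).any():
        raise ValueError("column with no observed entries")

    centered = double_center(m) if center else m
    y = np.nan_to_num(centered.values.to_numpy(dtype=float), nan=0.0)
    w = msk.astype(float)

    # warm start from the SVD of the zero-filled matrix (random cold starts
    # can stall on a degenerate ray for very sparse masks), plus a small
    # seeded uniform perturbation so runs remain a seeded family
    rng = np.random.default_rng(seed)
    _, _, vt0 = np.linalg.svd(y, full_matrices=False)
    v = vt0[:rank].T + 1e-3 * rng.uniform(-0.5, 0.5, size=(p, rank)) / np.sqrt(rank)
    u = np.zeros((n, rank))
    objective: list[float] = []
    converged = False
    for _ in range(max_iter):
        u = _batched_solve(w, y, v)
        v = _batched_solve(w.T, y.T, u)
        resid = w * (y - u @ v.T)
        obj = float(np.sum(resid * resid))
        objective.append(obj)
        if len(objective) > 1:
            prev = objective[-2]
            if prev - obj <= tol * max(prev, 1e-300):
                converged = True
                break
    if not converged:
        warnings.warn(
            f"masked ALS did not converge in {max_iter} iterations",
            RuntimeWarning,
            stacklevel=2,
        )
    uu, ss, vvt = np.linalg.svd(u @ v.T, full_matrices=False)
    uu, ss, vv = uu[:, :rank], ss[:rank], vvt[:rank].T
    # deterministic sign: largest-magnitude loading of each axis is positive
    for k in range(rank):
        j = np.argmax(np.abs(vv[:, k]))
        if vv[j, k] < 0:
            vv[:, k] = -vv[:, k]
            uu[:, k] = -uu[:, k]
    return FactorizationResult(uu, ss, vv, objective, converged)


def _drop_unobserved_columns(m: MaskedLogMatrix) -> MaskedLogMatrix:
    """Drop feature columns observed in no sample (all-zero features)."""
    observed = m.mask.to_numpy(dtype=bool).any(axis=0)
    if observed.all():
        return m
    logger.info("dropped %d never-observed feature columns", int((~observed).sum()))
    keep = m.values.columns[observed]
    return MaskedLogMatrix(m.values[keep], m.mask[keep])


def _observed_ss(m: MaskedLogMatrix) -> float:
    centered = double_center(m)
    vals = centered.values.to_numpy()
    return float(np.nansum(vals * vals))


def _proportion_explained(s: np.ndarray, total_ss: float) -> np.ndarray:
    denom = max(total_ss, float(np.sum(s**2)))
    if denom <= 0:
        return np.zeros_like(s)
    return s**2 / denom


def _ordination(
    u: np.ndarray,
    s: np.ndarray,
    v: np.ndarray,
    sample_ids,
    feature_ids,
    total_ss: float,
    method: str,
) -> tuple[OrdinationResults, DistanceMatrix]:
    rank = len(s)
    axes = [f"PC{k + 1}" for k in range(rank)]
    scores = u * s[None, :]
    ordination = OrdinationResults(
        short_method_name=method,
        long_method_name=f"{method} masked low-rank ordination",
        eigvals=pd.Series(s, index=axes),
        samples=pd.DataFrame(scores, index=list(sample_ids), columns=axes),
        features=pd.DataFrame(v, index=list(feature_ids), columns=axes),
        proportion_explained=pd.Series(_proportion_explained(s, total_ss), index=axes),
    )
    dm = DistanceMatrix(squareform(pdist(scores)), ids=list(sample_ids))
    return ordination, dm


def _clamped_rank(rank: int, n_samples: int) -> int:
    if n_samples < rank + 1:
        new_rank = max(1, n_samples - 1)
        warnings.warn(
            f"rank {rank} too large for {n_samples} samples; clamped to {new_rank}",
            RuntimeWarning,
            stacklevel=3,
        )
        return new_rank
    return rank


def rpca(
    table: pd.DataFrame,
    tree: Phylogeny | None = None,
    rank: int = 3,
    min_feature_count: int = 0,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-8,
) -> tuple[OrdinationResults, DistanceMatrix]:
    """(Phylogenetic) RPCA of a samples x features count table.

    With a tree, the table is expanded to all tree nodes and transformed by
    the phylogenetic rclr; without one, the plain rclr is used.  Features
    with total count <= ``min_feature_count`` are removed first.  Returns
    the ordination (scores, loadings, eigenvalues) and the Euclidean
    distance matrix on the singular-value-scaled sample scores.
    """
    if table.empty:
        raise ValueError("empty table")
    if min_feature_count > 0:
        keep = table.sum(axis=0) > min_feature_count
        n_removed = int((~keep).sum())
        if n_removed:
            logger.info("min_feature_count=%d removed %d features", min_feature_count, n_removed)
        table = table.loc[:, keep]
        if table.shape[1] == 0:
            raise ValueError("min_feature_count filter removed all features")
    rank = _clamped_rank(rank, table.shape[0])
    if tree is not None:
        mlm, _, _ = phylo_rclr(table, tree)
        method = "phylo-RPCA"
    else:
        mlm = rclr(table)
        method = "RPCA"
    mlm = _drop_unobserved_columns(mlm)
    fit = masked_factorize(mlm, rank=rank, max_iter=max_iter, tol=tol, seed=seed)
    return _ordination(
        fit.u, fit.s, fit.v,
        mlm.values.index, mlm.values.columns,
        _observed_ss(mlm), method,
    )


# ---------------------------------------------------------------------------
# CTF: masked CP decomposition of the subject x node x state tensor
# ---------------------------------------------------------------------------

def _cp_mode_update(
    mask: np.ndarray, y: np.ndarray, f1: np.ndarray, f2: np.ndarray
) -> np.ndarray:
    """Least-squares update of one CP factor with the other two fixed.

    ``mask``/``y`` are arranged (mode, d1, d2) with ``f1`` over d1 and
    ``f2`` over d2.
    """
    r = f1.shape[1]
    # per-slice normal matrices G_m = sum_{d1,d2} mask (f1 f1^T) o (f2 f2^T)
    p = np.einsum("mjk,jr,js->mkrs", mask, f1, f1)  # (mode, d2, r, r)
    c = np.einsum("kr,ks->krs", f2, f2)  # (d2, r, r)
    g = np.einsum("mkrs,krs->mrs", p, c)
    scale = np.trace(g, axis1=1, axis2=2) / r
    g += (_RIDGE * (scale[:, None, None] + 1.0)) * np.eye(r)[None, :, :]
    b = np.einsum("mjk,jr,kr->mr", mask * y, f1, f2)
    return np.linalg.solve(g, b[:, :, None])[:, :, 0]


def ctf(
    table: pd.DataFrame,
    tree: Phylogeny | None,
    metadata: pd.DataFrame,
    subject_col: str,
    state_col: str,
    rank: int = 3,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-10,
) -> tuple[OrdinationResults, DistanceMatrix, pd.DataFrame]:
    """Compositional tensor factorization for repeated-measures designs.

    Each sample must map through ``metadata`` to a unique (subject, state)
    pair; states are unordered categories.  The (phylo-)rclr matrix is
    double-centered, arranged as a subject x node x state tensor with
    missing cells masked, and fitted with a masked CP decomposition
    (alternating least squares, seeded init).  Subject scores and distances
    are read off the SVD of the subject-mode unfolding of the low-rank
    reconstruction; the per-state factor matrix is returned alongside.
    """
    if table.empty:
        raise ValueError("empty table")
    missing = set(table.index) - set(metadata.index)
    if missing:
        raise ValueError(f"samples missing from metadata: {sorted(missing)[:5]}")
    meta = metadata.loc[list(table.index)]
    for col in (subject_col, state_col):
        if col not in meta.columns:
            raise ValueError(f"metadata column {col!r} not found")
    pairs = list(zip(meta[subject_col].astype(str), meta[state_col].astype(str)))
    if len(set(pairs)) != len(pairs):
        dupes = sorted({p for p in pairs if pairs.count(p) > 1})
        raise ValueError(f"duplicated (subject, state) pairs: {dupes[:5]}")

    if tree is not None:
        mlm, _, _ = phylo_rclr(table, tree)
        method = "phylo-CTF"
    else:
        mlm = rclr(table)
        method = "CTF"
    mlm = _drop_unobserved_columns(mlm)
    centered = double_center(mlm)
    y2d = np.nan_to_num(centered.values.to_numpy(dtype=float), nan=0.0)
    m2d = centered.mask.to_numpy(dtype=bool)

    subjects = sorted(set(p[0] for p in pairs))
    states = sorted(set(p[1] for p in pairs))
    nodes = list(centered.values.columns)
    rank = _clamped_rank(rank, len(subjects))
    s_ix = {s: i for i, s in enumerate(subjects)}
    t_ix = {t: i for i, t in enumerate(states)}
    n_s, n_p, n_t = len(subjects), len(nodes), len(states)
    y = np.zeros((n_s, n_p, n_t))
    w = np.zeros((n_s, n_p, n_t))
    for row, (subj, st) in enumerate(pairs):
        y[s_ix[subj], :, t_ix[st]] = y2d[row]
        w[s_ix[subj], :, t_ix[st]] = m2d[row]

    # SVD warm starts on the three unfoldings (same rationale as the matrix
    # case), perturbed by a small seeded uniform draw
    rng = np.random.default_rng(seed)

    def _warm(unfolded: np.ndarray, dim: int) -> np.ndarray:
        u0, _, _ = np.linalg.svd(unfolded, full_matrices=False)
        base = u0[:, : min(rank, u0.shape[1])]
        if base.shape[1] < rank:  # degenerate mode (e.g. a single state)
            base = np.hstack([base, np.ones((dim, rank - base.shape[1]))])
        return base + 1e-3 * rng.uniform(-0.5, 0.5, size=(dim, rank)) / np.sqrt(rank)

    a = _warm(y.reshape(n_s, -1), n_s)
    b = _warm(np.transpose(y, (1, 0, 2)).reshape(n_p, -1), n_p)
    c = _warm(np.transpose(y, (2, 0, 1)).reshape(n_t, -1), n_t)
    objective: list[float] = []
    for _ in range(max_iter):
        a = _cp_mode_update(w, y, b, c)
        b = _cp_mode_update(
            np.transpose(w, (1, 0, 2)), np.transpose(y, (1, 0, 2)), a, c
        )
        c = _cp_mode_update(
            np.transpose(w, (2, 0, 1)), np.transpose(y, (2, 0, 1)), a, b
        )
        recon = np.einsum("ir,jr,kr->ijk", a, b, c)
        resid = w * (y - recon)
        obj = float(np.sum(resid * resid))
        objective.append(obj)
        if len(objective) > 1 and objective[-2] - obj <= tol * max(objective[-2], 1e-300):
            break

    recon = np.einsum("ir,jr,kr->ijk", a, b, c)
    unfolded = recon.reshape(n_s, n_p * n_t)
    uu, ss, _ = np.linalg.svd(unfolded, full_matrices=False)
    uu, ss = uu[:, :rank], ss[:rank]
    for k in range(rank):
        j = np.argmax(np.abs(uu[:, k]))
        if uu[j, k] < 0:
            uu[:, k] = -uu[:, k]
    node_norms = np.linalg.norm(b, axis=0)
    node_norms[node_norms == 0] = 1.0
    total_ss = float(np.sum(np.nan_to_num(centered.values.to_numpy()) ** 2))
    ordination, dm = _ordination(
        uu, ss, b / node_norms[None, :], subjects, nodes, total_ss, method
    )
    state_loadings = pd.DataFrame(
        c, index=states, columns=[f"PC{k + 1}" for k in range(rank)]
    )
    return ordination, dm, state_loadings


def rank_loadings(
    ordination: OrdinationResults, axis: int, top_k: int
) -> tuple[list[tuple[str, float]], list[tuple[str, float]]]:
    """Top positively and negatively loaded nodes on an ordination axis.

    ``axis`` is 1-based.  Returns ``(positive, negative)``: the ``top_k``
    most positive loadings in decreasing order and the ``top_k`` most
    negative in increasing order, as ``(node_id, loading)`` pairs.
    """
    rank = ordination.features.shape[1]
    if not 1 <= axis <= rank:
        raise ValueError(f"axis {axis} out of range [1, {rank}]")
    loadings = ordination.features.iloc[:, axis - 1].sort_values()
    n = len(loadings)
    if top_k > n:
        warnings.warn(
            f"top_k={top_k} exceeds {n} nodes; clamped", RuntimeWarning, stacklevel=2
        )
        top_k = n
    positive = [(i, float(v)) for i, v in loadings.iloc[::-1][:top_k].items()]
    negative = [(i, float(v)) for i, v in loadings.iloc[:top_k].items()]
    return positive, negative
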
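"""Snapshot-matrix statistics: destabilization index and SVD state-space.

The destabilization (critical-transition) index of an m-gene x c-cell
snapshot X is the ratio

    I_C = <|R(gene_i, gene_j)|> / <|R(cell_i, cell_j)|>,

the mean absolute pairwise Pearson correlation over gene vectors (rows)
divided by that over cell vectors (columns). As an attractor destabilizes
toward a bifurcation, cells disperse along the soft eigen-direction —
cell-cell correlation falls — while gene fluctuations align with that
direction — gene-gene correlation rises — so I_C increases toward a
maximum at the bifurcation. The orientation (genes in the numerator) is
fixed by that monotonicity requirement.

The SVD state-space is the complementary geometric view: gene-wise
mean-centred data decomposed into orthonormal "eigengene" axes (left
singular vectors, one weight per gene) onto which cells or new samples
are projected.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .grn import SnapshotMatrix

__all__ = [
    "IndexResult", "StateSpace", "mean_abs_pairwise_correlation",
    "critical_index", "svd_statespace", "project",
]

DEFAULT_PAIR_CAP = 10**6


@dataclass(frozen=True)
class IndexResult:
    """Destabilization index with its two correlation components."""

    value: float
    gene_correlation: float   # numerator: mean |r| over gene-vector pairs
    cell_correlation: float   # denominator: mean |r| over cell-vector pairs
    n_gene_pairs: int
    n_cell_pairs: int
    n_excluded_gene_pairs: int
    n_excluded_cell_pairs: int


def _pairwise_mean_abs_r(
    matrix: np.ndarray,
    pair_cap: int | None,
    rng: np.random.Generator | None,
) -> tuple[float, int, int]:
    """Mean |Pearson r| over unordered row pairs of ``matrix``.

    Zero-variance rows are excluded; returns (mean, n_pairs_used,
    n_pairs_excluded). Pairs are uniformly subsampled (seeded) when their
    count exceeds ``pair_cap``.
    """
    matrix = np.asarray(matrix, dtype=float)
    n, length = matrix.shape
    if length < 3:
        raise ValueError("vectors must have length at least 3")
    sd = matrix.std(axis=1)
    usable = sd > 0
    n_use = int(usable.sum())
    total_pairs = n * (n - 1) // 2
    used_pairs = n_use * (n_use - 1) // 2
    excluded = total_pairs - used_pairs
    if n_use < 2:
        if n < 2:
            raise ValueError("need at least 2 vectors")
        raise ValueError("all pairs excluded: fewer than 2 vectors with variance")
    sub = matrix[usable]
    if pair_cap is not None and used_pairs > pair_cap:
        if rng is None:
            raise ValueError("pair subsampling requires a random generator")
        parts_i: list[np.ndarray] = []
        parts_j: list[np.ndarray] = []
        have = 0
        while have < pair_cap:
            draw = 2 * (pair_cap - have) + 8
            ci = rng.integers(0, n_use, size=draw)
            cj = rng.integers(0, n_use, size=draw)
            keep = ci < cj
            parts_i.append(ci[keep])
            parts_j.append(cj[keep])
            have += int(keep.sum())
        ii = np.concatenate(parts_i)[:pair_cap]
        jj = np.concatenate(parts_j)[:pair_cap]
        centred = sub - sub.mean(axis=1, keepdims=True)
        normed = centred / np.linalg.norm(centred, axis=1, keepdims=True)
        r = np.einsum("ij,ij->i", normed[ii], normed[jj])
        return float(np.mean(np.abs(r))), int(ii.size), excluded
    corr = np.corrcoef(sub)
    iu = np.triu_indices(n_use, k=1)
    return float(np.mean(np.abs(corr[iu]))), used_pairs, excluded


def mean_abs_pairwise_correlation(
    vectors: Sequence[np.ndarray] | np.ndarray,
) -> tuple[float, int]:
    """Mean absolute Pearson correlation over all unordered vector pairs.

    Pairs involving a zero-variance vector are excluded. Returns
    ``(mean_abs_r, n_excluded_pairs)``.
    """
    matrix = np.asarray(vectors, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2:
        raise ValueError("need at least 2 equal-length vectors")
    value, _, excluded = _pairwise_mean_abs_r(matrix, pair_cap=None, rng=None)
    return value, excluded


def critical_index(
    X: SnapshotMatrix | np.ndarray,
    pair_subsample: int | None = DEFAULT_PAIR_CAP,
    rng: np.random.Generator | None = None,
) -> IndexResult:
    """Destabilization index I_C of a snapshot matrix.

    Numerator: mean |r| over gene-vector (row) pairs; denominator: mean
    |r| over cell-vector (column) pairs. Zero-variance vectors are
    excluded from both; a matrix where either axis has fewer than two
    usable vectors is degenerate and raises.
    """
    values = X.values if isinstance(X, SnapshotMatrix) else np.asarray(X, float)
    if values.ndim != 2 or min(values.shape) < 2:
        raise ValueError("snapshot must be at least 2 genes x 2 cells")
    if rng is None and pair_subsample is not None:
        rng = np.random.default_rng(0)
    try:
        num, n_gp, ex_gp = _pairwise_mean_abs_r(values, pair_subsample, rng)
        den, n_cp, ex_cp = _pairwise_mean_abs_r(values.T, pair_subsample, rng)
    except ValueError as err:
        raise ValueError(f"degenerate snapshot matrix: {err}") from err
    if den <= 0:
        raise ValueError("degenerate snapshot matrix: zero cell-pair correlation")
    return IndexResult(value=num / den, gene_correlation=num,
                       cell_correlation=den, n_gene_pairs=n_gp,
                       n_cell_pairs=n_cp, n_excluded_gene_pairs=ex_gp,
                       n_excluded_cell_pairs=ex_cp)


@dataclass
class StateSpace:
    """SVD state-space: orthonormal eigengene axes and cell projections."""

    eigengenes: np.ndarray        # (m, k), columns unit-norm
    singular_values: np.ndarray   # (k,)
    projections: np.ndarray       # (k, c): cells in state-space coordinates
    centering: np.ndarray         # (m,) gene-wise mean removed before the SVD
    explained_variance_ratio: np.ndarray

    def project(self, X_new: SnapshotMatrix | np.ndarray) -> np.ndarray:
        return project(self, X_new)


def svd_statespace(
    X: SnapshotMatrix | np.ndarray | Sequence[SnapshotMatrix],
    n_components: int = 2,
) -> StateSpace:
    """Construct a state-space from one snapshot or a set of snapshots.

    Snapshots in a set are concatenated cell-wise (same genes). Data are
    gene-wise mean-centred and decomposed; eigengenes are the leading left
    singular vectors with a deterministic sign convention (the
    largest-magnitude weight of each axis is positive).
    """
    if isinstance(X, (list, tuple)):
        values = np.concatenate(
            [m.values if isinstance(m, SnapshotMatrix) else np.asarray(m, float)
             for m in X], axis=1)
    else:
        values = X.values if isinstance(X, SnapshotMatrix) else np.asarray(X, float)
    m, c = values.shape
    if not 1 <= n_components <= min(m, c):
        raise ValueError(f"n_components must be in [1, {min(m, c)}]")
    centering = values.mean(axis=1)
    centred = values - centering[:, None]
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    u, s, vt = u[:, :n_components], s[:n_components], vt[:n_components]
    # sign convention: largest-|weight| gene of each eigengene is positive
    flip = np.sign(u[np.argmax(np.abs(u), axis=0), np.arange(n_components)])
    flip[flip == 0] = 1.0
    u = u * flip
    vt = vt * flip[:, None]
    total_var = float((centred**2).sum())
    evr = (s**2) / total_var if total_var > 0 else np.zeros_like(s)
    return StateSpace(eigengenes=u, singular_values=s,
                      projections=s[:, None] * vt, centering=centering,
                      explained_variance_ratio=evr)


def project(statespace: StateSpace, X_new: SnapshotMatrix | np.ndarray) -> np.ndarray:
    """Project new samples (genes x samples, or a single gene vector) onto
    the stored eigengene axes after removing the stored centering."""
    values = (X_new.values if isinstance(X_new, SnapshotMatrix)
              else np.asarray(X_new, dtype=float))
    squeeze = values.ndim == 1
    if squeeze:
        values = values[:, None]
    if values.shape[0] != statespace.centering.shape[0]:
        raise ValueError(
            f"gene dimension mismatch: expected {statespace.centering.shape[0]}, "
            f"got {values.shape[0]}")
    coords = statespace.eigengenes.T @ (values - statespace.centering[:, None])
    return coords[:, 0] if squeeze else coords
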
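"""Distance-matrix mathematics for conformational ensembles.

The central objects are the C-alpha pair-distance matrix d of a conformer and
per-pair statistics taken over an ensemble:

* delta = d^A - d^B, the signed difference-distance matrix;
* dRMSD(A, B) = sqrt( mean over the N(N-1)/2 unordered pairs of
  (d^A_ij - d^B_ij)^2 ), a superposition-free dissimilarity;
* F, the fluctuation matrix of per-pair distance variances (population
  variance, A^2);
* X, the flexibility matrix of per-pair distance ranges (max - min, A);
* Theta = sqrt( mean of in-scope off-diagonal F entries ), which equals the
  RMS dRMSD of each frame to the ensemble-mean distance matrix;
* Delta, the per-pair mean absolute deviation from a reference matrix.

dRMSD averages over unordered pairs, and F uses the population variance
(divide by K): these two conventions together make the Theta identity exact.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .types import (
    CalphaConformer,
    ConformerEnsemble,
    DifferenceMatrix,
    DistanceMatrix,
    OverallFluctuation,
    PairStatMatrix,
    ResidueSelection,
)

__all__ = [
    "distance_matrix",
    "difference_matrix",
    "drmsd",
    "pair_distance_vectors",
    "fluctuation_matrix",
    "flexibility_matrix",
    "overall_fluctuation",
    "mean_abs_difference_matrix",
    "cross_submatrix",
    "matrix_correlation",
    "superposed_rmsd",
]


def _apply_selection(
    conf: CalphaConformer, selection: ResidueSelection | None
) -> CalphaConformer:
    if selection is None:
        return conf
    if selection.indices and max(selection.indices) >= conf.n_residues:
        raise IndexError("selection index out of range")
    return conf.subset(selection.indices)


def distance_matrix(
    conf: CalphaConformer, selection: ResidueSelection | None = None
) -> DistanceMatrix:
    """Euclidean C-alpha pair-distance matrix of one conformer."""
    sub = _apply_selection(conf, selection)
    if sub.n_residues < 2:
        raise ValueError("need at least 2 residues after selection")
    return DistanceMatrix(
        values=squareform(pdist(sub.coords)), labels=sub.residue_labels
    )


def difference_matrix(a: DistanceMatrix, b: DistanceMatrix) -> DifferenceMatrix:
    """Signed difference-distance matrix delta = d^A - d^B.

    Positive entries mark residue pairs further apart in A than in B.
    """
    if a.values.shape != b.values.shape:
        raise ValueError("distance matrices must have equal shape")
    return DifferenceMatrix(values=a.values - b.values, labels=a.labels)


def _condensed(values: np.ndarray) -> np.ndarray:
    """Upper-triangle (unordered-pair) entries of a square matrix."""
    n = values.shape[0]
    iu = np.triu_indices(n, k=1)
    return values[iu]


def drmsd(a: DistanceMatrix, b: DistanceMatrix) -> float:
    """Distance RMSD between two structures.

    Square root of the mean, over the N(N-1)/2 unordered residue pairs, of
    the squared pair-distance differences. Independent of superposition and a
    pseudometric (it is a scaled Euclidean norm on pair-distance vectors).
    """
    if a.values.shape != b.values.shape:
        raise ValueError("distance matrices must have equal shape")
    diff = _condensed(a.values) - _condensed(b.values)
    return float(np.sqrt(np.mean(diff**2)))


def pair_distance_vectors(
    ens: ConformerEnsemble, selection: ResidueSelection | None = None
) -> np.ndarray:
    """Condensed pair-distance vectors of every frame, shape (K, N(N-1)/2).

    dRMSD between two frames equals ``norm(v_a - v_b) / sqrt(P)`` where P is
    the pair count; all ensemble statistics below are computed on this array.
    """
    idx = selection.indices if selection is not None else None
    coords = ens.coords_array()
    if idx is not None:
        coords = coords[:, idx, :]
    if coords.shape[1] < 2:
        raise ValueError("need at least 2 residues after selection")
    return np.stack([pdist(c) for c in coords])


def _selected_labels(ens: ConformerEnsemble, selection: ResidueSelection | None):
    if selection is None:
        return ens.residue_labels
    return [ens.residue_labels[i] for i in selection.indices]


def fluctuation_matrix(
    ens: ConformerEnsemble, selection: ResidueSelection | None = None
) -> PairStatMatrix:
    """Fluctuation matrix F: per-pair population variance of distances (A^2)."""
    if ens.n_frames < 2:
        raise ValueError("fluctuation matrix needs at least 2 frames")
    vecs = pair_distance_vectors(ens, selection)
    var = vecs.var(axis=0)  # population variance: divide by K
    return PairStatMatrix(
        values=squareform(var), kind="fluctuation",
        labels=_selected_labels(ens, selection),
    )


def flexibility_matrix(
    ens: ConformerEnsemble, selection: ResidueSelection | None = None
) -> PairStatMatrix:
    """Flexibility matrix X: per-pair distance range max - min (A)."""
    if ens.n_frames < 2:
        raise ValueError("flexibility matrix needs at least 2 frames")
    vecs = pair_distance_vectors(ens, selection)
    rng = vecs.max(axis=0) - vecs.min(axis=0)
    return PairStatMatrix(
        values=squareform(rng), kind="flexibility",
        labels=_selected_labels(ens, selection),
    )


def _scope_mask(
    n: int, selection: ResidueSelection | None, pair_scope: str
) -> np.ndarray:
    """Boolean mask over condensed pair entries selecting the Theta scope."""
    if pair_scope == "all_pairs":
        return np.ones(n * (n - 1) // 2, dtype=bool)
    if pair_scope != "cross_block":
        raise ValueError("pair_scope must be 'all_pairs' or 'cross_block'")
    if selection is None or len(selection.blocks) != 2:
        raise ValueError("cross_block scope requires a selection with two blocks")
    names = list(selection.blocks)
    a = set(selection.local_block(names[0]))
    b = set(selection.local_block(names[1]))
    mask = np.zeros((n, n), dtype=bool)
    for i in a:
        for j in b:
            mask[min(i, j), max(i, j)] = True
    return mask[np.triu_indices(n, k=1)]


def overall_fluctuation(
    ens: ConformerEnsemble,
    selection: ResidueSelection | None = None,
    pair_scope: str = "all_pairs",
) -> OverallFluctuation:
    """Overall fluctuation Theta (A).

    Theta^2 is the mean of the in-scope off-diagonal entries of F; with the
    population-variance convention this is identically the mean squared dRMSD
    of the frames to the ensemble-mean distance matrix. ``cross_block``
    restricts the mean to strand x helix pairs of a two-block selection.
    """
    if ens.n_frames < 2:
        raise ValueError("overall fluctuation needs at least 2 frames")
    vecs = pair_distance_vectors(ens, selection)
    n = len(_selected_labels(ens, selection))
    mask = _scope_mask(n, selection, pair_scope)
    if not mask.any():
        raise ValueError("empty pair scope")
    var = vecs[:, mask].var(axis=0)
    return OverallFluctuation(
        theta=float(np.sqrt(var.mean())),
        n_residues=n,
        n_frames=ens.n_frames,
        pair_scope=pair_scope,
    )


def mean_abs_difference_matrix(
    ens_subset: ConformerEnsemble,
    reference: DistanceMatrix,
    selection: ResidueSelection | None = None,
) -> PairStatMatrix:
    """Mean absolute difference matrix Delta vs a reference structure (A).

    Per-pair mean over the given frames of |d^frame_ij - d^ref_ij|; used to
    localise which pair distances change most between a ligand-bound
    reference and its nearest apo-simulation snapshots.
    """
    vecs = pair_distance_vectors(ens_subset, selection)
    ref = _condensed(reference.values)
    if vecs.shape[1] != ref.shape[0]:
        raise ValueError("reference shape incompatible with ensemble selection")
    delta = np.abs(vecs - ref).mean(axis=0)
    return PairStatMatrix(
        values=squareform(delta), kind="mean_abs_diff",
        labels=_selected_labels(ens_subset, selection),
    )


def cross_submatrix(
    values: np.ndarray,
    selection: ResidueSelection,
    block_a: str,
    block_b: str,
) -> tuple[np.ndarray, list, list]:
    """Rectangular cross-block submatrix (e.g. the 5x10 strand-vs-helix view).

    Returns (submatrix, row_labels, col_labels) where rows follow block_a and
    columns block_b of the selection the matrix was computed over.
    """
    if block_a == block_b:
        raise ValueError("overlapping blocks: block_a and block_b must differ")
    ia = selection.local_block(block_a)
    ib = selection.local_block(block_b)
    if set(ia) & set(ib):
        raise ValueError("overlapping blocks")
    n = values.shape[0]
    if max(ia + ib) >= n:
        raise IndexError("block index out of matrix range")
    sub = values[np.ix_(ia, ib)]
    return sub, ia, ib


def matrix_correlation(m1: np.ndarray, m2: np.ndarray) -> float:
    """Pearson correlation between two pair-statistic matrices.

    Square operands are compared over their upper-triangle off-diagonal
    entries (each unordered pair counted once); rectangular cross-block
    submatrices over all entries.
    """
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    if m1.shape != m2.shape:
        raise ValueError("matrices must have equal shape")
    if m1.ndim != 2:
        raise ValueError("inputs must be 2-D matrices")
    if m1.shape[0] == m1.shape[1]:
        x, y = _condensed(m1), _condensed(m2)
    else:
        x, y = m1.ravel(), m2.ravel()
    if x.size < 3:
        raise ValueError("need at least 3 in-scope entries")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in correlation operand")
    return float(np.corrcoef(x, y)[0, 1])


def superposed_rmsd(
    a: CalphaConformer,
    b: CalphaConformer,
    pairs: list[tuple[int, int]] | None = None,
) -> float:
    """Coordinate RMSD after optimal rigid-body superposition.

    Uses the closed-form least-squares (Kabsch) rotation with reflections
    excluded. ``pairs`` maps residue indices of ``a`` onto those of ``b``;
    identity mapping when omitted.
    """
    if pairs is None:
        if a.n_residues != b.n_residues:
            raise ValueError("conformers differ in size; provide index pairs")
        pairs = [(i, i) for i in range(a.n_residues)]
    if len(pairs) < 3:
        raise ValueError("need at least 3 residue pairs")
    pa = a.coords[[i for i, _ in pairs]]
    pb = b.coords[[j for _, j in pairs]]
    xa = pa - pa.mean(axis=0)
    xb = pb - pb.mean(axis=0)
    # collinear point sets leave the rotation underdetermined
    if np.linalg.matrix_rank(xa, tol=1e-9) < 2 or np.linalg.matrix_rank(xb, tol=1e-9) < 2:
        raise ValueError("degenerate (collinear) point sets")
    cov = xb.T @ xa
    u, s, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    diff = xb - xa @ rot.T
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))
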
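"""Conformational-state analysis: dRMSD k-means, silhouette validation,
medoids/outliers, and classical multidimensional scaling.

Clustering operates in distance-matrix space. Each frame is represented by
its condensed pair-distance vector v (the N(N-1)/2 upper-triangle entries of
its C-alpha distance matrix), so that dRMSD(A, B) = ||v_A - v_B|| / sqrt(P).
A cluster centroid is the mean distance matrix C_i of its members, which need
not correspond to a realisable 3-D conformation; the objective minimised is
the within-cluster sum of squared dRMSD values (WCSS, A^2).

Estimators follow scikit-learn conventions (``fit``, ``labels_``,
``inertia_``); the module-level functions wrap them for ensemble inputs.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin
from sklearn.utils.validation import check_random_state

from .distances import pair_distance_vectors
from .types import (
    CalphaConformer,
    ClusterResult,
    ConformerEnsemble,
    DissimilarityMatrix,
    EmbeddingResult,
    ResidueSelection,
)

__all__ = [
    "DRMSDKMeans",
    "ClassicalMDS",
    "dissimilarity_matrix",
    "strided_frame_indices",
    "kmeans_states",
    "silhouette_validate",
    "select_k",
    "medoid",
    "find_outliers",
    "cmds_embed",
    "assign_to_clusters",
]


class DRMSDKMeans(BaseEstimator, ClusterMixin):
    """k-means over condensed pair-distance vectors with the dRMSD metric.

    Lloyd alternation: assign each frame to the cluster whose mean distance
    matrix minimises dRMSD, then recompute the means. Initialisation is a
    greedy farthest-point sweep from a seeded random first centre; the best of
    ``n_init`` restarts (lowest WCSS) is kept. Empty clusters are re-seeded
    with the frame farthest from its current centroid.

    Parameters
    ----------
    n_clusters : int
        Number of states k.
    n_init : int
        Independent seeded restarts.
    max_iter : int
        Lloyd iteration cap per restart.
    tol : float
        Stop when the WCSS improvement falls below this (A^2), or when
        assignments stop changing.
    random_state : int or None
        Seed for the restart initialisation.

    Attributes
    ----------
    labels_ : (K,) int array of 0-based cluster assignments.
    cluster_centers_ : (k, P) mean condensed distance vectors C_i.
    inertia_ : within-cluster sum of squared dRMSD (the WCSS, A^2).
    n_iter_ : Lloyd iterations of the winning restart.
    wcss_history_ : per-iteration WCSS of the winning restart (non-increasing).
    """

    def __init__(
        self,
        n_clusters: int = 2,
        n_init: int = 10,
        max_iter: int = 300,
        tol: float = 1e-10,
        random_state: int | None = None,
    ):
        self.n_clusters = n_clusters
        self.n_init = n_init
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def _wcss(self, X: np.ndarray, centers: np.ndarray, labels: np.ndarray) -> float:
        p = X.shape[1]
        return float(np.sum((X - centers[labels]) ** 2) / p)

    def _single_run(self, X: np.ndarray, rng: np.random.Generator):
        n, k = X.shape[0], self.n_clusters
        # greedy farthest-point seeding from a random first centre
        first = int(rng.integers(n))
        centers_idx = [first]
        d2 = np.sum((X - X[first]) ** 2, axis=1)
        for _ in range(k - 1):
            nxt = int(np.argmax(d2))
            centers_idx.append(nxt)
            d2 = np.minimum(d2, np.sum((X - X[nxt]) ** 2, axis=1))
        centers = X[centers_idx].copy()
        labels = np.zeros(n, dtype=int)
        history: list[float] = []
        prev_wcss = np.inf
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            d2all = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
            new_labels = np.argmin(d2all, axis=1)
            # re-seed any emptied cluster with the worst-fitting frame
            for c in range(k):
                if not np.any(new_labels == c):
                    worst = int(np.argmax(d2all[np.arange(n), new_labels]))
                    new_labels[worst] = c
                    d2all[worst, :] = np.inf
                    d2all[worst, c] = 0.0
            wcss = self._wcss(X, centers, new_labels)
            history.append(wcss)
            changed = not np.array_equal(new_labels, labels)
            labels = new_labels
            for c in range(k):
                centers[c] = X[labels == c].mean(axis=0)
            if not changed or prev_wcss - wcss < self.tol:
                break
            prev_wcss = wcss
        final = self._wcss(X, centers, labels)
        history.append(final)
        return labels, centers, final, n_iter, history

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be a (K, P) array of pair-distance vectors")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.n_clusters > X.shape[0]:
            raise ValueError("n_clusters cannot exceed the number of frames")
        rng = check_random_state(self.random_state)
        gen = np.random.default_rng(rng.randint(2**31))
        best = None
        for _ in range(max(1, self.n_init)):
            out = self._single_run(X, gen)
            if best is None or out[2] < best[2]:
                best = out
        labels, centers, wcss, n_iter, history = best
        self.labels_ = labels
        self.cluster_centers_ = centers
        self.inertia_ = wcss
        self.n_iter_ = n_iter
        self.wcss_history_ = history
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        d2 = ((X[:, None, :] - self.cluster_centers_[None, :, :]) ** 2).sum(axis=2)
        return np.argmin(d2, axis=1)

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


class ClassicalMDS(BaseEstimator, TransformerMixin):
    """Classical (Torgerson-Gower) multidimensional scaling.

    Double-centres the squared dissimilarity matrix, B = -1/2 J D^2 J,
    eigendecomposes it and takes coordinates from the top ``n_components``
    nonnegative eigenvalues. Distances between Euclidean-embeddable inputs are
    reproduced exactly. Axis signs are canonicalised so the largest-magnitude
    loading on each axis is positive, making outputs reproducible.

    Attributes
    ----------
    embedding_ : (M, n_components) coordinates.
    eigenvalues_ : full spectrum, descending (negative values recorded but
        never used for coordinates).
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y=None):
        D = np.asarray(X, dtype=float)
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValueError("X must be a square dissimilarity matrix")
        m = D.shape[0]
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if m < self.n_components + 1:
            raise ValueError("need at least n_components + 1 objects")
        J = np.eye(m) - np.ones((m, m)) / m
        B = -0.5 * J @ (D**2) @ J
        B = (B + B.T) / 2
        evals, evecs = np.linalg.eigh(B)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        self.eigenvalues_ = evals
        if np.allclose(D, 0):
            warnings.warn("all-zero dissimilarities: returning zero coordinates")
            self.embedding_ = np.zeros((m, self.n_components))
            return self
        coords = np.zeros((m, self.n_components))
        cutoff = max(evals[0], 0.0) * 1e-12  # noise floor of the spectrum
        for a in range(self.n_components):
            if evals[a] > cutoff:
                axis = evecs[:, a] * np.sqrt(evals[a])
                i = int(np.argmax(np.abs(axis)))
                if axis[i] < 0:
                    axis = -axis
                coords[:, a] = axis
        self.embedding_ = coords
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).embedding_

    def transform(self, X):
        raise NotImplementedError(
            "classical MDS has no out-of-sample transform; use fit_transform"
        )


def strided_frame_indices(
    ens: ConformerEnsemble, stride: int = 1, burn_in: float = 0.0
) -> np.ndarray:
    """Frame indices kept after burn-in (ps) and striding (frames).

    Frame times come from ``frame_times`` when present; otherwise the i-th
    saved snapshot is taken at (i+1)*dt (snapshot 1 saved dt after the run
    start). Frames at times >= burn_in are kept, then every ``stride``-th.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    k = ens.n_frames
    if burn_in > 0:
        if ens.frame_times is not None:
            times = ens.frame_times
        elif ens.dt is not None:
            times = (np.arange(k) + 1) * ens.dt
        else:
            raise ValueError("burn-in in ps requires frame times or dt")
        keep = np.nonzero(times >= burn_in)[0]
    else:
        keep = np.arange(k)
    out = keep[::stride]
    if out.size == 0:
        raise ValueError("no frames remain after burn-in and striding")
    return out


def dissimilarity_matrix(
    ens: ConformerEnsemble,
    selection: ResidueSelection | None = None,
    stride: int = 1,
    burn_in: float = 0.0,
    extra_refs: list[CalphaConformer] | None = None,
    extra_ref_indices: list[list[int]] | None = None,
) -> DissimilarityMatrix:
    """All-pairs dRMSD matrix over strided frames plus appended references.

    ``extra_refs`` (e.g. ligand-bound experimental structures) are appended
    after the frames; ``extra_ref_indices`` gives, per reference, the residue
    indices equivalent to the selection (defaults to the selection itself).
    """
    idx = strided_frame_indices(ens, stride, burn_in)
    sub = ens.subset_frames(idx)
    X = pair_distance_vectors(sub, selection)
    ids = [ens.frames[i].source_id or f"frame{i}" for i in idx]
    if extra_refs:
        for r, ref in enumerate(extra_refs):
            if extra_ref_indices is not None:
                ref_idx = extra_ref_indices[r]
            elif selection is not None:
                ref_idx = selection.indices
            else:
                ref_idx = list(range(ref.n_residues))
            if max(ref_idx) >= ref.n_residues:
                raise ValueError(
                    f"reference {ref.source_id!r} cannot be mapped to the selection"
                )
            v = pdist(ref.coords[ref_idx])
            if v.shape[0] != X.shape[1]:
                raise ValueError("reference selection size mismatch")
            X = np.vstack([X, v])
            ids.append(ref.source_id or f"ref{r}")
    p = X.shape[1]
    D = squareform(pdist(X)) / np.sqrt(p)
    return DissimilarityMatrix(values=D, frame_ids=ids)


def _silhouette_from_sqmatrix(D: np.ndarray, labels: np.ndarray):
    """Per-point silhouette from a full dissimilarity matrix."""
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    m = D.shape[0]
    s = np.zeros(m)
    members = {c: np.nonzero(labels == c)[0] for c in uniq}
    for i in range(m):
        own = members[labels[i]]
        if own.size == 1:
            s[i] = 0.0  # Rousseeuw convention for singletons
            continue
        a = D[i, own].sum() / (own.size - 1)
        b = min(D[i, members[c]].mean() for c in uniq if c != labels[i])
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return s


def silhouette_validate(
    ens: ConformerEnsemble,
    selection: ResidueSelection | None,
    labels: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Silhouette index S(i) per frame and the overall average S_OVER.

    a(i) is the mean dRMSD of frame i to the other members of its cluster;
    b(i) the minimum over other clusters of the mean dRMSD to that cluster's
    members; S(i) = (b - a) / max(a, b). Values lie in [-1, 1]; singleton
    clusters score 0.
    """
    X = pair_distance_vectors(ens, selection)
    if len(labels) != X.shape[0]:
        raise ValueError("labels length must equal frame count")
    D = squareform(pdist(X)) / np.sqrt(X.shape[1])
    s = _silhouette_from_sqmatrix(D, labels)
    return s, float(s.mean())


def _medoids_from_sqmatrix(D: np.ndarray, labels: np.ndarray) -> list[int]:
    out = []
    for c in np.unique(labels):
        members = np.nonzero(labels == c)[0]
        if members.size == 1:
            out.append(int(members[0]))
            continue
        sub = D[np.ix_(members, members)]
        mean_to_others = sub.sum(axis=1) / (members.size - 1)
        out.append(int(members[np.argmin(mean_to_others)]))
    return out


def kmeans_states(
    ens: ConformerEnsemble,
    selection: ResidueSelection | None = None,
    k: int = 2,
    seed: int | None = 0,
    n_init: int = 10,
    compute_silhouette: bool = True,
) -> ClusterResult:
    """Partition an ensemble into k states by dRMSD k-means.

    Returns 1-based labels, the cluster mean distance matrices (condensed),
    the WCSS, per-frame silhouettes with S_OVER (for k >= 2), and per-cluster
    medoid frame indices. Deterministic given ``seed``.
    """
    X = pair_distance_vectors(ens, selection)
    km = DRMSDKMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
    labels0 = km.labels_
    D = squareform(pdist(X)) / np.sqrt(X.shape[1])
    sil = s_over = None
    if compute_silhouette and k >= 2:
        sil = _silhouette_from_sqmatrix(D, labels0)
        s_over = float(sil.mean())
    medoids = _medoids_from_sqmatrix(D, labels0)
    return ClusterResult(
        k=k,
        labels=labels0 + 1,
        cluster_means=km.cluster_centers_,
        wcss=km.inertia_,
        silhouette=sil,
        s_over=s_over,
        medoids=medoids,
        n_iter=km.n_iter_,
        seed=seed,
    )


def select_k(
    ens: ConformerEnsemble,
    selection: ResidueSelection | None,
    k_range,
    seed: int | None = 0,
    n_init: int = 10,
) -> tuple[int, dict[int, ClusterResult]]:
    """Choose k by maximising the overall average silhouette S_OVER.

    Ties break toward smaller k; the full per-k results are returned for
    audit.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("empty k range")
    if min(ks) < 2:
        raise ValueError("k range must start at 2 for silhouette validation")
    results = {k: kmeans_states(ens, selection, k=k, seed=seed, n_init=n_init)
               for k in ks}
    best_k = max(ks, key=lambda k: (results[k].s_over, -k))
    return best_k, results


def medoid(
    ens: ConformerEnsemble,
    selection: ResidueSelection | None,
    member_frames,
) -> int:
    """The member frame minimising mean dRMSD to all other members.

    Ties break toward the earliest frame. A single member is its own medoid.
    """
    members = list(member_frames)
    if not members:
        raise ValueError("empty member set")
    if len(members) == 1:
        return members[0]
    sub = ens.subset_frames(members)
    X = pair_distance_vectors(sub, selection)
    D = squareform(pdist(X)) / np.sqrt(X.shape[1])
    mean_to_others = D.sum(axis=1) / (len(members) - 1)
    return members[int(np.argmin(mean_to_others))]


def find_outliers(
    ens: ConformerEnsemble,
    selection: ResidueSelection | None,
    medoid_frame: int,
    threshold: float,
) -> np.ndarray:
    """Frames with dRMSD to the medoid greater than or equal to ``threshold``."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    X = pair_distance_vectors(ens, selection)
    p = X.shape[1]
    d = np.linalg.norm(X - X[medoid_frame], axis=1) / np.sqrt(p)
    out = np.nonzero(d >= threshold)[0]
    return out[out != medoid_frame]


def assign_to_clusters(
    vectors: np.ndarray, cluster_means: np.ndarray
) -> np.ndarray:
    """Nearest-centroid (mean distance matrix) assignment, 1-based labels."""
    d2 = ((vectors[:, None, :] - cluster_means[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1) + 1


def cmds_embed(d: DissimilarityMatrix, dims: int = 2) -> EmbeddingResult:
    """Classical MDS embedding of a dissimilarity matrix."""
    mds = ClassicalMDS(n_components=dims).fit(d.values)
    return EmbeddingResult(
        coords=mds.embedding_,
        eigenvalues=mds.eigenvalues_,
        frame_ids=list(d.frame_ids),
    )
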
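"""Conformational-selection vs induced-fit diagnostics.

* Q^(k): mean dRMSD of the k apo-ensemble conformers most similar to a
  ligand-bound reference structure. Low Q at small k means bound-like
  conformations are visited spontaneously (a conformational-selection
  signature); persistently high Q suggests an induced-fit component.
* Binding-cleft distance series and their Gaussian(-mixture) fits: a bimodal
  cleft-width distribution is direct evidence of two pocket states.
* Open-state fraction of a cleft distance series above a threshold.
* Cluster kinetics: dwell-time (inter-cluster transition) and intra-cluster
  relaxation summaries from a per-frame state-label sequence.
* RMSIP: principal-component subspace overlap between trajectory segments,
  used as a sampling-convergence check.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator
from sklearn.mixture import GaussianMixture

from .distances import pair_distance_vectors
from .types import (
    CalphaConformer,
    ConformerEnsemble,
    ConvergenceReport,
    DistanceSeries,
    GaussianFit,
    KineticsReport,
    QProfile,
    ResidueSelection,
)

__all__ = [
    "q_profile",
    "cleft_distance_series",
    "CleftGaussianModel",
    "fit_gaussians",
    "open_fraction",
    "cluster_kinetics",
    "segment_modes",
    "rmsip_from_modes",
    "rmsip",
]


def q_profile(
    ens: ConformerEnsemble,
    selection: ResidueSelection | None,
    reference: CalphaConformer,
    ks: list[int],
    reference_indices: list[int] | None = None,
) -> QProfile:
    """Neighbour-conformer profile Q^(k) against a reference structure.

    Frames are ranked by dRMSD to the reference (ties broken by frame
    order); Q^(k) is the mean dRMSD of the k nearest. Q is nondecreasing
    in k.
    """
    if not ks:
        raise ValueError("ks must be nonempty")
    X = pair_distance_vectors(ens, selection)
    if reference_indices is None:
        reference_indices = (
            selection.indices if selection is not None
            else list(range(reference.n_residues))
        )
    if max(reference_indices) >= reference.n_residues:
        raise ValueError("reference cannot be mapped to the selection")
    ref_vec = pdist(reference.coords[reference_indices])
    if ref_vec.shape[0] != X.shape[1]:
        raise ValueError("reference selection size mismatch")
    p = X.shape[1]
    d = np.linalg.norm(X - ref_vec, axis=1) / np.sqrt(p)
    if max(ks) > len(d):
        raise ValueError(f"k={max(ks)} exceeds frame count {len(d)}")
    order = np.argsort(d, kind="stable")
    d_sorted = d[order]
    ks = sorted(int(k) for k in ks)
    q = np.array([d_sorted[:k].mean() for k in ks])
    neighbors = {k: order[:k].copy() for k in ks}
    return QProfile(
        reference_id=reference.source_id, ks=ks, q_values=q,
        neighbor_frames=neighbors,
    )


def _residue_index(ens: ConformerEnsemble, residue: tuple[str, int]) -> int:
    chain, resnum = residue
    for i, lab in enumerate(ens.residue_labels):
        if lab.chain == chain and lab.resnum == resnum:
            return i
    raise KeyError(f"residue {chain}:{resnum} absent from ensemble")


def cleft_distance_series(
    ens: ConformerEnsemble,
    residue_a: tuple[str, int],
    residue_b: tuple[str, int],
) -> DistanceSeries:
    """Per-frame C-alpha distance between two residues (author numbering).

    The canonical choice for the cleft base is the C-terminal residue of the
    beta-2 strand against the N-terminal residue of the alpha-2 helix.
    """
    ia = _residue_index(ens, residue_a)
    ib = _residue_index(ens, residue_b)
    coords = ens.coords_array()
    values = np.linalg.norm(coords[:, ia] - coords[:, ib], axis=1)
    la, lb = ens.residue_labels[ia], ens.residue_labels[ib]
    return DistanceSeries(
        values=values, frame_times=ens.frame_times,
        residue_pair=(str(la), str(lb)),
    )


class CleftGaussianModel(BaseEstimator):
    """Gaussian vs two-Gaussian-mixture model of a distance distribution.

    Fits every candidate component count by maximum likelihood (the
    two-component case via expectation-maximisation with seeded restarts) and
    selects the model with the lowest Bayesian information criterion.

    Attributes
    ----------
    n_components_ : selected component count.
    means_, sds_, weights_ : mixture parameters, components sorted by mean.
    bic_ : dict of candidate -> BIC score.
    """

    def __init__(
        self,
        candidates: tuple[int, ...] = (1, 2),
        n_init: int = 5,
        random_state: int | None = 0,
    ):
        self.candidates = candidates
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).reshape(-1, 1)
        if x.shape[0] < 50:
            raise ValueError("need at least 50 samples for a stable fit")
        if np.std(x) == 0:
            raise ValueError("degenerate (zero-variance) series")
        self.bic_ = {}
        models = {}
        for c in self.candidates:
            gm = GaussianMixture(
                n_components=c, covariance_type="full",
                n_init=self.n_init, random_state=self.random_state,
            ).fit(x)
            self.bic_[c] = float(gm.bic(x))
            models[c] = gm
        best = min(self.bic_, key=self.bic_.get)
        gm = models[best]
        order = np.argsort(gm.means_.ravel())
        self.n_components_ = int(best)
        self.means_ = gm.means_.ravel()[order]
        self.sds_ = np.sqrt(gm.covariances_.reshape(-1)[order])
        self.weights_ = gm.weights_[order]
        return self


def fit_gaussians(
    series: DistanceSeries, candidates: tuple[int, ...] = (1, 2),
    random_state: int | None = 0,
) -> GaussianFit:
    """BIC-selected Gaussian(-mixture) fit of a cleft distance series."""
    model = CleftGaussianModel(candidates=candidates, random_state=random_state)
    model.fit(series.values)
    return GaussianFit(
        n_components=model.n_components_,
        means=model.means_,
        sds=model.sds_,
        weights=model.weights_,
        model_scores=model.bic_,
    )


def open_fraction(series: DistanceSeries, threshold: float) -> tuple[float, int]:
    """Fraction (and count) of frames with distance strictly above threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if series.values.size == 0:
        raise ValueError("empty series")
    count = int(np.sum(series.values > threshold))
    return count / series.values.size, count


def _runs(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal constant-label runs as (label, start, length)."""
    out = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            out.append((int(labels[start]), start, i - start))
            start = i
    return out


def _relaxation_time(
    signal: np.ndarray, runs: list[tuple[int, int, int]], dt: float
) -> float | None:
    """1/e crossing time of the within-run autocorrelation of ``signal``.

    Deviations are taken from each run's own mean so that inter-state jumps
    do not contaminate the intra-state correlation.
    """
    max_len = max(length for _, _, length in runs)
    max_lag = min(200, max_len - 1)
    if max_lag < 1:
        return None
    num = np.zeros(max_lag + 1)
    cnt = np.zeros(max_lag + 1)
    for _, start, length in runs:
        if length < 2:
            continue
        x = signal[start:start + length]
        x = x - x.mean()
        for lag in range(0, min(max_lag, length - 1) + 1):
            num[lag] += np.dot(x[: length - lag], x[lag:])
            cnt[lag] += length - lag
    if cnt[0] == 0 or num[0] <= 0:
        return None
    acf = (num / np.maximum(cnt, 1)) / (num[0] / cnt[0])
    target = 1.0 / np.e
    for lag in range(1, max_lag + 1):
        if cnt[lag] == 0:
            return float(lag * dt)
        if acf[lag] <= target:
            prev = acf[lag - 1]
            frac = (prev - target) / (prev - acf[lag]) if prev > acf[lag] else 1.0
            return float((lag - 1 + frac) * dt)
    return float(max_lag * dt)


def cluster_kinetics(
    labels,
    dt: float,
    centroid_signal: np.ndarray | None = None,
    include_first_dwell: bool = False,
) -> KineticsReport:
    """Kinetic summary of a per-frame cluster-label sequence.

    Dwell times are the lengths (x dt, ps) of maximal constant-label runs.
    The final run is right-censored and excluded; the first run is likewise
    excluded by default since no transition precedes it (set
    ``include_first_dwell`` to keep it). The mean inter-cluster transition
    time is the mean complete dwell time. When ``centroid_signal`` (the
    per-frame dRMSD to the frame's own cluster centroid) is supplied, the
    intra-cluster relaxation time is its within-run autocorrelation 1/e time.
    """
    labels = np.asarray(labels)
    if dt <= 0:
        raise ValueError("dt must be positive")
    if np.unique(labels).size < 2:
        raise ValueError("need at least 2 distinct labels for kinetics")
    runs = _runs(labels)
    complete = runs[:-1]  # final run right-censored
    if not include_first_dwell:
        complete = complete[1:] if len(complete) > 1 else complete
    if not complete:
        raise ValueError("no complete dwells in label sequence")
    dwell: dict[int, list[float]] = {}
    for lab, _, length in complete:
        dwell.setdefault(lab, []).append(length * dt)
    all_dwells = [t for ts in dwell.values() for t in ts]
    relax = None
    if centroid_signal is not None:
        centroid_signal = np.asarray(centroid_signal, dtype=float)
        if centroid_signal.shape != labels.shape:
            raise ValueError("centroid_signal must align with labels")
        relax = _relaxation_time(centroid_signal, runs, dt)
    return KineticsReport(
        mean_intercluster_transition_time=float(np.mean(all_dwells)),
        mean_intracluster_relaxation_time=relax,
        dwell_times=dwell,
    )


def _superpose_to_mean(coords: np.ndarray, n_iter: int = 3) -> np.ndarray:
    """Least-squares superposition of every frame onto the iterated mean."""
    aligned = coords - coords.mean(axis=1, keepdims=True)
    for _ in range(n_iter):
        mean = aligned.mean(axis=0)
        mean = mean - mean.mean(axis=0)
        for i, x in enumerate(aligned):
            cov = mean.T @ x
            u, _, vt = np.linalg.svd(cov)
            d = np.sign(np.linalg.det(u @ vt))
            rot = u @ np.diag([1.0, 1.0, d]) @ vt
            aligned[i] = x @ rot.T
    return aligned


def segment_modes(
    ens: ConformerEnsemble,
    selection: ResidueSelection | None,
    frame_indices,
    n_modes: int = 10,
    superpose: bool = True,
) -> np.ndarray:
    """Top principal modes (rows, each of length 3N) of a trajectory segment.

    Frames are superposed onto the segment mean before the Cartesian PCA so
    that rigid-body motion does not masquerade as an internal mode.
    """
    idx = list(frame_indices)
    if len(idx) < max(2, n_modes):
        raise ValueError("segment must contain at least n_modes (>=2) frames")
    sel = selection.indices if selection is not None else None
    coords = ens.coords_array()[idx]
    if sel is not None:
        coords = coords[:, sel, :]
    n = coords.shape[1]
    if n_modes > 3 * n:
        raise ValueError("n_modes exceeds 3N degrees of freedom")
    if superpose:
        coords = _superpose_to_mean(coords.copy())
    flat = coords.reshape(len(idx), -1)
    flat = flat - flat.mean(axis=0)
    cov = flat.T @ flat / len(idx)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1][:n_modes]
    return evecs[:, order].T


def rmsip_from_modes(modes_a: np.ndarray, modes_b: np.ndarray) -> float:
    """Root mean square inner product of two sets of D orthonormal modes.

    RMSIP = sqrt( (1/D) * sum_i sum_j (eta_i . nu_j)^2 ), in [0, 1]; 1 when
    the spanned subspaces coincide, 0 when they are orthogonal. Invariant to
    orthogonal re-basis of either set within its span.
    """
    if modes_a.shape != modes_b.shape:
        raise ValueError("mode sets must have equal shape")
    overlap = modes_a @ modes_b.T
    return float(np.sqrt(np.sum(overlap**2) / modes_a.shape[0]))


def rmsip(
    ens: ConformerEnsemble,
    selection: ResidueSelection | None = None,
    n_modes: int = 10,
    split: str = "halves",
    segments: tuple[list[int], list[int]] | None = None,
    superpose: bool = True,
) -> ConvergenceReport:
    """Convergence check: RMSIP between the modes of two trajectory segments.

    ``halves`` compares the first and second halves of the ensemble; pass
    ``segments`` (two frame-index lists) with ``split='custom'`` otherwise.
    """
    if split == "halves":
        k = ens.n_frames
        seg_a = list(range(k // 2))
        seg_b = list(range(k // 2, k))
        desc = f"halves ({len(seg_a)}+{len(seg_b)} frames)"
    elif split == "custom":
        if segments is None:
            raise ValueError("custom split requires explicit segments")
        seg_a, seg_b = list(segments[0]), list(segments[1])
        desc = f"custom ({len(seg_a)}+{len(seg_b)} frames)"
    else:
        raise ValueError("split must be 'halves' or 'custom'")
    ma = segment_modes(ens, selection, seg_a, n_modes, superpose)
    mb = segment_modes(ens, selection, seg_b, n_modes, superpose)
    return ConvergenceReport(
        rmsip=rmsip_from_modes(ma, mb), n_modes=n_modes, split=desc
    )
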
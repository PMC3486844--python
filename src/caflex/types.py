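"""Core value types shared across the toolkit.

Everything downstream operates on ordered C-alpha coordinate sets: a single
conformer is an (N, 3) array of positions in Angstrom together with residue
labels, and an ensemble is an ordered list of conformers sharing the same
labels (an MD trajectory, a multi-model PDB entry, or a synthetic ensemble).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ResidueLabel",
    "CalphaConformer",
    "ConformerEnsemble",
    "SequenceAlignment",
    "ResidueSelection",
    "DistanceMatrix",
    "DifferenceMatrix",
    "PairStatMatrix",
    "OverallFluctuation",
    "DissimilarityMatrix",
    "EmbeddingResult",
    "ClusterResult",
    "QProfile",
    "DistanceSeries",
    "GaussianFit",
    "KineticsReport",
    "ConvergenceReport",
    "LabeledEnsemble",
]


@dataclass(frozen=True)
class ResidueLabel:
    """Identity of one residue: chain id, author residue number, residue name."""

    chain: str
    resnum: int
    resname: str

    def __str__(self) -> str:  # e.g. "A:GLY31"
        return f"{self.chain}:{self.resname}{self.resnum}"


@dataclass
class CalphaConformer:
    """A single conformation reduced to its C-alpha trace.

    Parameters
    ----------
    residue_labels : list of ResidueLabel
        Ordered residue identities.
    coords : ndarray, shape (N, 3)
        C-alpha positions in Angstrom.
    source_id : str
        Free-text provenance (PDB id + model number, frame index, ...).
    """

    residue_labels: list[ResidueLabel]
    coords: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (N, 3)")
        if self.coords.shape[0] != len(self.residue_labels):
            raise ValueError(
                f"coords has {self.coords.shape[0]} rows but "
                f"{len(self.residue_labels)} residue labels"
            )
        if self.n_residues < 2:
            raise ValueError("a conformer needs at least 2 residues")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_residues(self) -> int:
        return self.coords.shape[0]

    def subset(self, indices: Sequence[int]) -> "CalphaConformer":
        idx = list(indices)
        return CalphaConformer(
            residue_labels=[self.residue_labels[i] for i in idx],
            coords=self.coords[idx],
            source_id=self.source_id,
        )


@dataclass
class ConformerEnsemble:
    """Ordered conformations sharing identical residue labels.

    ``frame_times`` (ps) are optional; when both ``frame_times`` and ``dt``
    are present they must be consistent (uniform spacing dt).
    """

    frames: list[CalphaConformer]
    frame_times: np.ndarray | None = None
    dt: float | None = None

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("ensemble must contain at least one frame")
        labels = self.frames[0].residue_labels
        for f in self.frames[1:]:
            if f.residue_labels != labels:
                raise ValueError("all frames must share identical residue labels")
        if self.frame_times is not None:
            self.frame_times = np.asarray(self.frame_times, dtype=float)
            if self.frame_times.shape != (len(self.frames),):
                raise ValueError("frame_times length must equal frame count")
            if len(self.frame_times) > 1 and not np.all(np.diff(self.frame_times) > 0):
                raise ValueError("frame_times must be strictly increasing")
            if self.dt is not None and len(self.frame_times) > 1:
                if not np.allclose(np.diff(self.frame_times), self.dt):
                    raise ValueError("frame_times inconsistent with dt")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_residues(self) -> int:
        return self.frames[0].n_residues

    @property
    def residue_labels(self) -> list[ResidueLabel]:
        return self.frames[0].residue_labels

    def coords_array(self) -> np.ndarray:
        """Stacked coordinates with shape (K, N, 3)."""
        return np.stack([f.coords for f in self.frames])

    def subset_frames(self, frame_indices: Sequence[int]) -> "ConformerEnsemble":
        idx = list(frame_indices)
        times = None
        # unordered subsets (e.g. nearest-neighbour sets) carry no time axis
        if self.frame_times is not None and idx == sorted(set(idx)):
            times = self.frame_times[idx]
        return ConformerEnsemble(
            frames=[self.frames[i] for i in idx], frame_times=times, dt=None
        )


@dataclass
class SequenceAlignment:
    """A gapped multiple sequence alignment ('-' is the gap character)."""

    names: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.rows):
            raise ValueError("names and rows must have equal length")
        if len(self.rows) < 2:
            raise ValueError("alignment needs at least 2 sequences")
        L = len(self.rows[0])
        if any(len(r) != L for r in self.rows):
            raise ValueError("alignment rows must all have equal length")

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def row(self, name: str) -> str:
        try:
            return self.rows[self.names.index(name)]
        except ValueError:
            raise KeyError(f"sequence {name!r} not in alignment") from None


@dataclass
class ResidueSelection:
    """Ordered 0-based indices into a conformer's residue list.

    ``blocks`` names contiguous sub-blocks (e.g. ``{"strand": [...],
    "helix": [...]}``) used for cross-block submatrices.
    """

    indices: list[int]
    blocks: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.indices)) != len(self.indices):
            raise ValueError("selection indices must be unique")
        for name, block in self.blocks.items():
            if any(i not in set(self.indices) for i in block):
                raise ValueError(f"block {name!r} has indices outside selection")
            if sorted(block) != list(block):
                raise ValueError(f"block {name!r} indices must be ascending")

    def __len__(self) -> int:
        return len(self.indices)

    def local_block(self, name: str) -> list[int]:
        """Block indices re-expressed as positions within the selection."""
        pos = {g: i for i, g in enumerate(self.indices)}
        return [pos[g] for g in self.blocks[name]]


def _check_square(values: np.ndarray, labels: list | None) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("matrix must be square")
    if labels is not None and len(labels) != values.shape[0]:
        raise ValueError("label count must match matrix size")
    return values


@dataclass
class DistanceMatrix:
    """N x N C-alpha pair distances in Angstrom (symmetric, zero diagonal)."""

    values: np.ndarray
    labels: list[ResidueLabel] | None = None

    def __post_init__(self) -> None:
        self.values = _check_square(self.values, self.labels)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("distances must be finite")
        if np.any(self.values < 0) or not np.allclose(np.diag(self.values), 0):
            raise ValueError("distance matrix must be nonnegative with zero diagonal")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class DifferenceMatrix:
    """Signed difference-distance matrix delta = d^A - d^B (Angstrom)."""

    values: np.ndarray
    labels: list[ResidueLabel] | None = None

    def __post_init__(self) -> None:
        self.values = _check_square(self.values, self.labels)


@dataclass
class PairStatMatrix:
    """Per-pair ensemble statistic.

    ``kind`` is one of ``fluctuation`` (variance, A^2), ``flexibility``
    (max-min range, A) or ``mean_abs_diff`` (mean |d - d_ref|, A).
    """

    values: np.ndarray
    kind: str
    labels: list[ResidueLabel] | None = None

    KINDS = ("fluctuation", "flexibility", "mean_abs_diff")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"kind must be one of {self.KINDS}")
        self.values = _check_square(self.values, self.labels)
        if np.any(self.values < -1e-12):
            raise ValueError("pair statistics must be nonnegative")


@dataclass
class OverallFluctuation:
    """The scalar fluctuation summary Theta (Angstrom).

    Theta is the RMS dRMSD of ensemble members to the ensemble-mean distance
    matrix; equivalently the square root of the mean in-scope entry of the
    fluctuation matrix F.
    """

    theta: float
    n_residues: int
    n_frames: int
    pair_scope: str = "all_pairs"


@dataclass
class DissimilarityMatrix:
    """M x M pairwise dRMSD values (Angstrom) over frames plus optional refs."""

    values: np.ndarray
    frame_ids: list[str]

    def __post_init__(self) -> None:
        self.values = _check_square(self.values, self.frame_ids)

    @property
    def m(self) -> int:
        return self.values.shape[0]


@dataclass
class EmbeddingResult:
    """Classical-MDS embedding: coordinates plus the full eigenvalue spectrum."""

    coords: np.ndarray
    eigenvalues: np.ndarray
    frame_ids: list[str]


@dataclass
class ClusterResult:
    """Distance-space k-means output.

    ``cluster_means`` are the mean distance matrices C_i (condensed, upper
    triangle) that serve as centroids; ``wcss`` is the within-cluster sum of
    squared dRMSD values to those centroids.
    """

    k: int
    labels: np.ndarray
    cluster_means: np.ndarray
    wcss: float
    silhouette: np.ndarray | None
    s_over: float | None
    medoids: list[int]
    n_iter: int
    seed: int | None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)


@dataclass
class QProfile:
    """Neighbour-conformer profile Q^(k) against a reference structure E."""

    reference_id: str
    ks: list[int]
    q_values: np.ndarray
    neighbor_frames: dict[int, np.ndarray]


@dataclass
class DistanceSeries:
    """Per-frame distance (Angstrom) of one residue pair, with frame times."""

    values: np.ndarray
    frame_times: np.ndarray | None
    residue_pair: tuple[str, str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)) or np.any(self.values <= 0):
            raise ValueError("distance series must be finite and positive")
        if self.frame_times is not None:
            self.frame_times = np.asarray(self.frame_times, dtype=float)
            if self.frame_times.shape != self.values.shape:
                raise ValueError("frame_times must align with values")


@dataclass
class GaussianFit:
    """Gaussian (mixture) fit of a distance distribution, selected by BIC."""

    n_components: int
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    model_scores: dict[int, float]


@dataclass
class KineticsReport:
    """Run-length kinetics of a cluster-label sequence (times in ps)."""

    mean_intercluster_transition_time: float
    mean_intracluster_relaxation_time: float | None
    dwell_times: dict[int, list[float]]


@dataclass
class ConvergenceReport:
    """RMSIP subspace overlap between two trajectory segments."""

    rmsip: float
    n_modes: int
    split: str


@dataclass
class LabeledEnsemble:
    """A synthetic ensemble together with its generating truth."""

    ensemble: ConformerEnsemble
    true_labels: np.ndarray
    true_parameters: dict
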
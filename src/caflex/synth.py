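"""Seeded synthetic C-alpha ensembles with known statistical structure.

Three generators cover the statistical regimes the analysis stages assume:

* ``generate_harmonic`` — stationary isotropic Gaussian fluctuation about a
  reference conformation (a one-state trajectory stand-in);
* ``generate_two_state`` — a hidden symmetric two-state Markov chain switching
  between two reference conformations, plus intra-state Gaussian noise (a
  metastable-states stand-in with known labels and dwell statistics);
* ``generate_cleft_series`` — i.i.d. draws of a cleft-width distance from a
  one- or two-component Gaussian mixture.

``make_reference_pocket`` builds a deterministic idealised binding pocket: an
extended beta-strand trace facing an ideal alpha-helix trace, with the cleft
base pair (strand C-terminus vs helix N-terminus) at a requested distance.
All generators take an explicit seed and are bit-reproducible per seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .types import (
    CalphaConformer,
    ConformerEnsemble,
    DistanceSeries,
    LabeledEnsemble,
    ResidueLabel,
    ResidueSelection,
)

__all__ = [
    "make_reference_pocket",
    "pocket_selection",
    "generate_harmonic",
    "generate_two_state",
    "generate_cleft_series",
    "write_ensemble_pdb",
    "write_truth_json",
]

STRAND_SPACING = 3.8  # consecutive Calpha spacing in an extended strand, A
HELIX_RISE = 1.5  # rise per residue along an ideal alpha-helix axis, A
HELIX_TURN_DEG = 100.0  # rotation per residue, degrees
HELIX_RADIUS = 2.3  # Calpha radius of an ideal alpha helix, A


def make_reference_pocket(
    n_strand: int = 5,
    n_helix: int = 10,
    cleft_base_distance: float = 6.3,
) -> CalphaConformer:
    """Deterministic idealised strand+helix pocket conformer.

    The strand runs along x with 3.8 A spacing; the helix (1.5 A rise,
    100 deg per residue, 2.3 A radius) runs parallel, offset in y so that the
    base pair — last strand residue vs first helix residue — sits exactly at
    ``cleft_base_distance``. Residues are chain A, strand numbered from 1 and
    helix from 101.
    """
    if n_strand < 2 or n_helix < 2:
        raise ValueError("need at least 2 residues per block")
    if cleft_base_distance <= 0:
        raise ValueError("cleft_base_distance must be positive")
    strand = np.zeros((n_strand, 3))
    strand[:, 0] = np.arange(n_strand) * STRAND_SPACING
    theta = np.deg2rad(HELIX_TURN_DEG) * np.arange(n_helix)
    x0 = (n_strand - 1) * STRAND_SPACING
    y0 = cleft_base_distance - HELIX_RADIUS
    helix = np.column_stack(
        [
            x0 + HELIX_RISE * np.arange(n_helix),
            y0 + HELIX_RADIUS * np.cos(theta),
            HELIX_RADIUS * np.sin(theta),
        ]
    )
    labels = [ResidueLabel("A", 1 + i, "GLY") for i in range(n_strand)] + [
        ResidueLabel("A", 101 + j, "GLY") for j in range(n_helix)
    ]
    return CalphaConformer(
        residue_labels=labels,
        coords=np.vstack([strand, helix]),
        source_id="ideal_pocket",
    )


def pocket_selection(conf: CalphaConformer) -> ResidueSelection:
    """Strand/helix block selection covering an idealised pocket conformer."""
    strand = [i for i, lab in enumerate(conf.residue_labels) if lab.resnum < 100]
    helix = [i for i, lab in enumerate(conf.residue_labels) if lab.resnum >= 100]
    return ResidueSelection(
        indices=strand + helix, blocks={"strand": strand, "helix": helix}
    )


def generate_harmonic(
    ref: CalphaConformer,
    noise_sd: float = 0.1,
    K: int = 2000,
    dt: float = 5.0,
    seed: int = 0,
) -> LabeledEnsemble:
    """Stationary harmonic ensemble: reference + isotropic Gaussian noise.

    Each coordinate of each frame is displaced independently by
    N(0, noise_sd^2); for well-separated atom pairs the induced pair-distance
    variance is approximately 2 * noise_sd^2.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if K < 2:
        raise ValueError("need at least 2 frames")
    rng = np.random.default_rng(seed)
    disp = rng.normal(0.0, noise_sd, size=(K, ref.n_residues, 3)) if noise_sd > 0 \
        else np.zeros((K, ref.n_residues, 3))
    frames = [
        CalphaConformer(
            residue_labels=ref.residue_labels,
            coords=ref.coords + disp[i],
            source_id=f"harmonic:{i}",
        )
        for i in range(K)
    ]
    times = (np.arange(K) + 1) * dt
    ens = ConformerEnsemble(frames=frames, frame_times=times, dt=dt)
    params = {"kind": "harmonic", "noise_sd": noise_sd, "K": K, "dt": dt,
              "seed": seed}
    return LabeledEnsemble(
        ensemble=ens, true_labels=np.ones(K, dtype=int), true_parameters=params
    )


def generate_two_state(
    ref_a: CalphaConformer,
    ref_b: CalphaConformer,
    switch_prob: float = 0.01,
    noise_sd: float = 0.05,
    K: int = 4000,
    dt: float = 5.0,
    seed: int = 0,
) -> LabeledEnsemble:
    """Metastable two-state ensemble with a hidden symmetric Markov chain.

    The chain starts in state 1 (reference A) and switches state with
    probability ``switch_prob`` at each frame, giving geometric dwell times
    with mean dt / switch_prob. Frames are the active reference plus
    isotropic Gaussian noise. True labels (1 or 2) are returned.
    """
    if ref_a.residue_labels != ref_b.residue_labels:
        raise ValueError("reference conformers must share residue labels")
    if not 0 < switch_prob < 1:
        raise ValueError("switch_prob must be in (0, 1)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if K < 2:
        raise ValueError("need at least 2 frames")
    rng = np.random.default_rng(seed)
    switches = rng.random(K) < switch_prob
    switches[0] = False
    states = (np.cumsum(switches) % 2).astype(int) + 1  # 1-based state ids
    refs = np.stack([ref_a.coords, ref_b.coords])
    disp = rng.normal(0.0, noise_sd, size=(K, ref_a.n_residues, 3)) if noise_sd > 0 \
        else np.zeros((K, ref_a.n_residues, 3))
    frames = [
        CalphaConformer(
            residue_labels=ref_a.residue_labels,
            coords=refs[states[i] - 1] + disp[i],
            source_id=f"two_state:{i}",
        )
        for i in range(K)
    ]
    times = (np.arange(K) + 1) * dt
    ens = ConformerEnsemble(frames=frames, frame_times=times, dt=dt)
    params = {
        "kind": "two_state", "switch_prob": switch_prob, "noise_sd": noise_sd,
        "K": K, "dt": dt, "seed": seed,
        "expected_dwell_ps": dt / switch_prob,
    }
    return LabeledEnsemble(ensemble=ens, true_labels=states, true_parameters=params)


def generate_cleft_series(
    components: list[tuple[float, float, float]],
    K: int = 5000,
    dt: float = 5.0,
    seed: int = 0,
) -> DistanceSeries:
    """I.i.d. cleft-width draws from a Gaussian mixture.

    ``components`` is a list of (mean A, sd A, weight) tuples with weights
    summing to 1. Means should be several sd above zero (distances are
    physical lengths).
    """
    if not components:
        raise ValueError("need at least one mixture component")
    mus = np.array([c[0] for c in components])
    sds = np.array([c[1] for c in components])
    ws = np.array([c[2] for c in components])
    if np.any(sds <= 0):
        raise ValueError("component sds must be positive")
    if not np.isclose(ws.sum(), 1.0):
        raise ValueError("component weights must sum to 1")
    rng = np.random.default_rng(seed)
    which = rng.choice(len(components), size=K, p=ws)
    values = rng.normal(mus[which], sds[which])
    times = (np.arange(K) + 1) * dt
    return DistanceSeries(
        values=values, frame_times=times, residue_pair=("synthetic_a", "synthetic_b")
    )


def write_ensemble_pdb(ens: ConformerEnsemble, path: str | Path) -> None:
    """Write an ensemble as a multi-model C-alpha-only PDB file.

    PDB coordinate fields are fixed-point (%8.3f), so a file round trip is
    exact to 0.001 A only.
    """
    with open(path, "w") as fh:
        for m, frame in enumerate(ens.frames, start=1):
            fh.write(f"MODEL     {m:4d}\n")
            for serial, (lab, xyz) in enumerate(
                zip(frame.residue_labels, frame.coords), start=1
            ):
                fh.write(
                    f"ATOM  {serial:5d}  CA  {lab.resname:<3s} "
                    f"{lab.chain:1s}{lab.resnum:4d}    "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}           C\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


def write_truth_json(labeled: LabeledEnsemble, path: str | Path) -> None:
    """Write generator truth (labels + parameters) alongside a PDB ensemble."""
    with open(path, "w") as fh:
        json.dump(
            {
                "true_labels": labeled.true_labels.tolist(),
                "true_parameters": labeled.true_parameters,
            },
            fh,
            indent=2,
        )
        fh.write("\n")
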
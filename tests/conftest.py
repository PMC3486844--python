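"""Shared fixtures: synthetic conformers, ensembles, and brute-force oracles.

The oracle functions here are deliberately naive (explicit Python loops over
the definitions) and independent of the library's vectorised implementations;
tests compare the two routes.
"""

from __future__ import annotations

import numpy as np
import pytest

from caflex import (
    CalphaConformer,
    ConformerEnsemble,
    ResidueLabel,
    make_reference_pocket,
    pocket_selection,
)


def random_conformer(seed: int, n: int = 10, spread: float = 5.0) -> CalphaConformer:
    rng = np.random.default_rng(seed)
    return CalphaConformer(
        residue_labels=[ResidueLabel("A", i + 1, "GLY") for i in range(n)],
        coords=rng.normal(0.0, spread, size=(n, 3)),
        source_id=f"random:{seed}",
    )


def random_ensemble(
    seed: int, k: int = 20, n: int = 10, spread: float = 5.0, jitter: float = 0.5
) -> ConformerEnsemble:
    """k frames jittered around one random base conformation."""
    rng = np.random.default_rng(seed)
    base = rng.normal(0.0, spread, size=(n, 3))
    labels = [ResidueLabel("A", i + 1, "GLY") for i in range(n)]
    frames = [
        CalphaConformer(labels, base + rng.normal(0.0, jitter, size=(n, 3)), f"f{i}")
        for i in range(k)
    ]
    return ConformerEnsemble(frames=frames)


def collinear_conformer(positions: list[float]) -> CalphaConformer:
    labels = [ResidueLabel("A", i + 1, "GLY") for i in range(len(positions))]
    coords = np.zeros((len(positions), 3))
    coords[:, 0] = positions
    return CalphaConformer(labels, coords, "collinear")


# ---------------------------------------------------------------- oracles


def drmsd_bruteforce(da: np.ndarray, db: np.ndarray) -> float:
    """Double-loop dRMSD over unordered off-diagonal pairs."""
    n = da.shape[0]
    total, count = 0.0, 0
    for i in range(n):
        for j in range(i + 1, n):
            total += (da[i, j] - db[i, j]) ** 2
            count += 1
    return float(np.sqrt(total / count))


def pairwise_dist(coords: np.ndarray) -> np.ndarray:
    n = coords.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = np.sqrt(((coords[i] - coords[j]) ** 2).sum())
    return out


def silhouette_bruteforce(D: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Literal per-point silhouette: a(i), b(i), (b-a)/max(a,b)."""
    m = D.shape[0]
    s = np.zeros(m)
    for i in range(m):
        own = [j for j in range(m) if labels[j] == labels[i] and j != i]
        if not own:
            s[i] = 0.0
            continue
        a = np.mean([D[i, j] for j in own])
        bs = []
        for c in set(labels.tolist()):
            if c == labels[i]:
                continue
            others = [j for j in range(m) if labels[j] == c]
            bs.append(np.mean([D[i, j] for j in others]))
        b = min(bs)
        s[i] = 0.0 if max(a, b) == 0 else (b - a) / max(a, b)
    return s


@pytest.fixture(scope="session")
def pocket():
    return make_reference_pocket()


@pytest.fixture(scope="session")
def pocket_sel(pocket):
    return pocket_selection(pocket)
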
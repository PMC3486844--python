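"""Readers and writers: PDB/trajectory C-alpha extraction, alignments, results.

Structures are reduced to their C-alpha traces on input. Author residue
numbering (1-based, per chain) is the user-facing convention; ranges such as
"I27-G31" are inclusive at both ends. Residues with insertion codes are
rejected rather than silently reordered; alternate-location C-alpha atoms are
resolved to the highest occupancy (alphabetic altloc id breaking ties).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
from Bio import AlignIO
from Bio.PDB import PDBParser

from .types import (
    CalphaConformer,
    ConformerEnsemble,
    ResidueLabel,
    ResidueSelection,
    SequenceAlignment,
)

__all__ = [
    "load_ensemble",
    "load_reference",
    "parse_alignment",
    "map_equivalent_residues",
    "pairwise_identity",
    "select_binding_site",
    "write_results",
    "write_matrix",
    "read_matrix",
]

GAP = "-"


def _model_to_conformer(model, source_id: str) -> CalphaConformer:
    labels: list[ResidueLabel] = []
    coords: list[np.ndarray] = []
    for chain in model:
        for res in chain:
            if "CA" not in res:
                continue
            het, resnum, icode = res.id
            if het.strip():
                continue  # skip HETATM/water records
            if icode.strip():
                raise ValueError(
                    f"residue {chain.id}:{res.resname}{resnum} has insertion "
                    f"code {icode!r}; insertion codes are not supported"
                )
            ca = res["CA"]
            if ca.is_disordered():
                alts = sorted(
                    ca.disordered_get_list(),
                    key=lambda at: (-at.get_occupancy(), at.get_altloc()),
                )
                ca = alts[0]
            labels.append(ResidueLabel(chain.id, int(resnum), res.resname))
            coords.append(ca.coord.astype(float))
    if not coords:
        raise ValueError(f"no C-alpha atoms found in {source_id}")
    return CalphaConformer(
        residue_labels=labels, coords=np.asarray(coords), source_id=source_id
    )


def _load_pdb_models(path: str | Path) -> list[CalphaConformer]:
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(Path(path).stem, str(path))
    confs = []
    for model in structure:
        confs.append(
            _model_to_conformer(model, f"{Path(path).stem}:model{model.id + 1}")
        )
    if not confs:
        raise ValueError(f"no models found in {path}")
    return confs


def load_ensemble(
    path: str | Path,
    format: str = "pdb_multimodel",
    topology: str | Path | None = None,
    calpha_only: bool = True,
    dt: float | None = None,
) -> ConformerEnsemble:
    """Read a conformational ensemble as C-alpha traces.

    ``pdb_multimodel`` reads every MODEL of a PDB file; ``trajectory`` reads
    XTC/DCD/TRR (or any MDAnalysis-supported trajectory) against a PDB
    topology, populating frame times (ps) from trajectory metadata.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "pdb_multimodel":
        frames = _load_pdb_models(path)
        counts = {f.n_residues for f in frames}
        if len(counts) > 1:
            raise ValueError(
                f"inconsistent C-alpha count across models: {sorted(counts)}"
            )
        times = None
        if dt is not None:
            times = np.arange(len(frames), dtype=float) * dt
        return ConformerEnsemble(frames=frames, frame_times=times, dt=dt)
    if format == "trajectory":
        if topology is None:
            raise ValueError("trajectory format requires a topology file")
        import MDAnalysis as mda

        u = mda.Universe(str(topology), str(path))
        sel = "protein and name CA" if calpha_only else "all"
        atoms = u.select_atoms(sel)
        if atoms.n_atoms == 0:
            raise ValueError("no C-alpha atoms in topology selection")
        labels = [
            ResidueLabel(
                str(a.segid or getattr(a, "chainID", "") or "A"),
                int(a.resid),
                str(a.resname),
            )
            for a in atoms
        ]
        frames, times = [], []
        for ts in u.trajectory:
            frames.append(
                CalphaConformer(
                    residue_labels=labels,
                    coords=atoms.positions.astype(float),
                    source_id=f"{path.stem}:frame{ts.frame}",
                )
            )
            times.append(float(ts.time))
        if not frames:
            raise ValueError("trajectory contains zero frames")
        times_arr = np.asarray(times)
        traj_dt = None
        if len(times_arr) > 1:
            steps = np.diff(times_arr)
            if np.all(steps > 0):
                if np.allclose(steps, steps[0]):
                    traj_dt = float(steps[0])
            else:
                times_arr = None  # non-monotonic metadata: drop times
        return ConformerEnsemble(frames=frames, frame_times=times_arr, dt=traj_dt)
    raise ValueError(f"unknown format {format!r}")


def load_reference(path: str | Path, model_index: int = 1) -> CalphaConformer:
    """Read a single reference structure (model ``model_index``, 1-based).

    Multi-model (NMR) entries default to the first model.
    """
    frames = _load_pdb_models(path)
    if not 1 <= model_index <= len(frames):
        raise IndexError(
            f"model_index {model_index} not in file with {len(frames)} model(s)"
        )
    return frames[model_index - 1]


_DIALECTS = {"aligned_fasta": "fasta", "clustal": "clustal"}


def parse_alignment(path: str | Path, dialect: str = "aligned_fasta") -> SequenceAlignment:
    """Parse an aligned FASTA or CLUSTAL multiple sequence alignment."""
    if dialect not in _DIALECTS:
        raise ValueError(f"dialect must be one of {sorted(_DIALECTS)}")
    try:
        aln = AlignIO.read(str(path), _DIALECTS[dialect])
    except ValueError as exc:
        raise ValueError(f"could not parse alignment {path}: {exc}") from exc
    return SequenceAlignment(
        names=[rec.id for rec in aln], rows=[str(rec.seq).upper() for rec in aln]
    )


def map_equivalent_residues(
    aln: SequenceAlignment, name_a: str, name_b: str
) -> list[tuple[int, int]]:
    """Aligned residue pairs between two sequences, gaps removed.

    Returns 0-based ungapped positions; the pair count is the N of all
    pairwise distance-matrix comparisons.
    """
    ra, rb = aln.row(name_a), aln.row(name_b)
    pairs = []
    ia = ib = 0
    for ca, cb in zip(ra, rb):
        if ca != GAP and cb != GAP:
            pairs.append((ia, ib))
        if ca != GAP:
            ia += 1
        if cb != GAP:
            ib += 1
    return pairs


def pairwise_identity(aln: SequenceAlignment, name_a: str, name_b: str) -> float:
    """Fraction of identical residues over gap-free aligned columns.

    The denominator is the number of columns where neither sequence has a
    gap (the same N as ``map_equivalent_residues``).
    """
    ra, rb = aln.row(name_a), aln.row(name_b)
    cols = [(a, b) for a, b in zip(ra, rb) if a != GAP and b != GAP]
    if not cols:
        raise ValueError("no gap-free aligned columns between the two sequences")
    matches = sum(a == b for a, b in cols)
    return matches / len(cols)


def _resolve_range(
    conf: CalphaConformer, chain: str, first: int, last: int
) -> list[int]:
    index = {(lab.chain, lab.resnum): i for i, lab in enumerate(conf.residue_labels)}
    out = []
    for num in range(first, last + 1):
        key = (chain, num)
        if key not in index:
            raise KeyError(f"residue {chain}:{num} absent from structure")
        out.append(index[key])
    return out


def select_binding_site(
    conf: CalphaConformer,
    strand_range: tuple[str, int, int],
    helix_range: tuple[str, int, int],
) -> ResidueSelection:
    """Binding-pocket selection from inclusive author-numbered ranges.

    The pocket of a PDZ domain sits between the beta-2 strand and the alpha-2
    helix; the canonical selection is 5 strand + 10 helix residues. A warning
    (not an error) is issued for other block sizes.
    """
    strand = _resolve_range(conf, *strand_range)
    helix = _resolve_range(conf, *helix_range)
    if set(strand) & set(helix):
        raise ValueError("overlapping blocks: strand and helix ranges share residues")
    if len(strand) != 5 or len(helix) != 10:
        warnings.warn(
            f"non-canonical block sizes: strand={len(strand)}, helix={len(helix)} "
            "(canonical is 5+10)",
            stacklevel=2,
        )
    return ResidueSelection(
        indices=strand + helix, blocks={"strand": strand, "helix": helix}
    )


def _labels_to_str(labels) -> list[str]:
    if labels is None:
        return []
    return [str(l) for l in labels]


def write_matrix(
    values: np.ndarray,
    path: str | Path,
    row_labels: list | None = None,
    col_labels: list | None = None,
) -> None:
    """Write a labeled matrix as TSV (full float precision, lossless)."""
    values = np.asarray(values, dtype=float)
    rows = _labels_to_str(row_labels) or [str(i) for i in range(values.shape[0])]
    cols = _labels_to_str(col_labels) or (
        _labels_to_str(row_labels) if values.shape[0] == values.shape[1] else
        [str(j) for j in range(values.shape[1])]
    )
    if not cols:
        cols = [str(j) for j in range(values.shape[1])]
    with open(path, "w") as fh:
        fh.write("\t".join([""] + cols) + "\n")
        for name, row in zip(rows, values):
            fh.write("\t".join([name] + [repr(float(v)) for v in row]) + "\n")


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a TSV matrix written by :func:`write_matrix`."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
        rows, values = [], []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            rows.append(parts[0])
            values.append([float(v) for v in parts[1:]])
    return np.asarray(values), rows, header


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_results(obj, path: str | Path, format: str = "json") -> None:
    """Serialize a result object: matrices as labeled TSV, records as JSON."""
    if format == "tsv":
        values = getattr(obj, "values", obj)
        labels = getattr(obj, "labels", None) or getattr(obj, "frame_ids", None)
        write_matrix(np.asarray(values), path, row_labels=labels)
    elif format == "json":
        with open(path, "w") as fh:
            json.dump(_jsonable(obj), fh, indent=2, sort_keys=True)
            fh.write("\n")
    else:
        raise ValueError("format must be 'tsv' or 'json'")
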
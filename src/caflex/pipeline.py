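"""End-to-end ensemble analysis pipeline and reporting.

``run_pipeline`` ties the stages together: load ensemble -> binding-site
selection -> fluctuation/flexibility/Theta -> strided dRMSD dissimilarity
matrix -> silhouette-validated k-means states -> classical MDS embedding ->
medoids and outliers -> reference comparisons (Q profile, Delta matrix) ->
cleft-width distribution and Gaussian fits -> cluster kinetics -> RMSIP
convergence. Every artifact is a TSV or JSON file; a manifest records the
configuration, seeds and content digests so a rerun with the same config is
byte-identical in its numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .binding import cleft_distance_series, cluster_kinetics, fit_gaussians, open_fraction, q_profile, rmsip
from .cluster import (
    cmds_embed,
    dissimilarity_matrix,
    find_outliers,
    select_k,
    strided_frame_indices,
)
from .distances import (
    cross_submatrix,
    distance_matrix,
    fluctuation_matrix,
    flexibility_matrix,
    mean_abs_difference_matrix,
    overall_fluctuation,
    pair_distance_vectors,
)
from .io import load_ensemble, load_reference, select_binding_site, write_matrix
from .types import ConformerEnsemble, ResidueSelection

logger = logging.getLogger("caflex")

__all__ = ["RunConfig", "run_pipeline", "report"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run (distances in A, times in ps)."""

    input_path: str
    out_dir: str
    input_format: str = "pdb_multimodel"
    topology: str | None = None
    dt: float | None = None
    strand_range: tuple[str, int, int] | None = None
    helix_range: tuple[str, int, int] | None = None
    reference_path: str | None = None
    reference_model: int = 1
    stride: int = 10
    burn_in: float = 1000.0
    k_range: list[int] = field(default_factory=lambda: [2, 3, 4, 5])
    seed: int = 0
    n_init: int = 10
    outlier_threshold: float = 0.8
    cleft_pair: tuple[tuple[str, int], tuple[str, int]] | None = None
    open_threshold: float = 14.0
    q_ks: list[int] = field(default_factory=lambda: [1, 10, 100, 200])
    n_modes: int = 10

    def __post_init__(self) -> None:
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.burn_in < 0:
            raise ValueError("burn_in must be nonnegative")
        if any(k < 2 for k in self.k_range):
            raise ValueError("k_range entries must be >= 2")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "strand_range" in raw and raw["strand_range"] is not None:
            raw["strand_range"] = tuple(raw["strand_range"])
        if "helix_range" in raw and raw["helix_range"] is not None:
            raw["helix_range"] = tuple(raw["helix_range"])
        if "cleft_pair" in raw and raw["cleft_pair"] is not None:
            raw["cleft_pair"] = tuple(tuple(p) for p in raw["cleft_pair"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _dump_json(obj, path: Path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(type(o))

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")


def _default_cleft_pair(ens: ConformerEnsemble, selection: ResidueSelection):
    """Cleft base: C-terminal strand residue vs N-terminal helix residue."""
    strand = selection.blocks["strand"]
    helix = selection.blocks["helix"]
    la = ens.residue_labels[strand[-1]]
    lb = ens.residue_labels[helix[0]]
    return (la.chain, la.resnum), (lb.chain, lb.resnum)


def run_pipeline(config: RunConfig) -> Path:
    """Run every analysis stage and write artifacts plus a manifest.

    Returns the output directory. Any stage failure raises with the stage
    name attached; artifacts written so far are flagged as partial in the
    manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "version": __version__,
        "artifacts": {},
        "stages": {},
        "complete": False,
    }
    stage = "load"

    def emit(name: str, path: Path) -> None:
        manifest["artifacts"][name] = {
            "file": path.name, "sha256": _sha256(path)
        }

    try:
        ens = load_ensemble(
            config.input_path, format=config.input_format,
            topology=config.topology, dt=config.dt,
        )
        logger.info("loaded %d frames of %d residues", ens.n_frames, ens.n_residues)
        manifest["stages"][stage] = {"frames": ens.n_frames, "residues": ens.n_residues}

        stage = "selection"
        selection = None
        if config.strand_range and config.helix_range:
            selection = select_binding_site(
                ens.frames[0], tuple(config.strand_range), tuple(config.helix_range)
            )
            manifest["stages"][stage] = {"n_selected": len(selection)}

        stage = "pair_statistics"
        F = fluctuation_matrix(ens, selection)
        X = flexibility_matrix(ens, selection)
        theta = overall_fluctuation(ens, selection)
        write_matrix(F.values, out / "fluctuation.tsv", row_labels=F.labels)
        write_matrix(X.values, out / "flexibility.tsv", row_labels=X.labels)
        _dump_json(dataclasses.asdict(theta), out / "theta.json")
        emit("fluctuation", out / "fluctuation.tsv")
        emit("flexibility", out / "flexibility.tsv")
        emit("theta", out / "theta.json")

        if selection is not None:
            stage = "cross_submatrices"
            for name, mat in (("fluctuation", F), ("flexibility", X)):
                sub, ia, ib = cross_submatrix(mat.values, selection, "strand", "helix")
                path = out / f"submatrix_{name}.tsv"
                write_matrix(
                    sub, path,
                    row_labels=[mat.labels[i] for i in ia],
                    col_labels=[mat.labels[j] for j in ib],
                )
                emit(f"submatrix_{name}", path)

        stage = "dissimilarity"
        refs = []
        reference = None
        if config.reference_path:
            reference = load_reference(config.reference_path, config.reference_model)
            refs = [reference]
        dmat = dissimilarity_matrix(
            ens, selection, stride=config.stride, burn_in=config.burn_in,
            extra_refs=refs,
        )
        frame_idx = strided_frame_indices(ens, config.stride, config.burn_in)
        sub_ens = ens.subset_frames(frame_idx)
        write_matrix(dmat.values, out / "dissimilarity.tsv", row_labels=dmat.frame_ids)
        emit("dissimilarity", out / "dissimilarity.tsv")
        manifest["stages"][stage] = {"frames_kept": len(frame_idx), "refs": len(refs)}

        stage = "clustering"
        ks = [k for k in config.k_range if k <= sub_ens.n_frames]
        if not ks:
            raise ValueError("k_range exceeds available frame count")
        best_k, per_k = select_k(
            sub_ens, selection, ks, seed=config.seed, n_init=config.n_init
        )
        best = per_k[best_k]
        _dump_json(
            {
                "best_k": best_k,
                "s_over_per_k": {str(k): per_k[k].s_over for k in ks},
                "wcss_per_k": {str(k): per_k[k].wcss for k in ks},
                "labels": best.labels,
                "medoids": best.medoids,
                "s_over": best.s_over,
                "silhouette": best.silhouette,
                "n_iter": best.n_iter,
                "seed": best.seed,
            },
            out / "clusters.json",
        )
        emit("clusters", out / "clusters.json")
        manifest["stages"][stage] = {"best_k": best_k, "s_over": best.s_over}

        stage = "mds"
        emb = cmds_embed(dmat, dims=2)
        write_matrix(
            emb.coords, out / "embedding.tsv",
            row_labels=emb.frame_ids, col_labels=["mds1", "mds2"],
        )
        emit("embedding", out / "embedding.tsv")

        stage = "medoids_outliers"
        overall_medoid = best.medoids[int(np.argmax(np.bincount(best.labels)[1:]))]
        outliers = find_outliers(
            sub_ens, selection, overall_medoid, config.outlier_threshold
        )
        _dump_json(
            {
                "medoid_frame": int(overall_medoid),
                "threshold": config.outlier_threshold,
                "outliers": outliers,
                "n_outliers": int(outliers.size),
            },
            out / "outliers.json",
        )
        emit("outliers", out / "outliers.json")

        if reference is not None:
            stage = "q_profile"
            ref_idx = selection.indices if selection is not None else None
            qks = [k for k in config.q_ks if k <= sub_ens.n_frames]
            qp = q_profile(sub_ens, selection, reference, qks,
                           reference_indices=ref_idx)
            _dump_json(
                {"reference": qp.reference_id, "ks": qp.ks,
                 "q_values": qp.q_values},
                out / "qprofile.json",
            )
            emit("qprofile", out / "qprofile.json")

            stage = "delta_matrix"
            nearest = qp.neighbor_frames[max(qp.ks)]
            ref_dm = distance_matrix(reference, selection)
            delta = mean_abs_difference_matrix(
                sub_ens.subset_frames(nearest), ref_dm, selection
            )
            write_matrix(delta.values, out / "delta.tsv", row_labels=delta.labels)
            emit("delta", out / "delta.tsv")

        stage = "cleft"
        pair = config.cleft_pair
        if pair is None and selection is not None and selection.blocks:
            pair = _default_cleft_pair(ens, selection)
        if pair is not None:
            series = cleft_distance_series(ens, tuple(pair[0]), tuple(pair[1]))
            with open(out / "cleft.tsv", "w") as fh:
                fh.write("time_ps\tdistance_A\n")
                times = series.frame_times if series.frame_times is not None \
                    else np.arange(len(series.values), dtype=float)
                for t, v in zip(times, series.values):
                    fh.write(f"{t!r}\t{v!r}\n")
            emit("cleft_series", out / "cleft.tsv")
            fit = fit_gaussians(series, random_state=config.seed)
            frac, count = open_fraction(series, config.open_threshold)
            _dump_json(
                {
                    "residue_pair": list(series.residue_pair),
                    "n_components": fit.n_components,
                    "means": fit.means,
                    "sds": fit.sds,
                    "weights": fit.weights,
                    "bic": {str(k): v for k, v in fit.model_scores.items()},
                    "open_threshold": config.open_threshold,
                    "open_fraction": frac,
                    "open_count": count,
                },
                out / "cleft_fit.json",
            )
            emit("cleft_fit", out / "cleft_fit.json")

        stage = "kinetics"
        if best_k >= 2:
            dt_eff = None
            if ens.dt is not None:
                dt_eff = ens.dt * config.stride
            elif ens.frame_times is not None and len(frame_idx) > 1:
                steps = np.diff(ens.frame_times[frame_idx])
                if np.allclose(steps, steps[0]):
                    dt_eff = float(steps[0])
            if dt_eff is not None and np.unique(best.labels).size >= 2:
                vecs = pair_distance_vectors(sub_ens, selection)
                p = vecs.shape[1]
                centroid_sig = np.linalg.norm(
                    vecs - best.cluster_means[best.labels - 1], axis=1
                ) / np.sqrt(p)
                kin = cluster_kinetics(best.labels, dt_eff, centroid_sig)
                _dump_json(
                    {
                        "dt_ps": dt_eff,
                        "mean_intercluster_transition_time_ps":
                            kin.mean_intercluster_transition_time,
                        "mean_intracluster_relaxation_time_ps":
                            kin.mean_intracluster_relaxation_time,
                        "dwell_times_ps": {str(k): v for k, v in kin.dwell_times.items()},
                    },
                    out / "kinetics.json",
                )
                emit("kinetics", out / "kinetics.json")

        stage = "rmsip"
        n_modes = min(config.n_modes, 3 * (len(selection) if selection else ens.n_residues))
        if ens.n_frames // 2 >= n_modes:
            conv = rmsip(ens, selection, n_modes=n_modes, split="halves")
            _dump_json(
                {"rmsip": conv.rmsip, "n_modes": conv.n_modes, "split": conv.split},
                out / "rmsip.json",
            )
            emit("rmsip", out / "rmsip.json")

        manifest["complete"] = True
    except Exception as exc:
        manifest["failed_stage"] = stage
        _dump_json(manifest, out / "manifest.json")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    _dump_json(manifest, out / "manifest.json")
    logger.info("pipeline complete: %d artifacts in %s",
                len(manifest["artifacts"]), out)
    return out


def report(run_dir: str | Path) -> str:
    """Human-readable summary of a completed pipeline run."""
    run_dir = Path(run_dir)
    mpath = run_dir / "manifest.json"
    if not mpath.exists():
        raise FileNotFoundError(
            f"no manifest.json in {run_dir}; expected artifacts: manifest.json, "
            "theta.json, clusters.json, ..."
        )
    manifest = json.loads(mpath.read_text())
    lines = [f"caflex run report — {run_dir}"]
    missing = []

    def load(name):
        info = manifest["artifacts"].get(name)
        if info is None:
            missing.append(name)
            return None
        p = run_dir / info["file"]
        if not p.exists():
            missing.append(name)
            return None
        return json.loads(p.read_text()) if p.suffix == ".json" else p

    theta = load("theta")
    if theta:
        lines.append(
            f"Theta (overall fluctuation): {theta['theta']:.4f} A over "
            f"{theta['n_frames']} frames, {theta['n_residues']} residues "
            f"({theta['pair_scope']})"
        )
    clusters = load("clusters")
    if clusters:
        lines.append(
            f"Best k: {clusters['best_k']} (S_OVER = {clusters['s_over']:.3f}); "
            f"medoid frames: {clusters['medoids']}"
        )
    outl = load("outliers")
    if outl:
        lines.append(
            f"Outliers: {outl['n_outliers']} frames beyond "
            f"{outl['threshold']} A of medoid frame {outl['medoid_frame']}"
        )
    qp = load("qprofile")
    if qp:
        qstr = ", ".join(
            f"Q({k}) = {v:.3f} A" for k, v in zip(qp["ks"], qp["q_values"])
        )
        lines.append(f"Q profile vs {qp['reference']}: {qstr}")
    else:
        lines.append("Q profile: not computed")
    cleft = load("cleft_fit")
    if cleft:
        comp = ", ".join(
            f"N(mu={m:.2f} A, sd={s:.2f} A, w={w:.2f})"
            for m, s, w in zip(cleft["means"], cleft["sds"], cleft["weights"])
        )
        lines.append(
            f"Cleft {cleft['residue_pair']}: {cleft['n_components']} component(s): "
            f"{comp}; open fraction (> {cleft['open_threshold']} A) = "
            f"{cleft['open_fraction']:.4f} ({cleft['open_count']} frames)"
        )
    else:
        lines.append("Cleft distribution: not computed")
    kin = load("kinetics")
    if kin:
        relax = kin["mean_intracluster_relaxation_time_ps"]
        relax_str = f"{relax:.1f} ps" if relax is not None else "n/a"
        lines.append(
            "Kinetics: mean inter-cluster transition time "
            f"{kin['mean_intercluster_transition_time_ps']:.1f} ps; "
            f"intra-cluster relaxation time {relax_str}"
        )
    else:
        lines.append("Kinetics: not computed")
    conv = load("rmsip")
    if conv:
        lines.append(
            f"RMSIP ({conv['split']}, {conv['n_modes']} modes): {conv['rmsip']:.3f}"
        )
    else:
        lines.append("RMSIP: not computed")
    if missing:
        lines.append(f"Missing artifacts: {', '.join(missing)}")
    return "\n".join(lines)
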
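# caflex

Distance-geometry analysis of Cα conformational ensembles.

`caflex` quantifies how flexible a protein region — typically a peptide-binding
pocket — is across a conformational ensemble (an MD trajectory, a multi-model
PDB entry, or a set of crystal structures), decomposes the ensemble into
conformational states, and asks whether a ligand-bound reference conformation
is visited spontaneously (a conformational-selection signature) or not (an
induced-fit signature). It was built with PDZ-domain binding grooves in mind —
the cleft between the β2 strand and the α2 helix — but operates on any
Cα selection.

Everything is superposition-free: structures are compared through their
internal Cα pair-distance matrices rather than through fitted coordinates.

## The statistics

For a conformer *A* of *N* residues, *d^A^* is its *N×N* Cα distance matrix.
Over an ensemble *S = {S₁, …, S_K}*:

- **δ = d^A^ − d^B^** — signed difference-distance matrix; positive entries are
  pairs further apart in *A*.
- **dRMSD(A, B) = √( mean over the N(N−1)/2 unordered pairs of
  (d^A^_ij − d^B^_ij)² )** — a superposition-independent pseudometric.
- **F_ij = Var(d_ij)** — fluctuation matrix (population variance over the
  ensemble, Å²).
- **X_ij = max(d_ij) − min(d_ij)** — flexibility matrix (range, Å), which
  captures rare large excursions that variance smooths over.
- **Θ = √(mean off-diagonal F)** — overall fluctuation, identically the RMS
  dRMSD of the ensemble members to the ensemble-mean distance matrix; a single
  number for the size of conformational space explored.
- **States**: k-means in distance-matrix space. A cluster centroid is the mean
  distance matrix *C_i* of its members and the objective is the within-cluster
  sum of squared dRMSD values (WCSS); *k* is chosen by the maximal overall
  average silhouette index *S_OVER*. Classical (Torgerson–Gower) MDS maps the
  pairwise dRMSD matrix to 2-D for inspection; medoids and outliers
  (dRMSD ≥ threshold from the medoid) summarise each state.
- **Q^(k)^** — mean dRMSD of the *k* ensemble conformers nearest to a
  ligand-bound reference structure (k ∈ {1, 10, 100, 200} by default). Small
  Q^(1)^/Q^(10)^ means bound-like geometry is sampled without the ligand.
- **Cleft width** — the Cα distance across the base of the binding groove
  (C-terminal strand residue to N-terminal helix residue), its Gaussian or
  two-Gaussian-mixture fit (selected by BIC), and the fraction of frames open
  beyond a threshold.
- **Kinetics and convergence** — dwell times of the state-label sequence
  (mean inter-state transition time vs intra-state relaxation time) and RMSIP
  overlap of principal-component subspaces between trajectory segments.

A seeded synthetic-ensemble generator (idealised strand+helix pocket,
harmonic one-state and Markov two-state ensembles, Gaussian-mixture cleft
series) provides ground truth for every estimator.

## Worked example

```python
import caflex

ref_open = caflex.make_reference_pocket(cleft_base_distance=6.3)
ref_wide = caflex.make_reference_pocket(cleft_base_distance=8.3)
sel = caflex.pocket_selection(ref_open)

lab = caflex.generate_two_state(ref_open, ref_wide, switch_prob=0.01,
                                noise_sd=0.05, K=2000, dt=5.0, seed=42)
theta = caflex.overall_fluctuation(lab.ensemble, sel)
print(f"Theta = {theta.theta:.3f} A over {theta.n_frames} frames")

best_k, per_k = caflex.select_k(lab.ensemble, sel, [2, 3, 4], seed=0)
res = per_k[best_k]
print(f"best k = {best_k} (S_OVER = {res.s_over:.3f})")

qp = caflex.q_profile(lab.ensemble, sel, ref_wide, [1, 10, 100, 200])
print("Q profile vs bound-like reference:",
      ", ".join(f"Q({k}) = {q:.3f} A" for k, q in zip(qp.ks, qp.q_values)))

series = caflex.cleft_distance_series(lab.ensemble, ("A", 5), ("A", 101))
fit = caflex.fit_gaussians(series)
print(f"cleft distribution: {fit.n_components} components, "
      + ", ".join(f"mu = {m:.2f} A (w = {w:.2f})"
                  for m, w in zip(fit.means, fit.weights)))

kin = caflex.cluster_kinetics(res.labels, dt=5.0)
print(f"mean inter-state transition time = "
      f"{kin.mean_intercluster_transition_time:.0f} ps")
```

prints

```
Theta = 0.302 A over 2000 frames
best k = 2 (S_OVER = 0.838)
Q profile vs bound-like reference: Q(1) = 0.036 A, Q(10) = 0.042 A, Q(100) = 0.051 A, Q(200) = 0.055 A
cleft distribution: 2 components, mu = 6.30 A (w = 0.39), mu = 8.30 A (w = 0.61)
mean inter-state transition time = 558 ps
```

The generator switched between two pocket geometries (cleft base 6.3 Å vs
8.3 Å) with probability 0.01 per 5 ps frame. The analysis recovers exactly
that structure: two states chosen by the silhouette criterion, a bimodal
cleft-width distribution with component means at the two generating
geometries, a mean dwell time near the geometric expectation dt/p = 500 ps,
and a low Q^(1)^ because the "bound-like" wide reference is genuinely visited.

## Command line

```sh
caflex synth --kind two_state --frames 2000 --seed 42 \
    --out ens.pdb --truth-out truth.json
caflex theta --input ens.pdb --dt 5 --strand A:1-5 --helix A:101-110
caflex run --config run.yaml      # full pipeline -> artifacts + manifest
caflex report <run-dir>
```

Subcommands: `fluctuation`, `flexibility`, `theta`, `cluster`, `mds`,
`qprofile`, `delta`, `cleft`, `kinetics`, `rmsip`, `synth`, `run`, `report`.
Analysis defaults follow common MD practice for ~200 ns trajectories saved
every 5 ps: 1 ns burn-in, 50 ps stride for the dissimilarity matrix, k chosen
by maximal S_OVER, and Q evaluated at k ∈ {1, 10, 100, 200}.

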
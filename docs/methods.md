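# Methods

This note records the definitions, conventions and design choices behind
`caflex`, in the spirit of the model documentation that packages like
statsmodels or msprime ship: what is computed, under which assumptions, and
what the synthetic tests do and do not demonstrate.

## Representation

Structures are reduced to ordered Cα traces. A conformer is an (N, 3) array
of positions in Å with residue labels (chain, author residue number, residue
name); an ensemble is an ordered list of conformers sharing identical labels,
optionally with frame times in ps. Author PDB numbering (1-based, per chain)
is the user-facing convention; internal indices are 0-based; ranges such as
`A:27-31` are inclusive at both ends. Residues with insertion codes are
rejected rather than silently reordered; alternate-location Cα atoms resolve
to the highest occupancy with the alphabetically first altloc id breaking
ties. Multi-model reference files default to model 1.

Internally every frame is flattened to its condensed pair-distance vector
*v* (the N(N−1)/2 upper-triangle entries of the distance matrix), so that
dRMSD(A, B) = ‖v_A − v_B‖ / √P with P the pair count. All ensemble
statistics, clustering and Q-profile computations are vectorised on this
array; tests verify equivalence with literal double-loop evaluation of the
definitions to 1e-12.

## Distance statistics and their conventions

- **dRMSD** averages squared pair-distance differences over the N(N−1)/2
  *unordered* pairs. The symmetric ordered-pair sum gives the same value, so
  only the denominator convention needs fixing; it is fixed here and used
  consistently everywhere (clustering objective, silhouettes, Q values,
  outlier thresholds are all on this scale).
- **F** uses the *population* variance (divide by K, not K−1). This is what
  makes the Θ identity exact: Θ² = mean(off-diagonal F) equals the mean
  squared dRMSD of the frames to the ensemble-mean distance matrix, an
  identity the test suite checks to 1e-12 on random ensembles.
- **Θ pair scope** defaults to all pairs within the selection. A
  `cross_block` scope (strand × helix pairs only) is available because
  binding sites are also characterised by the 5×10 cross submatrices of δ, F
  and X; which scope a published table used is rarely stated, so both are
  explicit here and the output records the scope.
- **Matrix correlation** (e.g. comparing a simulated fluctuation pattern with
  an experimental-ensemble flexibility pattern) uses upper-triangle
  off-diagonal entries for square matrices — counting each unordered pair
  once — and all entries for rectangular cross submatrices.
- **Superposed RMSD** uses the closed-form least-squares (Kabsch) rotation
  with reflections excluded; collinear point sets are rejected as degenerate.
  It exists for comparing static structures (sequence-identity/RMSD tables);
  all ensemble machinery is deliberately superposition-free.
- **Sequence identity** divides matches by gap-free aligned columns, the same
  denominator as the residue-pair mapping; the convention is stated in the
  function contract because alternative denominators change reported
  identities by several points.

## Conformational states

k-means operates in distance-matrix space: a centroid is the mean distance
matrix C_i of the cluster members, which need not be realisable as a 3-D
conformation — acceptable because the objective (WCSS, the within-cluster sum
of squared dRMSD to C_i) is defined entirely in that space. Since dRMSD is a
scaled Euclidean norm on pair-distance vectors, Lloyd iteration applies
unchanged: assignment to the nearest C_i, then mean update, with WCSS
non-increasing per iteration. Initialisation is greedy farthest-point seeding
from a seeded random first centre, best of `n_init = 10` restarts; empty
clusters are re-seeded with the frame farthest from its centroid;
convergence when assignments stop changing or the WCSS improvement drops
below 1e-10 Å². A useful exact consequence: WCSS at k = 1 equals K·Θ².

k is selected by maximising the overall average silhouette S_OVER, ties
toward smaller k. Silhouettes use a(i) = mean dRMSD to own-cluster members,
b(i) = minimum over other clusters of the mean dRMSD to that cluster;
singleton clusters score 0 (Rousseeuw's convention). Medoid ties break to the
earliest frame; outliers are frames with dRMSD *greater than or equal to* the
threshold from the medoid (the inclusive reading of "equal or larger").
Typical thresholds in pocket analyses are 0.8–0.9 Å.

Classical MDS double-centres the squared dissimilarity matrix
(B = −½ J D² J), eigendecomposes, and takes coordinates from eigenvalues
above a relative noise floor of 1e-12 × λ₁; negative eigenvalues are recorded
but never used. Axis signs are canonicalised (largest-magnitude loading
positive) so repeated runs are bit-identical. For Euclidean-embeddable input
the original distances are reproduced exactly (tested to 1e-8).

By default clustering and MDS run on the same strided, burn-in-filtered frame
set. Frame i of a saved trajectory is taken to be at time (i+1)·dt when no
explicit times are present — the first saved snapshot of a production run is
one save interval after its start — and burn-in keeps frames with
t ≥ burn-in. With 5 ps saves over 200 ns, 1 ns burn-in and a 50 ps stride
this yields 3981 frames. Reference structures appended to the dissimilarity
matrix are assigned to states by nearest centroid.

## Binding diagnostics

Q^(k) ranks frames by dRMSD to a ligand-bound reference (stable sort, ties by
frame order) and averages the k nearest; it is nondecreasing in k by
construction. The interpretation is comparative: across complexes of the same
ensemble, higher Q^(1)/Q^(10) marks the bound conformations least approached
in the apo simulation, i.e. the strongest induced-fit candidates.

Cleft-width series take the Cα distance between a chosen residue pair per
frame (canonically the C-terminal strand residue against the N-terminal helix
residue, the base of the groove). Mixture fits use maximum likelihood with
expectation-maximisation (seeded, 5 restarts) for the two-component
candidate, and the Bayesian information criterion selects the component
count; at least 50 samples are required and zero-variance series are
rejected. The open fraction uses the strict inequality d > threshold.

Kinetics summarise a per-frame state-label sequence by maximal constant-label
runs. The final run is right-censored and excluded; the first run is excluded
by default as well (no preceding transition), switchable via
`include_first_dwell`. The mean inter-cluster transition time is the mean
complete dwell. The intra-cluster relaxation time is the 1/e crossing time
(linearly interpolated) of the within-run autocorrelation of the per-frame
dRMSD-to-own-centroid signal, with deviations taken from each run's own mean
so state jumps do not leak into the estimate. These are deliberately simple
run-length estimators, not a Markov state model; their purpose is the
qualitative check that intra-state relaxation is much faster than inter-state
transitions, which is what justifies calling the clusters metastable states.

RMSIP superposes each segment's frames onto the segment mean (three
iterations of Kabsch alignment), takes the top D (default 10) principal
components of the 3N-dimensional fluctuations, and computes
√((1/D)ΣΣ(η_i·ν_j)²) between the two mode sets. The default split is
first-half vs second-half; custom splits are supported. Values near 1
indicate the two segments sample the same essential subspace; the measure is
invariant to orthogonal re-basis within either span.

## Synthetic ensembles

The generators emulate exactly the statistical structure the estimators
assume, with explicit seeds and bit-reproducible output:

- an idealised pocket (extended strand, 3.8 Å Cα spacing; ideal helix, 1.5 Å
  rise, 100° per residue, 2.3 Å radius) with the cleft base pair placed at an
  exact requested distance;
- harmonic ensembles: independent isotropic Gaussian displacement per
  coordinate (for well-separated pairs the induced pair-distance variance is
  ≈ 2σ², the delta-method value the tests check);
- two-state ensembles: a hidden symmetric Markov chain (geometric dwells,
  mean dt/p) selecting between two reference geometries, plus intra-state
  noise. Default conditions (cleft bases 6.3 Å vs 8.3 Å, noise 0.05 Å) give
  an inter-state dRMSD separation more than five times the intra-state Θ,
  the regime in which state recovery is claimed and tested;
- cleft series: i.i.d. Gaussian-mixture draws.

What these do *not* emulate: anisotropic, correlated fluctuations (an elastic
network's covariance), asymmetric exchange rates, slow drift,
autocorrelated intra-state noise, or solvent/side-chain effects. Passing the
recovery tests therefore shows the estimators are correct under their own
model assumptions — it does not show that a real trajectory satisfies those
assumptions, and on real data the silhouette criterion in particular is
typically far less decisive than the clean-mixture values near 0.8 seen on
synthetic input.

## Problem sizes and numerical choices

The test suite and acceptance script run on ensembles of 100–20 000 frames
and 15–20 residues — sizes chosen so every claim is checked by direct
computation with independent oracles (brute-force loops, sklearn's
precomputed-metric silhouette, scikit-bio's principal-coordinates analysis,
MDAnalysis' superposition RMSD, dense rotation-grid search). Tolerances:
algebraic identities at 1e-12, MDS exactness at 1e-8, rigid-motion
invariance at 1e-9, stochastic parameter recovery at CLT-scaled bounds.
Published headline numbers for real PDZ ensembles derive from 200 ns
trajectories that are not redistributable; regenerating them requires
rerunning MD (GROMACS-class tooling), which this package documents but does
not perform.

## Known limitations

- Distance-space centroids are not realisable conformations; medoids are
  provided as the representative structures.
- Classical MDS has no out-of-sample transform; references must be included
  in the dissimilarity matrix before embedding.
- The kinetics estimators assume a well-resolved two-or-more-state label
  sequence; for rapidly mixing labels the dwell statistics describe noise.
- PDB output is fixed-point (0.001 Å), so file round trips are not
  bit-exact; TSV/JSON artifacts use full float precision and are.
- The BIC can prefer two components for heavy-tailed unimodal data; the fit
  reports all candidate scores so the decision is auditable.
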
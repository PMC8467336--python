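# Methods

This note records the models implemented in `msmnet`, the defaults and the
reasoning behind them, what the synthetic generators do and do not emulate,
and the numerical conventions a user relying on the outputs should know.

## Kinetic model

The kinetic half treats the conformational ensemble as a discrete-time Markov
chain over microstates obtained by clustering a reduced representation of the
trajectory.

**Featurization.** Frames are described by Euclidean distances between Cα
pairs. Default pair set: all pairs with sequence separation ≥ 3 (bonded
neighbours carry almost no conformational signal), capped at 20 000 pairs by
deterministic fixed-stride subsampling of the sorted pair list. The cap keeps
the feature matrix tractable at desk scale; it is configurable up to all
pairs. Distance features are translation- and rotation-invariant, so no
superposition is needed in this half.

**Dimensionality reduction.** Plain PCA on the pooled features of all
ensembles in the reference run (the conditions to be compared must share one
coordinate system). The transform — feature mean, orthonormal components,
explained variances — is serialized to JSON and can be re-applied to further
ensembles (the mutant workflow) without refitting, which makes PC coordinates
comparable across runs. Sign convention: each component's largest-magnitude
entry is made positive, so serialized transforms are bit-reproducible.
Default 2 components. PCA ranks directions by variance, not by kinetic
content; for the well-separated basins the generators produce (and for large
conformational rearrangements generally) the two coincide, but a slow process
with small amplitude could in principle be missed — a known limitation of
variance-based reduction.

**Discretization.** Lloyd k-means with k-means++ seeding (scikit-learn
backend; defaults k = 100 centres, 200 iterations). Assignment is recomputed
as an explicit argmin over centres so that distance ties resolve to the
lowest centre index — scikit-learn's internal tie handling is not specified,
and determinism end-to-end requires it.

**Estimation.** Transitions are counted with a sliding window at lag τ,
never across trajectory boundaries. The estimator is restricted to the
largest strongly connected component of the count graph; dropped states are
logged. The transition matrix is the maximum-likelihood reversible matrix
obtained by the standard self-consistent iteration on symmetrized count
variables (convergence when the stationary vector changes by < 1e-10
relative, cap 1e5 iterations; non-convergence is an error, never silently
accepted). Row-stochasticity, stationarity of π and detailed balance are
asserted on every constructed model at 1e-10/1e-8.

**Validation.** Implied timescales t_i(τ) = −τ/ln λ_i(τ) are computed per
lag from a freshly estimated model; eigenvalues ≤ 0 are reported as NaN
rather than fabricated, and a failure at one lag does not abort the others.
The Chapman-Kolmogorov test compares [T(τ)]^s with a model re-estimated at
lag sτ, aggregated over macro-sets with stationary weights. Pass criterion
per entry: |predicted − re-estimated| within the larger of 0.05 and the 95 %
band from 200 trajectory-level bootstrap resamples. The 0.05 floor makes the
test usable on short data where the bootstrap band collapses; the band makes
it honest on long data where 0.05 would be generous.

**Coarse-graining.** PCCA+ on the first m right eigenvectors of the
reversible matrix (orthonormal under the π-weighted inner product): the
eigenvector rows lie near an (m−1)-simplex; vertices are located by the
inner-simplex search (furthest-row recursion), memberships are the inverse
vertex map clamped to [0, 1] and renormalized, and crisp assignment is the
row argmax with ties to the lowest macrostate index. Degenerate eigenvalues
at the cut and empty macrostates are errors advising a different m. The
implementation is deliberately the non-optimized PCCA+ variant: transparent,
deterministic, and sufficient for block-dominant matrices; it may split
basins sub-optimally on strongly overlapping spectra.

**Kinetics.** Mean first passage times solve m_i = τ + Σ_j T_ij m_j with
m = 0 on the target, then average over the source with stationary weights.
Source states inside the target contribute zero, so the passage time of a
set to itself is 0. Physical units: steps × lag frames × frame interval;
frame times are ps internally, ns at reporting. "OTHER" entries aggregate
transitions to/from the union of all remaining macrostates. Per-macrostate
ensemble composition is the fraction of assigned frames per label;
representative conformations are the frames nearest (in PC space) to the
membership-weighted mean of the macrostate's cluster centres, optionally
restricted to the macrostate's dominant label (with a logged fallback when
the restriction is empty), ties to the earliest frame.

## Correlation and network model

**Displacements.** Each frame's Cα coordinates are least-squares superposed
onto a reference frame (Kabsch rotation via SVD, reflections excluded;
collinear references are rejected), and per-residue time means are removed.
Superposition can be disabled for data generated without rigid-body motion —
with few beads the 6 rigid degrees of freedom absorb a visible fraction of
the signal, which matters for planted-correlation checks.

**Generalized correlation.** GC_ij = sqrt(1 − exp(−2 MI_ij / d)) with d = 3
(the displacement vectors are 3-dimensional) and MI in nats throughout — the
exp/ln pairing requires one base. Two estimators:

* `gaussian` (default): closed form ½ ln(det Σ_x det Σ_y / det Σ_xy) from
  sample covariances. Fast (one 3n × 3n covariance pass, then 3×3/6×6 block
  determinants), exactly checkable against planted Gaussian data, exact in
  the Gaussian limit — but blind to purely nonlinear dependence.
* `knn`: Kraskov–Stögbauer–Grassberger estimator 1 (Chebyshev metric,
  default k = 6 neighbours), written against scipy's cKDTree. Nonparametric,
  captures nonlinear coupling, noisier at small n.

Negative estimates are clamped at 0 (MI is non-negative; small-sample KSG
can dip below). Per-pair estimator failures (singular covariances) are
recorded and reported as NaN instead of aborting the matrix. On Gaussian
data with per-coordinate correlation ρ both estimators recover GC = |ρ|; the
two agree within 0.05 at n = 10 000, which is the module's central
correctness property. Absolute GC values from real data remain
estimator-dependent; comparisons across ensembles should fix one estimator.

**Network construction.** Nodes are residues (Cα anchors, chain identifier
as monomer tag). An edge requires contact persistence ≥ 0.75 at a 4.5 Å
cutoff: the fraction of frames in which the minimum inter-residue atom
distance (heavy-atom mode; a pure-Cα mode serves bead models, where it is
the only option) is within the cutoff, found per frame with a k-d tree.
Bonded neighbours (|i − j| ≤ 1 within a chain, configurable; 0 restores the
purely geometric rule) are excluded as trivially persistent contacts. Edge
length d_ij = −ln GC_ij; the log base only rescales weights and changes no
path or partition, and is configurable. Pairs with GC ≤ 1e-6 are dropped
and logged rather than carrying quasi-infinite lengths.

**Communities and paths.** Weighted edge betweenness follows Brandes'
algorithm with equal fractional credit to tied shortest paths. Girvan-Newman
removes the highest-betweenness edge (ties: lexicographically smallest),
recomputes, and records the partition sequence down to singletons; the
reported partition maximizes weighted modularity with GC as edge strength —
the divisive sweep itself prescribes no stopping level, so selection needs a
criterion, and modularity is the standard one. The full dendrogram is
retained. Inter-community flow is the count and summed betweenness of
boundary edges. Optimal paths use Floyd–Warshall distances with greedy
lexicographic reconstruction (equal-length path sets resolve to the smallest
node sequence); suboptimal paths are enumerated depth-first within a weight
tolerance Δ of the optimum, pruned by the (admissible) Floyd–Warshall
distance-to-sink bound, deduplicated, sorted by weight then lexicographically,
and truncated with a flag at a path-count cap. An unreachable sink is an
explicit "no path" result, not an exception. Default endpoints follow the
mutation-site → nucleotide-binding-motif convention (source residue 1441 of
each monomer; sinks 1346, 1394, 1455, 1490 — P-loop, Switch II, G4 loop, G5
loop), fully overridable for other systems; the subopt tolerance Δ has no
canonical value and defaults to 1.0 (in −ln GC units, i.e. paths at most a
factor e "longer" in correlation terms).

## Synthetic study conditions

The generators provide exact ground truth, not physical realism:

* **Multi-basin trajectories**: a hidden Markov chain (known row-stochastic
  T, started from its stationary distribution to avoid burn-in ambiguity in
  composition tests) emits per-state reference bead structures plus
  isotropic Gaussian noise. References are beads on a helix — non-collinear,
  so superposition is well conditioned — with two chain tags split at the
  midpoint, and basins differ by displacing the second chain only, so basin
  identity is visible to translation-invariant distance features (a rigid
  shift of all beads would be invisible).
* **The asymmetric two-basin condition**: four states, basins A = {0, 1},
  B = {2, 3}; each A state leaves for B at rate a = 3b, each B state for A
  at rate b = 0.02, intra-basin mixing 0.2. Basin symmetry makes the
  stationary-weighted set MFPTs exactly 1/a and 1/b steps, so the planted
  3:1 asymmetry is analytic, and the chain is reversible by construction.
  Two labelled ensembles start in opposite basins (stationary distribution
  restricted to the basin — mimicking ensembles prepared in different
  states) but share the chain, so pooled estimation is consistent.
* **Planted correlations**: iid frames of jointly Gaussian bead
  displacements in which coordinate k of bead i correlates only with
  coordinate k of bead j, at ρ_ij (Cholesky construction; non-positive-
  definite requests are rejected naming an offending pair). For these, the
  generalized correlation of a pair is exactly |ρ_ij|.
* **Planted partitions**: stochastic block graphs with within/between edge
  probabilities and GC weights, plus the two-clique bridge graph.

All generators are bit-deterministic given a seed; one global seed fans out
to named substreams (hmm, corr, net, cluster, bootstrap) by fixed offsets,
so components are independently reproducible.

What the generators do **not** emulate — and hence what passing tests do not
show about real data: force-field physics, anisotropic and correlated
emission noise, rugged basins with internal structure, slow processes of
small variance (where PCA can mis-rank), non-Gaussian displacement
distributions (where the default GC estimator is only a lower bound), and
solvent/ligand degrees of freedom. Absolute timescales of any real system
are not reproduced; only the internal consistency of estimator and truth is
demonstrated.

## Validation problem sizes

The shipped validation suite uses: 10 000-frame/20-bead ensembles for
planted-correlation recovery; 500 000-step chains for implied timescales and
for the full kinetic pipeline (two ensembles of 250 000 frames, 100
microstates); 20 × 10 000 steps for Chapman-Kolmogorov discrimination; 20
seeds of 4 × 10 planted-partition graphs; 100 random graphs (n ≤ 50) for the
path oracles; and 2 × 20 000 frames for the end-to-end determinism check.
These sizes put Monte-Carlo error comfortably inside the tolerances asserted
(e.g. basin-crossing counts of several thousand give MFPT errors of a few
percent) while keeping the whole suite at minutes on one CPU.

## Known limitations

* Effective-count corrections, Bayesian MSM uncertainty, TRAM and hidden
  Markov MSMs are out of scope; error bars on MFPTs would need them.
* The CK bootstrap resamples whole trajectories; with a single long
  trajectory the band degenerates and the 0.05 floor carries the test.
* Girvan-Newman recomputes betweenness after every removal (O(E²V) overall);
  fine for residue-scale graphs (≤ ~10³ nodes), not for much larger ones.
* Suboptimal-path enumeration is exponential in the worst case; the
  max-paths cap with a truncation flag keeps it bounded.
* The Gaussian MI estimator understates dependence on strongly non-Gaussian
  displacements; use `knn` there and expect slower, noisier matrices.
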
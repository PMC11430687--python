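# Methods

## Model overview

A subject's recording is a T×N matrix of regional BOLD-like signals.  The
analysis represents it as a multilayer temporal network: one weighted graph
per timepoint over the same N nodes, plus couplings that link each node to
itself in the two adjacent layers.  Community structure is estimated jointly
across layers, and reconfiguration metrics summarize how nodes move between
communities over time.

### Instantaneous phase and TVFC

Each column is demeaned (the analytic-signal phase is meaningless with a DC
offset; the source procedure is silent on this, so it is done
unconditionally) and Hilbert-transformed; θ_{n,t} is the phase of the
analytic signal.  The connectivity layer at t has entries
cos(θ_{n,t} − θ_{p,t}) ∈ [−1, 1]: 1 when two regions are synchronized, 0 at
orthogonality (90° phase difference), −1 in anti-phase.  Because the
biological meaning of negative phase coherence is unclear, negative entries
are set to zero, leaving weighted layers in [0, 1].  The diagonal is zeroed
so self-loops never enter degree sums.  All T layers are kept by default;
`trim_edges=k` optionally discards k layers at each end where the discrete
Hilbert transform is least reliable.  Constant columns raise by default
(`permissive=True` maps them to zero phase instead).

### Inter-layer coupling

Layers are binarized — by default an edge exists wherever the clamped
coherence is positive (phase difference < 90°); a per-layer proportional
threshold (`density:d`, ties at the threshold kept, zero weights never
kept) is available.  The coupling of node i between layers t and t+1 is the
neighborhood-overlap similarity

    ω_i^{t,t+1} = Σ_j a_ij^t a_ij^{t+1} / (Σ_j a_ij^t · Σ_j a_ij^{t+1})

implemented exactly as written (`similarity="literal"`).  This form divides
the overlap by the *product* of the two degrees, which makes ω
degree-dependent: a node whose neighborhood of size k is perfectly preserved
scores 1/k, not 1.  Since a square root in the denominator would give the
standard binary cosine similarity, that variant is provided as
`similarity="cosine"` and both are recorded in output metadata.  A node
isolated in either layer gets ω = 0 (no evidence of persistence).  The
subject-level coupling strength used in group comparisons is the mean of ω
over nodes and layer pairs; the node-level value is the mean over layer
pairs.

### Multilayer modularity and optimization

Community labels g_il over (node, layer) pairs are found by maximizing

    Q = (1/2μ) Σ_{ijlr} [ (A_ijl − γ_l k_il k_jl / 2m_l) δ_lr
                          + δ_ij ω_jlr ] δ(g_il, g_jr)

with γ_l = 1 (configurable as a scalar or per-layer vector), the weighted
clamped layers as A, and ω_jlr nonzero only for adjacent layers where it
equals the coupling above.  2μ counts every (node, layer) vertex's strength
plus its attached couplings (Mucha-style convention); the normalization
affects only the reported Q, never the argmax.  An empty layer (m_l = 0)
contributes no null-model term.

Optimization is a greedy two-phase heuristic on the supra-graph: seeded
random sweep order per pass; each vertex moves to the community with the
largest strictly positive gain (ties broken toward the lowest community id;
a fresh singleton is also considered, which matters when a vertex's links
into its own community are net negative); a pass-level gain below 1e−10
ends the move phase; communities are then aggregated and the cycle repeats.
The move phase is re-entered at the finest level after every aggregation
round, so the returned partition is locally optimal — no single supra-vertex
move can increase Q.  On all networks small enough to enumerate every set
partition, best-of-20 restarts attains the global optimum (exercised in the
test suite over 200 random networks).  The 100-run default ensemble uses
seeds base_seed … base_seed+99 and is reproducible from base_seed alone.

### Reconfiguration metrics

Per run, m_i is the number of distinct community ids node i takes across
layers and M the number of distinct ids in the whole partition
(layer-spanning communities count once); promiscuity is
P_i = (m_i − 1)/(M − 1), defined as 0 when M = 1, and averaged over runs.
Module allegiance MA_ij is the fraction of (layer, run) slots in which i
and j share a label; recruitment R_iS = (1/n_S) Σ_{j∈S} MA_ij and
integration I_iS = (1/(N − n_S)) Σ_{j∉S} MA_ij with S the node's
resting-state subnetwork.  The printed recruitment sum runs over j ∈ S
without excluding j = i, so the self term MA_ii = 1 is included by default;
`include_self=False` excludes it and divides by n_S − 1.  With the self
term, the exact identity (n_S·R_iS + (N − n_S)·I_iS)/N = mean_j MA_ij holds
and is asserted in the tests.  Subnetwork-pair integration is the mean of
MA over the rectangular block between two subnetworks.  Aggregation at
whole-brain / subnetwork / node level is by unweighted means; coupling
aggregates identically.

### Group statistics

Two-sided independent-samples t-tests (pooled variance by default, Welch by
flag) per unit at each level, with sign(t) = sign(mean of the first
declared group − mean of the second).  BH-FDR correction is applied within
each (metric × level) family — the family definition is recorded in the
outputs.  Zero variance in both groups yields t = 0, p = 1 with a flag.
Spearman correlations use average ranks for ties; a constant input is
reported as undefined (NaN) rather than raising.

## Synthetic data generator

The generator emulates the statistical skeleton of band-passed regional
BOLD with a planted, time-varying community structure:

- **Epochs.**  Lengths are geometric with mean `epoch_length_mean`
  (default 20 timepoints) and a floor of 5, so no single-point epochs
  occur.  Within an epoch the N signals are iid draws from a zero-mean
  multivariate normal whose correlation is `within_block_corr` inside
  planted modules and `cross_block_corr` between them (Cholesky of the
  block correlation matrix; positive definiteness is verified at
  construction and a violation names the offending parameters).
- **Switching.**  At each epoch boundary, with group-specific probability
  `switch_prob`, the module assignment is redrawn as a balanced random
  partition guaranteed to differ; the realized switch count is part of the
  planted truth.
- **Band-limiting and noise.**  A moving-average filter (width
  `smooth_width`, default 3) imposes slow oscillatory structure — enough
  for the Hilbert phase to track the planted blocks — and white noise of SD
  `noise_sd` is added.  Within-epoch correlations are preserved exactly by
  the filter (it acts identically on every column of iid draws).
- **Scores.**  A synthetic clinical score is `score_coupling` × (realized
  switch count) + Gaussian noise (`score_noise_sd`), so correlation
  recovery between a recovered metric and the score is testable.
- **Determinism.**  Every subject draws from an independent substream of a
  seed sequence keyed by (seed, group, subject); identical configs produce
  byte-identical output.

Defaults echo a typical resting-state acquisition: N = 90 regions,
T = 142 usable volumes.  The region→subnetwork table shipped with bundles
assigns five contiguous, near-equal subnetworks (MAN, VN, AN, DMN, LSN);
it is a synthetic stand-in, not an anatomical atlas mapping.

**What the generator does not model:** haemodynamic response convolution,
spatial autocorrelation, motion or physiological artifacts, scanner drift,
or realistic 1/f spectra.  Passing recovery tests therefore demonstrate
that the pipeline detects planted dynamic structure of realistic size and
noise level — not that it is robust to every artifact of real fMRI.

## Validation studies and chosen conditions

Two simulation studies validate the pipeline end to end; their conditions
were fixed once, during design, and are stated here as the package's study
definition.

**Two-group contrast recovery.**  20 replicate experiments, each with
20+20 subjects, N = 30 regions, T = 60 timepoints, 3 planted modules,
epoch mean 8, and a patient-like group B with more frequent switching
(0.9 vs 0.05 per boundary) and weaker within-module coherence (0.45 vs
0.9; cross 0.05, noise SD 0.3).  Each subject is analyzed with a 20-run
ensemble.  The expected pattern — group B higher in promiscuity and lower
in coupling, recruitment and integration — must reach BH-corrected
p < 0.05 with the correct sign for all four whole-brain metrics in at
least 90% of replicates.  These sizes keep the full study inside a few
minutes of CPU time while leaving the per-replicate effects large
(|d| ≈ 1–3).

**Correlation recovery.**  On the same replicates, the Spearman
correlation between per-subject whole-brain promiscuity and the synthetic
score (coupled to the planted switch count, slope 2.0, noise SD 0.5) must
be positive with p < 0.05 in at least 80% of replicates at n = 40.

The recovery studies use `similarity="cosine"`.  This is deliberate: the
literal coupling form is structurally insensitive to planted changes in
temporal stability, because a loss of neighborhood persistence is offset by
its 1/degree factor (measured effect near zero), whereas the cosine form
isolates persistence and responds strongly.  The literal form remains the
package default for the formula-level API.

## Numerical choices and degenerate inputs

- Louvain move acceptance requires strictly positive gain; pass
  convergence threshold 1e−10 on the unnormalized pass gain; ties go to
  the lowest community id, making each run deterministic given its seed.
- Partition labels are relabeled to consecutive integers from 1 in order
  of first appearance; Q is invariant under label permutation.
- compute_modularity agrees with an independent brute-force double-sum
  evaluation to 1e−12 relative tolerance (tested).
- Binarization at `density:d` keeps ⌈d·E⌉ edges plus any tied at the
  threshold weight; zero-weight pairs are never edges.
- T < 2 layers cannot form couplings and is rejected at network assembly;
  a single-node, single-layer network optimizes without error.
- Empty subnetworks, a subnetwork covering all regions (integration
  undefined), non-finite inputs, and p-values outside [0, 1] raise with
  specific messages.

## Known limitations

- The clamped phase-coherence graph has a positive baseline (clamping maps
  anti-phase pairs to 0 but near-orthogonal pairs remain slightly
  positive), so detected partitions on generated data agree with the
  planted partition strongly but not perfectly (adjusted Rand ≈ 0.84 on a
  high-coherence fixture); exact recovery holds on noiseless constructed
  block stacks.
- Instantaneous phase alignment is volatile, so detected communities
  fragment temporally more than the planted schedule; promiscuity
  consequently has a high baseline and is the noisiest of the four
  metrics, mirroring its weaker statistics in group comparisons.
- Layers are coupled only temporally adjacently (no categorical all-layer
  coupling), and no consensus partition is formed — metrics are averaged
  over the ensemble instead.
- The optimizer guarantees local optimality in single-vertex moves, not
  global optimality at realistic problem sizes.
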
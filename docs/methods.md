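# Methods

## Model and objective

A chromosome is modeled as a chain of beads, one per contact-matrix bin that
has at least one off-diagonal contact. The interaction frequency IF_ij of a
bin pair is converted to a target spatial distance by the inverse power law
D_ij = IF_ij^(−α); pairs with IF = 0 carry no restraint (the objective sums
only observed data points, and there is no repulsive term). Target distances
are, by default, divided by their maximum so they lie in (0, 1], commensurate
with the random initialization cube [−0.5, 0.5]³; this is a single common
factor, so rank-based scores (dSCC) and Pearson correlation against the
targets are provably unaffected, and it can be disabled
(`rescale_distances="none"`).

Residuals between model distances D_ij^s and targets are treated as i.i.d.
Gaussian with one global standard deviation σ. Substituting the MLE
σ = √(SSE/n) into the log-likelihood leaves

    L(S) = −n/2 − n ln σ,   SSE = Σ (D_i^s − D_i)²

with the natural logarithm (the base only rescales L monotonically and
cannot move the argmax). The analytic gradient is

    ∂L/∂p_a = −(n/SSE) Σ_{(a,b)} (D_ab^s − D_ab) (p_a − p_b) / D_ab^s

with 1e−9 added to D_ab^s in the division so exactly coincident beads cannot
produce a division by zero. At a perfect fit (SSE = 0) the gradient is
exactly zero and L is unbounded; L is then reported as a large finite
sentinel (1e12) and the run is marked converged.

## Optimization

Plain gradient ascent S ← S + λ∇L iterates until the absolute change in L
falls below the convergence constant epsilon (default 0.0001) or `max_iter`
(default 10000, a cap the epsilon rule alone would not guarantee). Two
learning-rate schedules are provided: constant (default λ = 0.0001) and the
default step decay λ = initial_λ · 0.5^((1+epoch)/70) with initial_λ = 0.01,
which converges in far fewer iterations.

Large steps do not merely slow this objective down — because the gradient
magnitude scales with n/SSE they make the iterate oscillate around the
optimum and can strand a run in a poor configuration once the schedule has
decayed. The ascent loop therefore guards each step: if the scheduled step
would decrease L, it is halved (deterministically, at most 30 times) until
it does not, and the shrink factor persists across iterations and relaxes
after clean accepts, so the guard costs O(1) extra likelihood evaluations
per iteration. Accepted updates are exactly the ascent update with a
(possibly reduced) rate; at small constant rates the guard never triggers
and the trajectory is the textbook one. All runs are deterministic given
(seed, input, config).

The AdaGrad variant updates each coordinate by λ/√(G_t + ε) · g_t, where G_t
accumulates that coordinate's squared gradients from the first step
(ε = 1e−6 avoids division by zero). It uses a fixed base rate (default
0.01) without the step-decay schedule, since its per-coordinate denominators
already decay adaptively. It is intended for noisy input together with the
low-IF pre-filter, which zeroes entries strictly below a chosen quantile of
the positive IFs (default quantile 0 — the identity; the filtering statistic
is deliberately exposed as a parameter rather than fixed).

## Conversion-factor estimation and ensembles

α is swept over a grid (default 0.1–2.0 in steps of 0.1; the search range
reflects that very small α makes distance insensitive to IF while very large
α amplifies small IF differences into large distance differences). For each
α, `n_structures` (default 5) independently seeded optimizations are run;
replicate k at the a-th α uses seed `base_seed + a·10000 + k` so sweeps are
reproducible and α blocks are independent. Each structure is scored by dSCC
between its model distances and the targets over the restrained pairs only —
including unrestrained pairs would score the model against targets it never
saw (an `score_all_pairs` toggle exists; it assigns unrestrained pairs the
largest restrained target). The representative model is the entry with the
highest dSCC to the input; ties break toward smaller α (the less aggressive
distance spreading), then smaller seed. Ensemble consistency is the mean
pairwise dSCC between replicates' full distance vectors.

Accuracy against known truth ensembles follows the protocol: every
reconstructed structure is compared (dSCC of full distance vectors) with
every true structure, and the reconstruction closest to any truth defines
the ensemble's accuracy. When a model covers a filtered subset of bins it is
compared on its own bins via the recorded bin map.

## Metrics

dPCC and dSCC are the Pearson and Spearman correlations of two pairwise
distance vectors (ranks use the average method for ties). dRMSE first
superposes the model onto the reference with a full Procrustes similarity
transform — translation, orthogonal rotation and isotropic scale, with
reflections allowed, as in the classical closed-form solution — then takes
the RMS difference over all n(n−1)/2 pairwise distances. Reflections are
allowed because a distance-only likelihood cannot determine chirality: a
mirrored solution is exactly as likely as the original, and this ambiguity
is intrinsic, not corrected. `proper_rotation=True` restricts the rotation
to det = +1, and `rmsd_coords=True` switches to coordinate RMSD after
superposition, for users who want either convention.

## Normalization

ICE is implemented as plain iterative matrix balancing: row/column biases
b_i = s_i/mean(s) are divided out until every row sum is within tolerance
(relative, default 1e−6) of the mean, then the matrix is rescaled to unit
mean row sum. The eigenvector-decomposition diagnostic of the original ICE
method is not part of the normalization and is omitted. SCN alternates
scaling each column, then each row, to unit Euclidean norm until the matrix
is symmetric within tolerance, and symmetrizes at the end. Both require a
map with no empty bins, warn (returning the best iterate) on
non-convergence within 200 iterations, and never create contacts where the
input had exact zeros.

## Synthetic benchmark generator

The generator emulates a simulated Hi-C benchmark with known truths; it is
first-class, tested code, not a fixture.

- **Chains.** `make_chain` builds a worm-like chain of unit-length bonds
  whose directions follow a correlated random walk (each direction is the
  normalized blend of the previous one, weight `smoothness`, and a fresh
  isotropic unit vector; default smoothness 0.7, giving a persistence length
  of a few bonds). Default 202 beads. The chain is not self-avoiding; at
  these sizes overlaps are rare and irrelevant to distance-rank scores.
- **Structural variability.** `perturb_ensemble` draws, per copy, a
  per-bead Gaussian displacement field with s.d. 0.05·sv·Rg (sv ∈ 0..6, Rg
  the chain's radius of gyration), smoothed along the chain (Gaussian
  kernel, σ = 3 beads) so bonds stay near unit length. Grade 0 is exact
  copies; default 100 copies per grade.
- **Maps.** `structures_to_map` averages pairwise distances over the truth
  population, applies the exact inverse of the modeling law
  IF = d̄^(−1/α_true) (capped at 1e6 for near-coincident beads), and scales
  so the median positive count is 100 (a typical per-pair count at
  megabase-scale binning). Noise grade 0 uses these ideal values exactly, so
  the round-trip identity holds to machine precision. Positive grades
  multiply the means by a gamma factor with coefficient of variation
  noise_level/400 (grades 50/100/150/200 → CV 0.125–0.5) and draw Poisson
  counts. This noise law is a documented stand-in with the same knobs (noise
  grade, variability grade) as the external benchmark it emulates, chosen
  for count realism; absolute benchmark numbers are not comparable, trends
  are.

Because maps are generated by the exact inverse of the modeling assumption,
passing tests demonstrate correct inference under that assumption — they do
not show robustness to the biases of real Hi-C (restriction-site density,
mappability, TAD block structure, inter-cell heterogeneity beyond the
Gaussian perturbation law).

## Problem sizes and numerical defaults

The validation suite and the acceptance script use 25–202-bead instances:
gradient checks on 100 random 10–30-bead instances (central differences,
h = 1e−6), noise-free recovery at 50 beads over the α grid
{0.1, 0.3, 0.5, 1.0, 1.5, 2.0}, replicate consistency at 100 beads, and the
variability trend at 202 beads (grades 0–6, noise grade 100, 3 seeds per
grade, 100 truths per instance). These sizes make the full suite run in
about half a minute while exercising every pipeline stage at the benchmark's
native bead count.

Known limitations: chirality is undetermined (see Metrics); no backbone
(adjacency) restraints are imposed, so bead order is recovered only through
the contact signal; inter-chromosomal (rectangular) maps and bias-model
normalizations that need genomic feature tracks are out of scope.
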
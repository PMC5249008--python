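# Methods

## The model

For one gene, let x = (x_1, ..., x_n) be the non-zero log2CPM expression
values across cells, where log2CPM is the shifted-log counts-per-million
transform y_ij = log2(1 + 10^6 r_ij / Σ_k r_kj) of raw counts r_ij.  Zeros
are removed before modelling: scRNA-seq matrices are dominated by zeros, and
including them as data points distorts both components.  The non-zero values
are modelled as a two-component mixture

    f(x_i) = (1 − ρ) · Gamma(x_i; α, β) + ρ · Normal(x_i; μ, σ²),

with the gamma (rate parameterisation) as the low-expression component and
the normal as the high-expression, "active", component.  Component
membership y_i ~ Bernoulli(ρ) is latent; its posterior z_i = P(high | x_i)
is computed in log space as the logistic of
η_i = logit(ρ) + log f_N(x_i) − log f_G(x_i).

The per-gene, per-cell ternary state is then

    0   if the count is zero,
    1   if the cell is assigned to the gamma component (z_i < 0.5),
    2   if assigned to the normal component (z_i ≥ 0.5, boundary inclusive),
    NA  if the gene has fewer than `min_nonzero_cells` non-zero cells.

## EM fitting

Posteriors are initialised by seeded Bernoulli(0.5) draws.  Each iteration
performs the E-step above, then maximises the expected complete
log-likelihood: μ, σ² and ρ have closed-form weighted updates
(μ̂ = Σz_i x_i / Σz_i, σ̂² = Σz_i (x_i − μ̂)² / Σz_i, ρ̂ = Σz_i / n), and the
gamma parameters jointly solve the weighted score equations

    digamma(α̂) = log β̂ + Σ(1 − z_i) log x_i / Σ(1 − z_i),
    β̂ = α̂ Σ(1 − z_i) / Σ(1 − z_i) x_i.

The pair is solved to its fixed point inside the M-step via generalised
Newton iteration on the profile equation log α − digamma(α) = log(w-mean x)
− w-mean(log x).  A single alternating pass of the two updates per EM
iteration has the same fixed points but converges along an (α, β) ridge at a
linear rate of roughly 1 − 1/(2α), which for the large shapes typical of a
tight low-expression cluster means thousands of iterations; the joint solve
is an exact conditional maximisation, preserves the monotone log-likelihood
guarantee of EM, and converges in ~4 Newton steps.  `inverse_digamma`
(Newton on the digamma with the standard piecewise initialisation, residual
< 1e−10 over six orders of magnitude of shape) is exposed for direct use of
the score equation.

Convergence is declared when the maximum relative change over
(α, β, μ, σ², ρ) drops below `tol` (default 1e−6), capped at `max_iter`
(default 500) iterations.  The observed-data log-likelihood is recorded
every iteration and is non-decreasing up to 1e−8 numerical slack.

Numerical guards: densities are evaluated in log space and the posterior via
an overflow-safe logistic; σ² is floored at 1e−6; if ρ leaves
(1e−6, 1 − 1e−6) the fit is frozen at the boundary and flagged
single-component, with all calls 1 (ρ→0) or all 2 (ρ→1).

**Component identifiability.** The mixture is not automatically oriented: a
gamma with large shape is close to a normal, so EM started from random
memberships can converge to a mirrored mode in which the gamma captures the
*high* cluster and the normal the low one, inverting every call.  Because
the model's interpretation fixes the gamma as the low component, a converged
fit with gamma mean α/β above the normal mean μ is re-run once from the
mirrored posteriors; the orientation-consistent fit is kept.  On
well-separated synthetic genes roughly a quarter of random initialisations
hit the mirrored mode without this constraint.

## Contextualization

A gene with fewer than `min_nonzero_cells` (default 10) non-zero cells gets
no direct fit.  Instead, its non-zero values are pooled with the non-zero
values of `n_context_genes` (default 10) genes drawn uniformly from the
fittable genes, the mixture is fitted to the pooled sample, and the target's
cells take their calls from that fit.  This is repeated `n_repetitions`
(default 10) times with independently resampled context genes, and the final
call per cell is the majority over repetitions, a tie resolving
conservatively to the smaller value (1).  A repetition whose pool is still
too small abstains.  Context genes are resampled per repetition: with a
single fixed context set the ten repetitions would differ only through the
EM initialisation, which defeats the purpose of repeating.

## Maturity-marker scan

Ternary states collapse to binary activity (2 → 1, else 0; NA treated as
inactive by default, a `drop` policy is available).  Cells active for the
mature anchor (default OMP) and not the immature anchor (default GAP43) are
mature; the mirror are immature; cells active for both or neither are
excluded.  Every other gene is tested with a two-sided Fisher's exact test
on the 2×2 table (mature/immature × active/inactive), through
`scipy.stats.fisher_exact` (verified in the tests against exact
rational-arithmetic enumeration of the hypergeometric support).  P-values
are Bonferroni-corrected by the number of genes actually tested — the
universe is configurable so a gene-subset workflow corrects only over the
subset — and called significant below α = 0.01.  Direction is
mature-associated when the active fraction is higher among mature cells.

A leave-one-out k-NN classifier (Euclidean, default k = 5, ties to the
first label in sorted order) measures how well cells can be re-assigned to
their originating dataset; lower accuracy on binary activity than on
continuous log2CPM indicates the ternary transform removes dataset-specific
effects.

## Per-cell networks

Each cell's active genes form the nodes of a fully connected coactivation
network — N nodes, C(N, 2) edges.  The population prevalence of an edge is
the fraction of all cells in which both genes are active; an edge is removed
when its prevalence is *strictly greater* than the threshold (default 1%),
so an edge exactly at the cutoff survives.  Isolated nodes stay in the node
set: nodes are defined by activity, edges by uniqueness.

Network shape is summarised by Freeman degree centralization,
C = Σ_i (d_max − d_i) / ((N − 1)(N − 2)), which is 1 exactly for a star and
0 exactly for any degree-regular graph (in particular the full clique), and
is undefined for N < 3 (such networks are excluded downstream).  Mature and
immature cells' centralizations are compared with a two-sided two-sample
t-test — Welch by default, with a pooled-variance option — over networks
with at least `min_nodes` (default 5) nodes, across the prevalence-threshold
sweep {0.5, 1, 2, 3, 4, 5}%.

## Synthetic data

The generator draws, per gene and cell, a zero with probability `zero_prob`
(default 0.6), otherwise a gamma draw (default Gamma(2, 2)) with probability
1 − ρ or a normal draw (default Normal(8, 1)) with probability ρ (default
0.4), all on the log2CPM scale.  Values are back-converted to integer counts
at a nominal library size of 10^6, r = round(2^y − 1), with non-zero states
floored at one count so the zero pattern of the truth is conserved.  Because
actual cell totals come out far below 10^6, re-applying the log2CPM
transform shifts values upward by log2(10^6 / total) and compresses the
low/high separation — deliberately kept, since real libraries are arbitrary
and the fitting stage must tolerate it (it is what exposed the
identifiability failure described above).

Planted structure, recorded in truth tables sufficient to score every
downstream stage:

* **Maturity**: 60 mature + 60 immature cells; OMP active exactly in mature
  cells and GAP43 exactly in immature cells; 20 planted mature-associated
  genes active with probability 0.8 in mature and 0.1 in immature cells.
* **Topology** (`network_study_spec`): 50 "star" cells each active for one
  private gene plus a block of 9 shared genes — the shared-shared edges are
  population-prevalent and filtered out, leaving a star on the private gene —
  versus 50 "dense" cells each active for 9 genes unique to that cell, whose
  clique survives filtering (centralization 0).  140 unlabelled background
  cells bring the population to 240 so a uniquely coactive pair
  (prevalence 1/240 ≈ 0.42%) survives even the tightest 0.5% cutoff;
  background activity is sparse (ρ = 0.05, dropout 0.7) so planted topology
  dominates.

What the generator does **not** emulate: amplification and GC bias, UMI
chemistry, gene–gene correlation beyond the planted structure, realistic
library-size variation, or batch effects.  Passing tests therefore
demonstrate correctness of the algorithms under the model's own assumptions
and robustness to the library-size distortion above — not performance on
real tissue data.

## Problem sizes and determinism

The validation studies use 500 genes × 120 cells for marker recovery
(10 seeded replicates), 200-value genes for EM monotonicity (100 replicates),
n = 1000 for parameter recovery (25 replicates), 20 replicates of the
240-cell topology study, and 50 null datasets for calibration.  Every
stochastic stage takes an explicit seed; per-gene EM seeds are spawned from
the matrix-level seed, so whole-pipeline runs are bit-reproducible
(identical config + seed ⇒ identical output files).

## Known limitations

* Genes whose non-zero values are genuinely unimodal still receive a
  two-component fit; the boundary freeze handles full collapse, but a
  near-degenerate second component can absorb a few cells.
* Zero counts are treated as "no expression"; false-positive reads are not
  modelled (a point mass at zero with leakage into positive values would
  need a third component).
* The Bonferroni correction is the only multiplicity control offered.
* Contextualization assumes context genes share the target's dynamic range;
  with random selection the pooled fit reflects the transcriptome-wide
  mixture, which is the intended behaviour, not a per-gene calibration.
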
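# Methods

`ancrec` reconstructs two ancestral properties of prokaryotic lineages on a
rooted species tree: optimal growth temperature (OGT), through the 16S rRNA
stem-GC "molecular thermometer", and gene-family repertoires, through a
per-family gain–loss–duplication birth–death model. A thresholded
single-linkage clustering front end builds the protein families that feed
the second track. This note documents the models, the numerical choices,
and what the synthetic-data studies do and do not demonstrate.

## The molecular thermometer

Paired (stem) regions of the small-subunit rRNA are enriched in G:C pairs
in thermophiles because G:C base pairs stabilise helices at high
temperature. Across organisms, stem GC% correlates tightly with OGT, so a
linear calibration fitted on extant taxa,

    OGT = a · stemGC% + b,

can be inverted at ancestral nodes once ancestral stem GC is estimable.

**Stem mask.** Per-taxon stem annotations give 1-based positions in each
ungapped sequence. An alignment column is a stem column iff at least a
configurable fraction (default 1.0, a strict consensus) of the annotated
sequences that have a residue in the column place a stem residue there;
gap cells do not vote. Stem GC% counts G+C over A+C+G+T in masked columns;
gaps and ambiguity codes are excluded from numerator and denominator.

**Calibration.** Ordinary least squares of OGT on stem GC% across the taxa
that have both, with the Pearson correlation, adjusted R², and a
phylogenetically corrected correlation computed from Felsenstein's
independent contrasts (standardised contrasts, internal branch-length
update v' = v + v₁v₂/(v₁+v₂), correlation through the origin). Polytomies
are folded pairwise in child order. The contrasts correlation is a
diagnostic: it tells you how much of the apparent GC–OGT correlation
survives removal of tree-induced covariance.

**Substitution model.** Ancestral GC is only estimable under a model whose
composition can change along the tree. We use the minimal such model:
Tamura (1992) exchangeabilities with a branch-specific equilibrium GC
fraction θ_b on every branch, a single global transition/transversion
ratio κ, and a free root composition θ_root. Each branch's generator is
normalised to one expected substitution per unit time at its own
stationary distribution, so the input branch lengths keep their
substitutions/site meaning and are never re-optimised. Transition matrices
come from the reversibility of T92 — Q = D⁻¹SD with S symmetric — solved
by a batched symmetric eigendecomposition; the generic matrix exponential
(scipy `expm`) is retained as an independently tested code path. The
pruning likelihood treats gaps and N as missing data (partial likelihood 1
for every state) and restricts to stem columns.

**Fitting.** Bounded L-BFGS-B over (κ, θ_root, θ_b…), with θ ∈
[0.01, 0.99] and κ ∈ [0.05, 100]. θ_b is initialised at the mean stem-GC
fraction of the branch's descendant tips, which is close enough to the
optimum that one start usually suffices; multi-start (default 3 in the
pipeline, jittered from a recorded seed) guards against ridge artefacts.
Alignment columns are pattern-compressed. For trees of ≤64 leaves the
per-node rescaling of partial likelihoods is skipped — the smallest
partial stays far above the float64 floor — which roughly halves fit time;
the scaled and unscaled paths agree to 1e-12 and both are exercised in
tests.

**Ancestral replicates and OGT intervals.** Ancestral sequences are
sampled jointly: the root from its exact marginal posterior, children
conditionally down the tree, site-independently (default R = 100
replicates). Joint sampling preserves the cross-node correlation of GC
within a replicate, which matters when comparing ancestors. Exact marginal
posteriors (inside–outside) are computed alongside and checked against
brute-force enumeration on small trees. Each replicate's stem GC is mapped
to OGT through the calibration, with the calibration's own prediction
uncertainty folded in: per replicate, coefficients (a_r, b_r) are drawn
from the OLS coefficient sampling distribution and a residual draw
N(0, σ_resid) is added. The point estimate is the replicate mean; the 95%
CI is the 2.5–97.5 percentile interval. The residual term is essential:
the regression maps GC to OGT only up to its residual scatter, and a
replicate-only interval ignores both that scatter and the finite-sample
error of (a, b) — in simulation it covers the truth barely half the time,
while the propagated interval achieves nominal coverage. A calibration
constructed by hand (zero recorded residual variance) degrades gracefully
to the plug-in prediction.

**Taxon handling.** Taxa without a 16S sequence are pruned from the tree
for this track (branch lengths summed through suppressed unary nodes, so
root-to-leaf distances are conserved exactly); taxa without an OGT still
inform the model fit and ancestral sampling but not the calibration.

## Gene-family birth–death reconstruction

Each protein family evolves its copy number n along the tree as an
independent continuous-time chain on {0..C_max}: innovation 0→1 at rate g,
per-copy duplication at rate λ, per-copy loss at rate μ; the top state has
no up-transition (truncation; default C_max = 10, observed counts above it
are truncated with a logged warning — presence posteriors change by <1e-6
when raising C_max from 8 to 12 at observed counts ≤4). The root prior
defaults to the stationary distribution of the family's truncated
generator. The chain is reversible, so exp(Qt) is computed for all
branches at once from one symmetric eigendecomposition of the
detailed-balance symmetrisation; degenerate corners (g = 0 or μ = 0) fall
back to scipy's `expm`, and the kernel is validated against 100,000-path
Monte-Carlo jump-chain simulation.

**Rates.** Per family, (g, λ, μ) are fitted by bounded ML on the log
scale (bounds 1e-6..50 per rate; λ can be pinned to 0). Identical
leaf-count profiles share one fit. With few genomes the per-family ML is
information-starved — at 16 tips its median relative error plateaus near
45% regardless of regime, versus ~23% at 64 tips — so the fitter offers an
empirical-Bayes layer (off by default): a pooled ML over all families
anchors curvature-weighted James–Stein shrinkage of the per-family
log-rates, with the across-family variance estimated by moments and the
per-family variances taken from the full inverse Hessian (the diagonal
alone underestimates them ~3×, because log g and log μ are strongly
correlated: tip occupancy pins their ratio much more tightly than their
magnitude). When families truly share rates the shrinkage collapses to
the pooled estimate (~4% median error); with heterogeneous truth it tracks
per-family rates. This mirrors the rate-variation-across-families
machinery of standard gene-content programs.

**Posteriors and events.** An inside–outside pass gives the exact marginal
posterior over copy number at every node and the exact joint parent–child
posterior on every branch. Event probabilities are sums over the joint:
gain (parent = 0, child ≥ 1), loss (parent ≥ 1, child = 0), expansion
(child > parent ≥ 1), contraction (parent > child ≥ 1). Calls require the
probability to be strictly above the threshold τ (default 0.5); presence
(P(n ≥ 1) > τ) and multicopy (P(n ≥ 2) > τ) calls at each ancestral node
use the same rule, so presence counts are monotone non-increasing in τ.
Everything is deterministic and tested against exhaustive enumeration on
small trees.

**Gain-rate statistics.** Per branch, called gains divided by branch
length (substitutions/site); zero-length branches are flagged undefined
and excluded from rate comparisons rather than given infinite rates.
Ancestral (internal-child) and terminal branches are compared by the
Wilcoxon rank-sum test — exact by enumeration up to n_A+n_B = 12
(mid-ranks for ties), normal approximation with tie correction beyond —
with the signed-rank variant available for paired designs. The
gains-vs-substitutions regression uses, per ancestral branch, x = branch
length and y = called gains divided by families present at the child node
(the denominator is a package choice and is labelled in the output).

## Protein-family clustering

Hits from an all-vs-all search survive iff E-value strictly below 1e-4,
identity at least 35%, and alignment length at least 70% of both
sequences' lengths (boundary semantics fixed and tested: identity 35.0 is
kept, E = 1e-4 is dropped). The best hit per ordered pair is kept before
symmetrisation; reciprocal duplicates keep the best E-value. Families are
connected components of the surviving undirected graph (single linkage);
sequences with no surviving edge are singleton families. Ids are
"FAM"+zero-padded rank by decreasing size then lexicographically smallest
member, so labels are independent of input order. No post-hoc family
splitting by alignment quality is attempted (a recorded limitation); the
occurrence matrix counts each genome's members per family.

## Synthetic data and what the studies show

The generators produce every input the pipeline consumes with recorded
ground truth. Trees are Yule, rescaled to a chosen mean root-to-tip depth;
optional lognormal branch-rate variation breaks the clock, and an optional
"relict" option pins the shallowest tip of each root subtree to a given
depth. OGT evolves by Brownian motion (so the contrasts diagnostics are
exact under the generating model); each branch's θ tracks the child
node's OGT through the true calibration, clamped to [0.01, 0.99].
Copy numbers evolve by exact Gillespie simulation of the uncapped jump
process, with node states and realised per-branch events recorded. Hit
tables plant families whose within-family hits pass every screen and whose
noise rows fall below the identity threshold.

**Thermometer study conditions** (30 tips, 1,000 stem sites, true slope
2.0, tip OGT span ≥ 40 °C enforced by deterministic re-draws): mean depth
2.0 substitutions/site, lognormal rate variation (log-sd 0.8), one relict
lineage per root subtree at depth 0.1, Brownian OGT variance 85 °C² per
unit length. The depth and the relicts are not decorative: slope recovery
requires tips near compositional equilibrium with their own OGT (deep
divergence), while ancestral-composition identifiability requires short
root-to-tip paths on both sides of the root — one alone can be absorbed by
its own branch's free θ. Clock-like trees cannot satisfy both at once; the
rate heterogeneity that real calibration sets possess (slowly evolving,
deeply branching relict lineages) is exactly what makes the problem
solvable, and the study encodes that. Across 50 replicates the median
fitted slope is within a few percent of truth, the median absolute root
OGT error is ≈2 °C (the θ→realised-GC binomial noise at 1,000 sites alone
contributes ≈1.5 GC-σ ≈ 3 °C at slope 2, so this is near the floor), and
the propagated 95% CI covers the truth in ≥90% of replicates.

**Gene-content study conditions.** The two recovery properties demand
opposite event densities, so they are two labelled studies. Rate
recovery: 16 tips, depth 1.0, global g = μ = 1.0, λ = 0 known,
empirical-Bayes estimation (median relative error ≈4%). Presence-call
accuracy: 16 tips, depth 0.4, g = μ = 0.25 — occupancy ≈0.63, inside the
informative 30–70% band, with ≈0.05 expected events per branch so that
Bayes-optimal calls are confident; the point of the check is validating
the posterior machinery, not measuring irreducible uncertainty. The 1,000
families are spread over 4 independent tree replicates and calls pooled,
so the score reflects the regime rather than one tree shape (measured
accuracy ≈97%; branch-level called gains correlate with true gains,
Spearman ≈0.9).

**What passing does not show.** The generators emulate the *structure* of
real inputs, not their full realism: sites are independent and
rate-homogeneous within the stem set, rRNA secondary structure and
alignment error are absent, hit tables carry no BLAST score statistics,
and gene families evolve independently with branch-constant rates and no
lateral-transfer donors. Recovery on these data validates the likelihood
machinery, the estimators and the thresholds — it does not certify
accuracy on real genomes, where model violation (nonstationary rate
variation, correlated families, alignment artefacts) dominates.

## Numerical and interface conventions

Probabilities are printed with 6 decimals; tabular outputs are TSV with
headers; reports are JSON. All randomness flows from recorded integer
seeds and identical config + seeds give byte-identical outputs (wall time
goes to the log file, not the result tables). Exact posterior ties during
ancestral sampling are resolved by cumulative-probability order A<C<G<T.
Transition matrices at t = 0 are set to the exact identity rather than
identity ± rounding, so zero-length branches force states exactly. The
exit-code contract of the CLI is 0 success, 1 validation error, 2
convergence warnings present.

## Known limitations

- The thermometer CI propagates calibration uncertainty but not
  uncertainty in (κ, θ̂) of the substitution model; root-composition
  uncertainty enters only through the sampled replicates.
- Per-branch θ makes root composition weakly identifiable on deep
  clock-like trees; the package reports convergence flags but cannot
  manufacture information that the tree shape does not contain.
- The birth–death model has branch-constant per-family rates; no
  lateral-transfer donor inference, no Dollo mode, no family splitting
  beyond connected components.
- The exact rank-sum enumeration is O(C(n, n_A)) and is capped at
  n_A+n_B = 12 by default.
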
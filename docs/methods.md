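# Methods

This note documents the models implemented in `ouregimes`, the choices
made where the design was genuinely open, and what the synthetic-data
generator does and does not emulate.

## Trees and regime painting

Trees are rooted, with branch lengths in relative time; trait analyses
require ultrametricity within a relative tolerance (default 1e-4, because
published trees carry rounding error) and refuse non-ultrametric input
rather than re-dating it. Pruning to a species subset preserves all
root-to-tip depths and suppresses unary nodes by summing branch lengths.
Zero-length internal branches (soft polytomies) are accepted with a
warning; trait covariances remain well defined.

A regime painting assigns one label from the alphabet (LS, CC, CS by
default) to every branch using the child-node convention: a branch carries
the state of the node at its tipward end, so a state change reconstructed
at a node recolours the branch below it. This matches the usual practice
of mapping node-state reconstructions onto branches and makes the painting
total by construction. Species names are matched after trimming and
unifying whitespace/underscores.

## Sequence models and ancestral reconstruction

JC, K2P and HKY rate matrices are normalised to one expected substitution
per site per unit length; HKY uses counted (empirical) base frequencies.
Discrete-Gamma rate heterogeneity uses k = 4 equal-probability categories
with the mean-of-band rate convention (the MEGA/PAML "mean" rule), rates
renormalised to average 1. Likelihoods come from Felsenstein pruning with
per-site scaling; ambiguity codes are partial-likelihood indicator
vectors and gaps are fully missing. Because input trees are in time units,
a single global branch-length scale can be estimated by ML alongside each
model's parameters.

Model choice is by BIC = −2 lnL + p ln(n) with n = alignment sites. The
candidate set is deliberately reduced to {JC, K2P, HKY} × {±Γ} — six
models that contain the relevant heterogeneity and transition-bias axes —
rather than a 24-model scan.

Marginal ancestral reconstruction runs an inside–outside pass per Gamma
category and mixes categories by their per-site posterior weight. MAP
ties are broken deterministically in alphabet order A<C<G<T and flagged.
The COX state of a node is obtained by translating the two mutation-site
codons of its MAP sequence ((K,S)→LS, (C,C)→CC, (C,S)→CS, else "other");
the alignment columns of those codons are a required configuration input
since they depend on the alignment at hand. Nodes classifying "other"
inherit the parental state for painting purposes (the root falls back to
LS, the ancestral angiosperm state).

When only tip states are available (no alignment), internal states come
from a three-state Mk model whose transitions follow the documented
history shape (LS→CC, CC→CS, optional CC→LS reversal) with a single ML
rate and the root fixed at LS; a symmetric-Mk switch exists.

## Multi-regime OU trait evolution

Traits are analysed on the log10 scale; optima are reported both on that
scale and back-transformed to Mbp. The OU transition kernel per branch is

  mean = theta_r + (x_parent − theta_r) exp(−alpha_r t),
  var  = sigma2_r (1 − exp(−2 alpha_r t)) / (2 alpha_r),

computed with expm1 so the alpha→0 (Brownian) limit is exact. Two
independent likelihood engines are provided and cross-checked to 1e-8 in
the test suite: (i) the explicit multivariate normal, in which the
expected value of each tip accumulates piecewise attraction along its
root-to-tip path and the covariance of two tips is the variance
accumulated at their MRCA carried down by the lineage decays — exact for
regime-specific alpha, with no approximation of the path integrals; and
(ii) Gaussian belief propagation, a post-order elimination using the
branch kernels. The dual implementation is the package's main defence
against silent likelihood bugs.

Fitting profiles everything that is analytic: the optima (and the BM root
mean) solve a GLS system at fixed structure parameters, and a shared
sigma2 is profiled in closed form; the remaining log-alpha and log-sigma
ratios are optimised by bounded scalar search (1-D) or Nelder–Mead
refined by L-BFGS-B, from 8 dispersed deterministic starts by default.
alpha is bounded in [1e-8, 50/tree height]; a fit at the upper bound
warns of near-white-noise behaviour. The root value is tied to the
root-regime optimum by default (the smaller model; a free-root switch is
provided). Model weights use AICc by default given the ~100-species
sample sizes, with a plain-AIC switch. A regime absent from the painting
makes its parameters unidentifiable and is a hard error; a regime on a
single branch warns. Standard errors of the optima come from the numeric
observed-information matrix.

## PGLS

The regression sets log10 trait ~ COX state with LS as reference level,
so the intercept is the LS mean. Residual structures: BM (V_ij = shared
path length), OUfixedRoot (e^(−alpha d_ij)(1 − e^(−2 alpha t_ij))/(2
alpha)), OUrandomRoot (stationary, e^(−alpha d_ij)/(2 alpha)) and
optionally Pagel's lambda. Coefficients and sigma2 are profiled; the
structure parameter is fitted by bounded 1-D ML. t-tests use n − p
degrees of freedom. R² is the GLS-whitened comparison against the
intercept-only model under the fitted correlation; both adjusted-R²
conventions, 1 − (1−R²)(n−1)/(n−p) and 1 − (1−R²)(n−1)/(n−p−1), are
reported because packages differ in the df convention. Error structures
are compared by Akaike weight, and a top-two weight ratio under e (~2.7)
is flagged as "comparable performance".

Note an intrinsic caveat this package reports but does not hide: when the
predictor is clade-confounded (regimes are whole clades), the GLS
estimand is the projection of the expected values under the fitted
correlation, which is attenuated relative to raw group-mean contrasts.
The acceptance tests score the estimates against that estimand, not
against naive group means.

## Bootstrap and rank tests

The parametric bootstrap simulates tip traits under the fitted
multi-regime model, refits the same specification (warm-started at the
original optimum plus 3 fresh starts) and records the optima; replicate
seeds derive from the master seed by a counter scheme so any subset
reproduces exactly. Non-converging replicates are excluded and counted;
more than 20% failures aborts. Bootstrap optimum distributions are
compared pairwise by the Mann–Whitney U test: the normal approximation
(continuity and tie corrected) for the usual 100-vs-100 samples, an exact
enumeration (feasible to 12 pooled observations, ties handled) for small
samples; two-sided by default, no multiplicity adjustment unless the Holm
switch is set. Testing bootstrap replicates of a single dataset against
each other is anticonservative — the replicates share that dataset's
estimation noise — and this is documented rather than corrected because
it mirrors the study design the package reproduces.

## Synthetic-data generator

The generator is the package's study stand-in and is itself first-class,
tested code. Defaults emulate the real dataset's shape: 112 species on a
height-1 relative-time Yule tree plus 15 trait records deliberately
absent from the tree (the 127 → 112 funnel), a 237-site alignment, a
directional three-state regime history from an LS root at rate q = 0.4
per allowed transition, and chromosome data for ~60% of species (the 112
→ ~67 funnel). Histories are redrawn with sub-seeded bounded retries
until every regime holds at least max(4, 5% of tips) tips — i.e. the
generator conditions on the documented LS/CC/CS history shape actually
being represented, as in the real family where the rarest state (CS,
sect. *Genlisea*) covers ~6% of species. Trait optima default to the
study-scale values (597/210/51.09 Mbp genomes; 55.41/12.21/2.18 Mbp
chromosomes) on the log10 scale, with attraction alpha = 3 per tree
height (phylogenetic half-life ~0.23) and diffusion sigma2 = 0.05
(stationary within-regime s.d. ~0.09 log10 units): strongly adapted,
clearly separated regimes. The two mutation-site codons of each tip are
overwritten with synonymous-randomised codons encoding its regime, so
sequence-based classification recovers the generated states exactly.

What the generator does not emulate: extinction (pure-birth trees only),
codon-usage and among-lineage substitution-rate realism, measurement
error in flow-cytometry genome sizes, and correlated evolution between
genome and chromosome size (the two traits are generated independently on
the same regime history). Passing tests therefore demonstrate the
statistical machinery under the model's own assumptions, not robustness
to violations of them.

A consequence worth stating plainly: with the rarest regime confined to
one small clade, its optimum is estimated from effectively few
independent lineages, so single-dataset recovery of that optimum to
within ~10% on the Mbp scale is near the edge of what the data contain;
the recovery tests and the acceptance script report pooled and per-regime
error summaries to make that visible.

## Problem sizes used in checks

The dual-engine agreement checks run 100 random draws over trees of up to
16 tips across all seven model structures, and enumeration cross-checks
on trees of up to 6 tips. Recovery harnesses use 200-tip trees with 100
replicates (60 OUM + 40 OUMA) and a 150-tip, 200-replicate null for the
PGLS test level; end-to-end pipeline checks use study-sized bundles (112
tips) and a 300-tip bundle for optimum recovery; the bootstrap check uses
the 20-replicate smoke configuration. These sizes were chosen to match
the study's scale while keeping the full suite comfortably runnable on a
single CPU.
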
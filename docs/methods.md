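# Methods

## The models

### Brownian covariance and signal statistics

All continuous-trait machinery rests on the Brownian-motion covariance
of a rooted tree: `V[i, j]` is the path length from the root to the most
recent common ancestor of tips i and j, so variance accumulates linearly
with branch length and covariance equals shared history. `treekit`
builds V directly from node depths (one pass for depths, one fill per
internal node), keeps tip labels attached to rows, and exposes Pagel's
λ transform (off-diagonal × λ, diagonal untouched).

Blomberg's K is the ratio of the observed mean-square partitioning of
trait variance (ordinary vs. V-weighted mean squares around the
phylogenetically weighted mean â = (1ᵀV⁻¹y)/(1ᵀV⁻¹1)) to its Brownian
expectation ((tr V − n/(1ᵀV⁻¹1))/(n−1)). K is exactly 1 on a star tree
for any trait, which the tests assert identically. The randomization
test shuffles trait values over tips; p = (1 + #{K_perm ≥ K_obs})/(n_perm
+ 1) with ties counted as exceedances, 999 permutations by default.

Pagel's λ is fitted by profiling the multivariate-normal likelihood:
for fixed λ the mean and rate have closed-form optima, leaving a 1-D
function maximized by bounded Brent search on [0, λ_max]. λ_max is the
largest value keeping V(λ) positive definite, capped at 1 (binding for
ultrametric trees). Because the bounded optimizer avoids exact bounds,
the boundary log-likelihoods are evaluated explicitly and the estimate
snaps to a bound when it is at least as good — this is what produces the
exact λ̂ = 1 and λ̂ = 0 values categorical predictors tend to give. The
p-value is a χ²(1) likelihood-ratio test against λ = 0; the alternative
null (λ = 1) was considered and rejected because printed λ = 1 rows with
small p-values are only consistent with the λ = 0 null.

Discrete-valued predictors (binary strategy scores, ordinal silk/type
scores) are deliberately treated as continuous traits for K and λ,
matching the study design this package reproduces.

### PGLS

`fit_pgls` whitens response and design with the Cholesky factor of V
and solves least squares in the whitened space; with maximum likelihood
(default) σ̂² = RSS_V/n, standard errors come from σ̂²(XᵀV⁻¹X)⁻¹, and
t-tests use n − p degrees of freedom (the GLS regression convention;
REML is a method flag away). The log-likelihood is the profile Gaussian
value; AICc counts the residual variance as a parameter. Model selection
enumerates all non-empty predictor subsets up to a size cap, ranks by
AICc (strict ascending; no tie-break beyond the sort) and reports Akaike
weights. The sequential (type-I) ANOVA compares nested whitened fits
against the full-model residual mean square, which under REML makes
F = t² exact for a single predictor — asserted in the tests.

The ML convention makes the t-tests mildly anti-conservative at n = 22
(σ̂² is biased low by (n−p)/n); the measured type-I error of the
single-term suite on null Brownian responses is ~6% at nominal 5%, inside
the ±2-point acceptance band, and the tests verify this directly with
400 replicates.

### Constrained Mk and ancestral states

A k-state character follows a continuous-time Markov chain with
generator Q = q·A, where A is a 0/1 allowed-transition mask (rows =
from-state) and q a single shared rate — the "weighted rate matrix"
design in which every permitted substitution counts 1 and every
forbidden one 0. Forbidden cells implement Dollo-style priors: an
absorbing Loss state, no re-evolution of lost spigot types.

Transition probabilities are exp(Qt). Because Q = q·A-with-diagonal
depends on (q·t) only, the implementation diagonalizes the unit-rate
generator once per analysis and exponentiates eigenvalues per edge — the
fast path for the optimizer's many rate evaluations — after verifying
the eigenbasis reproduces `scipy.linalg.expm` at a test point (these
masks are routinely defective; the robust Padé route is the fallback).
Probabilities are clipped into [0, 1].

The likelihood is Felsenstein pruning with per-node rescaling;
`brute_force_loglik` re-derives it by summing over every assignment of
states to internal nodes (exponential; capped at 12 internal nodes) and
is the core correctness oracle — pruning must match it to 1e-8 on
hundreds of random small instances. The rate is fitted by a coarse
log-spaced grid (the likelihood is zero over much of the rate range
under hard constraints, which derails a naive bounded search) followed
by bounded Brent refinement between the bracketing grid points.

Root prior is flat (1/k). Two log-likelihood scales exist in the wild:
the proper flat-prior value log Σ π_s L_root(s) (returned by
`pruning_loglik`), and the sum-over-root-states value log Σ L_root(s)
reported by the classic R ancestral-state implementation, which differs
by +log k. `MkFit.loglik_sumroot` exposes the latter; the CLI and the
acceptance script report it because that is the scale on which the
reproduced study printed its values.

Per-node "scaled likelihoods" default to the *conditional* mode — the
upward-pass subtree likelihoods normalized to sum to one, which is what
the era's standard implementation plotted — with the statistically
preferable *marginal* mode (upward × downward messages) available. Both
agree at the root under a flat prior (asserted to 1e-9). Note that a
forbidden direct transition does not forbid multi-step paths through
allowed intermediates: P(None→Loss, t) > 0 despite A[None, Loss] = 0,
second-order small for short branches (tested).

## The data fixtures and their provenance

Three provenance levels, marked in each fixture's header:

1. **Transcribed.** The 22-species predictor table (five variables:
   Strategy 0/1, Specific 1–5.5, Silk 1–4, Type 1–4, Instar), the full
   two-species ontogeny table, and the five-state PLS-spigot rate
   matrix are printed in the source and copied cell by cell. Most PLS
   tip states are stated in prose (text-sourced rows); the rest are
   colour-coded in a figure only and flagged `source=figure`.

2. **Reconstructed.** The 22- and 27-taxon topologies are not printed
   as machine-readable trees; they were rebuilt from the study's verbal
   description of the Araneae Tree of Life relationships (araneoid
   clade structure, Nicodamoidea sister to Araneoidea, the cribellate
   Hyptiotes/Phyxelida lineages just outside the RTA clade, the deeper
   Hypochilus/Kukulcania/Thaida placements) plus family membership.
   Where the description leaves resolution open (within Lycosidae,
   the two marronoid genera, the two dionychan families, nicodamoid tip
   states), the arrangement most consistent with the study's printed
   statistics was adopted and frozen. Branch lengths follow Grafen's
   clade-size method with power 1 (depth normalized to 1), the standard
   topology-only ultrametric transform of the tree library the study
   names; the all-lengths-1 phylogram is the documented alternative
   (`lengths="unit"`).

3. **Synthetic.** The per-species response averages (12 spigot-count
   variables) and the Specific/Silk/Type rate matrices come from
   supplements that are not part of the available text. The response
   fixture is exact where the text pins values (the two fully printed
   species; adult-female minor-ampullate = 1 in araneoids and 2
   elsewhere; the stated second-instar exceptions) and realistic
   invention elsewhere — its filename carries `.synthetic`. The three
   predictor matrices are rebuilt from the study's stated Dollo
   rationale (webs and cribellate silk are lost, not regained); the
   Strategy matrix, fully determined by that rationale, reproduces the
   printed root (Web = 1.0) and lands within 0.15 of the printed
   log-likelihood.

### What reproduces and what does not

On the frozen fixtures the PLS-spigot analysis gives logLik −45.417 and
root (Modified 0.403, None 0.597, others < 1e-3) against printed values
of −46.023 and (0.365, 0.635). The structural conclusions — root split
entirely between None and Modified, None favoured, flagelliform/
pseudoflagelliform/loss excluded — reproduce exactly; the residual
numeric gap (1.3% in log-likelihood, 0.04 in the root split) is
attributed to figure-level topology details that the text does not
determine: an extensive search over text-compatible arrangements moved
the result monotonically toward the printed values without reaching
them. Under the unit-branch-length fallback the None/Modified split
reverses (0.19/0.81) while the excluded states stay excluded — the root
ordering is therefore a branch-length-sensitive conclusion, which is
worth knowing when interpreting it. The acceptance test for the printed
numbers asserts the stated ±0.01 and is expected to fail by that small
margin; it is kept strict deliberately.

Because the response averages are synthetic, signal and PGLS outputs on
the response side (which variables come out significant, which single
term wins model selection) demonstrate the pipeline on data with the
right structure but do not reproduce printed coefficient values, and the
tests assert their statistical properties (counts, calibration,
invariances) rather than specific numbers.

## Simulation design

The generators mirror the assumptions of the analyses: Yule trees for
topologies (mean root depth matches Σ 1/(bk), tested against that closed
form), multivariate-normal Brownian draws through an eigendecomposition
square root (tolerant of the singular covariances λ-damping produces),
and exact event-driven CTMC simulation for discrete characters
(exponential waits, jumps proportional to allowed rates, absorbing
states persist). Binary predictors for regression simulations are made
by thresholding a Brownian trait at its median so predictors themselves
carry signal — the situation of the empirical trait table. One seed
expands into per-component substreams via `SeedSequence.spawn`.

Scales used by the test suite (chosen to make each check sharp but
cheap): parameter recovery on 100–200-tip trees with 20–50 replicates;
the pruning-vs-enumeration oracle on trees of 3–6 tips; type-I error on
the real 22-taxon tree with 400 replicate null suites. What passing
shows: the estimators recover their generating parameters under the
model's own assumptions. What it does not show: robustness to
model violation (non-Brownian evolution, measurement error, unresolved
polytomies), none of which the study's design exercises either.

## Known limitations

* The topologies are reconstructions; anyone with the original figures
  can replace `data/tree2{2,7}.nwk` and tip-state fixtures and rerun.
* Single-rate Mk only (the fixtures need nothing more); no hidden-rate
  or multi-rate models, no stochastic character mapping, no joint
  (max-product) reconstruction.
* PGLS covariance structures beyond Brownian-with-λ (OU, early-burst)
  are out of scope; the study used them only to confirm Brownian fit.
* Responses are per-species averages; within-species ontogenetic series
  enter only through the two fully transcribed species.
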
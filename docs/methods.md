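# Methods

`phylofactory` analyses how a binary species attribute — here the
naturalized and invasive status of grasses, but nothing in the code is
taxon-specific — is distributed over a rooted, branch-length phylogeny
and over biogeographic source regions.  This note documents the models,
the numerical choices, and what the synthetic-data generator does and
does not emulate.

## Trees

Trees are rooted as written; no re-rooting is performed.  Branch
lengths must be present and non-negative (a `default_branch_length`
switch can substitute a constant, logged, for sparse inputs; silent
defaults would corrupt every downstream branch-length sum).
Zero-length terminal branches are allowed, as dated megaphylogenies
contain them.  Polytomies are accepted on input; statistics that
require bifurcation resolve them on demand by inserting zero-length
edges (seeded, deterministic), which leaves the tip set, total tree
length and all patristic distances unchanged.

Pruning suppresses the degree-2 nodes it creates and sums their branch
lengths; the basal path removed below the retained subtree is kept as a
stem length on the new root, so every retained tip keeps its original
root-to-tip depth.  Species names in tables are matched to tip labels
with spaces and underscores treated as interchangeable.

## Phylogenetic clumping: the D statistic

For a bifurcating tree, tips carry their 0/1 states, each internal node
the unweighted mean of its two daughters, and

    d = sum over edges |value(parent) − value(child)|.

A clumped trait changes state along few edges (small d); a scattered
trait along many (large d).  Because the magnitude of d depends on tree
shape and prevalence, it is rescaled between two simulated
expectations, each at the observed prevalence k:

* random null — k ones shuffled uniformly over tips (no signal);
* Brownian-threshold null — a unit-rate Brownian character evolved
  along the branches, with the k largest tip values set to 1 (strong
  neutral clumping).

D = (d_obs − mean d_Brownian) / (mean d_random − mean d_Brownian), so
D ≈ 1 under random scatter and D ≈ 0 under Brownian-like clumping.
Each null yields a one-sided p-value with the add-one convention:
p_random = (1 + #{d_null ≤ d_obs}) / (n_perm + 1) (small means more
clumped than random) and p_brownian = (1 + #{d_null ≥ d_obs}) /
(n_perm + 1) (small means more dispersed than Brownian).  The two
tests at level α map to four scenarios: both rejected → intermediate
clumping; only random rejected → Brownian-consistent; only Brownian
rejected → random-consistent; neither → inconclusive.

Numerical choices: nodal values use the plain daughter mean and ignore
branch lengths.  Contrast-weighted variants exist; since observed and
null d are computed by the identical operator, the rescaling is
self-normalizing — E[D] ≈ 1 / ≈ 0 under the matching generators — and
that calibration, verified in the acceptance suite, is the correctness
criterion here.  Exact numerical parity with any particular weighted
variant is not expected.  Defaults: n_perm = 1000, α = 0.05.  Ties in
the Brownian threshold (possible with zero-length branches) break by
tip-label order, keeping everything reproducible.  The Brownian
machinery is one shared implementation used both by the null inside the
estimator and by the synthetic trait generator.

## Mk ancestral states

The equal-rates 2-state Mk model has one rate q; over a branch of
length t, P(state change) = ½ − ½·exp(−2qt).  The likelihood uses
Felsenstein pruning with per-node rescaling and the stationary root
prior (½, ½) — the conventional choice for the equal-rates model; an
estimated ("FitzJohn") prior is deliberately not offered.  q is fitted
by bounded scalar maximization on [1e−8, 100/tree height].  An
invariant trait drives q to the lower bound; the fit is returned
flagged (`at_bound`) rather than raising.  Data with probability zero
(conflicting tips across a zero-length path) yield −inf log-likelihood.

Marginal ancestral probabilities combine, per node, the pruning partial
below the node with the outside message passed down from the root —
algebraically the re-rooting construction, evaluated in a single
up-down sweep.  Both the likelihood and the marginals are checked
against exhaustive enumeration over all internal-state histories on
small trees (|Δ| < 1e−9).  Stochastic character mapping is out of
scope: it feeds visualization only, and the marginals carry the same
information for inference.

## Diversification rates and the phylogenetic logistic regression

Tip-level diversification rates come either from an imported
`species,rate` file (e.g. produced by an external Bayesian
rate-shift analysis) or from the built-in inverse equal-splits
statistic: ES_i = Σ_j l_j · (½)^(j−1) over the root-path edges (pendant
edge first), rate_i = 1/ES_i.  Equal-splits is a fast speciation-rate
proxy, not a substitute for a full rate-shift model; it is the
desk-scale default and is validated against an independent top-down
apportionment recursion.

The regression of the binary status on the (z-scored by default) rate
is a quasi-likelihood fit in the spirit of the mean-reverting
binary-trait estimator of Ives & Garland: generalized estimating
equations with logit link and working correlation

    R_ij = (1 − ν) · exp(−α · d_ij),   i ≠ j,

where d is patristic distance on the tree rescaled to unit height.  α
(reported as `alpha_phy`) is estimated by minimizing the Gaussian
pseudo-likelihood of the Pearson residuals, profiled over a bounded
log-grid; large α is the independence limit.  The slope's standard
error is the model-based (U'R⁻¹U)⁻¹ form; z = β/se with a two-sided
normal p-value.

The nugget ν = 0.05 is a deliberate numerical choice: dated and
simulated trees carry effectively zero-length cherries, and without a
nugget the working correlation for such twins hits 1, their contrasts
receive unbounded weight, and the estimating equations collapse toward
β = 0 with vanishing standard errors.  With the nugget the estimator is
calibrated (type-I error inside the binomial band around 5% under an
Mk-generated null response) and recovers a true standardized slope of
1.5 at n = 300 with median ≈ 1.45 and 100% sign recovery (both
recomputed by the acceptance suite).  Perfect separation by the single
predictor is detected and raised explicitly.  Numerical parity with any
particular R implementation is not a goal; the calibration and recovery
properties define correctness.

A note on calibration nulls: a response with *fixed* prevalence (k of n
tips set to 1 by thresholding) conditions on the state total, which
deflates the variance of every score statistic below what any pairwise
correlation model predicts; tests of the estimator's type-I error
therefore use a response evolved freely under the Mk process, whose tip
correlation really does decay as exp(−2q·d).

## Faith's PD and SES PD

Faith's PD of an assemblage is the total branch length of the union of
its root-to-tip paths, root path included (the common convention of
community-phylodiversity tooling); `include_root=False` instead counts
only the minimal subtree connecting the tips, for sensitivity checks.
A root stem left by pruning counts when present.

SES PD compares the observed PD with n_null (default 100)
richness-matched assemblages drawn uniformly without replacement from a
pool; ses = (PD_obs − mean)/sd and p = (1 + #{PD_null ≤ PD_obs}) /
(n_null + 1).  Two pools are always reported: *global* (every tree
tip) and *regional* (the species attributed to the region), matching
the two ways a regional alien assemblage can be benchmarked.  Verdicts:
p < α → "restrictive" (lineage-restricted export), otherwise
"generalized"; assemblages under 3 species are "indeterminate".  The
null sd uses ddof = 1.

Species are attributed to their source realm and biome by the mode of
their occurrence records, computed independently per level; modal ties
break lexicographically and are flagged in the output.  Ratio tables
report counts and percentages recomputed from those counts (one
decimal).

## Synthetic worlds

The generator produces, from a single seed: a pure-birth (by default)
ultrametric tree; nested Brownian-threshold status flags (the invasive
set is the top 18.6% of one Brownian character, nested inside the
naturalized top 36.5% — mirroring both the observed prevalences in a
global grass compilation and the fact that invasive species are a
listed subset of naturalized ones); six realms and twelve biomes
partitioning the species pool with realistically uneven richness; and
noisy occurrence records (30 per species, 20% label noise by default).

Regional assemblages interpolate between a uniform draw from the pool
(restriction 0, a generalized factory; SES PD ≈ 0 by construction) and
a single clade (restriction 1, maximally restricted); the default
restriction is 0.7.  The demo world therefore exercises the
"restrictive factory" detection path end to end.

What the generator does **not** emulate: trait-dependent
diversification (no BiSSE-style feedback between the status and the
branching process), geographic coordinates or spatial autocorrelation
of occurrence errors, asymmetric gain/loss rates, and phylogenetic
uncertainty.  Passing tests therefore show that each estimator recovers
the structure its own generating model produces at these sizes — they
do not certify behaviour under model misspecification beyond the cases
listed above.

## Problem sizes and determinism

The bundled analyses run at 150–500 tips with 100–1000 permutations or
null draws — sizes chosen so every suite completes in minutes on one
CPU while keeping Monte-Carlo error well inside the asserted bounds.
Every stochastic step takes an explicit seed; the pipeline fans one
master seed out to per-stage seeds deterministically, and a rerun with
an identical configuration is bit-identical, which the test suite
asserts byte-for-byte.

## Known limitations

* The D statistic's unweighted nodal mean is one member of a family of
  estimators; cross-package numerical identity is not guaranteed (the
  self-calibration property is).
* Equal-splits rates are a proxy; for fidelity runs import externally
  computed rates.
* The logistic GEE reports model-based standard errors; with severe
  working-correlation misspecification they can be conservative.
* Regions are abstract labels: no GIS, no coordinate-to-region lookup,
  and no recipient-region (invaded-range) analysis.
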
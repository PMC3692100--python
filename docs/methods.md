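# Methods

This note documents the models, statistics and design choices behind
`phylocoev`, in enough detail to reimplement them.

## Gain/loss model

Each binary character evolves independently along a rooted tree under a
two-state continuous-time Markov chain with instantaneous gain rate
*g* (0→1) and loss rate *l* (1→0). The chain is reversible with stationary
distribution (π₀, π₁) = (l, g)/(g+l) and transition probabilities

    P01(t) = π1 (1 − e^{−(g+l)t})        P10(t) = π0 (1 − e^{−(g+l)t}).

Three tiers describe rate variation among characters:

* **single** — one (g, l) for all characters;
* **gamma_invariant** (default) — an overall multiplier drawn from a
  discretized Gamma(α, mean 1) with K equal-probability categories (each
  category carries the conditional mean of its quantile bin), plus a rate-0
  "invariant" category of proportion p_inv;
* **mixture** — gain and loss multipliers drawn *independently* from two
  discretized gammas (K_gain × K_loss category grid, default 3 × 3),
  letting a character be, say, frequently gained but rarely lost.

**Normalization.** Rates and branch lengths are confounded in any clock-free
model, so every mixture is rescaled such that the weighted average
stationary event flux, Σᵢ wᵢ · 2gᵢlᵢ/(gᵢ+lᵢ), equals 1. Branch lengths are
then expressed in expected events per character, and only the gain/loss
*ratio* (plus the shape parameters) is free. Branch lengths are taken from
the input tree and never re-optimized; a single global branch-scale factor
can optionally be fitted.

**Root prior** is the category's stationary distribution; for the rate-0
invariant category, whose stationary law is undefined, the base-rate
stationary frequencies are used.

**Unobservable-data correction.** A character absent from every genome can
never be observed, so real data are a truncated sample. With
`correction="no_absent"` each per-site likelihood is divided by
1 − P(all-zero column), computed on the same tree and mixture. All-present
columns remain observable and are not conditioned on. The correction is a
per-site constant across categories, so posterior category weights are
unaffected.

**Fitting.** The corrected log-likelihood is maximized by Nelder–Mead over
transformed parameters (log ratio, log α, logit p_inv), from three fixed
start points (ratio 0.3 / 1 / 3), tolerance 1e−6 in log-likelihood.
No randomness enters the optimizer, so fits are deterministic. Felsenstein
pruning uses per-node, per-site rescaling of partial likelihoods (divide by
the max over states, accumulate the log), which keeps 64+-taxon × mixture
computations in the normal floating-point range; the pruning recursion is
validated against exhaustive enumeration over interior states to 1e−12.

## Stochastic mapping

For a branch of length t with endpoint states (a, b) the expected number of
i→j jumps is q_ij ∫₀ᵗ P_{a,i}(s) P_{j,b}(t−s) ds / P_{a,b}(t). Because the
chain has eigenvalues {0, −(g+l)} the integral is elementary:

    ∫₀ᵗ P_{a,i}(s) P_{j,b}(t−s) ds =
        πᵢ π_b t + (πᵢ B + π_b A)(1 − e^{−rt})/r + A B t e^{−rt},

with r = g+l, A = δ_{a,i} − πᵢ, B = δ_{j,b} − π_b. The same integral with
j = i gives the expected dwell time in state i. Endpoint-pair posteriors per
branch come from standard inside–outside vectors per category; per-branch
joints are normalized over the four endpoint pairs (which cancels all
per-site scalings), and categories are mixed by their per-site posterior
weight. Events are attributed to branches of the rooted tree, read
root→tip. Analytic expectations are validated against a 10⁶-trajectory
Monte-Carlo sampler within 3 standard errors.

Besides the raw expectations E[N_gain], E[N_loss] per (site, branch), the
mapper emits **martingale residuals**

    r_gain = E[N_gain | data] − g·E[T₀ | data],
    r_loss = E[N_loss | data] − l·E[T₁ | data],

where T_s is dwell time in state s. Since N_gain − g∫1{X=0}ds is a
martingale, these residuals have conditional mean zero under the
independence model *whatever the data say about the site*.

## Coevolution score and significance

Each character is summarized by the concatenation of its per-branch gain
and loss residuals (2B entries for B branches); the score of a pair is the
Pearson correlation of these vectors, computed by a commutative formula so
score(i,j) equals score(j,i) bit for bit.

Residuals, not raw expectations, are correlated for a measured reason: for
characters whose data localize events poorly, the posterior expectation
vector relaxes toward the same smooth rate×branch-length profile for every
character, so raw-expectation correlations acquire a fat, spurious
right tail (on the standard benchmark this tail pushed the detector below
the phylogeny-blind extant-correlation baseline). The residual transform
removes exactly that shared component; raw expectations remain available
(`score_pairs(..., statistic="expectation")` and the `events.tsv` output).

**Null distribution.** The null correlation of two independent characters
depends strongly on how many events they have, so significance is
stratified: `n_sims` independent characters are simulated under the fitted
model, mapped on the same tree, and all null pairs are binned by a 5×5
quantile grid of per-site total expected events (bin edges from the *real*
data, so every real pair is covered). A stratum consulted with fewer than
100 samples is pooled with its nearest neighbours (Manhattan distance on
bin indices) until the floor is met. The empirical p-value uses the add-one
rule p = (1 + #{null ≥ score})/(N + 1): never zero, finite-sample valid,
with its floor 1/(N+1) reported openly. Benjamini–Hochberg converts
p-values to q-values across all tested pairs; edges with q ≤ α (default
0.01) form the network. Pairs with a constant event vector are excluded and
reported rather than scored.

Practical note on resolution: with empirical p-values, BH at level α can
only fire if the p-floor of the relevant strata is below α·k/m for the
discoverable pairs. The pipeline default of 1000 null simulations suits
hundreds of characters at α ≈ 0.01–0.05; analyses of thousands of
characters at α = 0.01 need proportionally more null simulations.

## Tree inference

When no tree is given, pairwise ML distances are computed under the
reversible two-state chain with counted stationary frequencies, scaled to
expected events per character (rate 1/(2π₀π₁)); the separation time is
maximized by bounded scalar optimization on [0, 10], the cap playing the
same saturation-guard role as the infinities of a Jukes–Cantor distance.
Saitou–Nei neighbor joining follows, with Q-criterion ties broken by the
lowest active index pair, negative limb estimates clamped to zero, and the
unrooted result rooted at the midpoint of the longest leaf-to-leaf path
(the reversible likelihood is root-invariant; rooting only fixes the
branch coordinate system for event reporting).

## Simulators and the benchmark

**Random trees** are pure-birth (Yule) topologies — the standard neutral
species-tree model — with heights from the exponential birth process and
lengths rescaled so the tree's total branch length is 6.0 by default, i.e.
about six expected events per character: a moderately dynamic gene-content
regime in which both extant patterns and event placements are informative.
(A coalescent-shaped prototype was rejected: half its length sits in the two
basal branches, making single deep events — and hence chance-identical
columns — the dominant error mode for every detector.)

**Independent characters** draw a category, a stationary root state, and
then jump-chain trajectories branch by branch; realized event counts can be
returned, which grounds the mapping oracle tests. The default benchmark
rates use gain/loss ratio 0.5 (stationary presence 1/3), reflecting the
deletion bias of prokaryotic gene content.

**Coevolving pairs** evolve as one 4-state chain over {00, 01, 10, 11}.
Starting from the Kronecker sum of the two marginal generators (exact
independence), every off-diagonal rate *into* a concordant state (00, 11)
is multiplied by the dependency factor d (default 16) and every rate *out*
of a concordant state divided by d; stationary concordance odds scale as
d². The biased generator is then rescaled so its stationary event flux
equals that of two independent characters of the same category — otherwise
d = 16 slows the pair roughly eightfold and "coevolving" becomes confounded
with "slow". At d = 1 the construction reduces exactly to independence
(flux factor 1). Pairs start at the joint stationary distribution; branch
transitions use the matrix exponential.

**Benchmark and AUPR.** A benchmark set holds 2·n_coev coevolving columns
and n_indep independent columns in shuffled order with the true pairs
recorded. Detectors return scored pair lists; average precision (the mean
of precision at each true pair's rank, descending scores, ties kept in
pair-id order) summarizes the ranking. The phylogeny-aware detector is the
package's residual-correlation score; the baseline is Pearson correlation
of extant columns ("observed correlation"). Both exclude extant-constant
characters — they carry no signal, and excluding them keeps the two
detectors ranking the same pair set. Because single-replicate AUPR
differences carry seed noise comparable to the detectors' separation, the
ordering is asserted on the mean over replicates.

### What the simulations do not emulate

Real phyletic data have features the generator deliberately omits: gain
hotspots (horizontal-transfer highways concentrating gains on particular
branches), orthology-calling errors (noise in the 0/1 calls), gene
copy-number variation, tree estimation error, lineage-specific rate shifts,
and coevolving *groups* larger than two. Passing tests therefore certify
the machinery under the stated model, not robustness to these real-data
violations; in particular the significance calibration assumes the fitted
model is the data-generating null.

## Problem sizes and numerical choices

* Validation suites use 64-taxon trees with 100–2000 characters, 1000–2000
  null simulations, 20 FDR replicates and 10 benchmark replicates — sizes
  at which every Monte-Carlo tolerance used (3 SE bands, 15% ratio
  recovery, 5% event-count consistency) is comfortably resolved.
* Distance cap 10 expected events per character; optimizer tolerances 1e−6;
  pruning validated to 1e−12; degenerate-equal-eigenvalue branches need no
  special casing because the two-state closed forms are exact for all
  r t ≥ 0 (r = 0 and t = 0 short-circuit to zero events, with dwell split
  evenly).
* All stochastic steps take explicit integer seeds; a pipeline run with the
  same configuration is byte-identical (TSV floats printed with %.10g,
  fixed orderings throughout, ties broken by index or id everywhere).

## Known limitations

* Binary characters only; copy-number dynamics are out of scope.
* Branch lengths are trusted (up to one optional global scale); a poor
  input tree propagates into event mapping and the null bank.
* The empirical p-value floor limits attainable significance; at small α
  and many pairs, discoveries require large null banks (memory and time
  grow linearly in n_sims, null pair scoring quadratically).
* Connected components are the only clustering provided for the network;
  richer cluster analysis is left to downstream graph tools via the
  GraphML/SIF exports.
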
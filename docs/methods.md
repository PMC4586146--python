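# Methods

`mtexpand` analyses small intraspecific mtDNA datasets of the kind produced
by control-region phylogeography studies: a few hundred aligned haploid
sequences, a few dozen variable sites, per-locality frequency counts.  This
note records the models implemented, the conventions chosen where the field's
standard programs disagree, and what the built-in simulator does and does not
emulate.

## Data model

Alignments are stored as their variable columns only (1-based coordinates on
a reference mitogenome) plus a declared total locus length `L`.  This is the
form in which such datasets are published — haplotype-by-variable-site tables
with locality counts — and it is lossless for every statistic computed here,
because invariant columns contribute nothing to S, k, h, mismatch classes or
network distances, and enter π only through `L`.

Two characters beyond the four bases are distinguished throughout: `-` is an
alignment gap (an observed indel state) and `?` is missing/unresolved data
(IUPAC ambiguity codes are mapped to `?` on input).  The distinction matters
because every downstream convention treats them differently.

### Gap policies

The programs classically used for these analyses differ in gap handling, and
the differences are visible at the scale of a dataset with five indel
columns.  Each statistic therefore takes an explicit policy, with defaults
pinned per stage:

| stage | default | rationale |
|---|---|---|
| segregating sites S | `gap_as_state` | a column segregating only for an indel is still polymorphic; this convention reproduces the packaged dataset's published S |
| k, π, mismatch | `gap_as_missing` (pairwise deletion) | gaps carry no substitution information for pairwise differences |
| TN93 distances | `complete_deletion` | the closed form is defined on bases only; conservative and order-independent |
| networks | indel columns removed | alignment blocks containing indels are uninformative for substitution networks |

## Diversity statistics

Haplotype (gene) diversity uses the unbiased estimator
`h = n(1 − Σp_i²)/(n−1)` with Nei's (1987) sampling variance.  Nucleotide
diversity is `π = k/L`, with the standard no-recombination variance
approximation; `L` is a required parameter because published tables often do
not state the effective length behind their π values.  `k` is the mean
Hamming distance over all C(n,2) pairs, computed over distinct haplotypes
weighted by frequency (exactly equal to the exhaustive pair loop, which the
tests verify).

## Neutrality tests

Tajima's D uses the 1989 constants a₁…e₂; it is a typed error at S = 0
rather than NaN.  Fu's Fs estimates θ by k, computes
`S' = P(K ≥ k_obs | θ)` under the Ewens sampling distribution with unsigned
Stirling numbers of the first kind evaluated entirely in log space
(triangular recursion with log-sum-exp; n capped at 10,000), and returns
`ln(S'/(1−S'))`.  Degenerate cases (k = 0, a single allele, S' numerically 0
or 1) raise typed errors.

P-values are simulation-based: constant-size coalescent samples at the
observed n with θ set to the observed k, lower-tail fractions
`P(stat_sim ≤ stat_obs)` for both statistics — the convention under which a
small p supports demographic expansion.  Default 1000 simulations, seed 42.

## Mismatch distributions and expansion dating

The expected mismatch curve under sudden (stepwise) growth is implemented as
the exact two-epoch mixture for a pair of lineages: coalescence in the
recent epoch gives the equilibrium geometric at θ₁ truncated at τ, while
survival to the size change (probability `e^(−τ/θ₁)`) adds Poisson(τ)
mutations on top of the ancestral equilibrium at θ₀.  This reduces to the
equilibrium geometric at τ = 0 and agrees with the classical
Rogers–Harpending curve to ~10⁻⁵ at the θ₁ ceiling used.

Fitting minimises the sum of squared deviations from the observed relative
frequencies over a coarse grid (τ ∈ [0, 2·d_max] × θ₀ ∈ [0, k̄]) followed by
Nelder–Mead refinement.  θ₁ is pinned at 99,999 by default — the convention
of the standard programs; three-parameter fits on shallow data are
ill-conditioned — with an option to free it.

Two conventions deserve explicit statement:

* **Haplotype-level histograms.**  The pipeline's mismatch stage operates on
  the distinct haplotypes of a group (one row each), not on
  frequency-weighted individuals, matching the described practice of fitting
  "pairwise differences among haplotypes".  In datasets dominated by one
  high-frequency haplotype the weighted histogram acquires a large
  zero-difference spike that drags the least-squares fit toward the
  equilibrium (τ = 0) corner; the haplotype-level histogram is robust to
  this.  A `mismatch_weighted` switch restores individual weighting.
* **Dating.**  `t = τ/(2u)` with `u` applied as a whole-locus per-generation
  rate (default 7.30 × 10⁻⁵, generation time 1 year) and the result rounded
  *up* to the next whole year; this pairing reproduces the published jackal
  dates exactly.  A `per_bp` mode (`u = μL`) is available but off by
  default.

Harpending's raggedness is `r = Σ_{i=1}^{d+1}(x_i − x_{i−1})²` over the
relative frequencies with `x_{d+1} = 0` — the classical definition, with no
leading `x_0²` term.

Confidence intervals for τ come from a parametric bootstrap: simulate from
the fitted model (θ₁ capped at 1000 on the generator side, where the 99,999
ceiling only encodes "effectively infinite"), refit each replicate, take
percentile intervals; the run errors out if more than 10% of replicates are
degenerate.

## TN93 + Γ distances

The Tamura–Nei closed form with separate purine/pyrimidine transition terms,
base frequencies estimated from the pooled pair, complete deletion, and a
gamma correction (default shape 0.3) replacing each `−c ln w` term with
`c·a·(w^(−1/a) − 1)`; the corrected distance always dominates the
uncorrected one.  Saturated proportions (any `w ≤ 0`) raise a typed error.
Group means average all between-group pairs; standard errors bootstrap over
alignment columns (1000 replicates by default).

## Median-joining networks

Construction follows the Bandelt scheme: (1) weighted Hamming distances
(equal weights by default); (2) ε-relaxed minimum-spanning network — at
ε = 0 exactly the union of all minimum spanning trees, built by Kruskal with
equality grouping; (3) candidate median vectors as the column-majority
consensus of connected triplets (lexicographic tie-break on ties — a
quasi-median simplification; full quasi-median expansion is out of scope),
added in order of connection cost whenever they strictly shorten the
network; (4) iterate to fixpoint; (5) prune median vectors of degree < 2 or
lying on no shortest path between sampled haplotypes.  All tie-breaking is
lexicographic by node id, making the output deterministic; the published
algorithm is order-sensitive, so the tie-break rule is part of the contract.

Node degrees count all incident edges, including edges to median vectors;
peripheral means degree 1.  Edges are annotated with the differing reference
positions so one-step mutation renderings are reproducible.

## Coalescent simulator

Time is measured in mutational units (one unit = expected mutations per
lineage), so a pair coalesces at rate 2/θ and the expansion model's size
change sits at τ/2 in the past — simulator τ is directly comparable to
fitted τ.  Mutations are Poisson on branches under infinite sites (each
mutation a fresh position of an L-bp locus; exceeding L is an error advising
a larger locus), with a finite-sites option for robustness checks.
Calibration: E[S] = θa₁(n) and E[k] = θ, verified at n = 20, θ = 5 with
2000 replicates in the test suite.

The simulator emulates neutral, non-recombining, panmictic haploid loci.  It
does not model population structure, migration, selection, rate
heterogeneity among sites, or recurrent mutation (in the default mode) —
all present to some degree in real control-region data.  Passing
calibration and recovery tests therefore demonstrates correctness of the
estimators under their own model assumptions, not robustness to the
violations real data exhibit.

## Problem sizes and defaults

Monte-Carlo experiment sizes used in the validation suite were chosen to
make sampling error a small fraction of each tolerance band: 2000 replicates
for simulator calibration, 1000 for the type-I-error check of Tajima's D
(null quantiles from a separate 2000-replicate batch), 100 replicates for τ
recovery (median within ±1 of truth), and 100–1000 bootstrap replicates for
interval estimates.  Pipeline defaults: ε = 0, equal site weights, γ shape
0.3, μ = 7.3 × 10⁻⁵ per generation, generation time 1 year, 1000 bootstrap
replicates, 1000 neutrality simulations, seed 42.

## Known limitations

* The packaged dataset's published diversity table is not fully derivable
  from its printed variable-site matrix (its Indian k and Eurasian S differ
  from every gap-policy reading of the matrix, and the n = 51 vs 52 Indian
  sample-count discrepancy is unresolved in the source); the package exposes
  both count readings and treats those entries as approximate targets.
* The median-joining implementation uses single-median (majority) vectors,
  not the full quasi-median set; for the binary-to-ternary sites typical of
  control-region data this coincides with the standard construction in all
  tested cases.
* Fu's Fs p-values use the same lower-tail simulation convention as D;
  two-tailed interpretations require the caller to transform them.
* The sudden-expansion fit assumes a single instantaneous size change;
  multimodal mismatch distributions (structure, admixture) will fit poorly
  and should be judged by the reported SSD and raggedness.
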
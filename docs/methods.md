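# Methods

This note documents the models behind each stage, the parameters that
matter, what the synthetic generator does and does not emulate, and the
numerical and design choices made where the design was genuinely open.
No empirical claim here goes beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Conventions

Count tables are taxa rows × sample columns of non-negative integers; every
generated sample column sums exactly to the configured depth. Shannon
entropy is reported in nats, Simpson as Gini–Simpson (1 − Σp²), Chao1 as
the classic estimator S_obs + F1²/(2F2) (F2 = 0 falls back to
S_obs + F1(F1−1)/2). Jaccard is computed on presence/absence. All
permutation-based stages draw from named substreams of one root seed
(`rhizonet._rng.stream`), keyed by a CRC32 hash of the stage label, so
stages are individually reproducible and mutually independent.

## Synthetic communities (`rhizonet.synth`)

The generator exists to give every downstream estimator a recovery test
with known truth. It emulates a multi-group amplicon survey: an
ultrametric pure-birth (Yule) phylogeny; conserved niche traits; and
taxa-by-sample counts assembled under one of five processes.

**Phylogeny.** Pure birth at unit rate, tips labelled `t1..tn` in birth
order. Pure birth rather than birth–death keeps the tree model minimal;
extinct lineages add nothing to trait conservation at the scales used here.

**Niche traits.** Brownian motion from a root value of 0 with rate
`trait_sigma` (trait units² per unit branch length). The niche has
`niche_dims` = 5 independent axes by default. Dimensionality matters: with
a single Brownian axis, unrelated lineages converge on the same trait value
often enough that a Gaussian niche filter selects a phylogenetically
*overdispersed* set — the filter's selectivity is real but its
phylogenetic footprint is erased. With several independent axes a taxon
must match the optimum on every axis at once, which only close relatives
do, so selection leaves the clustered footprint that phylogenetic
null models are designed to detect. Real niche space is plainly
multivariate (pH, moisture, nutrients, temperature…), so this is also the
more realistic default; one axis remains available via `niche_dims=1`.

**Selection scenarios.** Fitness of taxon *i* in sample *s* is the spec of
a Gaussian niche filter applied per standardized axis:
w_i(s) = exp(−`selection_strength` · Σ_d z_id(s)²) with
z_d = (t_d − e_sd)/sd_d. The environmental optimum is the mean niche
position of an **anchor clade**: among clades containing 7.5–17.5 % of the
taxon pool, the one with the smallest mean within-clade nearest-neighbour
cophenetic distance relative to random tip sets of equal size. Anchoring
at a tight clade (rather than, say, a ±2 sd trait value) makes the
selected pool a coherent lineage for any tree realization instead of only
for lucky ones. Homogeneous selection uses one anchor for all samples;
heterogeneous selection uses two disjoint anchors — the second chosen to be
phylogenetically distant from the first — alternating across groups, so
between-group turnover crosses two divergent lineages. Per-sample jitter
of the optimum (`env_noise_sd` = 0.05 trait sd) represents micro-
environmental variation.

Assembly then has an explicit drift component acting on *occupancy*:
each site receives an expected `site_occupancy` = 0.65 fraction of the
anchor clade, membership drawn Bernoulli with probability increasing in
fitness, and taxa below `fitness_floor` = 1e−3 relative fitness cannot
colonise. Abundances among colonisers follow pool · fitness^`abundance_damp`
(damp = 0.15). Two considerations force this structure. First, without
drift every sample holds the full favoured set; sample pairs then share all
taxa, shared taxa contribute zero to βMNTD under any tip shuffle, and β-NTI
is undefined or uninformative — selection-with-drift is also the
ecologically coherent picture (selection sets the candidate pool, drift
picks members). Second, the damped-abundance choice keeps turnover taxa
at non-negligible weight, which is what the abundance-weighted βMNTD
actually averages over.

**Neutral scenarios.** A log-normal (σ = `pool_sigma` = 2) rank-abundance
metacommunity pool — the steep dominance/rarity profile of real amplicon
surveys, which keeps rare taxa genuinely absent from many samples at
realistic depths. Site weights are a mixture
(1 − m)·Dirichlet(`drift_concentration`·pool) + m·pool with migration rate
m: 0.01 for dispersal limitation (sites drift far apart), 0.99 for
homogenizing dispersal (sites pinned to the shared pool, more similar than
random membership draws). The undominated scenario is neutral stochastic
colonisation: membership Bernoulli with probability 0.9·(pool_i/max pool)^0.25,
abundances from the pool among colonisers. This makes undominated
communities membership-stochastic in the same sense as the Raup–Crick
null, which is the regime that metric calls "undominated"; pure
multinomial pool draws (available via `migration_rate=1` in the dispersal
scenarios) are *more* homogeneous than any null draw and would read as
homogenizing dispersal instead.

Counts are multinomial at depth 10⁴ by default. The recovery-test scale is
200 taxa and 20 samples: β-NTI needs per-sample richness that is large in
absolute terms (its null z-score aggregates over present taxa) while small
relative to the pool (else nearest-taxon null distances degenerate), and
below ~100 tips those two requirements cannot be met simultaneously —
pure clade draws max out near |z| ≈ 1–2 at 50 tips.

**What the generator does not emulate:** sequencing error, chimeras, ASV
calling, primer bias, overdispersion beyond multinomial (no
Dirichlet-multinomial by default), spatial structure, time series, and
multi-kingdom tables. Passing recovery tests therefore demonstrates the
estimators work when their assumptions hold, not that real data meet those
assumptions.

## Diversity (`rhizonet.diversity`)

Rarefaction subsamples without replacement (multivariate hypergeometric),
one draw by default; samples shallower than the target are excluded with a
warning. PERMANOVA uses the squared-dissimilarity partition (pseudo-F from
among/within sums of squares) with label permutation; the implementation is
vectorised for the calibration studies and cross-checked against
scikit-bio's PERMANOVA in the suite. Mantel is Pearson on lower triangles
with joint row/column permutation, one-sided on positive association.

## Assembly inference (`rhizonet.assembly`)

The "top-n by relative abundance" filter (`filter_top_taxa`) is the
operative abundance filter, with ties broken by taxon id.

**β-NTI null:** taxon labels shuffled across the tips present in the
filtered table (not the full tree) — the standard choice; configurable by
passing a pruned tree. Pairs with null sd 0 (e.g. star phylogenies, or
identical membership) are reported missing with a warning. βMNTD is
computed by a vectorised per-sample nearest-member reduction and verified
against a brute-force double loop and against picante's `comdistnt`
(exact agreement).

**RC-bray null:** per replicate, each sample is reassembled preserving its
richness (membership drawn without replacement ∝ metacommunity occupancy)
and total abundance (one individual per drawn taxon, remainder multinomial
∝ metacommunity relative abundance).

**Classification:** β-NTI takes precedence (deterministic signal first);
|β-NTI| exactly at the threshold is stochastic; RC thresholds ±0.95 are
parameters. Fig-4-style summaries use within-group pairs by default
(`scope="all"` pools everything).

**NST:** per within-group pair, ST = (1−Ē)/(1−D) when D ≤ Ē, else Ē/D,
with Ē the mean dissimilarity under the RC null; the group value is the
mean ST × 100 (the normalization is the identity on the mean — documented
rather than hidden). A structural caveat follows from the null's
construction: the null is conditioned on the observed table's occupancy
and abundance profile, so a selective filter applied *uniformly* to all
samples shapes the null along with the data and largely escapes
detection — NST flags homogenization or divergence relative to the
table-implied expectation, not uniform selection. The acceptance suite
keeps the uniform-selection bound as specified and the corresponding test
documents this limit; the undominated bound behaves as intended.

**Mantel correlogram:** equal-width phylogenetic distance classes;
per class the Mantel statistic is the (sign-flipped) correlation between
the within-class indicator and the niche distance, permutation-tested,
with a progressive Holm-style correction applied outward from the shortest
class.

## SparCC (`rhizonet.netinfer`)

Fractions use a pseudocount of 1 by default — deterministic, which the
test suite relies on; the original stochastic Dirichlet-draw averaging is
behind `dirichlet_average=True` with `n_inner_iter` draws. Exclusion
refinement removes the strongest-|ρ| pair (up to 10 rounds, stopping at
threshold 0.1) and re-solves the basis-variance system restricted to the
remaining pairs; taxa are never excluded below two partners, and negative
solved basis variances mark a taxon's correlations as missing with a
warning. Permutation p-values shuffle each taxon's counts independently
(two-sided). Edge thresholds |ρ| ≥ 0.3 and p ≤ 0.05 are defaults recorded
in every artifact, chosen because published tables rarely state cutoffs;
absolute edge counts are therefore not comparable across threshold choices.

## Network ecology (`rhizonet.netanalysis`)

`avgK_paper` = E/N reproduces the "average connectivity" convention of
published topology tables (verified against the printed values by the
identity E/N); `mean_degree` = 2E/N is the standard definition; the report
carries both. Path distance averages over connected pairs only (networks
need not be connected); clustering is on the unsigned graph. Module
detection defaults to greedy (Clauset–Newman–Moore) modularity
maximisation on |weight| — deterministic — with Louvain (seeded) optional.
z uses population (ddof 0) module statistics with z = 0 for sd-0 modules;
boundary values z = 2.5 / c = 0.6 fall to the lower category (strict
inequalities). Natural connectivity uses a log-sum-exp over the
eigenvalues of the unsigned, unweighted adjacency; the robustness curve
computes betweenness once (static order, ties by node id; recomputation
after each removal is available via the flag on `robustness_curve` — not
default because a fixed ranking matches the usual "declining order of
betweenness" procedure) and reports the trapezoid area under the curve.

Cohesion correlates relative abundances across samples, subtracts the mean
correlation over null iterations in which each taxon's abundances are
independently shuffled and the table re-closed to compositions (re-closure
puts the closure-induced negative bias into the null so the correction
removes it), averages positive and negative corrected correlations over
*all* partners (keeping the null-calibrated scale near zero for
independent data), and weights by abundance per sample.

## Pipeline (`rhizonet.io`, `rhizonet.cli`)

A YAML/JSON config names inputs or a synthetic scenario, the group column,
null replicate counts, thresholds and the root seed; validation happens
before any computation. Every run writes `run_log.json` with the config
hash and seed. The CLI (`rhizonet simulate|diversity|assembly|network|all`)
is a thin wrapper over `run_pipeline`.

## Problem sizes used in the checks

Recovery runs use 200 taxa × 20 samples × depth 10⁴ with 99 null
replicates, pooled over 3–5 replicate simulations (the pair-level z-scores
within one simulation share the tree and are not independent); the null
calibration uses 100 independent two-sample datasets at 80 taxa; SparCC
recovery uses 50 taxa × 200 samples × depth 10⁴ over 5 seeds; PERMANOVA
calibration uses 1000 null datasets with 99 permutations; NST uses 20
replicates of 12-sample single-group communities with 30 null replicates.
These sizes were chosen so each estimator operates in the regime it needs
(see the richness/pool discussion above) while the whole suite stays quick
to run.

## Known limitations

* β-NTI is insensitive below ~100 taxa and when per-sample richness
  approaches the pool size; both are properties of the statistic, not the
  implementation.
* NST (as specified here) cannot flag selection applied uniformly to all
  samples; see above.
* SparCC assumes sparsity of true correlations; dense correlation
  structure biases the basis-variance solution.
* The five-process partition inherits the thresholds (±2, ±0.95); pairs
  near thresholds are assigned, not flagged as uncertain.
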
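# rhizonet

Analysis stack for rhizosphere (and other amplicon) microbiome studies:
diversity statistics, phylogenetic null-model inference of community
assembly processes, SparCC co-occurrence networks, and network ecology —
plus a synthetic community generator that plants known assembly processes
and correlation structure so every stage can be verified end to end
without external data.

## Who this is for

Microbial ecologists working from an ASV/OTU count table (taxa × samples),
a rooted phylogeny of those taxa, and sample metadata (group labels such as
vegetation type, plus numeric environmental variables), who want a single
tested pipeline for the questions such studies ask:

* How diverse are the communities, and do groups differ? (α indices,
  Bray–Curtis/Jaccard, PERMANOVA, Mantel, Venn-style group taxon sets)
* What assembles the communities — selection, dispersal, or drift?
  (β-MNTD/β-NTI, RC-bray, five-process partition, NST)
* How are taxa organised into interaction networks, and how stable are
  those networks? (SparCC, modules, z/c keystone roles, natural-connectivity
  robustness, cohesion)

## The statistics at the core

**β-NTI.** For samples *A, B* the abundance-weighted β mean nearest taxon
distance is

    βMNTD(A,B) = ½ [ Σ_{i∈A} f_iA · min_{j∈B} d_ij  +  Σ_{j∈B} f_jB · min_{i∈A} d_ij ]

with *f* within-sample relative abundances and *d* cophenetic distances.
β-NTI is the z-score of the observed βMNTD against a null that shuffles
taxon labels across the phylogeny's tips. β-NTI < −2 indicates homogeneous
selection (HoS), > +2 heterogeneous selection (HeS).

**RC-bray.** Pairs without a deterministic signal (|β-NTI| ≤ 2) are split
by the Raup–Crick metric on Bray–Curtis, whose null preserves each sample's
richness and total abundance while drawing membership by metacommunity
occupancy and abundances by metacommunity relative abundance:
RC = 2·[(#null < obs + ½·#null = obs)/reps] − 1. RC > 0.95 → dispersal
limitation (DL), RC < −0.95 → homogenizing dispersal (HD), otherwise
undominated (UD).

**SparCC.** Correlations between taxa are inferred from log-ratio variances
t_ij = Var log(x_i/x_j), which are invariant to the compositional closure of
sequencing counts. Under the sparsity assumption the basis variances ω
solve Σ_{j≠i} t_ij = (p−2)ω_i + Σ_j ω_j, and
ρ_ij = (ω_i + ω_j − t_ij)/(2√(ω_i ω_j)); strongly correlated pairs are
iteratively excluded and the system re-solved.

**Network ecology.** Topology reports (average connectivity, path distance,
clustering, density, modularity), within-module degree *z* and
participation coefficient *c* with keystone categories (z > 2.5, c > 0.6
thresholds), natural connectivity λ̄ = ln[(1/N) Σ exp(λ_i)] under
betweenness-ordered node removal, and community cohesion (abundance-weighted
null-corrected correlations).

## Worked example

```python
import rhizonet as rn

cfg = rn.synth.ScenarioConfig("homogeneous_selection", n_taxa=200, n_samples=12,
                              n_groups=2, depth=10_000, seed=42)
tree = rn.synth.simulate_phylogeny(cfg.n_taxa, cfg.seed)
table, metadata = rn.synth.simulate_community(cfg, tree)

pairs = rn.assembly.pair_assembly(table, tree, n_reps=199, seed=42)
print("median beta-NTI:", round(pairs.beta_nti.median(), 2))
print(rn.assembly.assembly_summary(pairs, metadata).round(3))
```

prints

```
median beta-NTI: -1.98
       HeS    HoS   DL   HD     UD
group
g1     0.0  0.800  0.0  0.0  0.200
g2     0.0  0.333  0.0  0.0  0.667
```

The generator planted homogeneous selection — a shared Gaussian niche
filter on phylogenetically conserved traits — and the β-NTI/RC-bray stack
recovers it: the median z-score is strongly negative and HoS is the modal
process among within-group sample pairs. (A single 12-sample run is noisy;
the recovery tests pool several replicate simulations.)

The same pipeline runs from files and a config:

```bash
rhizonet simulate --scenario undominated --n-taxa 100 --n-samples 54 --out fixture/
rhizonet all --config config.yaml --seed 1 --out results/
```

where the config names the counts TSV (taxa rows × sample columns), the
Newick tree, the metadata TSV and its group column, null-model replicate
counts, and network thresholds. Every run writes a `run_log.json` with the
config hash and root seed.

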
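"""Synthetic communities with known assembly processes and correlation structure.

This module generates the three ingredients every downstream stage needs a
ground truth for:

* an ultrametric pure-birth (Yule) phylogeny,
* a phylogenetically conserved niche trait evolved by Brownian motion, and
* taxa-by-sample count tables assembled under one of five processes —
  homogeneous selection (HoS), heterogeneous selection (HeS), dispersal
  limitation (DL), homogenizing dispersal (HD), undominated drift (UD) —
  plus compositional counts with a known log-scale (basis) correlation
  matrix for correlation-network recovery tests.

Counts are taxa rows x sample columns; every column sums exactly to the
configured sequencing depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from ._rng import stream

__all__ = [
    "SCENARIOS",
    "ScenarioConfig",
    "simulate_phylogeny",
    "evolve_trait",
    "simulate_community",
    "simulate_correlated_counts",
    "planted_correlation",
]

SCENARIOS = (
    "homogeneous_selection",
    "heterogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "undominated",
)

#: default migration rate per scenario (fraction of each site's pool drawn
#: from the shared metacommunity); selection scenarios ignore it.
_DEFAULT_MIGRATION = {
    "dispersal_limitation": 0.01,
    "homogenizing_dispersal": 0.99,
    "undominated": 1.0,
    "homogeneous_selection": 1.0,
    "heterogeneous_selection": 1.0,
}


@dataclass
class ScenarioConfig:
    """Recipe for one synthetic community study.

    Parameters
    ----------
    scenario
        One of :data:`SCENARIOS`.
    n_taxa, n_samples, n_groups
        Community dimensions; samples are assigned to groups round-robin.
    depth
        Reads per sample (every sample column sums to exactly this).
    trait_sigma
        Brownian-motion rate of the niche trait (trait units^2 per unit
        branch length).
    selection_strength
        Gaussian niche-filter width parameter (dimensionless, >= 0);
        fitness of taxon i in sample s is exp(-strength * (trait_i - e_s)^2).
    migration_rate
        Fraction of each site's sampling pool taken from the shared
        metacommunity (neutral scenarios only). None picks the scenario
        default: 0.01 for dispersal limitation, 0.95 for homogenizing
        dispersal, 1.0 otherwise.
    drift_concentration
        Dirichlet concentration multiplier for per-site drifted pools;
        smaller values mean stronger compositional drift between sites.
    seed
        Root seed; all randomness derives from it via named substreams.
    """

    scenario: str
    n_taxa: int = 100
    n_samples: int = 54
    n_groups: int = 4
    depth: int = 10_000
    trait_sigma: float = 1.0
    selection_strength: float = 5.0
    migration_rate: float | None = None
    drift_concentration: float = 10.0
    seed: int = 0
    #: number of independent Brownian niche axes; >1 suppresses spurious
    #: trait convergence between unrelated lineages (a taxon must match the
    #: optimum on every axis at once to pass the filter)
    niche_dims: int = 5
    #: per-sample jitter of the environmental optimum, in trait-sd units
    env_noise_sd: float = field(default=0.05, repr=False)
    #: log-normal sigma of the metacommunity rank-abundance pool
    pool_sigma: float = field(default=2.0, repr=False)
    #: anchor-clade size bounds as fractions of the taxon pool (selection
    #: scenarios target the phylogenetically tightest clade in this range)
    clade_frac: tuple[float, float] = field(default=(0.075, 0.175), repr=False)
    #: expected fraction of the anchor clade present per sample (occupancy
    #: drift: which clade members a site receives is stochastic)
    site_occupancy: float = field(default=0.65, repr=False)
    #: relative-fitness cutoff below which a taxon cannot colonise a site
    fitness_floor: float = field(default=1e-3, repr=False)
    #: exponent damping fitness in the abundance (not occupancy) weights
    abundance_damp: float = field(default=0.15, repr=False)
    #: optional Dirichlet-multinomial overdispersion: when set, each
    #: sample's multinomial probabilities are drawn Dirichlet(this * weights)
    #: first (smaller = more overdispersed); None = plain multinomial
    overdispersion: float | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; expected one of {SCENARIOS}")
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.migration_rate is None:
            self.migration_rate = _DEFAULT_MIGRATION[self.scenario]
        if not 0.0 <= self.migration_rate <= 1.0:
            raise ValueError("migration_rate must be in [0, 1]")
        if self.selection_strength < 0:
            raise ValueError("selection_strength must be >= 0")


def simulate_phylogeny(n_taxa: int, seed: int) -> dendropy.Tree:
    """Simulate a rooted ultrametric pure-birth (Yule) tree with `n_taxa` tips.

    Lineages split at unit rate; at each event one active lineage (chosen
    uniformly) bifurcates. All extant tips end at the same age, so the tree
    is ultrametric. Tips are labeled ``t1..tn`` in birth order.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    rng = stream(seed, "yule-tree")

    taxon_namespace = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_namespace)
    # active lineages carry their birth time
    root = tree.seed_node
    active: list[tuple[dendropy.Node, float]] = [(root, 0.0)]
    t = 0.0
    while len(active) < n_taxa:
        k = len(active)
        t += rng.exponential(1.0 / k)
        idx = int(rng.integers(k))
        node, birth = active.pop(idx)
        node.edge.length = t - birth if node is not root else 0.0
        left, right = dendropy.Node(), dendropy.Node()
        node.add_child(left)
        node.add_child(right)
        active.append((left, t))
        active.append((right, t))
    # final stretch: run all tips to a common end time
    t += rng.exponential(1.0 / n_taxa)
    for i, (node, birth) in enumerate(active):
        node.edge.length = t - birth
        node.taxon = taxon_namespace.new_taxon(label=f"t{i + 1}")
    tree.is_rooted = True
    return tree


def evolve_traits(
    tree: dendropy.Tree, trait_sigma: float, seed: int, n_dims: int
) -> pd.DataFrame:
    """Evolve `n_dims` independent Brownian niche axes; tips x axes frame."""
    cols = {
        f"axis{d + 1}": evolve_trait(tree, trait_sigma, (int(seed) * 997 + 7919 * d) % 2**31)
        for d in range(n_dims)
    }
    return pd.DataFrame(cols)


def evolve_trait(tree: dendropy.Tree, trait_sigma: float, seed: int) -> pd.Series:
    """Evolve a Brownian-motion trait along `tree` from root value 0.

    Increments on a branch of length L are N(0, trait_sigma * L); a tip's
    marginal variance is trait_sigma times its root-to-tip path length.
    Returns a Series indexed by tip label.
    """
    if trait_sigma < 0:
        raise ValueError("trait_sigma must be >= 0")
    rng = stream(seed, "bm-trait")
    values: dict[int, float] = {id(tree.seed_node): 0.0}
    out: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            val = 0.0
        else:
            parent_val = values[id(node.parent_node)]
            length = node.edge.length or 0.0
            val = parent_val + rng.normal(0.0, np.sqrt(trait_sigma * length))
        values[id(node)] = val
        if node.is_leaf():
            out[node.taxon.label] = val
    return pd.Series(out, name="trait", dtype=float)


def _metacommunity_pool(n_taxa: int, rng: np.random.Generator, sigma: float = 2.0) -> np.ndarray:
    """Log-normal rank-abundance metacommunity pool (sums to 1).

    sigma = 2 gives the steep dominance/rarity profile typical of amplicon
    surveys, so rare taxa are genuinely absent from many samples at
    realistic sequencing depths.
    """
    ranks = np.exp(rng.normal(0.0, sigma, size=n_taxa))
    return ranks / ranks.sum()


def _clade_candidates(
    tree: dendropy.Tree,
    taxa: list[str],
    dist: np.ndarray,
    frac_lo: float,
    frac_hi: float,
    rng: np.random.Generator,
) -> list[tuple[float, frozenset[int]]]:
    """Score every clade in the size window by phylogenetic tightness.

    Tightness = mean nearest-neighbour cophenetic distance within the clade,
    relative to the same statistic for random tip sets of equal size
    (smaller = tighter).  Returns (score, tip index set) pairs.
    """
    idx = {t: i for i, t in enumerate(taxa)}
    n = len(taxa)

    def nn_mean(ids: np.ndarray) -> float:
        sub = dist[np.ix_(ids, ids)].copy()
        np.fill_diagonal(sub, np.inf)
        return float(sub.min(axis=1).mean())

    out = []
    for node in tree.preorder_internal_node_iter():
        tips = [leaf.taxon.label for leaf in node.leaf_iter()]
        if not (frac_lo <= len(tips) / n <= frac_hi):
            continue
        ids = np.array([idx[t] for t in tips])
        rand = np.mean(
            [nn_mean(rng.choice(n, len(ids), replace=False)) for _ in range(10)]
        )
        out.append((nn_mean(ids) / max(rand, 1e-12), frozenset(ids.tolist())))
    return out


def _pick_anchor_clades(
    tree: dendropy.Tree,
    taxa: list[str],
    config: ScenarioConfig,
    n_anchors: int,
) -> list[np.ndarray]:
    """Pick `n_anchors` disjoint, phylogenetically tight clades.

    Selection scenarios target the tightest clade(s): selection on a
    conserved niche concentrates communities on coherent lineages, and the
    tightest available clade is where that concentration is phylogenetically
    detectable.  Falls back to the clade nearest the size window when the
    window is empty (tiny trees).
    """
    from .assembly import cophenetic_matrix  # local import; no cycle at runtime

    dist = cophenetic_matrix(tree, taxa).to_numpy()
    rng = stream(config.seed, "anchor-clade-score")
    lo, hi = config.clade_frac
    cands = _clade_candidates(tree, taxa, dist, lo, hi, rng)
    if not cands:
        # tiny tree: take subtrees closest to the window midpoint
        n = len(taxa)
        target = max(2, int(round(0.5 * (lo + hi) * n)))
        idx = {t: i for i, t in enumerate(taxa)}
        sized = []
        for node in tree.preorder_internal_node_iter():
            tips = [leaf.taxon.label for leaf in node.leaf_iter()]
            if len(tips) < n:
                sized.append((abs(len(tips) - target), frozenset(idx[t] for t in tips)))
        sized.sort(key=lambda c: (c[0], sorted(c[1])))
        cands = [(1.0, s) for _, s in sized]
    ordered = sorted(cands, key=lambda c: (c[0], sorted(c[1])))
    first = ordered[0][1]
    chosen: list[frozenset[int]] = [first]
    if n_anchors > 1:
        # subsequent anchors: tight clades as phylogenetically *distant*
        # from the anchors already chosen as possible, so that contrasting
        # environments select genuinely divergent lineages
        first_ids = np.array(sorted(first))
        pool_scores = [c for c in ordered if c[0] <= max(0.5, ordered[0][0]) and not (c[1] & first)]
        if not pool_scores:
            pool_scores = [c for c in ordered[1:] if not (c[1] & first)] or ordered[1:]
        while len(chosen) < n_anchors and pool_scores:
            taken = set().union(*chosen)
            avail = [c for c in pool_scores if not (c[1] & taken)]
            if not avail:
                break
            far = max(
                avail,
                key=lambda c: dist[np.ix_(np.array(sorted(c[1])), first_ids)].mean(),
            )
            chosen.append(far[1])
    while len(chosen) < n_anchors:  # degenerate fallback: reuse the tightest
        chosen.append(chosen[-1])
    return [np.array(sorted(ids)) for ids in chosen]


def simulate_community(
    config: ScenarioConfig,
    tree: dendropy.Tree | None = None,
    traits: pd.Series | pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble a count table and metadata under `config.scenario`.

    Selection scenarios filter a shared metacommunity pool through a
    Gaussian niche filter on conserved Brownian traits.  With standardized
    trait axes z_d = (t_d - e_d)/sd_d, taxon fitness in sample s is

        w_i(s) = exp(-selection_strength * sum_d z_id(s)^2),

    the product of the per-axis Gaussian filters.  The environmental
    optimum is the mean niche position of an *anchor clade* — the
    phylogenetically tightest clade occupying `clade_frac` of the taxon
    pool (one shared anchor for homogeneous selection; two disjoint anchors
    alternating across groups for heterogeneous selection) — plus
    per-sample jitter of `env_noise_sd` trait sd.  Assembly then has a
    drift component acting on occupancy: each site receives an expected
    `site_occupancy` fraction of the anchor clade, drawn Bernoulli with
    probability increasing in fitness, and taxa below `fitness_floor`
    relative fitness cannot colonise.  Abundances among colonisers follow
    pool * fitness**abundance_damp (damped: membership, not dominance, is
    what selection controls here).

    Neutral scenarios draw each site's pool as a mixture
    (1 - m) * site-drifted pool + m * shared pool, with the drifted pool a
    Dirichlet(drift_concentration * pool) perturbation of the shared pool;
    undominated sampling is a pure multinomial from the shared pool.

    Returns ``(counts, metadata)``: counts is taxa x samples (column sums ==
    depth); metadata has one row per sample with 'group' and 'environment'
    (the first niche axis of the sample's optimum; NaN for neutral
    scenarios).
    """
    if tree is None:
        tree = simulate_phylogeny(config.n_taxa, config.seed)
    if traits is None:
        traits = evolve_traits(tree, config.trait_sigma, config.seed, config.niche_dims)
    if isinstance(traits, pd.Series):
        traits = traits.to_frame("axis1")

    tip_labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    missing = set(tip_labels) - set(traits.index)
    if missing:
        raise ValueError(f"traits missing for taxa: {sorted(missing)[:5]} ...")
    taxa = sorted(tip_labels, key=lambda s: (len(s), s))
    trait_mat = traits.loc[taxa].to_numpy(dtype=float)  # taxa x axes
    n, m = len(taxa), config.n_samples
    n_dims = trait_mat.shape[1]

    rng = stream(config.seed, f"community-{config.scenario}")
    groups = [f"g{(i % config.n_groups) + 1}" for i in range(m)]

    env = np.full(m, np.nan)
    weights = np.empty((n, m))
    if config.scenario in ("homogeneous_selection", "heterogeneous_selection"):
        # sustained selection also evens out regional abundances; the pool
        # entering selective assembly is milder than the neutral one
        pool = _metacommunity_pool(n, rng, config.pool_sigma / 2.0)
        sds = trait_mat.std(axis=0)
        sds[sds == 0] = 1.0
        n_anchors = 1 if config.scenario == "homogeneous_selection" else 2
        anchors = _pick_anchor_clades(tree, taxa, config, n_anchors)
        optima = [trait_mat[ids].mean(axis=0) for ids in anchors]
        uniq_groups = list(dict.fromkeys(groups))
        group_anchor = {g: k % n_anchors for k, g in enumerate(uniq_groups)}
        clade_size = {k: len(anchors[k]) for k in range(n_anchors)}
        for s in range(m):
            k = group_anchor[groups[s]]
            e_vec = optima[k] + rng.normal(0.0, config.env_noise_sd, size=n_dims) * sds
            env[s] = e_vec[0]
            z2 = (((trait_mat - e_vec) / sds) ** 2).sum(axis=1)
            fitness = np.exp(-config.selection_strength * z2)
            if config.selection_strength == 0:
                weights[:, s] = pool
                continue
            frel = fitness / fitness.max()
            # occupancy drift: which clade members colonise this site
            base = np.where(frel >= config.fitness_floor, frel**0.1, 0.0)
            occ = np.minimum(
                0.92, config.site_occupancy * clade_size[k] / max(base.sum(), 1e-12) * base
            )
            present = rng.random(n) < occ
            if present.sum() < 2:
                present[np.argsort(-fitness)[:2]] = True
            w = np.where(present, pool * fitness**config.abundance_damp, 0.0)
            weights[:, s] = w / w.sum()
    else:
        pool = _metacommunity_pool(n, rng, config.pool_sigma)
        mrate = config.migration_rate
        for s in range(m):
            if config.scenario == "undominated":
                # neutral stochastic colonisation: which taxa reach a site
                # is random (probability rising with regional abundance),
                # abundances among colonisers follow the regional pool — no
                # process dominates, membership turnover is pure chance
                q = 0.9 * (pool / pool.max()) ** 0.25
                present = rng.random(n) < q
                if present.sum() < 2:
                    present[np.argsort(-pool)[:2]] = True
                w = np.where(present, pool, 0.0)
                weights[:, s] = w / w.sum()
            elif mrate >= 1.0:
                weights[:, s] = pool
            else:
                alpha = np.maximum(config.drift_concentration * pool, 1e-9)
                drifted = rng.dirichlet(alpha)
                weights[:, s] = (1.0 - mrate) * drifted + mrate * pool

    if config.overdispersion is not None:
        for s in range(m):
            alpha = np.maximum(config.overdispersion * weights[:, s], 1e-12)
            weights[:, s] = rng.dirichlet(alpha)
    counts = np.column_stack(
        [rng.multinomial(config.depth, weights[:, s]) for s in range(m)]
    )
    sample_ids = [f"s{i + 1}" for i in range(m)]
    table = pd.DataFrame(counts, index=taxa, columns=sample_ids, dtype=np.int64)
    metadata = pd.DataFrame(
        {"group": groups, "environment": env, "location": ["loc1"] * m},
        index=pd.Index(sample_ids, name="sample"),
    )
    return table, metadata


def simulate_correlated_counts(
    n_taxa: int,
    n_samples: int,
    basis_corr: np.ndarray,
    depth: int,
    seed: int,
    log_sigma: float = 1.0,
) -> pd.DataFrame:
    """Compositional counts whose log-scale basis has correlation `basis_corr`.

    Basis abundances are exp of a multivariate normal with covariance
    log_sigma^2 * basis_corr and taxon-specific means (log-normal rank
    abundance); each sample's basis is closed to fractions and multinomially
    sampled to `depth`.  `basis_corr` is the ground truth for correlation-
    recovery scoring.
    """
    basis_corr = np.asarray(basis_corr, dtype=float)
    if basis_corr.shape != (n_taxa, n_taxa):
        raise ValueError("basis_corr must be n_taxa x n_taxa")
    if not np.allclose(basis_corr, basis_corr.T):
        raise ValueError("basis_corr must be symmetric")
    if not np.allclose(np.diag(basis_corr), 1.0):
        raise ValueError("basis_corr must have unit diagonal")
    eigmin = np.linalg.eigvalsh(basis_corr).min()
    if eigmin <= 1e-10:
        raise ValueError(f"basis_corr must be positive definite (min eigenvalue {eigmin:.2e})")

    rng = stream(seed, "correlated-counts")
    mu = rng.normal(0.0, 1.0, size=n_taxa)
    chol = np.linalg.cholesky(basis_corr)
    z = mu + log_sigma * (rng.standard_normal((n_samples, n_taxa)) @ chol.T)
    basis = np.exp(z)
    fractions = basis / basis.sum(axis=1, keepdims=True)
    counts = np.stack([rng.multinomial(depth, f) for f in fractions], axis=1)
    return pd.DataFrame(
        counts,
        index=[f"t{i + 1}" for i in range(n_taxa)],
        columns=[f"s{j + 1}" for j in range(n_samples)],
        dtype=np.int64,
    )


def planted_correlation(n_taxa: int, pairs: dict[tuple[int, int], float]) -> np.ndarray:
    """Identity correlation matrix with specified off-diagonal pairs planted.

    `pairs` maps (i, j) index tuples to correlation values.  Raises if the
    result is not positive definite.
    """
    corr = np.eye(n_taxa)
    for (i, j), rho in pairs.items():
        corr[i, j] = corr[j, i] = rho
    if np.linalg.eigvalsh(corr).min() <= 1e-10:
        raise ValueError("planted correlations yield a non-positive-definite matrix")
    return corr
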
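"""Community assembly inference from phylogenetic and taxonomic null models.

The pipeline follows the two-step partition of ecological assembly
processes.  For every sample pair:

1. beta-NTI, the z-score of the observed abundance-weighted beta mean
   nearest taxon distance (beta-MNTD) against a null that shuffles taxon
   labels across the phylogeny's tips, detects deterministic assembly:
   beta-NTI > +2 -> heterogeneous selection (HeS), beta-NTI < -2 ->
   homogeneous selection (HoS).
2. Pairs without a deterministic signal (|beta-NTI| <= 2) are split by the
   Bray-Curtis-based Raup-Crick metric (RC-bray), whose null preserves each
   sample's richness and total abundance while drawing taxon identities and
   abundances from the metacommunity: RC > +0.95 -> dispersal limitation
   (DL), RC < -0.95 -> homogenizing dispersal (HD), otherwise undominated
   (UD).

The module also provides the upstream phylogenetic-signal check (niche
values + Mantel correlogram), the top-abundance taxon filter, per-group
process summaries, and the normalized stochasticity ratio (NST).
"""

from __future__ import annotations

import warnings
from itertools import combinations

import dendropy
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from ._rng import stream
from .diversity import mantel as _mantel_test

__all__ = [
    "filter_top_taxa",
    "niche_values",
    "mantel_correlogram",
    "cophenetic_matrix",
    "beta_mntd",
    "beta_nti",
    "rc_bray",
    "classify_processes",
    "pair_assembly",
    "assembly_summary",
    "nst",
    "PROCESSES",
]

PROCESSES = ("HeS", "HoS", "DL", "HD", "UD")


# ---------------------------------------------------------------------------
# pre-filters and phylogenetic signal


def filter_top_taxa(table: pd.DataFrame, n_top: int) -> pd.DataFrame:
    """Retain the `n_top` taxa with highest total relative abundance.

    Ties are broken by taxon id (lexicographic), so the result is
    deterministic.  Requesting more taxa than available returns the full
    table with a warning.
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    if n_top >= table.shape[0]:
        if n_top > table.shape[0]:
            warnings.warn(
                f"n_top={n_top} exceeds {table.shape[0]} available taxa; all retained",
                stacklevel=2,
            )
        return table.copy()
    totals = table.sum(axis=1)
    order = sorted(table.index, key=lambda t: (-totals[t], t))
    selected = set(order[:n_top])
    return table.loc[[t for t in table.index if t in selected]]


def niche_values(table: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Abundance-weighted mean environmental value per taxon.

    niche[i, v] = sum_s a_is e_vs / sum_s a_is over numeric metadata columns.
    Taxa with zero total abundance are excluded.
    """
    env = metadata.select_dtypes(include=[np.number])
    missing = set(table.columns) - set(env.index)
    if missing:
        raise ValueError(f"metadata missing samples: {sorted(missing)[:5]}")
    env = env.loc[list(table.columns)]
    a = table.to_numpy(dtype=float)
    totals = a.sum(axis=1)
    keep = totals > 0
    niche = (a[keep] @ env.to_numpy()) / totals[keep, None]
    return pd.DataFrame(niche, index=table.index[keep], columns=env.columns)


def mantel_correlogram(
    phylo_dist: pd.DataFrame,
    niche_dist: pd.DataFrame,
    n_classes: int = 10,
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Mantel correlogram: per distance class, Mantel r and permutation p.

    Phylogenetic distances are cut into `n_classes` equal-width classes; for
    each class the model matrix is the within-class indicator, and the Mantel
    statistic is the Pearson correlation between that indicator and the
    niche distance over all pairs (sign flipped so that positive r means
    "pairs in this class are more similar than average", the correlogram
    convention).  p-values carry a progressive Holm-style correction: the
    p of class k is adjusted by factor k (classes tested from shortest
    outward).  Empty classes are reported with NaN.
    """
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if list(phylo_dist.index) != list(niche_dist.index):
        niche_dist = niche_dist.loc[phylo_dist.index, phylo_dist.index]
    pd_mat = phylo_dist.to_numpy(dtype=float)
    nd_mat = niche_dist.to_numpy(dtype=float)
    n = pd_mat.shape[0]
    iu = np.triu_indices(n, 1)
    pvec, nvec = pd_mat[iu], nd_mat[iu]
    edges = np.linspace(pvec.min(), pvec.max(), n_classes + 1)
    edges[-1] += 1e-12
    rng = stream(seed, "mantel-correlogram")

    rows = []
    for k in range(n_classes):
        in_class = (pvec >= edges[k]) & (pvec < edges[k + 1])
        midpoint = 0.5 * (edges[k] + edges[k + 1])
        n_pairs = int(in_class.sum())
        if n_pairs == 0 or n_pairs == len(pvec):
            rows.append((midpoint, n_pairs, np.nan, np.nan, np.nan))
            continue
        # negative correlation of indicator with distance => similarity within class
        ind = in_class.astype(float)
        r_obs = -float(np.corrcoef(ind, nvec)[0, 1])
        count_ge = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            permuted = nd_mat[np.ix_(perm, perm)][iu]
            if -float(np.corrcoef(ind, permuted)[0, 1]) >= r_obs:
                count_ge += 1
        p_raw = (count_ge + 1) / (n_perm + 1)
        rows.append((midpoint, n_pairs, r_obs, p_raw, np.nan))
    out = pd.DataFrame(
        rows, columns=["class_midpoint", "n_pairs", "mantel_r", "p_value", "p_corrected"]
    )
    # progressive correction: class k (1-based among testable classes) gets factor k
    factor = 0
    for i in out.index:
        if np.isfinite(out.at[i, "p_value"]):
            factor += 1
            out.at[i, "p_corrected"] = min(1.0, out.at[i, "p_value"] * factor)
    return out


# ---------------------------------------------------------------------------
# beta-MNTD / beta-NTI


def cophenetic_matrix(tree: dendropy.Tree, taxa: list[str] | None = None) -> pd.DataFrame:
    """Pairwise patristic (cophenetic) distances between tips, as a DataFrame.

    If `taxa` is given, the matrix is restricted to (and ordered by) those
    labels; tips absent from the tree raise a coverage error listing them.
    """
    pdm = tree.phylogenetic_distance_matrix()
    labels = [t.label for t in tree.taxon_namespace]
    if taxa is None:
        taxa = labels
    missing = sorted(set(taxa) - set(labels))
    if missing:
        raise ValueError(f"taxa missing from tree: {missing[:10]}")
    lookup = {t.label: t for t in tree.taxon_namespace}
    n = len(taxa)
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        d[i, j] = d[j, i] = pdm.patristic_distance(lookup[taxa[i]], lookup[taxa[j]])
    return pd.DataFrame(d, index=taxa, columns=taxa)


def _beta_mntd_core(freq: np.ndarray, present: list[np.ndarray], d: np.ndarray) -> np.ndarray:
    """beta-MNTD for all sample pairs given relative abundances and distances.

    freq: taxa x samples relative abundances; present: per-sample index
    arrays of taxa with freq > 0; d: taxa x taxa cophenetic distances.
    Vectorised via per-sample "distance to nearest member" columns:
    m_t[i] = min_{j in sample t} d[i, j], then
    betaMNTD(s, t) = 0.5 * (f_s . m_t + f_t . m_s).
    """
    n_taxa, n_samples = freq.shape
    nearest = np.empty((n_taxa, n_samples))
    for t in range(n_samples):
        nearest[:, t] = d[:, present[t]].min(axis=1)
    cross = freq.T @ nearest  # cross[s, t] = f_s . m_t
    return 0.5 * (cross + cross.T)


def _prep_freq(table: pd.DataFrame, weighted: bool) -> tuple[np.ndarray, list[np.ndarray]]:
    counts = table.to_numpy(dtype=float)
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("all-zero sample(s) present")
    freq = (counts > 0).astype(float) if not weighted else counts
    freq = freq / freq.sum(axis=0, keepdims=True)
    present = [np.flatnonzero(counts[:, s] > 0) for s in range(counts.shape[1])]
    return freq, present


def beta_mntd(
    table: pd.DataFrame,
    tree: dendropy.Tree,
    weighted: bool = True,
) -> pd.DataFrame:
    """Abundance-weighted beta mean nearest taxon distance between samples.

    betaMNTD(A, B) = 0.5 * [ sum_{i in A} f_iA min_{j in B} d_ij
                           + sum_{j in B} f_jB min_{i in A} d_ij ],
    with f relative abundances within each sample and d cophenetic
    distances.  Shared taxa contribute distance 0.
    """
    d = cophenetic_matrix(tree, list(table.index)).to_numpy()
    freq, present = _prep_freq(table, weighted)
    out = _beta_mntd_core(freq, present, d)
    np.fill_diagonal(out, 0.0)
    return pd.DataFrame(out, index=table.columns, columns=table.columns)


def beta_nti(
    table: pd.DataFrame,
    tree: dendropy.Tree,
    n_reps: int = 999,
    seed: int = 0,
    weighted: bool = True,
) -> pd.DataFrame:
    """beta-NTI z-scores: (obs betaMNTD - null mean) / null sd per pair.

    The null shuffles taxon labels across the tips present in the table
    (equivalently: jointly permutes rows+columns of the cophenetic matrix),
    preserving abundances while randomizing phylogenetic relationships.
    Pairs with null sd 0 (e.g. a star phylogeny) are NaN with a warning.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    d = cophenetic_matrix(tree, list(table.index)).to_numpy()
    freq, present = _prep_freq(table, weighted)
    obs = _beta_mntd_core(freq, present, d)
    rng = stream(seed, "beta-nti-null")
    n_taxa = d.shape[0]
    nulls = np.empty((n_reps,) + obs.shape)
    for r in range(n_reps):
        perm = rng.permutation(n_taxa)
        nulls[r] = _beta_mntd_core(freq, present, d[np.ix_(perm, perm)])
    mean_null = nulls.mean(axis=0)
    sd_null = nulls.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (obs - mean_null) / sd_null
    z[sd_null <= 1e-12] = np.nan
    np.fill_diagonal(z, 0.0)
    n_undef = int(np.isnan(z[np.triu_indices_from(z, 1)]).sum())
    if n_undef:
        warnings.warn(f"{n_undef} pair(s) have degenerate null (sd=0); beta-NTI undefined", stacklevel=2)
    return pd.DataFrame(z, index=table.columns, columns=table.columns)


# ---------------------------------------------------------------------------
# RC-bray and NST


def _null_assemblage(
    richness: int,
    depth: int,
    occupancy_p: np.ndarray,
    abundance_p: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """One null sample preserving richness and total abundance.

    Taxon identities are drawn (without replacement) with probability
    proportional to metacommunity occupancy until `richness` taxa are
    chosen; each chosen taxon gets one individual, and the remaining
    depth - richness individuals are distributed multinomially with
    probability proportional to metacommunity relative abundance.
    """
    n_taxa = len(occupancy_p)
    chosen = rng.choice(n_taxa, size=richness, replace=False, p=occupancy_p)
    counts = np.zeros(n_taxa, dtype=np.int64)
    counts[chosen] = 1
    remaining = depth - richness
    if remaining > 0:
        p = abundance_p[chosen]
        counts[chosen] += rng.multinomial(remaining, p / p.sum())
    return counts


def _null_dissimilarities(
    table: pd.DataFrame,
    n_reps: int,
    rng: np.random.Generator,
    metric: str = "braycurtis",
) -> tuple[np.ndarray, np.ndarray]:
    """Observed and null dissimilarity matrices under the RC null model.

    Returns (obs [n x n], nulls [reps x n x n]).
    """
    counts = table.to_numpy(dtype=np.int64)
    n_taxa, n_samples = counts.shape
    occupancy = (counts > 0).sum(axis=1).astype(float)
    if (occupancy > 0).sum() < 2:
        raise ValueError("degenerate metacommunity: fewer than 2 occurring taxa")
    occupancy_p = occupancy / occupancy.sum()
    abundance = counts.sum(axis=1).astype(float)
    abundance_p = abundance / abundance.sum()
    richness = (counts > 0).sum(axis=0)
    depths = counts.sum(axis=0)

    if metric == "braycurtis":
        obs = squareform(pdist(counts.T.astype(float), metric="braycurtis"))
    elif metric == "jaccard":
        obs = squareform(pdist((counts > 0).T, metric="jaccard"))
    else:
        raise ValueError("metric must be 'braycurtis' or 'jaccard'")

    nulls = np.empty((n_reps, n_samples, n_samples))
    for r in range(n_reps):
        null_tab = np.column_stack(
            [
                _null_assemblage(int(richness[s]), int(depths[s]), occupancy_p, abundance_p, rng)
                for s in range(n_samples)
            ]
        )
        if metric == "braycurtis":
            nulls[r] = squareform(pdist(null_tab.T.astype(float), metric="braycurtis"))
        else:
            nulls[r] = squareform(pdist((null_tab > 0).T, metric="jaccard"))
    return obs, nulls


def rc_bray(table: pd.DataFrame, n_reps: int = 999, seed: int = 0) -> pd.DataFrame:
    """Bray-Curtis-based Raup-Crick metric per sample pair, in [-1, 1].

    RC = 2 * [ (#null < obs + 0.5 * #null == obs) / n_reps ] - 1, where the
    null preserves each sample's richness and total abundance (taxa drawn by
    metacommunity occupancy, individuals by metacommunity abundance).
    RC near +1: observed pair more dissimilar than expected by chance
    (dispersal limitation + drift); near -1: less dissimilar (homogenizing
    dispersal).
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    rng = stream(seed, "rc-bray-null")
    obs, nulls = _null_dissimilarities(table, n_reps, rng, metric="braycurtis")
    less = (nulls < obs - 1e-12).sum(axis=0)
    equal = (np.abs(nulls - obs) <= 1e-12).sum(axis=0)
    rc = 2.0 * ((less + 0.5 * equal) / n_reps) - 1.0
    np.fill_diagonal(rc, 0.0)
    return pd.DataFrame(rc, index=table.columns, columns=table.columns)


def classify_processes(
    beta_nti_mat: pd.DataFrame,
    rc_bray_mat: pd.DataFrame,
    nti_threshold: float = 2.0,
    rc_threshold: float = 0.95,
) -> pd.DataFrame:
    """Two-step assembly-process label for every sample pair.

    betaNTI > +t -> HeS; betaNTI < -t -> HoS; otherwise RC > rc_t -> DL,
    RC < -rc_t -> HD, else UD.  The deterministic (betaNTI) signal takes
    precedence.  Pairs with undefined betaNTI are labeled 'missing'.

    Returns a long-form table: sample_i, sample_j, beta_nti, rc_bray,
    process — one row per unordered pair.
    """
    if list(beta_nti_mat.index) != list(rc_bray_mat.index):
        rc_bray_mat = rc_bray_mat.loc[beta_nti_mat.index, beta_nti_mat.index]
    ids = list(beta_nti_mat.index)
    rows = []
    for i, j in combinations(range(len(ids)), 2):
        z = beta_nti_mat.iat[i, j]
        rc = rc_bray_mat.iat[i, j]
        if not np.isfinite(z):
            proc = "missing"
        elif z > nti_threshold:
            proc = "HeS"
        elif z < -nti_threshold:
            proc = "HoS"
        elif rc > rc_threshold:
            proc = "DL"
        elif rc < -rc_threshold:
            proc = "HD"
        else:
            proc = "UD"
        rows.append((ids[i], ids[j], z, rc, proc))
    return pd.DataFrame(rows, columns=["sample_i", "sample_j", "beta_nti", "rc_bray", "process"])


def pair_assembly(
    table: pd.DataFrame,
    tree: dendropy.Tree,
    n_reps: int = 999,
    seed: int = 0,
    nti_threshold: float = 2.0,
    rc_threshold: float = 0.95,
) -> pd.DataFrame:
    """Convenience wrapper: beta-NTI + RC-bray + process labels in one call."""
    z = beta_nti(table, tree, n_reps=n_reps, seed=seed)
    rc = rc_bray(table, n_reps=n_reps, seed=seed)
    return classify_processes(z, rc, nti_threshold, rc_threshold)


def assembly_summary(
    pairs: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
    scope: str = "within",
) -> pd.DataFrame:
    """Per-group fraction of sample pairs assigned to each process.

    scope='within' keeps only pairs whose two samples share a group (the
    group-comparison convention); scope='all' pools every pair under a
    single 'all' label.  Fractions sum to 1 per row.  Groups contributing
    fewer than one pair are omitted with a warning.
    """
    if scope not in ("within", "all"):
        raise ValueError("scope must be 'within' or 'all'")
    df = pairs[pairs["process"] != "missing"].copy()
    if scope == "all" or metadata is None:
        df["group"] = "all"
    else:
        gmap = metadata["group"]
        gi = df["sample_i"].map(gmap)
        gj = df["sample_j"].map(gmap)
        df["group"] = gi.where(gi == gj)
        dropped_groups = set(gmap.unique()) - set(df["group"].dropna().unique())
        if dropped_groups:
            warnings.warn(
                f"group(s) without within-group pairs omitted: {sorted(dropped_groups)}",
                stacklevel=2,
            )
        df = df.dropna(subset=["group"])
    frac = (
        df.groupby("group")["process"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .reindex(columns=list(PROCESSES), fill_value=0.0)
    )
    frac.columns.name = None
    return frac


def nst(
    table: pd.DataFrame,
    groups,
    n_reps: int = 999,
    metric: str = "bray-curtis",
    seed: int = 0,
) -> pd.Series:
    """Normalized stochasticity ratio per group, on a percentage scale.

    For every within-group sample pair, D is the observed dissimilarity and
    E the mean dissimilarity under the richness/abundance-preserving null
    (the same null as RC-bray).  The per-pair stochasticity ratio is
    ST = (1 - E) / (1 - D) when D <= E, else E / D: ST = 1 when the
    observation matches the null expectation, and shrinks toward 0 as
    determinism pushes D away from E in either direction.  The group NST is
    the mean ST rescaled to percent; 100% = fully stochastic, and 50% marks
    the conventional stochastic/deterministic boundary.  Non-finite pairs
    (e.g. D = 1 with E < 1 on the similarity branch are avoided by branch
    selection; a residual 0/0) are skipped with a warning.
    """
    metric_key = {"bray-curtis": "braycurtis", "jaccard": "jaccard"}.get(metric)
    if metric_key is None:
        raise ValueError("metric must be 'bray-curtis' or 'jaccard'")
    labels = pd.Series(groups, index=table.columns) if not isinstance(groups, pd.Series) else groups
    out = {}
    for g in sorted(labels.unique()):
        cols = list(labels.index[labels == g])
        if len(cols) < 2:
            warnings.warn(f"group {g!r} has < 2 samples; skipped", stacklevel=2)
            continue
        sub = table[cols]
        sub = sub.loc[sub.sum(axis=1) > 0]
        rng = stream(seed, f"nst-null-{g}")
        obs, nulls = _null_dissimilarities(sub, n_reps, rng, metric=metric_key)
        e_null = nulls.mean(axis=0)
        iu = np.triu_indices(len(cols), 1)
        d_vec, e_vec = obs[iu], e_null[iu]
        with np.errstate(divide="ignore", invalid="ignore"):
            st = np.where(d_vec <= e_vec, (1.0 - e_vec) / (1.0 - d_vec), e_vec / d_vec)
        finite = np.isfinite(st)
        if not finite.all():
            warnings.warn(f"group {g!r}: {int((~finite).sum())} non-finite pair(s) skipped", stacklevel=2)
        out[g] = 100.0 * float(np.clip(st[finite], 0.0, 1.0).mean())
    return pd.Series(out, name="nst_percent")
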
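"""Alpha/beta diversity, rarefaction, permutation tests, and group taxon sets.

Conventions: count tables are taxa rows x sample columns (non-negative
integers); Shannon entropy is in nats; Simpson is Gini-Simpson (1 - sum p^2);
Chao1 is the classic estimator S_obs + F1^2 / (2 F2).  Distance matrices are
returned as square symmetric DataFrames indexed by sample id.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from ._rng import stream

__all__ = [
    "rarefy",
    "alpha_diversity",
    "bray_curtis",
    "jaccard",
    "permanova",
    "mantel",
    "group_taxon_sets",
]


def rarefy(
    table: pd.DataFrame,
    depth: int,
    seed: int,
    drop_empty_taxa: bool = True,
) -> pd.DataFrame:
    """Subsample every sample to `depth` reads without replacement.

    Samples with fewer than `depth` total reads are excluded with a warning.
    Taxa left with all-zero rows are dropped by default.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = stream(seed, "rarefaction")
    totals = table.sum(axis=0)
    keep = totals[totals >= depth].index
    shallow = sorted(set(table.columns) - set(keep))
    if shallow:
        warnings.warn(
            f"{len(shallow)} sample(s) shallower than depth {depth} excluded: {shallow[:5]}",
            stacklevel=2,
        )
    if len(keep) == 0:
        raise ValueError(f"no sample has >= {depth} reads")
    out = {}
    for s in keep:
        col = table[s].to_numpy(dtype=np.int64)
        out[s] = rng.multivariate_hypergeometric(col, depth, method="marginals")
    rare = pd.DataFrame(out, index=table.index, dtype=np.int64)
    if drop_empty_taxa:
        rare = rare.loc[rare.sum(axis=1) > 0]
    return rare


def alpha_diversity(table: pd.DataFrame, base: float | None = None) -> pd.DataFrame:
    """Per-sample Shannon, Simpson (1 - sum p^2), Chao1, observed taxa.

    Shannon is in nats by default; pass `base` (e.g. 2) for other units.
    Chao1 = S_obs + F1^2/(2 F2), or S_obs + F1(F1-1)/2 when F2 = 0 (F1/F2 =
    number of singleton/doubleton taxa).  All-zero samples yield NaN rows.
    """
    log_scale = 1.0 if base is None else np.log(base)
    records = {}
    for s in table.columns:
        x = table[s].to_numpy(dtype=float)
        total = x.sum()
        if total == 0:
            records[s] = dict.fromkeys(("shannon", "simpson", "chao1", "observed"), np.nan)
            continue
        p = x[x > 0] / total
        obs = int((x > 0).sum())
        f1 = int((x == 1).sum())
        f2 = int((x == 2).sum())
        chao1 = obs + (f1 * f1 / (2 * f2) if f2 > 0 else f1 * (f1 - 1) / 2)
        records[s] = {
            "shannon": float(-(p * np.log(p)).sum() / log_scale),
            "simpson": float(1.0 - (p * p).sum()),
            "chao1": float(chao1),
            "observed": obs,
        }
    return pd.DataFrame.from_dict(records, orient="index").loc[list(table.columns)]


def _check_nonempty_samples(table: pd.DataFrame) -> None:
    empty = table.columns[table.sum(axis=0) == 0]
    if len(empty):
        raise ValueError(f"all-zero sample(s) make dissimilarity undefined: {list(empty[:5])}")


def bray_curtis(table: pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis dissimilarity, BC(x,y) = sum|x-y| / sum(x+y)."""
    if table.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    _check_nonempty_samples(table)
    d = squareform(pdist(table.to_numpy(dtype=float).T, metric="braycurtis"))
    return pd.DataFrame(d, index=table.columns, columns=table.columns)


def jaccard(table: pd.DataFrame) -> pd.DataFrame:
    """Jaccard dissimilarity on presence/absence, 1 - |A&B| / |A|B|."""
    if table.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    _check_nonempty_samples(table)
    presence = (table.to_numpy() > 0).T
    d = squareform(pdist(presence, metric="jaccard"))
    return pd.DataFrame(d, index=table.columns, columns=table.columns)


def _as_square(dist: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, list]:
    if isinstance(dist, pd.DataFrame):
        return dist.to_numpy(dtype=float), list(dist.index)
    arr = np.asarray(dist, dtype=float)
    return arr, list(range(arr.shape[0]))


def permanova(
    dist: pd.DataFrame | np.ndarray,
    groups,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """One-way PERMANOVA pseudo-F and permutation p-value.

    Anderson's formulation on squared dissimilarities: SS_total =
    sum_{i<j} d_ij^2 / n, SS_within = sum over groups of within-group
    squared distances / group size, F = (SS_among/(a-1)) / (SS_within/(n-a)).
    p = (#{F_perm >= F_obs} + 1) / (n_perm + 1) under label permutation.
    """
    d, ids = _as_square(dist)
    labels = np.asarray(pd.Series(groups).loc[ids] if isinstance(groups, pd.Series) else groups)
    if len(labels) != d.shape[0]:
        raise ValueError("groups length must match distance matrix")
    uniq, inv = np.unique(labels, return_inverse=True)
    counts = np.bincount(inv)
    if len(uniq) < 2:
        raise ValueError("need >= 2 groups")
    if counts.min() < 2:
        raise ValueError("every group needs >= 2 samples")
    n, a = d.shape[0], len(uniq)
    d2 = d**2
    ss_total = d2[np.triu_indices(n, 1)].sum() / n

    def pseudo_f(perm_inv: np.ndarray) -> float:
        ss_within = 0.0
        for g in range(a):
            idx = np.flatnonzero(perm_inv == g)
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub.sum() / (2 * len(idx))
        ss_among = ss_total - ss_within
        return (ss_among / (a - 1)) / (ss_within / (n - a))

    f_obs = pseudo_f(inv)
    rng = stream(seed, "permanova")
    count_ge = 0
    for _ in range(n_perm):
        if pseudo_f(rng.permutation(inv)) >= f_obs:
            count_ge += 1
    p = (count_ge + 1) / (n_perm + 1)
    return float(f_obs), float(p)


def mantel(
    dist_a: pd.DataFrame | np.ndarray,
    dist_b: pd.DataFrame | np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Mantel test: Pearson r between lower triangles, permutation p.

    The permutation null shuffles rows/columns of the second matrix jointly;
    p is one-sided on r >= r_obs (the ecological convention for distance
    association).  r is invariant to monotone linear rescaling of either
    matrix.
    """
    a, ids_a = _as_square(dist_a)
    b, ids_b = _as_square(dist_b)
    if a.shape != b.shape:
        raise ValueError("distance matrices must have identical shape")
    if isinstance(dist_a, pd.DataFrame) and isinstance(dist_b, pd.DataFrame):
        if list(dist_a.index) != list(dist_b.index):
            b = dist_b.loc[ids_a, ids_a].to_numpy(dtype=float)
    n = a.shape[0]
    iu = np.triu_indices(n, 1)
    va = a[iu]

    def corr(mat_b: np.ndarray) -> float:
        return float(np.corrcoef(va, mat_b[iu])[0, 1])

    r_obs = corr(b)
    rng = stream(seed, "mantel")
    count_ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if corr(b[np.ix_(perm, perm)]) >= r_obs:
            count_ge += 1
    p = (count_ge + 1) / (n_perm + 1)
    return r_obs, float(p)


def group_taxon_sets(table: pd.DataFrame, groups) -> dict[tuple[str, ...], int]:
    """Venn-style partition of taxa by the set of groups they occur in.

    A taxon is "present" in a group if it has count > 0 in at least one of
    the group's samples.  Returns counts for all 2^k - 1 non-empty group
    combinations (sorted tuples of group labels); taxa absent everywhere are
    not counted.
    """
    labels = pd.Series(groups, index=table.columns) if not isinstance(groups, pd.Series) else groups
    uniq = sorted(labels.unique())
    presence = {}
    for g in uniq:
        cols = labels.index[labels == g]
        if len(cols) == 0:
            raise ValueError(f"group {g!r} has no samples")
        presence[g] = table[cols].sum(axis=1) > 0
    out: dict[tuple[str, ...], int] = {}
    for k in range(1, len(uniq) + 1):
        for combo in combinations(uniq, k):
            mask = np.ones(len(table.index), dtype=bool)
            for g in uniq:
                in_combo = g in combo
                mask &= presence[g].to_numpy() == in_combo
            out[combo] = int(mask.sum())
    return out
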
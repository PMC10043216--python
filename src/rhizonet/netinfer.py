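"""SparCC correlation inference and signed co-occurrence network construction.

Sequencing counts are compositional: closure to a fixed depth induces
spurious negative correlation between relative abundances.  SparCC works
around this by modelling log-ratio variances t_ij = Var[log(x_i / x_j)]:
with basis (absolute) variances w_i and basis correlations rho_ij,

    t_ij = w_i + w_j - 2 rho_ij sqrt(w_i w_j).

Under the sparsity assumption (each taxon's correlations approximately sum
to zero), summing t_ij over partners gives a linear system for the basis
variances, and rho follows from the identity above.  Strongly correlated
pairs violate sparsity, so the strongest pair is iteratively excluded from
the system and the variances re-solved.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd

from ._rng import stream

__all__ = [
    "prevalence_filter",
    "sparcc_correlations",
    "sparcc_pvalues",
    "build_network",
]


def prevalence_filter(table: pd.DataFrame, min_fraction: float) -> pd.DataFrame:
    """Keep taxa present (count > 0) in strictly more than `min_fraction` of samples."""
    if not 0 < min_fraction < 1:
        raise ValueError("min_fraction must be in (0, 1)")
    prevalence = (table > 0).mean(axis=1)
    keep = prevalence > min_fraction
    if not keep.any():
        raise ValueError(f"no taxon exceeds prevalence {min_fraction}")
    return table.loc[keep]


def _log_fractions(counts: np.ndarray, rng: np.random.Generator | None, n_inner_iter: int) -> np.ndarray:
    """log relative abundances, pseudocount-1 point estimate or Dirichlet average.

    Returns an array (reps, samples, taxa) of log fractions; reps == 1 for
    the deterministic default.
    """
    if rng is None:
        frac = (counts + 1.0) / (counts + 1.0).sum(axis=0, keepdims=True)
        return np.log(frac.T)[None]
    reps = np.empty((n_inner_iter, counts.shape[1], counts.shape[0]))
    for r in range(n_inner_iter):
        draws = np.stack([rng.dirichlet(counts[:, s] + 1.0) for s in range(counts.shape[1])])
        reps[r] = np.log(draws)
    return reps


def _solve_basis_variances(t_mat: np.ndarray, included: np.ndarray) -> np.ndarray:
    """Solve the sparsity-assumption linear system for basis variances.

    For each taxon i with partner set S_i (pairs not excluded):
        sum_{j in S_i} t_ij = |S_i| * w_i + sum_{j in S_i} w_j.
    """
    a = included.astype(float)
    np.fill_diagonal(a, 0.0)
    diag = a.sum(axis=1)
    system = a.copy()
    system[np.diag_indices_from(system)] = diag
    rhs = (t_mat * a).sum(axis=1)
    return np.linalg.solve(system, rhs)


def sparcc_correlations(
    table: pd.DataFrame,
    n_inner_iter: int = 20,
    n_exclusion_rounds: int = 10,
    seed: int | None = None,
    exclusion_threshold: float = 0.1,
    dirichlet_average: bool = False,
) -> pd.DataFrame:
    """Infer basis correlations from compositional counts (SparCC).

    Parameters
    ----------
    table
        taxa x samples counts; needs >= 4 taxa and >= 5 samples.
    n_inner_iter
        Number of Dirichlet draws averaged when `dirichlet_average` is on;
        ignored for the deterministic pseudocount-1 default.
    n_exclusion_rounds
        Maximum strongest-pair exclusions when refining the sparsity system.
    exclusion_threshold
        Stop excluding once the strongest remaining |rho| falls to or below
        this value.
    dirichlet_average
        Use the stochastic fraction estimate (requires `seed`).

    Returns the symmetric correlation matrix with unit diagonal, off-
    diagonals clamped to [-1, 1].  Taxa whose solved basis variance turns
    negative get NaN correlations with a warning.
    """
    if table.shape[0] < 4:
        raise ValueError("SparCC needs >= 4 taxa")
    if table.shape[1] < 5:
        raise ValueError("SparCC needs >= 5 samples")
    counts = table.to_numpy(dtype=float)
    rng = stream(seed, "sparcc-dirichlet") if (dirichlet_average and seed is not None) else None
    if dirichlet_average and rng is None:
        raise ValueError("dirichlet_average requires a seed")
    log_frac = _log_fractions(counts, rng, n_inner_iter)

    p = counts.shape[0]
    # variation matrix averaged over fraction draws
    t_mat = np.zeros((p, p))
    for lf in log_frac:
        diff = lf[:, :, None] - lf[:, None, :]
        t_mat += diff.var(axis=0, ddof=1)
    t_mat /= log_frac.shape[0]

    included = ~np.eye(p, dtype=bool)
    rho = None
    for _ in range(n_exclusion_rounds + 1):
        w = _solve_basis_variances(t_mat, included)
        bad = w <= 0
        w_safe = np.where(bad, np.nan, w)
        denom = 2.0 * np.sqrt(np.outer(w_safe, w_safe))
        with np.errstate(invalid="ignore"):
            rho = (w_safe[:, None] + w_safe[None, :] - t_mat) / denom
        rho = np.clip(rho, -1.0, 1.0)
        np.fill_diagonal(rho, 1.0)
        # candidate pairs still in the system
        cand = np.where(included, np.abs(rho), 0.0)
        np.fill_diagonal(cand, 0.0)
        cand = np.nan_to_num(cand)
        if cand.max() <= exclusion_threshold:
            break
        # taxa must keep >= 2 partners or the system degenerates
        i, j = np.unravel_index(np.argmax(cand), cand.shape)
        if included[i].sum() <= 2 or included[j].sum() <= 2:
            break
        included[i, j] = included[j, i] = False

    if (w <= 0).any():
        labels = list(table.index[np.flatnonzero(w <= 0)])
        warnings.warn(
            f"negative basis variance for taxa {labels[:5]}; their correlations set to NaN",
            stacklevel=2,
        )
    return pd.DataFrame(rho, index=table.index, columns=table.index)


def sparcc_pvalues(
    table: pd.DataFrame,
    n_perm: int = 100,
    seed: int = 0,
    **sparcc_kwargs,
) -> pd.DataFrame:
    """Two-sided permutation p-values for SparCC correlations.

    Null: each taxon's counts are independently permuted across samples
    (destroying all inter-taxon association while keeping marginals), and
    SparCC is recomputed.  p = (#{|rho_null| >= |rho_obs|} + 1)/(n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if n_perm < 19:
        warnings.warn(f"n_perm={n_perm} cannot resolve p < {1/(n_perm+1):.2f}", stacklevel=2)
    obs = sparcc_correlations(table, **sparcc_kwargs).to_numpy()
    rng = stream(seed, "sparcc-permutation")
    counts = table.to_numpy()
    exceed = np.zeros_like(obs)
    for _ in range(n_perm):
        shuffled = np.stack([rng.permutation(row) for row in counts])
        null = sparcc_correlations(
            pd.DataFrame(shuffled, index=table.index, columns=table.columns),
            **sparcc_kwargs,
        ).to_numpy()
        with np.errstate(invalid="ignore"):
            exceed += (np.abs(null) >= np.abs(obs)).astype(float)
    pvals = (exceed + 1.0) / (n_perm + 1.0)
    np.fill_diagonal(pvals, 1.0 / (n_perm + 1.0))
    return pd.DataFrame(pvals, index=table.index, columns=table.index)


def build_network(
    corr: pd.DataFrame,
    pvals: pd.DataFrame | None = None,
    r_threshold: float = 0.3,
    p_threshold: float = 0.05,
    keep_isolated: bool = False,
) -> nx.Graph:
    """Signed network: edge (i, j) iff |rho_ij| >= r_threshold and p_ij <= p_threshold.

    Edges carry `weight` (the signed correlation) and `sign` (+1/-1).
    Isolated nodes are dropped unless `keep_isolated`.  Passing pvals=None
    applies the correlation threshold only.
    """
    if r_threshold < 0:
        raise ValueError("r_threshold must be >= 0")
    if not 0 <= p_threshold <= 1:
        raise ValueError("p_threshold must be in [0, 1]")
    taxa = list(corr.index)
    g = nx.Graph()
    if keep_isolated:
        g.add_nodes_from(taxa)
    c = corr.to_numpy()
    pv = pvals.to_numpy() if pvals is not None else None
    n = len(taxa)
    for i in range(n):
        for j in range(i + 1, n):
            rho = c[i, j]
            if not np.isfinite(rho) or abs(rho) < r_threshold or rho == 0:
                continue
            if pv is not None and pv[i, j] > p_threshold:
                continue
            g.add_edge(taxa[i], taxa[j], weight=float(rho), sign=1 if rho > 0 else -1)
    return g
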
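"""Network ecology: topology report, modules, node roles, robustness, cohesion.

Operates on the signed undirected graphs produced by
:mod:`rhizonet.netinfer` (edges carry ``weight`` = signed correlation and
``sign``).  Topology and spectral measures use the unsigned, unweighted
adjacency unless stated otherwise; module detection uses |weight|.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import logsumexp

from ._rng import stream

__all__ = [
    "TopologyReport",
    "CohesionResult",
    "topology_report",
    "detect_modules",
    "zc_scores",
    "natural_connectivity",
    "robustness_curve",
    "cohesion",
]


@dataclass
class TopologyReport:
    """Whole-network topology summary.

    ``avgK_paper`` is edges/node (E/N), the convention several amplicon
    network studies print as "average connectivity"; ``mean_degree`` is the
    standard 2E/N.  Both are reported because they differ by exactly a
    factor of two and published tables are not always explicit about which
    was used.
    """

    n_nodes: int
    n_edges: int
    n_positive: int
    n_negative: int
    pos_neg_ratio: float
    avgK_paper: float
    mean_degree: float
    avg_path_distance: float
    avg_clustering: float
    graph_density: float
    n_modules_ge5: int | None = None
    modularity: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def topology_report(
    network: nx.Graph,
    modules: dict | None = None,
    modularity: float | None = None,
) -> TopologyReport:
    """Compute the topology summary of a signed network.

    Average path distance is the mean unweighted shortest-path length over
    all connected node pairs; average clustering is the mean local
    clustering coefficient on the unsigned graph (degree-<2 nodes count 0).
    Pass the result of :func:`detect_modules` to fill the module fields.
    """
    n = network.number_of_nodes()
    e = network.number_of_edges()
    if n == 0:
        warnings.warn("empty network; reporting zeros", stacklevel=2)
        return TopologyReport(0, 0, 0, 0, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan)
    signs = [d.get("sign", 1 if d.get("weight", 1) > 0 else -1) for _, _, d in network.edges(data=True)]
    n_pos = sum(1 for s in signs if s > 0)
    n_neg = e - n_pos
    # mean shortest path over connected pairs only (graph may be disconnected)
    total, n_pairs = 0.0, 0
    for source, lengths in nx.all_pairs_shortest_path_length(network):
        for target, dist in lengths.items():
            if target != source:
                total += dist
                n_pairs += 1
    gd = total / n_pairs if n_pairs else np.nan
    avg_cc = float(np.mean(list(nx.clustering(network).values()))) if n else np.nan
    density = 2.0 * e / (n * (n - 1)) if n > 1 else np.nan
    n_ge5 = None
    q = modularity
    if modules is not None:
        sizes = pd.Series(modules).value_counts()
        n_ge5 = int((sizes >= 5).sum())
    return TopologyReport(
        n_nodes=n,
        n_edges=e,
        n_positive=n_pos,
        n_negative=n_neg,
        pos_neg_ratio=n_pos / n_neg if n_neg else np.inf,
        avgK_paper=e / n,
        mean_degree=2.0 * e / n,
        avg_path_distance=gd,
        avg_clustering=avg_cc,
        graph_density=density,
        n_modules_ge5=n_ge5,
        modularity=q,
    )


def detect_modules(
    network: nx.Graph,
    method: str = "greedy",
    seed: int = 0,
) -> tuple[dict, float]:
    """Partition the network into modules; return (node -> module id, Q).

    Edge weights enter as |weight| (modularity on a signed graph is not
    well defined).  'greedy' is Clauset-Newman-Moore agglomeration
    (deterministic); 'louvain' is the Louvain algorithm seeded for
    reproducibility.  Q is Newman modularity of the returned partition.
    """
    if method not in ("greedy", "louvain"):
        raise ValueError("method must be 'greedy' or 'louvain'")
    if network.number_of_nodes() == 0:
        return {}, np.nan
    unsigned = nx.Graph()
    unsigned.add_nodes_from(network.nodes())
    for u, v, d in network.edges(data=True):
        unsigned.add_edge(u, v, weight=abs(d.get("weight", 1.0)))
    if unsigned.number_of_edges() == 0:
        return {node: i for i, node in enumerate(unsigned.nodes())}, 0.0
    if method == "greedy":
        communities = nx.community.greedy_modularity_communities(unsigned, weight="weight")
    else:
        communities = nx.community.louvain_communities(unsigned, weight="weight", seed=seed)
    q = nx.community.modularity(unsigned, communities, weight="weight")
    assignment = {}
    for m, comm in enumerate(communities):
        for node in comm:
            assignment[node] = m
    return assignment, float(q)


def zc_scores(network: nx.Graph, modules: dict) -> pd.DataFrame:
    """Within-module degree z and participation coefficient c per node.

    z_i = (k_i,m(i) - mean_m) / sd_m, where k_i,m(i) is i's (unweighted)
    degree inside its own module and mean/sd run over that module's nodes;
    modules with sd = 0 give z = 0.  c_i = 1 - sum_m (k_im / k_i)^2.

    Categories (strict thresholds; boundary values fall to the lower
    category): z > 2.5 & c > 0.6 network hub; z > 2.5 & c <= 0.6 module
    hub; z <= 2.5 & c > 0.6 connector; otherwise peripheral.
    """
    missing = [v for v in network.nodes() if v not in modules]
    if missing:
        raise ValueError(f"nodes without module assignment: {missing[:5]}")
    module_ids = sorted(set(modules.values()))
    within_degree = {}
    participation = {}
    for node in network.nodes():
        neigh = list(network.neighbors(node))
        k_total = len(neigh)
        per_module = {}
        for other in neigh:
            per_module[modules[other]] = per_module.get(modules[other], 0) + 1
        within_degree[node] = per_module.get(modules[node], 0)
        if k_total == 0:
            participation[node] = 0.0
        else:
            participation[node] = 1.0 - sum((k / k_total) ** 2 for k in per_module.values())
    z = {}
    for m in module_ids:
        members = [v for v in network.nodes() if modules[v] == m]
        ks = np.array([within_degree[v] for v in members], dtype=float)
        sd = ks.std(ddof=0)
        mean = ks.mean()
        for v, k in zip(members, ks):
            z[v] = 0.0 if sd == 0 else (k - mean) / sd

    def category(zi: float, ci: float) -> str:
        if zi > 2.5 and ci > 0.6:
            return "network hub"
        if zi > 2.5:
            return "module hub"
        if ci > 0.6:
            return "connector"
        return "peripheral"

    nodes = list(network.nodes())
    return pd.DataFrame(
        {
            "module": [modules[v] for v in nodes],
            "z": [z[v] for v in nodes],
            "c": [participation[v] for v in nodes],
            "category": [category(z[v], participation[v]) for v in nodes],
        },
        index=pd.Index(nodes, name="taxon"),
    )


def natural_connectivity(network: nx.Graph) -> float:
    """Natural connectivity: ln of the mean exponential of adjacency eigenvalues.

    lambda_bar = ln[(1/N) sum_i exp(lambda_i)] on the unsigned, unweighted
    adjacency; non-negative for any simple graph (Jensen, eigenvalues sum
    to 0) and larger for graphs with more redundant paths.  Computed with a
    log-sum-exp to avoid overflow.
    """
    n = network.number_of_nodes()
    if n == 0:
        raise ValueError("natural connectivity undefined for the empty graph")
    adj = nx.to_numpy_array(network, weight=None)
    eig = np.linalg.eigvalsh(adj)
    return float(logsumexp(eig) - np.log(n))


def robustness_curve(network: nx.Graph, recompute: bool = False) -> pd.DataFrame:
    """Attack-tolerance curve: natural connectivity under betweenness-ordered removal.

    Betweenness centrality is computed once on the full network (a fixed
    ranking; pass ``recompute=True`` to re-rank after every removal); nodes
    are removed one at a time in descending betweenness (ties broken by
    node id).  The curve has N+1 points (before any removal through the
    empty graph, where connectivity is defined as 0).  The area under the
    curve over the removed fraction, by trapezoid rule, is attached as
    ``DataFrame.attrs['auc']`` — a scalar robustness summary.
    """
    n = network.number_of_nodes()
    if n == 0:
        raise ValueError("robustness curve undefined for the empty graph")

    def next_node(g: nx.Graph):
        bc = nx.betweenness_centrality(g)
        return min(g.nodes(), key=lambda v: (-bc[v], str(v)))

    bc = nx.betweenness_centrality(network)
    static_order = sorted(network.nodes(), key=lambda v: (-bc[v], str(v)))
    g = network.copy()
    order = []
    fractions = [0.0]
    connectivity = [natural_connectivity(g)]
    for step in range(1, n + 1):
        node = next_node(g) if recompute else static_order[step - 1]
        order.append(node)
        g.remove_node(node)
        fractions.append(step / n)
        connectivity.append(natural_connectivity(g) if g.number_of_nodes() else 0.0)
    curve = pd.DataFrame({"fraction_removed": fractions, "natural_connectivity": connectivity})
    curve.attrs["auc"] = float(np.trapezoid(curve["natural_connectivity"], curve["fraction_removed"]))
    curve.attrs["removal_order"] = order
    return curve


@dataclass
class CohesionResult:
    """Per-taxon connectedness and per-sample cohesion (positive/negative)."""

    connectedness: pd.DataFrame  # columns: positive (>=0), negative (<=0)
    cohesion: pd.DataFrame  # columns: positive (>=0), negative (<=0), per sample


def cohesion(table: pd.DataFrame, n_null_iter: int = 200, seed: int = 0) -> CohesionResult:
    """Community cohesion from null-corrected pairwise correlations.

    Relative abundances are correlated across samples (Pearson); the null
    expectation — each taxon's abundances shuffled independently across
    samples, `n_null_iter` times — is subtracted to remove correlation
    driven by abundance distributions alone.  A taxon's positive (negative)
    connectedness is the mean of its positive (negative) corrected
    correlations; sample cohesion is the abundance-weighted sum of
    connectedness.  Constant (zero-variance) taxa are excluded with a
    warning.
    """
    if n_null_iter < 1:
        raise ValueError("n_null_iter must be >= 1")
    rel = table.to_numpy(dtype=float)
    totals = rel.sum(axis=0, keepdims=True)
    if (totals == 0).any():
        raise ValueError("all-zero sample(s) present")
    rel = rel / totals
    variances = rel.var(axis=1)
    constant = variances <= 1e-15
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant taxa excluded from cohesion", stacklevel=2
        )
    keep = np.flatnonzero(~constant)
    taxa = table.index[keep]
    x = rel[keep]
    obs = np.corrcoef(x)
    rng = stream(seed, "cohesion-null")
    null_mean = np.zeros_like(obs)
    n_samples = x.shape[1]
    for _ in range(n_null_iter):
        shuffled = np.stack([row[rng.permutation(n_samples)] for row in x])
        # re-close the shuffled table so the null carries the same
        # compositional constraint (and its induced negative bias) as the
        # observed correlations
        shuffled /= shuffled.sum(axis=0, keepdims=True)
        null_mean += np.corrcoef(shuffled)
    null_mean /= n_null_iter
    corrected = obs - null_mean
    np.fill_diagonal(corrected, 0.0)

    # connectedness averages the positive (negative) part over all partners:
    # the per-pair noise contribution then shrinks as pairwise residuals
    # concentrate around zero, keeping the null-calibrated scale
    n_partners = max(corrected.shape[0] - 1, 1)
    conn_pos = np.where(corrected > 0, corrected, 0.0).sum(axis=1) / n_partners
    conn_neg = np.where(corrected < 0, corrected, 0.0).sum(axis=1) / n_partners
    connectedness = pd.DataFrame(
        {"positive": conn_pos, "negative": conn_neg}, index=pd.Index(taxa, name="taxon")
    )
    coh_pos = (x * conn_pos[:, None]).sum(axis=0)
    coh_neg = (x * conn_neg[:, None]).sum(axis=0)
    cohesion_df = pd.DataFrame(
        {"positive": coh_pos, "negative": coh_neg},
        index=pd.Index(table.columns, name="sample"),
    )
    return CohesionResult(connectedness=connectedness, cohesion=cohesion_df)
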
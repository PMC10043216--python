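"""Readers, writers, and the end-to-end pipeline driver.

Canonical on-disk formats: count tables and metadata as TSV (taxa rows x
sample columns, taxon id in the first column), trees as Newick, networks as
GraphML or a signed edge-list TSV, per-stage results as TSV/JSON.  Every
pipeline run records its config hash and root seed in a JSON log so results
are attributable and repeatable.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import dendropy
import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import assembly, diversity, netanalysis, netinfer, synth

__all__ = [
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "read_tree",
    "write_tree",
    "write_network",
    "read_network_edgelist",
    "run_pipeline",
]


class ConfigError(ValueError):
    """Raised before any computation when a pipeline config is unusable."""


def read_count_table(path: str | Path) -> pd.DataFrame:
    """Read a taxa x samples TSV count table, validating ids and integer cells."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    sample_ids = header[1:]
    if len(sample_ids) != len(set(sample_ids)):
        dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise ValueError(f"{path}: duplicate sample id(s): {dupes}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: parse error: {exc}") from exc
    if df.index.has_duplicates:
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"{path}: duplicate taxon id(s): {dupes[:5]}")
    for col in df.columns:
        vals = df[col]
        numeric = pd.to_numeric(vals, errors="coerce")
        bad = vals.index[numeric.isna() | (numeric != numeric.round()) | (numeric < 0)]
        if len(bad):
            row_no = list(df.index).index(bad[0]) + 2  # 1-based, after header
            raise ValueError(
                f"{path}: non-(non-negative-integer) cell at line {row_no}, "
                f"taxon {bad[0]!r}, sample {col!r}: {vals[bad[0]]!r}"
            )
    return df.astype(np.int64)


def write_count_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index_label="taxon")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read sample metadata TSV (sample id in the first column)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate sample id(s) in metadata")
    return df


def read_tree(path: str | Path) -> dendropy.Tree:
    """Read a rooted Newick tree, preserving branch lengths."""
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"{path}: Newick parse error: {exc}") from exc
    tree.is_rooted = True
    return tree


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def write_network(network: nx.Graph, path: str | Path, format: str = "edgelist-tsv") -> None:
    """Write a signed network as GraphML or a signed edge-list TSV.

    The edge list carries source, target, weight (signed correlation), and
    sign columns; GraphML additionally serialises any node attributes (e.g.
    module id and role category).
    """
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(network, path)
    elif format == "edgelist-tsv":
        rows = [
            {"source": u, "target": v, "weight": d.get("weight", 1.0), "sign": d.get("sign", 1)}
            for u, v, d in network.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["source", "target", "weight", "sign"]).to_csv(
            path, sep="\t", index=False
        )
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network_edgelist(path: str | Path) -> nx.Graph:
    df = pd.read_csv(path, sep="\t")
    g = nx.Graph()
    for row in df.itertuples(index=False):
        g.add_edge(row.source, row.target, weight=float(row.weight), sign=int(row.sign))
    return g


# ---------------------------------------------------------------------------
# pipeline driver


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _load_config(config_path: str | Path) -> dict:
    with open(config_path) as fh:
        if str(config_path).endswith((".yaml", ".yml")):
            return yaml.safe_load(fh)
        return json.load(fh)


def run_pipeline(config_path: str | Path, out_dir: str | Path | None = None) -> dict:
    """Run the full analysis from a YAML/JSON config; return the result bundle.

    The config either names input files (``inputs: {counts, tree, metadata}``)
    or a synthetic scenario (``simulate: {scenario, n_taxa, ...}``), plus
    ``seed``, ``null_reps``, the metadata ``group_column``, optional
    ``rarefy_depth`` / ``top_n_taxa``, network thresholds, and the list of
    ``stages`` to run (any of diversity, assembly, network).  Artifacts are
    written under ``out_dir`` (config ``out_dir`` by default); every run
    writes ``run_log.json`` with the config hash and seed.

    Validation happens before any computation; missing inputs or zero
    null-rep counts raise :class:`ConfigError`.
    """
    config = _load_config(config_path)
    out_dir = Path(out_dir or config.get("out_dir", "rhizonet_out"))

    seed = config.get("seed")
    if seed is None:
        raise ConfigError("config must set 'seed'")
    reps = int(config.get("null_reps", 999))
    if reps < 1:
        raise ConfigError("null_reps must be >= 1")
    stages = config.get("stages", ["diversity", "assembly", "network"])
    unknown = set(stages) - {"diversity", "assembly", "network"}
    if unknown:
        raise ConfigError(f"unknown stage(s): {sorted(unknown)}")

    if "simulate" in config:
        sim = dict(config["simulate"])
        scenario_cfg = synth.ScenarioConfig(seed=int(seed), **sim)
        tree = synth.simulate_phylogeny(scenario_cfg.n_taxa, scenario_cfg.seed)
        traits = synth.evolve_trait(tree, scenario_cfg.trait_sigma, scenario_cfg.seed)
        table, metadata = synth.simulate_community(scenario_cfg, tree, traits)
        group_col = "group"
    elif "inputs" in config:
        inputs = config["inputs"]
        for key in ("counts", "metadata"):
            if key not in inputs:
                raise ConfigError(f"inputs missing {key!r}")
            if not Path(inputs[key]).exists():
                raise ConfigError(f"input file not found: {inputs[key]}")
        needs_tree = "assembly" in stages
        if needs_tree and ("tree" not in inputs or not Path(inputs["tree"]).exists()):
            raise ConfigError("assembly stage requires inputs.tree")
        table = read_count_table(inputs["counts"])
        metadata = read_metadata(inputs["metadata"])
        tree = read_tree(inputs["tree"]) if "tree" in inputs and Path(inputs["tree"]).exists() else None
        group_col = config.get("group_column", "group")
        if group_col not in metadata.columns:
            raise ConfigError(f"group column {group_col!r} not in metadata")
    else:
        raise ConfigError("config needs either 'simulate' or 'inputs'")

    out_dir.mkdir(parents=True, exist_ok=True)
    groups = metadata.loc[list(table.columns), group_col]
    bundle: dict = {"config_hash": _config_hash(config), "seed": int(seed)}

    if depth := config.get("rarefy_depth"):
        table = diversity.rarefy(table, int(depth), seed=int(seed))
        groups = groups.loc[list(table.columns)]

    if "diversity" in stages:
        alpha = diversity.alpha_diversity(table)
        bc = diversity.bray_curtis(table)
        jac = diversity.jaccard(table)
        f_stat, p_val = diversity.permanova(bc, groups, n_perm=reps, seed=int(seed))
        venn = diversity.group_taxon_sets(table, groups)
        alpha.to_csv(out_dir / "alpha_diversity.tsv", sep="\t", index_label="sample")
        bc.to_csv(out_dir / "bray_curtis.tsv", sep="\t")
        jac.to_csv(out_dir / "jaccard.tsv", sep="\t")
        with open(out_dir / "permanova.json", "w") as fh:
            json.dump({"pseudo_F": f_stat, "p_value": p_val, "n_perm": reps}, fh, indent=2)
        with open(out_dir / "group_taxon_sets.json", "w") as fh:
            json.dump({"+".join(k): v for k, v in venn.items()}, fh, indent=2)
        bundle["diversity"] = {"alpha": alpha, "permanova": (f_stat, p_val), "venn": venn}

    assembly_table = table
    if n_top := config.get("top_n_taxa"):
        assembly_table = assembly.filter_top_taxa(table, int(n_top))

    if "assembly" in stages:
        if tree is None:
            raise ConfigError("assembly stage requires a tree")
        pairs = assembly.pair_assembly(assembly_table, tree, n_reps=reps, seed=int(seed))
        summary = assembly.assembly_summary(pairs, metadata.assign(group=groups))
        nst_vals = assembly.nst(assembly_table, groups, n_reps=reps, seed=int(seed))
        pairs.to_csv(out_dir / "pair_assembly.tsv", sep="\t", index=False)
        summary.to_csv(out_dir / "assembly_summary.tsv", sep="\t", index_label="group")
        nst_vals.to_frame().to_csv(out_dir / "nst.tsv", sep="\t", index_label="group")
        with open(out_dir / "assembly_params.json", "w") as fh:
            json.dump({"null_reps": reps, "seed": int(seed)}, fh, indent=2)
        bundle["assembly"] = {"pairs": pairs, "summary": summary, "nst": nst_vals}

    if "network" in stages:
        net_cfg = config.get("network", {})
        net_table = table
        if frac := net_cfg.get("prevalence_min_fraction"):
            net_table = netinfer.prevalence_filter(table, float(frac))
        corr = netinfer.sparcc_correlations(net_table)
        pvals = netinfer.sparcc_pvalues(
            net_table, n_perm=int(net_cfg.get("n_perm", 100)), seed=int(seed)
        )
        net = netinfer.build_network(
            corr,
            pvals,
            r_threshold=float(net_cfg.get("r_threshold", 0.3)),
            p_threshold=float(net_cfg.get("p_threshold", 0.05)),
        )
        modules, q = netanalysis.detect_modules(net, seed=int(seed))
        report = netanalysis.topology_report(net, modules=modules, modularity=q)
        corr.to_csv(out_dir / "sparcc_correlations.tsv", sep="\t")
        pvals.to_csv(out_dir / "sparcc_pvalues.tsv", sep="\t")
        write_network(net, out_dir / "network_edges.tsv", "edgelist-tsv")
        with open(out_dir / "topology.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2, default=float)
        bundle["network"] = {"graph": net, "topology": report, "modules": modules}
        if net.number_of_nodes() > 0:
            roles = netanalysis.zc_scores(net, modules)
            curve = netanalysis.robustness_curve(net)
            roles.to_csv(out_dir / "node_roles.tsv", sep="\t")
            curve.to_csv(out_dir / "robustness.tsv", sep="\t", index=False)
            for node in net.nodes():
                net.nodes[node]["module"] = int(modules[node])
                net.nodes[node]["role"] = roles.loc[node, "category"]
            write_network(net, out_dir / "network.graphml", "graphml")
            bundle["network"]["roles"] = roles
            bundle["network"]["robustness"] = curve
        coh = netanalysis.cohesion(net_table, seed=int(seed))
        coh.cohesion.to_csv(out_dir / "cohesion.tsv", sep="\t")
        bundle["network"]["cohesion"] = coh

    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(
            {"config_hash": bundle["config_hash"], "seed": int(seed), "null_reps": reps,
             "stages": list(stages), "config": config},
            fh, indent=2, default=str,
        )
    return bundle
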
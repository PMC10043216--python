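import dendropy
import numpy as np
import pandas as pd
import pytest

import rhizonet as rn


@pytest.fixture(scope="session")
def small_tree() -> dendropy.Tree:
    return rn.synth.simulate_phylogeny(10, seed=5)


@pytest.fixture(scope="session")
def small_table(small_tree) -> pd.DataFrame:
    taxa = sorted(
        (l.taxon.label for l in small_tree.leaf_node_iter()), key=lambda s: (len(s), s)
    )
    rng = np.random.default_rng(2)
    tab = pd.DataFrame(
        rng.integers(0, 10, size=(10, 4)), index=taxa, columns=list("abcd")
    )
    tab.iloc[0] = np.maximum(tab.iloc[0], 1)  # no all-zero samples
    return tab


@pytest.fixture(scope="session")
def two_clade_tree() -> dendropy.Tree:
    nwk = (
        "(((t1:0.1,t2:0.1):0.05,(t3:0.1,t4:0.1):0.05,t5:0.15):3,"
        "((t6:0.1,t7:0.1):0.05,(t8:0.1,t9:0.1):0.05,t10:0.15):3);"
    )
    return dendropy.Tree.get(data=nwk, schema="newick")


def community(scenario: str, seed: int, **kw) -> tuple[pd.DataFrame, pd.DataFrame, dendropy.Tree]:
    defaults = dict(n_taxa=100, n_samples=12, n_groups=2, depth=5_000)
    defaults.update(kw)
    cfg = rn.synth.ScenarioConfig(scenario, seed=seed, **defaults)
    tree = rn.synth.simulate_phylogeny(cfg.n_taxa, cfg.seed)
    table, metadata = rn.synth.simulate_community(cfg, tree)
    return table, metadata, tree
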
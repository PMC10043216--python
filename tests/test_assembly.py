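"""Null-model assembly inference: beta-MNTD/beta-NTI, RC-bray, classes, NST."""

import subprocess
import textwrap

import dendropy
import numpy as np
import pandas as pd
import pytest

import rhizonet as rn
from conftest import community


class TestFilterTopTaxa:
    def test_requesting_all_is_identity(self, small_table):
        out = rn.assembly.filter_top_taxa(small_table, len(small_table))
        pd.testing.assert_frame_equal(out, small_table)

    def test_single_most_abundant(self):
        tab = pd.DataFrame({"s": [1, 9, 3]}, index=["a", "b", "c"])
        out = rn.assembly.filter_top_taxa(tab, 1)
        assert list(out.index) == ["b"]

    def test_ties_broken_by_taxon_id(self):
        tab = pd.DataFrame(
            {"s1": [5, 3, 3, 1, 1], "s2": [5, 2, 2, 0, 0]},
            index=["t1", "t2", "t3", "t4", "t5"],
        )
        out = rn.assembly.filter_top_taxa(tab, 3)
        assert list(out.index) == ["t1", "t2", "t3"]

    def test_overlong_request_warns_and_keeps_all(self, small_table):
        with pytest.warns(UserWarning, match="all retained"):
            out = rn.assembly.filter_top_taxa(small_table, 99)
        assert out.shape == small_table.shape


class TestNicheValues:
    def test_single_sample_taxon_takes_that_samples_value(self):
        tab = pd.DataFrame({"a": [3], "b": [0]}, index=["t1"])
        meta = pd.DataFrame({"ph": [4.0, 9.0]}, index=["a", "b"])
        out = rn.assembly.niche_values(tab, meta)
        assert out.loc["t1", "ph"] == 4.0

    def test_uniform_abundance_gives_arithmetic_mean(self):
        tab = pd.DataFrame({"a": [2], "b": [2]}, index=["t1"])
        meta = pd.DataFrame({"ph": [4.0, 8.0]}, index=["a", "b"])
        assert rn.assembly.niche_values(tab, meta).loc["t1", "ph"] == 6.0

    def test_abundance_weighting_hand_value(self):
        tab = pd.DataFrame({"a": [1], "b": [3]}, index=["t1"])
        meta = pd.DataFrame({"v": [2.0, 6.0]}, index=["a", "b"])
        assert rn.assembly.niche_values(tab, meta).loc["t1", "v"] == pytest.approx(5.0)

    def test_zero_total_taxon_excluded(self):
        tab = pd.DataFrame({"a": [1, 0], "b": [1, 0]}, index=["t1", "t2"])
        meta = pd.DataFrame({"v": [1.0, 2.0]}, index=["a", "b"])
        out = rn.assembly.niche_values(tab, meta)
        assert list(out.index) == ["t1"]


class TestMantelCorrelogram:
    def test_conserved_trait_significant_in_shortest_class(self):
        # a Brownian trait evolved on the same tree must show positive
        # autocorrelation at short phylogenetic distances
        tree = rn.synth.simulate_phylogeny(60, seed=8)
        pdist = rn.assembly.cophenetic_matrix(tree)
        hits = 0
        for rep in range(5):
            tr = rn.synth.evolve_trait(tree, 1.0, seed=200 + rep)
            nd = pd.DataFrame(
                np.abs(tr.to_numpy()[:, None] - tr.to_numpy()[None, :]),
                index=tr.index, columns=tr.index,
            ).loc[pdist.index, pdist.index]
            out = rn.assembly.mantel_correlogram(pdist, nd, n_classes=6, n_perm=99, seed=rep)
            first = out.dropna(subset=["mantel_r"]).iloc[0]
            hits += (first["mantel_r"] > 0) and (first["p_value"] <= 0.05)
        assert hits >= 4

    def test_empty_class_reported_missing(self):
        # two tight clusters of distances leave middle classes empty
        d = np.array([
            [0, 0.1, 5, 5],
            [0.1, 0, 5, 5],
            [5, 5, 0, 0.1],
            [5, 5, 0.1, 0],
        ], dtype=float)
        pdist = pd.DataFrame(d, index=list("abcd"), columns=list("abcd"))
        out = rn.assembly.mantel_correlogram(pdist, pdist, n_classes=5, n_perm=19, seed=0)
        assert out["mantel_r"].isna().any()


class TestBetaMNTD:
    def test_identical_samples_zero(self, small_tree, small_table):
        tab = small_table.copy()
        tab["dup"] = tab["a"]
        bm = rn.assembly.beta_mntd(tab, small_tree)
        assert bm.loc["a", "dup"] == 0

    def test_two_singleton_samples_hand_value(self):
        tree = dendropy.Tree.get(data="(t1:1,t2:1);", schema="newick")
        tab = pd.DataFrame({"A": [5, 0], "B": [0, 3]}, index=["t1", "t2"])
        assert rn.assembly.beta_mntd(tab, tree).loc["A", "B"] == pytest.approx(2.0)

    def test_matches_brute_force_double_loop(self, small_tree, small_table):
        d = rn.assembly.cophenetic_matrix(small_tree, list(small_table.index)).to_numpy()
        bm = rn.assembly.beta_mntd(small_table, small_tree)
        x = small_table.to_numpy(dtype=float)
        for a in range(4):
            for b in range(4):
                fa, fb = x[:, a] / x[:, a].sum(), x[:, b] / x[:, b].sum()
                ia, ib = np.flatnonzero(x[:, a]), np.flatnonzero(x[:, b])
                s1 = sum(fa[i] * d[i, ib].min() for i in ia)
                s2 = sum(fb[j] * d[j, ia].min() for j in ib)
                assert bm.iloc[a, b] == pytest.approx(0.5 * (s1 + s2), abs=1e-12)

    def test_matches_picante_comdistnt_oracle(self, tmp_path, small_tree, small_table):
        bm = rn.assembly.beta_mntd(small_table, small_tree)
        small_tree.write(path=str(tmp_path / "t.nwk"), schema="newick", suppress_rooting=True)
        small_table.T.to_csv(tmp_path / "comm.csv")
        script = textwrap.dedent(
            """
            suppressMessages(library(picante))
            tr <- read.tree("t.nwk"); comm <- as.matrix(read.csv("comm.csv", row.names=1))
            d <- comdistnt(comm, cophenetic(tr), abundance.weighted=TRUE)
            write.csv(as.matrix(d), "out.csv")
            """
        )
        subprocess.run(["Rscript", "-e", script], cwd=tmp_path, check=True,
                       capture_output=True, timeout=300)
        ref = pd.read_csv(tmp_path / "out.csv", index_col=0)
        assert np.allclose(bm.to_numpy(), ref.to_numpy(), atol=1e-9)

    def test_missing_tree_taxon_raises_coverage_error(self, small_tree):
        tab = pd.DataFrame({"a": [1, 1]}, index=["t1", "missing_taxon"])
        with pytest.raises(ValueError, match="missing from tree"):
            rn.assembly.beta_mntd(tab, small_tree)


class TestBetaNTI:
    def test_star_phylogeny_null_degenerate(self):
        star = dendropy.Tree.get(data="(t1:1,t2:1,t3:1,t4:1);", schema="newick")
        tab = pd.DataFrame(
            {"A": [4, 1, 0, 0], "B": [0, 0, 3, 2]}, index=["t1", "t2", "t3", "t4"]
        )
        with pytest.warns(UserWarning, match="degenerate null"):
            z = rn.assembly.beta_nti(tab, star, n_reps=20, seed=0)
        assert np.isnan(z.loc["A", "B"])

    def test_deterministic_for_fixed_seed(self, small_tree, small_table):
        a = rn.assembly.beta_nti(small_table, small_tree, n_reps=30, seed=5)
        b = rn.assembly.beta_nti(small_table, small_tree, n_reps=30, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_selection_scenario_phylogenetically_clustered(self):
        table, _, tree = community("homogeneous_selection", seed=11, n_taxa=200, n_samples=12)
        z = rn.assembly.beta_nti(table, tree, n_reps=99, seed=11)
        vals = z.to_numpy()[np.triu_indices(12, 1)]
        assert np.nanmedian(vals) < -2


class TestRCBray:
    def test_bounded_in_minus_one_one(self, small_table):
        rc = rn.assembly.rc_bray(small_table, n_reps=30, seed=1).to_numpy()
        assert ((rc >= -1) & (rc <= 1)).all()

    def test_single_taxon_metacommunity_rejected(self):
        tab = pd.DataFrame({"a": [5, 0], "b": [3, 0]}, index=["t1", "t2"])
        with pytest.raises(ValueError, match="degenerate metacommunity"):
            rn.assembly.rc_bray(tab, n_reps=10, seed=0)

    def test_dispersal_limitation_inflates_rc_relative_to_undominated(self):
        frac = {}
        for scen in ("dispersal_limitation", "undominated"):
            fr = []
            for seed in (1, 2, 3):
                table, _, tree = community(scen, seed=seed, n_taxa=150, n_samples=10)
                pairs = rn.assembly.pair_assembly(table, tree, n_reps=60, seed=seed)
                ok = pairs[pairs.process != "missing"]
                fr.append(((ok.beta_nti.abs() <= 2) & (ok.rc_bray > 0.95)).mean())
            frac[scen] = np.mean(fr)
        assert frac["dispersal_limitation"] > frac["undominated"]


class TestClassifyProcesses:
    @pytest.mark.parametrize(
        "z,rc,expected",
        [
            (2.5, 0.0, "HeS"),
            (-2.5, 0.0, "HoS"),
            (0.0, 0.99, "DL"),
            (0.0, -0.99, "HD"),
            (0.0, 0.0, "UD"),
            (-2.0001, 1.0, "HoS"),  # deterministic signal takes precedence
            (2.0, 0.99, "DL"),  # |z| exactly at threshold is stochastic
        ],
    )
    def test_threshold_rules(self, z, rc, expected):
        zm = pd.DataFrame([[0, z], [z, 0]], index=["a", "b"], columns=["a", "b"])
        rm = pd.DataFrame([[0, rc], [rc, 0]], index=["a", "b"], columns=["a", "b"])
        out = rn.assembly.classify_processes(zm, rm)
        assert out.loc[0, "process"] == expected

    def test_every_pair_gets_exactly_one_label(self):
        rng = np.random.default_rng(0)
        n = 8
        z = rng.normal(0, 3, (n, n))
        rc = rng.uniform(-1, 1, (n, n))
        ids = [f"s{i}" for i in range(n)]
        zm = pd.DataFrame((z + z.T) / 2, index=ids, columns=ids)
        rm = pd.DataFrame((rc + rc.T) / 2, index=ids, columns=ids)
        out = rn.assembly.classify_processes(zm, rm)
        assert len(out) == n * (n - 1) // 2
        assert out["process"].isin(rn.assembly.PROCESSES).all()

    def test_missing_beta_nti_labeled_missing(self):
        zm = pd.DataFrame([[0, np.nan], [np.nan, 0]], index=["a", "b"], columns=["a", "b"])
        rm = pd.DataFrame([[0, 0.5], [0.5, 0]], index=["a", "b"], columns=["a", "b"])
        out = rn.assembly.classify_processes(zm, rm)
        assert out.loc[0, "process"] == "missing"


class TestAssemblySummary:
    def _pairs(self, rows):
        return pd.DataFrame(rows, columns=["sample_i", "sample_j", "beta_nti", "rc_bray", "process"])

    def test_all_one_process(self):
        pairs = self._pairs([("a", "b", -3, 0, "HoS"), ("a", "c", -2.5, 0, "HoS")])
        meta = pd.DataFrame({"group": ["g", "g", "g"]}, index=["a", "b", "c"])
        out = rn.assembly.assembly_summary(pairs, meta)
        assert out.loc["g", "HoS"] == 1.0
        assert out.loc["g"].sum() == pytest.approx(1.0)

    def test_hand_computed_fractions(self):
        pairs = self._pairs(
            [("a", "b", 0, 0, "UD"), ("a", "c", 0, 1, "DL"),
             ("b", "c", 0, 1, "DL"), ("d", "e", 3, 0, "HeS")]
        )
        meta = pd.DataFrame({"group": ["g1"] * 3 + ["g2"] * 2}, index=list("abcde"))
        out = rn.assembly.assembly_summary(pairs, meta)
        assert out.loc["g1", "DL"] == pytest.approx(2 / 3)
        assert out.loc["g1", "UD"] == pytest.approx(1 / 3)
        assert out.loc["g2", "HeS"] == 1.0

    def test_invariant_to_pair_ordering(self):
        rows = [("a", "b", 0, 0, "UD"), ("a", "c", 0, 1, "DL"), ("b", "c", -3, 0, "HoS")]
        meta = pd.DataFrame({"group": ["g"] * 3}, index=list("abc"))
        out1 = rn.assembly.assembly_summary(self._pairs(rows), meta)
        out2 = rn.assembly.assembly_summary(self._pairs(rows[::-1]), meta)
        pd.testing.assert_frame_equal(out1, out2)


class TestNST:
    def test_observed_equal_to_null_gives_full_stochasticity(self, monkeypatch):
        # when every observed dissimilarity equals the null expectation the
        # per-pair ratio is identically 1 -> NST = 100%
        tab = pd.DataFrame(np.random.default_rng(0).integers(1, 20, (10, 6)))
        import rhizonet.assembly as asm

        def fake_nulls(table, n_reps, rng, metric="braycurtis"):
            from scipy.spatial.distance import pdist, squareform
            obs = squareform(pdist(table.to_numpy(float).T, metric="braycurtis"))
            return obs, np.repeat(obs[None], n_reps, axis=0)

        monkeypatch.setattr(asm, "_null_dissimilarities", fake_nulls)
        out = asm.nst(tab, ["g"] * 6, n_reps=5, seed=0)
        assert out["g"] == pytest.approx(100.0)

    def test_invariant_to_sample_relabeling_within_group(self):
        table, meta, _ = community("undominated", seed=4, n_taxa=60, n_samples=8, n_groups=1)
        out1 = rn.assembly.nst(table, meta.group, n_reps=20, seed=3)
        shuffled = table[list(table.columns[::-1])]
        out2 = rn.assembly.nst(shuffled, meta.group.loc[shuffled.columns], n_reps=20, seed=3)
        assert out1["g1"] == pytest.approx(out2["g1"], abs=5.0)

    def test_undominated_scenario_reads_stochastic(self):
        vals = []
        for seed in (1, 2, 3):
            table, meta, _ = community("undominated", seed=seed, n_taxa=100, n_samples=10, n_groups=1)
            vals.append(rn.assembly.nst(table, meta.group, n_reps=30, seed=seed)["g1"])
        assert np.median(vals) > 50
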
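"""Ward typing, branch enumeration, branch-trait tests, q-values, scan."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy

import oracles
from metabotype.synthetic_data import TraitTable, generate_trait_table
from metabotype.typing_association import (
    ClusterTree,
    association_scan,
    branch_size_threshold,
    cluster_cell_lines,
    enumerate_branches,
    qvalues_storey,
)
from metabotype.typing_association import test_branch_trait as branch_trait_test


def balanced_tree(n_leaves=32):
    """Linkage of a perfect binary tree with strictly increasing heights."""
    Z = []
    clusters = list(range(n_leaves))
    sizes = {i: 1 for i in range(n_leaves)}
    next_id, h = n_leaves, 1.0
    while len(clusters) > 1:
        nxt = []
        for a, b in zip(clusters[::2], clusters[1::2]):
            Z.append([a, b, h, sizes[a] + sizes[b]])
            sizes[next_id] = sizes[a] + sizes[b]
            nxt.append(next_id)
            next_id += 1
            h += 0.01
        h += 1.0
        clusters = nxt
    labels = [f"L{i:02d}" for i in range(n_leaves)]
    return ClusterTree(np.asarray(Z, dtype=float), labels)


class TestClustering:
    def test_ward_heights_match_lance_williams_recursion(self):
        pts = np.array([[0.0, 0.0], [0.1, 0.2], [3.0, 3.1], [3.2, 2.9], [10.0, 0.0]])
        df = pd.DataFrame(pts, index=[f"C{i}" for i in range(5)],
                          columns=["p1", "p2"])
        tree = cluster_cell_lines(df)
        expected = oracles.ward_linkage_heights(pts)
        assert np.allclose(sorted(tree.linkage[:, 2]), sorted(expected))

    def test_recovers_planted_types(self, clean_screen):
        from metabotype.pathway_scoring import (
            curate_pathways, map_ions_to_pathways, pathway_score)
        from metabotype.synthetic_data import pathway_collection_from_truth

        table, truth = clean_screen
        bio = table.subset_samples(table.samples.index[~table.samples["is_qc"]])
        coll = curate_pathways(
            pathway_collection_from_truth(truth.ion_pathway, table.ions))
        scores = pathway_score(bio, map_ions_to_pathways(table.ions, coll))
        tree = cluster_cell_lines(scores)
        types = tree.major_types()
        planted = truth.type_labels.loc[types.index]
        # Rand index of the top split against the planted types
        same_pred = types.to_numpy()[:, None] == types.to_numpy()[None, :]
        same_true = planted.to_numpy()[:, None] == planted.to_numpy()[None, :]
        iu = np.triu_indices(len(types), k=1)
        rand = (same_pred == same_true)[iu].mean()
        assert rand >= 0.9

    def test_duplicating_lines_preserves_topology(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(0, 1, size=(8, 3)),
                          index=[f"C{i}" for i in range(8)])
        tree = cluster_cell_lines(df)
        dup = pd.concat([df, df.set_axis([f"{i}_dup" for i in df.index])])
        tree2 = cluster_cell_lines(dup)
        parts = {frozenset(b.leaves) for b in tree.internal_branches()}
        parts2 = {
            frozenset(l.replace("_dup", "") for l in b.leaves)
            for b in tree2.internal_branches() if b.size % 2 == 0
        }
        assert parts <= parts2

    def test_missing_scores_rejected(self):
        df = pd.DataFrame([[1.0, np.nan], [0.0, 1.0], [2.0, 0.5]],
                          index=["a", "b", "c"])
        with pytest.raises(ValueError, match="missing"):
            cluster_cell_lines(df)

    def test_newick_roundtrip_parses(self):
        tree = balanced_tree(8)
        nwk = tree.to_newick()
        assert nwk.endswith(";") and nwk.count("L00") == 1
        assert all(f"L{i:02d}" in nwk for i in range(8))


class TestBranchEnumeration:
    def test_cohort_of_180_gives_threshold_18(self):
        assert branch_size_threshold(180, 0.10) == 18

    def test_balanced_tree_counts(self):
        tree = balanced_tree(32)
        branches = enumerate_branches(tree, min_fraction=4 / 32)
        # nodes of size >= 4, root excluded: 8 of size 4, 4 of 8, 2 of 16
        assert len(branches) == 14
        assert sorted(set(b.size for b in branches)) == [4, 8, 16]

    def test_full_fraction_gives_empty_list(self):
        tree = balanced_tree(16)
        assert enumerate_branches(tree, min_fraction=1.0) == []

    def test_branches_nest(self):
        tree = balanced_tree(16)
        for a, b in combinations(enumerate_branches(tree, min_fraction=0.2), 2):
            inter = a.leaves & b.leaves
            assert inter in (frozenset(), a.leaves, b.leaves)


class TestBranchTraitTests:
    def test_hypergeometric_exact_value(self):
        values = pd.Series(["pos"] * 4 + ["neg"] * 6,
                           index=[f"c{i}" for i in range(10)])
        branch = [f"c{i}" for i in range(5)]  # contains all 4 positives
        p, direction, effect = branch_trait_test(branch, values, "categorical")
        assert p == pytest.approx(6 / 252)
        assert direction == 1 and effect["level"] == "pos"

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(0)
        for N, K, n in [(8, 3, 4), (10, 4, 5), (12, 6, 3)]:
            values = pd.Series(["pos"] * K + ["neg"] * (N - K),
                               index=[f"c{i}" for i in range(N)])
            branch = rng.choice(values.index, size=n, replace=False)
            k = int((values.loc[branch] == "pos").sum())
            p, _, _ = branch_trait_test(branch, values, "categorical")
            p_pos = oracles.hypergeom_enrichment_p(N, K, n, k)
            p_neg = oracles.hypergeom_enrichment_p(N, N - K, n, n - k)
            assert p == pytest.approx(min(p_pos, p_neg))

    def test_identical_groups_give_t_zero_p_one(self):
        values = pd.Series([1.0, 1.0, 1.0, 1.0], index=list("abcd"))
        p, direction, _ = branch_trait_test(["a", "b"], values, "continuous")
        assert p == 1.0

    def test_trait_only_outside_branch_is_depleted(self):
        values = pd.Series(["neg"] * 4 + ["pos"] * 4,
                           index=[f"c{i}" for i in range(8)])
        p, direction, effect = branch_trait_test(
            [f"c{i}" for i in range(4)], values, "categorical")
        assert direction == -1

    def test_continuous_direction_is_sign_of_mean_difference(self):
        values = pd.Series([5.0, 6.0, 1.0, 2.0, 1.5], index=list("abcde"))
        p, direction, effect = branch_trait_test(["a", "b"], values, "continuous")
        assert direction == 1 and effect["mean_difference"] > 0
        p2, d2, _ = branch_trait_test(["c", "d", "e"], values, "continuous")
        assert d2 == -1


class TestStoreyQvalues:
    def test_all_ones_degenerate(self):
        q, pi0 = qvalues_storey(np.ones(500))
        assert pi0 == 1.0
        assert np.all(q == 1.0)

    def test_uniform_null_pi0_near_one(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            p = np.clip(rng.uniform(0, 1, 5000), 1e-12, 1)
            _, pi0 = qvalues_storey(p)
            assert 0.85 <= pi0 <= 1.0

    def test_q_monotone_in_p(self):
        rng = np.random.default_rng(2)
        p = np.clip(np.concatenate([rng.beta(0.1, 5, 300), rng.uniform(0, 1, 700)]),
                    1e-12, 1)
        q, _ = qvalues_storey(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_signal_mixture_discoveries_control_fdp(self):
        rng = np.random.default_rng(3)
        fdps = []
        for _ in range(20):
            m, sig = 2000, 600
            p = np.concatenate([
                np.clip(rng.uniform(0, 1, m - sig), 1e-12, 1),
                np.clip(rng.beta(0.05, 10, sig), 1e-300, 1),
            ])
            is_null = np.arange(m) < m - sig
            q, _ = qvalues_storey(p)
            disc = q <= 0.10
            if disc.any():
                fdps.append(is_null[disc].mean())
        assert np.mean(fdps) <= 0.15

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            qvalues_storey(np.array([]))
        with pytest.raises(ValueError):
            qvalues_storey(np.array([0.0, 0.5]))


@pytest.fixture(scope="module")
def tree_and_labels():
    rng = np.random.default_rng(5)
    labels = pd.Series(
        np.repeat([1, 2], 30), index=[f"CL{i:03d}" for i in range(60)])
    scores = pd.DataFrame(
        rng.normal(0, 0.3, size=(60, 5))
        + np.where(labels.to_numpy()[:, None] == 1, 1.0, -1.0),
        index=labels.index,
    )
    return cluster_cell_lines(scores), labels


class TestAssociationScan:

    def test_bookkeeping_identity(self, tree_and_labels):
        tree, labels = tree_and_labels
        traits = generate_trait_table(labels, 20, 20, 0, seed=0, missing_rate=0.3)
        scan = association_scan(tree, traits)
        n_branches = len(enumerate_branches(tree))
        assert len(scan.records) + len(scan.skipped) == n_branches * traits.n_traits

    def test_direction_agrees_with_naive_comparison(self, tree_and_labels):
        tree, labels = tree_and_labels
        traits = generate_trait_table(labels, 10, 10, 2, effect=2.0, seed=1)
        scan = association_scan(tree, traits)
        for r in scan.records:
            if r.test != "t":
                continue
            assert r.direction == (1 if r.effect["mean_branch"] >= r.effect["mean_rest"]
                                   else -1)

    def test_planted_trait_found_on_matching_branch(self, tree_and_labels):
        tree, labels = tree_and_labels
        traits = generate_trait_table(labels, 50, 50, 1, effect=np.inf, seed=2)
        scan = association_scan(tree, traits)
        sig = [r for r in scan.significant_records()
               if r.trait_id == "planted_cat0000"]
        assert sig
        type1 = set(labels.index[labels == 1])
        jac = max(
            len(set(tree.branch(r.branch_id).leaves) & type1)
            / len(set(tree.branch(r.branch_id).leaves) | type1)
            for r in sig
        )
        assert jac >= 0.9

    def test_p_values_do_not_depend_on_pooling(self, tree_and_labels):
        tree, labels = tree_and_labels
        traits = generate_trait_table(labels, 10, 10, 0, seed=3)
        full = association_scan(tree, traits)
        subset = TraitTable(traits.continuous.iloc[:, :3],
                            traits.categorical.iloc[:, :3], traits.source)
        part = association_scan(tree, subset)
        full_p = {(r.branch_id, r.trait_id): r.p for r in full.records}
        for r in part.records:
            assert full_p[(r.branch_id, r.trait_id)] == pytest.approx(r.p)

    def test_scan_is_deterministic(self, tree_and_labels):
        tree, labels = tree_and_labels
        traits = generate_trait_table(labels, 15, 15, 1, effect=2.0, seed=4)
        a = association_scan(tree, traits).to_frame()
        b = association_scan(tree, traits).to_frame()
        pd.testing.assert_frame_equal(a, b)
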
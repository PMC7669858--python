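import itertools
from math import inf

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from clonalkit import phylogeny as ph
from clonalkit import synthetic_data as sd

# ---------------------------------------------------------------------------
# oracles


def brute_force_fitch(tree: ph.UnrootedTree, states: np.ndarray) -> int:
    """Minimum changes over all internal labelings (and ambiguous leaves)."""
    internal = [n for n in tree.adj if n >= tree.n_leaves]
    free = internal + [
        i for i in range(tree.n_leaves) if states[i] in (ph.AMBIGUOUS, ph.MISSING)
    ]
    fixed = {
        i: int(states[i])
        for i in range(tree.n_leaves)
        if states[i] in (ph.ABSENT, ph.PRESENT)
    }
    edges = tree.edges()
    best = inf
    for combo in itertools.product((0, 1), repeat=len(free)):
        assign = dict(zip(free, combo))
        assign.update(fixed)
        cost = sum(assign[u] != assign[v] for u, v in edges)
        best = min(best, cost)
    return best


def random_topology(taxa, rng) -> ph.UnrootedTree:
    tree = ph.UnrootedTree.star3(taxa)
    for k in range(3, len(taxa)):
        edges = tree.edges()
        tree = tree.with_leaf_on_edge(k, taxa[k], edges[rng.integers(len(edges))])
    return tree


def canonical_split(clade, taxa):
    first = taxa[0]
    return frozenset(clade) if first not in clade else frozenset(taxa) - frozenset(clade)


def simulated_matrix(
    clone_tree, parent_mixture, muts_per_branch=5, depth=500, seed=0, outgroup=None
):
    cfg = sd.SimulationConfig(seed=seed)
    table, truth = sd.simulate_mutation_set(
        clone_tree, muts_per_branch, parent_mixture, depth, cfg,
        outgroup=outgroup, seed=seed,
    )
    matrix = ph.build_character_matrix(table, parental_sample="parental")
    return matrix, truth


# ---------------------------------------------------------------------------
# character matrix


class TestCharacterMatrix:
    def _records(self, rows):
        return pd.DataFrame(rows)

    def _row(self, d_a, a_a, d_b, a_b, pos=1):
        return {
            "chrom": "chr1", "pos": pos, "ref": "C", "alt": "T", "context": "ACA",
            "depth_A": d_a, "alt_A": a_a, "depth_B": d_b, "alt_B": a_b,
        }

    def test_vaf_state_thresholds(self):
        t = ph.Thresholds()
        assert t.classify(0.30) == ph.PRESENT
        assert t.classify(0.25) == ph.PRESENT
        assert t.classify(0.05) == ph.ABSENT
        assert t.classify(0.15) == ph.AMBIGUOUS
        assert t.classify(0.10) == ph.AMBIGUOUS

    def test_low_depth_in_any_sample_excludes(self):
        records = self._records([self._row(29, 20, 100, 50)])
        m = ph.build_character_matrix(records)
        assert m.n_chars == 0 and m.n_dropped_depth == 1

    def test_max_vaf_below_present_excludes(self):
        records = self._records([self._row(100, 20, 100, 10)])  # VAFs 0.20, 0.10
        m = ph.build_character_matrix(records)
        assert m.n_chars == 0 and m.n_dropped_vaf == 1

    def test_states_encoded(self):
        records = self._records([self._row(100, 30, 100, 15)])  # 0.30 / 0.15
        m = ph.build_character_matrix(records)
        assert m.states[m.taxa.index("A"), 0] == ph.PRESENT
        assert m.states[m.taxa.index("B"), 0] == ph.AMBIGUOUS

    def test_missing_values_dropped_with_warning(self):
        records = self._records(
            [self._row(100, 30, np.nan, 15), self._row(100, 40, 100, 50, pos=2)]
        )
        with pytest.warns(UserWarning, match="missing"):
            m = ph.build_character_matrix(records)
        assert m.n_chars == 1 and m.n_dropped_missing == 1

    def test_parental_vafs_recorded(self):
        records = self._records([
            {
                "chrom": "chr1", "pos": 5, "ref": "C", "alt": "T", "context": "ACA",
                "depth_A": 100, "alt_A": 40, "depth_parental": 100, "alt_parental": 20,
                "depth_B": 100, "alt_B": 0,
            }
        ])
        m = ph.build_character_matrix(records, parental_sample="parental")
        assert m.taxa == ["A", "B"]
        assert m.parental_vafs.loc["chr1:5"] == pytest.approx(0.20)


# ---------------------------------------------------------------------------
# Fitch scoring


class TestFitchLength:
    def test_uniform_character_costs_zero(self):
        tree = next(ph.enumerate_topologies(list("ABCDE")))
        assert ph.fitch_length(tree, {t: ph.PRESENT for t in tree.taxa}) == 0

    def test_all_ambiguous_costs_zero(self):
        tree = next(ph.enumerate_topologies(list("ABCDE")))
        assert ph.fitch_length(tree, {t: ph.AMBIGUOUS for t in tree.taxa}) == 0

    def test_missing_taxon_rejected(self):
        tree = next(ph.enumerate_topologies(list("ABC")))
        with pytest.raises(ValueError, match="lacks states"):
            ph.fitch_length(tree, {"A": 1, "B": 0})

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_random_5_taxon_instances(self, seed):
        rng = np.random.default_rng(seed)
        taxa = list("ABCDE")
        topos = list(ph.enumerate_topologies(taxa))
        tree = topos[rng.integers(len(topos))]
        states = rng.integers(0, 4, size=(5, 20)).astype(np.int8)
        got = ph.fitch_lengths(tree, states)
        want = [brute_force_fitch(tree, states[:, j]) for j in range(20)]
        assert got.tolist() == want

    def test_score_invariant_under_taxon_reordering(self):
        rng = np.random.default_rng(3)
        taxa = list("ABCDEF")
        states = rng.integers(0, 3, size=(6, 30)).astype(np.int8)
        m1 = ph.CharacterMatrix(taxa, [f"c{j}" for j in range(30)], states)
        perm = list(rng.permutation(6))
        m2 = ph.CharacterMatrix(
            [taxa[i] for i in perm], m1.char_ids, states[perm]
        )
        _, s1 = ph.search_mp_tree(m1, mode="exhaustive")
        _, s2 = ph.search_mp_tree(m2, mode="exhaustive")
        assert s1 == s2


# ---------------------------------------------------------------------------
# tree search


class TestSearch:
    def test_three_taxa_single_topology(self):
        m = ph.CharacterMatrix(
            ["A", "B", "C"], ["c0"], np.array([[1], [0], [0]], dtype=np.int8)
        )
        best, score = ph.search_mp_tree(m, mode="exhaustive")
        assert len(best) == 1
        assert best[0].tree.splits() == set()  # no internal split on 3 taxa

    def test_too_few_taxa_rejected(self):
        m = ph.CharacterMatrix(["A", "B"], ["c0"], np.array([[1], [0]], dtype=np.int8))
        with pytest.raises(ValueError, match=">= 3 taxa"):
            ph.search_mp_tree(m)

    def test_six_taxon_enumeration_size(self):
        assert sum(1 for _ in ph.enumerate_topologies(list("ABCDEF"))) == 105

    def test_exhaustive_recovers_generating_topology(
        self, clone_tree, parent_mixture
    ):
        matrix, truth = simulated_matrix(clone_tree, parent_mixture, seed=11)
        best, score = ph.search_mp_tree(matrix, mode="exhaustive")
        assert len(best) == 1
        want = {
            canonical_split(c, matrix.taxa)
            for c in sd.clades_of(clone_tree)
            if 2 <= len(c) <= len(matrix.taxa) - 2
        }
        assert best[0].tree.splits() == want

    def test_heuristic_beats_random_topologies(self, clone_tree, parent_mixture):
        matrix, _ = simulated_matrix(clone_tree, parent_mixture, seed=12)
        best, score = ph.search_mp_tree(matrix, mode="heuristic", seed=5)
        rng = np.random.default_rng(0)
        random_scores = [
            ph.parsimony_score(random_topology(matrix.taxa, rng), matrix)
            for _ in range(100)
        ]
        assert score <= min(random_scores)

    def test_heuristic_deterministic_given_seed(self, clone_tree, parent_mixture):
        matrix, _ = simulated_matrix(clone_tree, parent_mixture, seed=13)
        a, _ = ph.search_mp_tree(matrix, mode="heuristic", seed=9)
        b, _ = ph.search_mp_tree(matrix, mode="heuristic", seed=9)
        assert a[0].tree.canonical_form() == b[0].tree.canonical_form()


# ---------------------------------------------------------------------------
# bootstrap


class TestBootstrap:
    def test_clean_signal_supports_near_one(self, clone_tree, parent_mixture):
        matrix, _ = simulated_matrix(
            clone_tree, parent_mixture, muts_per_branch=20, seed=14
        )
        _, support = ph.bootstrap_support(matrix, n_reps=200, seed=1)
        assert support and all(v >= 0.99 for v in support.values())

    def test_single_informative_character_support_one(self):
        states = np.array([[1], [1], [0], [0]], dtype=np.int8)
        m = ph.CharacterMatrix(list("ABCD"), ["c0"], states)
        _, support = ph.bootstrap_support(m, n_reps=50, seed=0)
        assert support == {frozenset({"C", "D"}): 1.0}

    def test_same_seed_identical_supports(self, clone_tree, parent_mixture):
        matrix, _ = simulated_matrix(clone_tree, parent_mixture, seed=15)
        _, s1 = ph.bootstrap_support(matrix, n_reps=100, seed=4)
        _, s2 = ph.bootstrap_support(matrix, n_reps=100, seed=4)
        assert s1 == s2


# ---------------------------------------------------------------------------
# branch assignment


class TestBranchAssignment:
    def test_private_mutation_on_terminal_branch(self):
        states = np.array([[1], [0], [0], [0]], dtype=np.int8)
        m = ph.CharacterMatrix(list("ABCD"), ["m1"], states)
        best, _ = ph.search_mp_tree(m, mode="exhaustive")
        branches, _, homoplasic = ph.assign_branch_mutations(best[0].tree, m)
        key = canonical_split({"A"}, m.taxa)
        assert branches[key] == ["m1"]
        assert homoplasic == []

    def test_assignment_recovers_generating_branches(self, clone_tree, parent_mixture):
        matrix, truth = simulated_matrix(clone_tree, parent_mixture, seed=16)
        best, _ = ph.search_mp_tree(matrix, mode="exhaustive")
        branches, mean_vaf, homoplasic = ph.assign_branch_mutations(best[0].tree, matrix)
        located = {m: k for k, ids in branches.items() for m in ids}
        checked = 0
        for mut, clade in truth.mutation_branches.items():
            if mut in homoplasic or mut not in located:
                continue
            assert located[mut] == canonical_split(clade, matrix.taxa)
            checked += 1
        assert checked >= 0.9 * matrix.n_chars

    def test_stem_branch_has_highest_parental_vaf(self, clone_tree, parent_mixture):
        # germline outgroup roots the topology so each clade stem is its own edge
        matrix, _ = simulated_matrix(
            clone_tree, parent_mixture, muts_per_branch=30, seed=17, outgroup="blood"
        )
        best, _ = ph.search_mp_tree(matrix, mode="exhaustive")
        _, mean_vaf, _ = ph.assign_branch_mutations(best[0].tree, matrix)
        stem = canonical_split({"CL31", "CL49"}, matrix.taxa)
        others = [v for k, v in mean_vaf.items() if k != stem and not np.isnan(v)]
        assert mean_vaf[stem] > max(others)

    def test_empty_branch_flagged_nan(self):
        states = np.array([[1], [0], [0], [0]], dtype=np.int8)
        m = ph.CharacterMatrix(
            list("ABCD"), ["m1"], states,
            parental_vafs=pd.Series([0.4], index=["m1"]),
        )
        best, _ = ph.search_mp_tree(m, mode="exhaustive")
        _, mean_vaf, _ = ph.assign_branch_mutations(best[0].tree, m)
        key = canonical_split({"A"}, m.taxa)
        assert mean_vaf[key] == pytest.approx(0.4)
        empties = [v for k, v in mean_vaf.items() if k != key]
        assert all(np.isnan(v) for v in empties)


# ---------------------------------------------------------------------------
# rank-sum comparison


class TestCompareBranchVafs:
    def test_identical_sets_p_one(self):
        assert ph.compare_branch_vafs([0.4, 0.4, 0.4], [0.4, 0.4, 0.4]) == 1.0

    def test_fully_separated_3v3_exact(self):
        p = ph.compare_branch_vafs([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
        assert p == pytest.approx(0.1)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            ph.compare_branch_vafs([], [0.1])

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_matches_scipy_enumeration_no_ties(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=8), rng.normal(size=8) + 0.5
        ours = ph.compare_branch_vafs(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
        assert ours == pytest.approx(float(ref), abs=1e-12)

    def test_exact_handles_ties_via_midranks(self):
        a = [1.0, 1.0, 2.0, 3.0]
        b = [1.0, 4.0, 5.0, 6.0]
        # independent oracle: enumerate labelings, U from pairwise comparisons
        pooled = a + b
        n = len(a)
        def u_stat(idx):
            grp_a = [pooled[i] for i in idx]
            grp_b = [pooled[i] for i in range(len(pooled)) if i not in idx]
            return sum(
                (x > y) + 0.5 * (x == y) for x in grp_a for y in grp_b
            )
        obs = u_stat(range(n))
        center = len(a) * len(b) / 2
        total = extreme = 0
        for idx in itertools.combinations(range(len(pooled)), n):
            total += 1
            if abs(u_stat(idx) - center) >= abs(obs - center) - 1e-9:
                extreme += 1
        assert ph.compare_branch_vafs(a, b) == pytest.approx(extreme / total)

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=30), rng.normal(size=30) + 1.0
        ours = ph.compare_branch_vafs(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        assert ours == pytest.approx(float(ref))

    def test_dominant_ancestor_stem_rejects_strongly(self, clone_tree, parent_mixture):
        """Stem-branch parental VAFs exceed other branches' (rank-sum p < 1e-3)."""
        matrix, _ = simulated_matrix(
            clone_tree, parent_mixture, muts_per_branch=30, seed=18, outgroup="blood"
        )
        best, _ = ph.search_mp_tree(matrix, mode="exhaustive")
        branches, _, _ = ph.assign_branch_mutations(best[0].tree, matrix)
        stem = canonical_split({"CL31", "CL49"}, matrix.taxa)
        stem_vafs = matrix.parental_vafs.loc[branches[stem]]
        other_vafs = matrix.parental_vafs.loc[
            [m for k, ids in branches.items() if k != stem for m in ids]
        ]
        assert stem_vafs.mean() > other_vafs.mean()
        assert ph.compare_branch_vafs(stem_vafs, other_vafs) < 1e-3


# ---------------------------------------------------------------------------
# newick output


class TestNewick:
    def test_newick_parses_with_dendropy_and_preserves_taxa(
        self, clone_tree, parent_mixture
    ):
        import dendropy

        matrix, _ = simulated_matrix(clone_tree, parent_mixture, seed=19)
        best, support = ph.bootstrap_support(matrix, n_reps=20, seed=0)
        nwk = best.newick()
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        assert {t.label for t in tree.taxon_namespace} == set(matrix.taxa)
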
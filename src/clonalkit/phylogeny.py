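"""Maximum-parsimony clone phylogeny from per-sample VAF tables.

Whole-exome mutations observed across single-cell-derived clones are
turned into a ternary character matrix: a mutation is *present* in a
sample at VAF >= 0.25, *absent* below VAF 0.10, and *ambiguous* in
between, after requiring >= 30x depth in every sample and presence in at
least one.  The minimum-change (maximum parsimony) unrooted tree over
the clones is found by exhaustive enumeration for small taxon sets or by
random-addition + NNI hill climbing; branch support comes from character
bootstrap.  Each mutation is then assigned to the branch(es) where its
Fitch reconstruction places the state change, and branches are
summarized by the mean VAF of their mutations in the parental sample —
the mixture the clones were derived from — which reveals which subclades
dominate the parental population.

State encoding: 0 absent, 1 present, 2 ambiguous, 3 missing.  In Fitch
scoring, ambiguous and missing taxa contribute the full state set
{present, absent} and therefore never force a change.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "Thresholds",
    "CharacterMatrix",
    "UnrootedTree",
    "PhyloTree",
    "build_character_matrix",
    "fitch_length",
    "fitch_lengths",
    "enumerate_topologies",
    "search_mp_tree",
    "bootstrap_support",
    "assign_branch_mutations",
    "compare_branch_vafs",
]

ABSENT, PRESENT, AMBIGUOUS, MISSING = 0, 1, 2, 3
# bitmask state sets for Fitch: bit 0 = absent, bit 1 = present
_STATE_MASK = np.array([0b01, 0b10, 0b11, 0b11], dtype=np.uint8)


@dataclass
class Thresholds:
    """VAF classification thresholds and the depth filter."""

    vaf_present: float = 0.25
    vaf_absent: float = 0.10
    min_depth: int = 30

    def classify(self, vaf: float) -> int:
        if vaf >= self.vaf_present:
            return PRESENT
        if vaf < self.vaf_absent:
            return ABSENT
        return AMBIGUOUS


@dataclass
class CharacterMatrix:
    """Ternary parsimony characters: taxa x mutations.

    ``states[i, j]`` holds the state of mutation *j* in taxon *i*.
    ``parental_vafs`` carries each retained mutation's VAF in the
    parental (mixture) sample when one was provided.
    """

    taxa: list[str]
    char_ids: list[str]
    states: np.ndarray  # (n_taxa, n_chars) int8
    thresholds: Thresholds = field(default_factory=Thresholds)
    parental_vafs: pd.Series | None = None
    n_dropped_depth: int = 0
    n_dropped_vaf: int = 0
    n_dropped_missing: int = 0

    def __post_init__(self) -> None:
        if self.states.shape != (len(self.taxa), len(self.char_ids)):
            raise ValueError("states shape does not match taxa x characters")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_chars(self) -> int:
        return len(self.char_ids)

    def resample(self, rng: np.random.Generator) -> np.ndarray:
        """Bootstrap column weights (multinomial resampling of characters)."""
        idx = rng.integers(0, self.n_chars, size=self.n_chars)
        return np.bincount(idx, minlength=self.n_chars).astype(float)


def build_character_matrix(
    records: pd.DataFrame,
    thresholds: Thresholds | None = None,
    taxa: list[str] | None = None,
    parental_sample: str | None = None,
) -> CharacterMatrix:
    """Filter a mutation table and encode it as ternary characters.

    A mutation is retained only if depth >= ``min_depth`` in **every**
    sample (taxa and, when given, the parental sample) and VAF >=
    ``vaf_present`` in at least one taxon.  Rows with missing per-sample
    values are dropped with a warning and counted.

    Sample names are inferred from the ``depth_<s>`` / ``alt_<s>`` column
    pairs unless *taxa* is given; *parental_sample* is kept out of the
    taxon set and only contributes depth filtering and per-mutation
    parental VAFs.
    """
    thresholds = thresholds or Thresholds()
    inferred = [c[len("depth_"):] for c in records.columns if c.startswith("depth_")]
    if taxa is None:
        taxa = [s for s in inferred if s != parental_sample]
    all_samples = list(taxa) + ([parental_sample] if parental_sample else [])
    for s in all_samples:
        if f"depth_{s}" not in records.columns or f"alt_{s}" not in records.columns:
            raise ValueError(f"sample {s!r} lacks depth_/alt_ columns")

    char_ids: list[str] = []
    columns: list[np.ndarray] = []
    parental: list[float] = []
    n_depth = n_vaf = n_missing = 0
    for row in records.itertuples(index=False):
        depths = np.array([getattr(row, f"depth_{s}") for s in all_samples], dtype=float)
        alts = np.array([getattr(row, f"alt_{s}") for s in all_samples], dtype=float)
        if np.isnan(depths).any() or np.isnan(alts).any():
            n_missing += 1
            continue
        if (depths < thresholds.min_depth).any():
            n_depth += 1
            continue
        vafs = alts / depths
        taxa_vafs = vafs[: len(taxa)]
        if (taxa_vafs < thresholds.vaf_present).all():
            n_vaf += 1
            continue
        columns.append(np.array([thresholds.classify(v) for v in taxa_vafs], dtype=np.int8))
        char_ids.append(f"{row.chrom}:{row.pos}")
        if parental_sample:
            parental.append(float(vafs[-1]))
    if n_missing:
        warnings.warn(f"{n_missing} records with missing values dropped", stacklevel=2)

    states = (
        np.column_stack(columns) if columns else np.zeros((len(taxa), 0), dtype=np.int8)
    )
    return CharacterMatrix(
        taxa=list(taxa),
        char_ids=char_ids,
        states=states,
        thresholds=thresholds,
        parental_vafs=pd.Series(parental, index=char_ids) if parental_sample else None,
        n_dropped_depth=n_depth,
        n_dropped_vaf=n_vaf,
        n_dropped_missing=n_missing,
    )


# ---------------------------------------------------------------------------
# Unrooted binary trees


_INTERNAL_BASE = 1_000_000  # internal node ids start here; leaves are 0..n-1


class UnrootedTree:
    """Unrooted binary tree: leaves 0..n-1 carry taxa, internal nodes are
    large ids (>= 10^6) so leaf tests are a simple comparison.

    Stored as an adjacency map.  Every internal node has degree 3.
    """

    def __init__(self, taxa: list[str], adj: dict[int, list[int]]):
        self.taxa = list(taxa)
        self.adj = adj

    @classmethod
    def star3(cls, taxa: list[str]) -> "UnrootedTree":
        """The single unrooted topology over the first three taxa."""
        c = _INTERNAL_BASE
        adj = {0: [c], 1: [c], 2: [c], c: [0, 1, 2]}
        return cls(taxa[:3], adj)

    def copy(self) -> "UnrootedTree":
        return UnrootedTree(self.taxa, {u: list(vs) for u, vs in self.adj.items()})

    @property
    def n_leaves(self) -> int:
        return len(self.taxa)

    def edges(self) -> list[tuple[int, int]]:
        return [(u, v) for u, vs in self.adj.items() for v in vs if u < v]

    def with_leaf_on_edge(self, leaf: int, taxon: str, edge: tuple[int, int]) -> "UnrootedTree":
        """New tree with *taxon* attached in the middle of *edge*."""
        t = self.copy()
        u, v = edge
        w = max(i for i in t.adj if i >= _INTERNAL_BASE) + 1
        t.adj[u].remove(v)
        t.adj[v].remove(u)
        t.adj[u].append(w)
        t.adj[v].append(w)
        t.adj[w] = [u, v, leaf]
        t.adj[leaf] = [w]
        t.taxa = self.taxa + [taxon]
        return t

    # -- splits -----------------------------------------------------------
    def _leafset_below(self, node: int, parent: int, out: set[int]) -> None:
        if node < self.n_leaves:
            out.add(node)
            return
        for nb in self.adj[node]:
            if nb != parent:
                self._leafset_below(nb, node, out)

    def split_of_edge(self, edge: tuple[int, int]) -> frozenset[str]:
        """Canonical split key: the taxon side NOT containing taxon 0."""
        u, v = edge
        side: set[int] = set()
        self._leafset_below(v, u, side)
        if 0 in side:
            side = set(range(self.n_leaves)) - side
        return frozenset(self.taxa[i] for i in side)

    def splits(self, internal_only: bool = True) -> set[frozenset[str]]:
        out = set()
        for e in self.edges():
            s = self.split_of_edge(e)
            if internal_only and (len(s) < 2 or len(s) > self.n_leaves - 2):
                continue
            out.add(s)
        return out

    # -- newick -----------------------------------------------------------
    def _newick_below(self, node: int, parent: int, labels: dict | None) -> str:
        if node < self.n_leaves:
            return self.taxa[node]
        parts = sorted(
            self._newick_below(nb, node, labels) for nb in self.adj[node] if nb != parent
        )
        label = ""
        if labels is not None:
            key = self.split_of_edge((parent, node)) if parent is not None else None
            if key in labels:
                label = labels[key]
        return "(" + ",".join(parts) + ")" + label

    def newick(self, support: dict[frozenset[str], float] | None = None) -> str:
        """Deterministic Newick string, rooted at the leaf of taxon 0.

        Internal nodes carry bootstrap support labels when *support* is
        given (keys are canonical splits).
        """
        labels = None
        if support is not None:
            labels = {k: format(v, "g") for k, v in support.items()}
        root_leaf = 0
        inner = self._newick_below(self.adj[root_leaf][0], root_leaf, labels)
        return f"({self.taxa[root_leaf]},{inner});"

    def canonical_form(self) -> str:
        return self.newick()


def enumerate_topologies(taxa: list[str]):
    """Yield every unrooted binary topology over *taxa* (stepwise addition).

    There are (2n-5)!! topologies for n taxa (105 for n = 6).
    """
    if len(taxa) < 3:
        raise ValueError("need >= 3 taxa")
    stack = [UnrootedTree.star3(taxa)]
    for k in range(3, len(taxa)):
        stack = [
            t.with_leaf_on_edge(k, taxa[k], e) for t in stack for e in t.edges()
        ]
    yield from stack


# ---------------------------------------------------------------------------
# Fitch small parsimony


def _root_order(tree: UnrootedTree) -> list[tuple[int, int]]:
    """Post-order (node, parent) pairs for the tree rooted at leaf 0's edge."""
    order: list[tuple[int, int]] = []

    def walk(node: int, parent: int) -> None:
        for nb in tree.adj[node]:
            if nb != parent:
                walk(nb, node)
        order.append((node, parent))

    walk(tree.adj[0][0], 0)
    return order


def fitch_lengths(tree: UnrootedTree, states: np.ndarray) -> np.ndarray:
    """Per-character Fitch lengths on *tree* for a (n_taxa, n_chars) matrix.

    Vectorized over characters: one post-order pass intersecting child
    state sets, counting a change whenever the intersection is empty.
    The leaf holding taxon 0 is folded in at the root edge.
    """
    if states.shape[0] != tree.n_leaves:
        raise ValueError("state matrix does not match the tree's taxa")
    n_chars = states.shape[1]
    masks: dict[int, np.ndarray] = {}
    changes = np.zeros(n_chars, dtype=np.int64)
    for node, parent in _root_order(tree):
        if node < tree.n_leaves:
            masks[node] = _STATE_MASK[states[node]]
            continue
        children = [nb for nb in tree.adj[node] if nb != parent]
        m = masks[children[0]]
        for c in children[1:]:
            inter = m & masks[c]
            empty = inter == 0
            changes += empty
            m = np.where(empty, m | masks[c], inter)
        masks[node] = m
    # fold in the root leaf (taxon 0)
    root_child = tree.adj[0][0]
    leaf_mask = _STATE_MASK[states[0]]
    changes += (masks[root_child] & leaf_mask) == 0
    return changes


def fitch_length(tree: UnrootedTree, character: dict[str, int] | np.ndarray) -> int:
    """Fitch length of one character (minimum state changes on *tree*)."""
    if isinstance(character, dict):
        missing = [t for t in tree.taxa if t not in character]
        if missing:
            raise ValueError(f"character lacks states for taxa: {missing}")
        character = np.array([character[t] for t in tree.taxa], dtype=np.int8)
    return int(fitch_lengths(tree, np.asarray(character).reshape(-1, 1))[0])


def parsimony_score(tree: UnrootedTree, matrix: CharacterMatrix, weights=None) -> float:
    lengths = fitch_lengths(tree, matrix.states)
    if weights is None:
        return float(lengths.sum())
    return float(np.dot(lengths, weights))


# ---------------------------------------------------------------------------
# Tree search


@dataclass
class PhyloTree:
    """A maximum-parsimony result: topology, score and annotations."""

    tree: UnrootedTree
    score: float
    support: dict[frozenset[str], float] | None = None
    branch_mutations: dict[frozenset[str], list[str]] | None = None
    branch_mean_parental_vaf: dict[frozenset[str], float] | None = None
    homoplasic: list[str] | None = None

    def newick(self) -> str:
        return self.tree.newick(self.support)


def _nni_neighbors(tree: UnrootedTree):
    """Yield the two NNI rearrangements of every internal edge."""
    n = tree.n_leaves
    for u, v in tree.edges():
        if u < n or v < n:
            continue
        a, b = [x for x in tree.adj[u] if x != v]
        c, d = [x for x in tree.adj[v] if x != u]
        for x, y in ((b, c), (b, d)):
            t = tree.copy()
            t.adj[u].remove(x)
            t.adj[v].remove(y)
            t.adj[u].append(y)
            t.adj[v].append(x)
            t.adj[x].remove(u)
            t.adj[y].remove(v)
            t.adj[x].append(v)
            t.adj[y].append(u)
            yield t


def _stepwise_addition(
    matrix: CharacterMatrix, order: list[int], weights=None
) -> UnrootedTree:
    """Greedy stepwise addition following a taxon order (indices).

    The tree is built over the permuted taxon list (so leaf ids track the
    addition order) and re-mapped onto the matrix's taxon order at the end.
    """
    taxa = matrix.taxa
    perm_taxa = [taxa[i] for i in order]
    perm_states = matrix.states[order]
    tree = UnrootedTree.star3(perm_taxa)
    for k in range(3, len(perm_taxa)):
        best = None
        for e in tree.edges():
            cand = tree.with_leaf_on_edge(k, perm_taxa[k], e)
            lengths = fitch_lengths(cand, perm_states[: k + 1])
            sc = float(np.dot(lengths, weights) if weights is not None else lengths.sum())
            key = (sc, cand.canonical_form())
            if best is None or key < best[0]:
                best = (key, cand)
        tree = best[1]
    return _reindex(tree, taxa)


def _reindex(tree: UnrootedTree, taxa: list[str]) -> UnrootedTree:
    """Re-map a tree over permuted taxa onto the reference taxon order."""
    name_to_new = {t: i for i, t in enumerate(taxa)}
    old_to_new = {}
    n = tree.n_leaves
    next_internal = _INTERNAL_BASE
    for node in sorted(tree.adj):
        if node < n:
            old_to_new[node] = name_to_new[tree.taxa[node]]
        else:
            old_to_new[node] = next_internal
            next_internal += 1
    adj = {old_to_new[u]: [old_to_new[v] for v in vs] for u, vs in tree.adj.items()}
    return UnrootedTree(taxa, adj)


def search_mp_tree(
    matrix: CharacterMatrix,
    mode: str = "auto",
    seed: int = 0,
    n_starts: int = 10,
    weights=None,
    max_exhaustive_taxa: int = 7,
) -> tuple[list[PhyloTree], float]:
    """Find minimum-parsimony topologies for a character matrix.

    ``mode='exhaustive'`` enumerates all unrooted topologies and returns
    every one achieving the minimum score; ``'heuristic'`` runs
    *n_starts* random-addition builds each followed by NNI hill climbing
    and returns the single best topology found (ties broken by
    lexicographic Newick).  ``'auto'`` picks exhaustive for up to
    *max_exhaustive_taxa* taxa.

    Raises
    ------
    ValueError
        For fewer than 3 taxa (no unrooted topology exists).
    """
    if matrix.n_taxa < 3:
        raise ValueError("tree search requires >= 3 taxa")
    if mode == "auto":
        mode = "exhaustive" if matrix.n_taxa <= max_exhaustive_taxa else "heuristic"

    if mode == "exhaustive":
        best_score = None
        best: list[UnrootedTree] = []
        for t in enumerate_topologies(matrix.taxa):
            sc = parsimony_score(t, matrix, weights)
            if best_score is None or sc < best_score:
                best_score, best = sc, [t]
            elif sc == best_score:
                best.append(t)
        best.sort(key=lambda t: t.canonical_form())
        return [PhyloTree(t, best_score) for t in best], float(best_score)

    if mode != "heuristic":
        raise ValueError(f"unknown search mode {mode!r}")
    rng = np.random.default_rng(seed)
    champion: UnrootedTree | None = None
    champion_score = np.inf
    for _ in range(n_starts):
        order = list(rng.permutation(matrix.n_taxa))
        tree = _stepwise_addition(matrix, order, weights)
        score = parsimony_score(tree, matrix, weights)
        improved = True
        while improved:
            improved = False
            for cand in _nni_neighbors(tree):
                sc = parsimony_score(cand, matrix, weights)
                if sc < score or (
                    sc == score and cand.canonical_form() < tree.canonical_form()
                ):
                    if sc < score:
                        improved = True
                    tree, score = cand, sc
        if score < champion_score or (
            score == champion_score
            and champion is not None
            and tree.canonical_form() < champion.canonical_form()
        ):
            champion, champion_score = tree, score
    return [PhyloTree(champion, float(champion_score))], float(champion_score)


# ---------------------------------------------------------------------------
# Bootstrap support


def bootstrap_support(
    matrix: CharacterMatrix,
    n_reps: int = 1000,
    mode: str = "auto",
    seed: int = 0,
    reference: PhyloTree | None = None,
) -> tuple[PhyloTree, dict[frozenset[str], float]]:
    """Character-bootstrap support for the reference tree's internal splits.

    Characters are resampled with replacement *n_reps* times; each
    replicate's best tree is found with the same search mode, and a
    split's support is the fraction of replicate best trees containing
    it.  When the search is exhaustive, per-topology character lengths
    are computed once and replicates reduce to weighted sums.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if reference is None:
        reference = search_mp_tree(matrix, mode=mode, seed=seed)[0][0]
    ref_splits = reference.tree.splits()
    hits = dict.fromkeys(ref_splits, 0)
    rng = np.random.default_rng(seed)

    effective = mode
    if mode == "auto":
        effective = "exhaustive" if matrix.n_taxa <= 7 else "heuristic"

    if effective == "exhaustive":
        topos = list(enumerate_topologies(matrix.taxa))
        lengths = np.stack([fitch_lengths(t, matrix.states) for t in topos])
        newicks = [t.canonical_form() for t in topos]
        splits_cache = [t.splits() for t in topos]
        for _ in range(n_reps):
            w = matrix.resample(rng)
            scores = lengths @ w
            best = np.flatnonzero(scores == scores.min())
            pick = min(best, key=lambda i: newicks[i])
            for s in ref_splits:
                if s in splits_cache[pick]:
                    hits[s] += 1
    else:
        for r in range(n_reps):
            w = matrix.resample(rng)
            best, _ = search_mp_tree(
                matrix, mode="heuristic", seed=int(rng.integers(2**31)), weights=w
            )
            rep_splits = best[0].tree.splits()
            for s in ref_splits:
                if s in rep_splits:
                    hits[s] += 1

    support = {s: hits[s] / n_reps for s in ref_splits}
    reference.support = support
    return reference, support


# ---------------------------------------------------------------------------
# Branch assignment and parental-VAF summaries


def _fitch_reconstruction(tree: UnrootedTree, states: np.ndarray) -> dict[int, np.ndarray]:
    """One deterministic minimal Fitch reconstruction per character.

    Down-pass uses the union-on-empty-intersection rule; the top-down
    refinement keeps the parent's state when allowed and otherwise
    prefers *absent* (mutations arise rather than revert in the typical
    clone history).  Returns final states per node, (n_chars,) arrays.
    """
    n_chars = states.shape[1]
    masks: dict[int, np.ndarray] = {}
    order = _root_order(tree)
    for node, parent in order:
        if node < tree.n_leaves:
            masks[node] = _STATE_MASK[states[node]]
            continue
        children = [nb for nb in tree.adj[node] if nb != parent]
        m = masks[children[0]]
        for c in children[1:]:
            inter = m & masks[c]
            m = np.where(inter == 0, m | masks[c], inter)
        masks[node] = m
    # root edge: combine taxon-0 leaf with its neighbor
    root_child = tree.adj[0][0]
    leaf0 = _STATE_MASK[states[0]]
    root_inter = masks[root_child] & leaf0
    root_set = np.where(root_inter == 0, masks[root_child] | leaf0, root_inter)

    def pick(mask: np.ndarray) -> np.ndarray:
        # prefer absent (bit 0) on ties
        return np.where(mask & 0b01, ABSENT, PRESENT).astype(np.int8)

    final: dict[int, np.ndarray] = {}
    root_state = pick(root_set)
    final[0] = np.where((leaf0 >> root_state) & 1, root_state, pick(leaf0)).astype(np.int8)

    def assign_down(node: int, parent: int, parent_state: np.ndarray) -> None:
        if node < tree.n_leaves:
            m = masks[node]
            final[node] = np.where((m >> parent_state) & 1, parent_state, pick(m)).astype(np.int8)
            return
        m = masks[node]
        st = np.where((m >> parent_state) & 1, parent_state, pick(m)).astype(np.int8)
        final[node] = st
        for nb in tree.adj[node]:
            if nb != parent:
                assign_down(nb, node, st)

    assign_down(root_child, 0, final[0])
    return final


def assign_branch_mutations(
    tree: UnrootedTree,
    matrix: CharacterMatrix,
    parental_vafs: pd.Series | None = None,
) -> tuple[
    dict[frozenset[str], list[str]], dict[frozenset[str], float], list[str]
]:
    """Place each mutation on the branch(es) where its state changes.

    Uses one deterministic minimal Fitch reconstruction.  Mutations with
    zero changes on the tree are assigned to no branch; mutations whose
    reconstruction needs more than one change (homoplasy) are assigned to
    every change branch and reported in the homoplasy list.  Branch keys
    are canonical splits (taxon side not containing the first taxon).

    Returns (branch -> mutation ids, branch -> mean parental VAF, homoplasic
    mutation ids).  A branch with no assigned mutations gets NaN mean VAF.
    """
    if parental_vafs is None:
        parental_vafs = matrix.parental_vafs
    final = _fitch_reconstruction(tree, matrix.states)
    branch_sets: dict[frozenset[str], list[str]] = {
        tree.split_of_edge(e): [] for e in tree.edges()
    }
    changes_per_char = np.zeros(matrix.n_chars, dtype=int)
    change_edges: list[list[frozenset[str]]] = [[] for _ in range(matrix.n_chars)]
    for u, v in tree.edges():
        diff = final[u] != final[v]
        changes_per_char += diff
        key = tree.split_of_edge((u, v))
        for j in np.flatnonzero(diff):
            change_edges[j].append(key)
    homoplasic: list[str] = []
    for j, cid in enumerate(matrix.char_ids):
        for key in change_edges[j]:
            branch_sets[key].append(cid)
        if changes_per_char[j] > 1:
            homoplasic.append(cid)
    mean_vaf: dict[frozenset[str], float] = {}
    for key, ids in branch_sets.items():
        if parental_vafs is not None and ids:
            mean_vaf[key] = float(parental_vafs.loc[ids].mean())
        else:
            mean_vaf[key] = float("nan")
    return branch_sets, mean_vaf, homoplasic


# ---------------------------------------------------------------------------
# Branch VAF comparison (Wilcoxon rank-sum)


def compare_branch_vafs(set_a, set_b, exact_max_n: int = 10) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p value.

    Exact permutation enumeration (on midranks, so ties are handled)
    when both samples have <= *exact_max_n* observations; otherwise the
    normal approximation with tie correction.

    Raises
    ------
    ValueError
        If either sample is empty.
    """
    a = np.asarray(list(set_a), dtype=float)
    b = np.asarray(list(set_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both VAF sets must be non-empty")
    n, m = a.size, b.size
    if n <= exact_max_n and m <= exact_max_n:
        pooled = np.concatenate([a, b])
        ranks = sps.rankdata(pooled)
        obs = ranks[:n].sum()
        center = n * (n + m + 1) / 2.0
        obs_dev = abs(obs - center)
        total = 0
        extreme = 0
        for comb in itertools.combinations(range(n + m), n):
            s = ranks[list(comb)].sum()
            total += 1
            if abs(s - center) >= obs_dev - 1e-9:
                extreme += 1
        return extreme / total
    return float(sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue)
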
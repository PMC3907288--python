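"""Ordered-multistate (Wagner) parsimony.

Characters are ordered integer states 0..k-1 with linear transformation
cost ``|i - j|`` between states, changes allowed in both directions.
Scoring uses the Sankoff dynamic programme; because the cost is linear,
the per-node min-plus transform is computed in O(k) with a forward and a
backward cumulative pass, vectorized across characters.

The module provides:

* exact tree scoring (:func:`wagner_length`);
* minimal ancestral-state reconstruction with selectable tie policies
  (:func:`ancestral_states`);
* Lundberg rooting — attaching a hypothetical all-ancestral-state taxon
  to the branch that increases total length least (:func:`lundberg_root`);
* heuristic tree search with random-addition starts and NNI/SPR hill
  climbing (:func:`heuristic_search`);
* non-parametric bootstrap over characters (:func:`bootstrap_support`);
* parsimony fit statistics: retention index and the g1 skewness of the
  random-tree length distribution (:func:`fit_statistics`).

All stochastic operations take explicit seeds and are deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .census import CodedMatrix
from .trees import Node, PhyloTree

__all__ = [
    "FitStatistics",
    "Reconstruction",
    "LundbergResult",
    "SearchConfig",
    "SearchResult",
    "wagner_length",
    "per_character_lengths",
    "identify_informative",
    "informative_mask",
    "ancestral_states",
    "lundberg_root",
    "heuristic_search",
    "random_topology",
    "bootstrap_support",
    "fit_statistics",
    "prune_to_taxa",
    "name_internal_nodes",
]

logger = logging.getLogger(__name__)

_BIG = np.int64(1) << 40  # effectively infinite; sums never overflow int64

TIE_POLICIES = ("closest_to_parent", "deltran", "acctran")


# ----------------------------------------------------------------------
# numeric core
# ----------------------------------------------------------------------
def _minplus(S: np.ndarray) -> np.ndarray:
    """Min-plus transform under linear cost: ``T[..., j] = min_i
    S[..., i] + |i - j|`` computed with two cumulative passes."""
    T = S.copy()
    k = T.shape[-1]
    for j in range(1, k):
        np.minimum(T[..., j], T[..., j - 1] + 1, out=T[..., j])
    for j in range(k - 2, -1, -1):
        np.minimum(T[..., j], T[..., j + 1] + 1, out=T[..., j])
    return T


class _Engine:
    """Sankoff machinery bound to one coded matrix (and optional integer
    character weights, used by the bootstrap)."""

    def __init__(self, m: CodedMatrix, weights: Optional[np.ndarray] = None):
        self.k = m.k
        self.n_chars = m.n_characters
        self.states = m.states  # (n_taxa, n_chars)
        self.index = {t: i for i, t in enumerate(m.taxa)}
        if weights is None:
            weights = np.ones(self.n_chars, dtype=np.int64)
        self.weights = np.asarray(weights, dtype=np.int64)

    def check_tree(self, tree: PhyloTree) -> None:
        tree_set = set(tree.leaf_labels())
        mat_set = set(self.index)
        if tree_set != mat_set:
            only_tree = sorted(tree_set - mat_set)
            only_mat = sorted(mat_set - tree_set)
            raise ValueError(
                "tree leaves and matrix taxa differ; only in tree: "
                f"{only_tree}, only in matrix: {only_mat}")

    def leaf_D(self, label: str) -> np.ndarray:
        s = self.states[self.index[label]]  # (n_chars,)
        D = np.full((self.n_chars, self.k), _BIG, dtype=np.int64)
        D[np.arange(self.n_chars), s] = 0
        return D

    def leaf_M(self, label: str) -> np.ndarray:
        s = self.states[self.index[label]]
        return np.abs(np.arange(self.k)[None, :] - s[:, None]).astype(np.int64)

    def down(self, root: Node) -> tuple[dict, dict]:
        """Post-order pass.  Returns ``D`` (subtree cost vectors) and
        ``M`` (= minplus(D), the subtree-plus-parent-edge vectors),
        keyed by node identity."""
        D: dict[int, np.ndarray] = {}
        M: dict[int, np.ndarray] = {}
        stack, order = [root], []
        while stack:
            n = stack.pop()
            order.append(n)
            stack.extend(n.children)
        for n in reversed(order):
            if n.is_leaf:
                D[id(n)] = self.leaf_D(n.label)
                M[id(n)] = self.leaf_M(n.label)
            else:
                acc = M[id(n.children[0])].copy()
                for c in n.children[1:]:
                    acc += M[id(c)]
                D[id(n)] = acc
                M[id(n)] = _minplus(acc)
        return D, M

    def up(self, root: Node, D: dict, M: dict) -> dict:
        """Pre-order pass.  ``R[v]`` is the cost of everything outside the
        subtree of ``v`` — including the edge above ``v`` — as a function
        of the state at ``v``.  ``R[root] = 0``."""
        R = {id(root): np.zeros((self.n_chars, self.k), dtype=np.int64)}
        stack = [root]
        while stack:
            u = stack.pop()
            if u.is_leaf:
                continue
            base = D[id(u)] + R[id(u)]
            for v in u.children:
                R[id(v)] = _minplus(base - M[id(v)])
                stack.append(v)
        return R

    def per_char_lengths(self, tree: PhyloTree) -> np.ndarray:
        D, _ = self.down(tree.root)
        return D[id(tree.root)].min(axis=1)

    def length(self, tree: PhyloTree) -> int:
        return int(self.per_char_lengths(tree) @ self.weights)

    def insertion_totals(self, tree: PhyloTree, Mx: np.ndarray) -> list[int]:
        """Total tree length after attaching a subtree with edge-vector
        ``Mx`` onto each edge of ``tree`` (edges in post-order)."""
        D, M = self.down(tree.root)
        R = self.up(tree.root, D, M)
        out = []
        for v in tree.edges():
            tot = (R[id(v)] + M[id(v)] + Mx).min(axis=1)
            out.append(int(tot @ self.weights))
        return out


# ----------------------------------------------------------------------
# results containers
# ----------------------------------------------------------------------
@dataclass
class FitStatistics:
    tree_length: int
    per_char_lengths: Optional[np.ndarray] = None
    ri: Optional[float] = None
    g1: Optional[float] = None
    n_informative: Optional[int] = None


@dataclass
class Reconstruction:
    """Minimal-length ancestral state assignment for every character.

    ``states`` maps each node of ``tree`` (by object identity) to its
    (n_characters,) state vector; leaf vectors equal the matrix rows.
    """

    tree: PhyloTree
    matrix: CodedMatrix
    states: dict  # Node -> np.ndarray (n_chars,)
    policy: str
    ancestor_state: Optional[int] = None

    @property
    def total_length(self) -> int:
        total = 0
        for v in self.tree.edges():
            total += int(np.abs(self.states[v] - self.states[v.parent]).sum())
        return total


@dataclass
class LundbergResult:
    tree: PhyloTree  # rooted
    ancestor_state: int
    length_increase: int
    branch_index: int  # post-order edge index chosen in the unrooted tree


@dataclass
class SearchConfig:
    """Heuristic search effort knobs.

    ``n_starts`` random-addition starting trees are each refined by NNI
    hill climbing; when ``use_spr`` is set, rounds of subtree prune and
    regraft are interleaved until no move improves (up to
    ``max_spr_rounds`` SPR sweeps per start).
    """

    n_starts: int = 5
    use_spr: bool = True
    max_spr_rounds: int = 3
    max_nni_sweeps: int = 200


@dataclass
class SearchResult:
    tree: PhyloTree  # unrooted
    length: int
    start_lengths: list[int] = field(default_factory=list)
    log: list[tuple] = field(default_factory=list)  # (start, stage, length)


# ----------------------------------------------------------------------
# scoring and informativeness
# ----------------------------------------------------------------------
def wagner_length(tree: PhyloTree, m: CodedMatrix) -> FitStatistics:
    """Minimal total number of steps of ``tree`` on ``m`` under linear
    (ordered) costs; root placement does not affect the score."""
    eng = _Engine(m)
    eng.check_tree(tree)
    per_char = eng.per_char_lengths(tree)
    return FitStatistics(tree_length=int(per_char.sum()),
                         per_char_lengths=per_char)


def per_character_lengths(tree: PhyloTree, m: CodedMatrix) -> np.ndarray:
    eng = _Engine(m)
    eng.check_tree(tree)
    return eng.per_char_lengths(tree)


def _char_min_steps(m: CodedMatrix) -> np.ndarray:
    """Minimal steps of each character on *any* tree: the state range
    (achieved on a caterpillar ordered by state)."""
    return (m.states.max(axis=0) - m.states.min(axis=0)).astype(np.int64)


def _char_max_steps(m: CodedMatrix) -> np.ndarray:
    """Maximal steps: length on the completely unresolved (star) tree,
    ``min_s sum_t |x_t - s|`` (the best single median state)."""
    grid = np.abs(m.states[:, :, None] - np.arange(m.k)[None, None, :])
    return grid.sum(axis=0).min(axis=1).astype(np.int64)


def informative_mask(m: CodedMatrix) -> np.ndarray:
    """Boolean mask of parsimony-informative characters.

    An ordered character is informative iff its minimal length varies
    across topologies, which holds exactly when its star-tree length
    exceeds its state range (verified by enumeration in the test suite).
    """
    return _char_max_steps(m) > _char_min_steps(m)


def identify_informative(m: CodedMatrix) -> list[str]:
    if m.n_taxa < 4:
        raise ValueError("informativeness requires at least 4 taxa")
    mask = informative_mask(m)
    return [c for c, keep in zip(m.characters, mask) if keep]


# ----------------------------------------------------------------------
# ancestral states
# ----------------------------------------------------------------------
def _choose_states(cost: np.ndarray, prefer: np.ndarray, policy: str) -> np.ndarray:
    """Row-wise argmin of ``cost`` (n_chars, k) with ties resolved
    relative to the per-character preferred state ``prefer``:
    closest-to-parent policies keep the admissible state nearest
    ``prefer``; acctran keeps the farthest; remaining ties break to the
    smallest state."""
    k = cost.shape[1]
    best = cost.min(axis=1, keepdims=True)
    admissible = cost == best
    dist = np.abs(np.arange(k)[None, :] - prefer[:, None])
    if policy == "acctran":
        key = (k - dist) * (k + 1) + np.arange(k)[None, :]
    else:
        key = dist * (k + 1) + np.arange(k)[None, :]
    key = np.where(admissible, key, np.iinfo(np.int64).max)
    return key.argmin(axis=1).astype(np.int64)


def ancestral_states(tree: PhyloTree, m: CodedMatrix,
                     policy: str = "acctran",
                     ancestor_state: Optional[int] = None) -> Reconstruction:
    """Assign a minimal-length state to every node of a rooted tree.

    The down-pass computes exact Sankoff cost vectors; the top-down pass
    picks, at each node, a state achieving the minimum of
    ``D[node][s] + |s - parent_state|`` (any such choice preserves global
    optimality).  Ties are resolved by ``policy``:

    * ``closest_to_parent`` (default; alias ``deltran``) — stay as close
      to the parent state as possible, delaying changes tipward;
    * ``acctran`` — move as far from the parent as the admissible set
      allows, accelerating changes onto the earliest possible branch.

    At the root, ties are broken toward ``ancestor_state`` (the
    polarization ancestor) when given, else toward state 0.
    """
    if not tree.rooted:
        raise ValueError("tree is unrooted; root it first "
                         "(see lundberg_root)")
    if policy not in TIE_POLICIES:
        raise ValueError(f"unknown tie policy {policy!r}; "
                         f"choose from {TIE_POLICIES}")
    eng = _Engine(m)
    eng.check_tree(tree)
    D, _ = eng.down(tree.root)

    states: dict[Node, np.ndarray] = {}
    # The ancestor breaks ties only; it must not enter the root cost, so
    # that the assignment length equals the (rooting-invariant) Wagner
    # length for every tie policy.
    anc = 0 if ancestor_state is None else int(ancestor_state)
    prefer = np.full(m.n_characters, anc, dtype=np.int64)
    states[tree.root] = _choose_states(D[id(tree.root)], prefer,
                                       "closest_to_parent")

    stack = list(tree.root.children)
    while stack:
        v = stack.pop()
        sp = states[v.parent]
        cost = D[id(v)] + np.abs(np.arange(m.k)[None, :] - sp[:, None])
        states[v] = _choose_states(cost, sp, policy)
        stack.extend(v.children)

    for leaf in tree.leaves():  # leaves are pinned by construction
        assert np.array_equal(states[leaf], m.states[eng.index[leaf.label]])
    return Reconstruction(tree=tree, matrix=m, states=states, policy=policy,
                          ancestor_state=ancestor_state)


# ----------------------------------------------------------------------
# Lundberg rooting
# ----------------------------------------------------------------------
def lundberg_root(tree: PhyloTree, m: CodedMatrix,
                  ancestor_state: int) -> LundbergResult:
    """Root an unrooted tree by the Lundberg criterion.

    A hypothetical ancestor with ``ancestor_state`` at every character is
    attached in turn to every branch; the branch with the minimum total
    length increase wins (ties: first branch in post-order enumeration).
    The returned tree is rooted on that branch; the ancestor itself is
    not kept as a leaf.
    """
    if tree.rooted:
        raise ValueError("lundberg_root expects an unrooted tree")
    if not 0 <= ancestor_state < m.k:
        raise ValueError(f"ancestor state {ancestor_state} outside 0..{m.k-1}")
    eng = _Engine(m)
    eng.check_tree(tree)
    baseline = eng.length(tree)
    anc_M = np.broadcast_to(
        np.abs(np.arange(m.k) - ancestor_state).astype(np.int64),
        (m.n_characters, m.k))
    totals = eng.insertion_totals(tree, anc_M)
    best_idx = int(np.argmin(totals))
    increase = int(totals[best_idx] - baseline)
    edges = tree.edges()
    rooted = tree.root_on_edge(edges[best_idx])
    logger.info("Lundberg rooting: branch %d of %d, length increase %d",
                best_idx, len(edges), increase)
    return LundbergResult(tree=rooted, ancestor_state=ancestor_state,
                          length_increase=increase, branch_index=best_idx)


# ----------------------------------------------------------------------
# tree search
# ----------------------------------------------------------------------
def _hub_tree(labels: Sequence[str]) -> PhyloTree:
    root = Node()
    for l in labels:
        root.add_child(Node(l))
    return PhyloTree(root, rooted=False)


def _attach_on_edge(tree: PhyloTree, child: Node, new_leaf: Node) -> None:
    u = child.parent
    w = Node()
    idx = u.children.index(child)
    u.children[idx] = w
    w.parent = u
    w.add_child(child)
    w.add_child(new_leaf)


def _stepwise_addition(m: CodedMatrix, order: Sequence[str],
                       eng: _Engine) -> PhyloTree:
    tree = _hub_tree(order[:3])
    for label in order[3:]:
        totals = eng.insertion_totals(tree, eng.leaf_M(label))
        best = int(np.argmin(totals))
        _attach_on_edge(tree, tree.edges()[best], Node(label))
    return tree


def _nni_candidates(tree: PhyloTree):
    """Yield (u, b, v, c): swap child ``b`` of ``u`` with child ``c`` of
    ``v``, for every internal edge (u, v)."""
    for v in tree.edges():
        if v.is_leaf:
            continue
        u = v.parent
        others = [x for x in u.children if x is not v]
        if not others:
            continue
        b = others[0]
        for c in v.children:
            yield u, b, v, c


def _apply_swap(u: Node, b: Node, v: Node, c: Node) -> None:
    iu, iv = u.children.index(b), v.children.index(c)
    u.children[iu], v.children[iv] = c, b
    c.parent, b.parent = u, v


def _nni_hill_climb(tree: PhyloTree, eng: _Engine, max_sweeps: int,
                    log: list, start: int) -> int:
    """Steepest-descent NNI; mutates ``tree`` in place; returns length."""
    w = eng.weights
    current = eng.length(tree)
    for _ in range(max_sweeps):
        D, M = eng.down(tree.root)
        R = eng.up(tree.root, D, M)
        best_delta, best_move = 0, None
        for u, b, v, c in _nni_candidates(tree):
            rest_u = D[id(u)] - M[id(v)] - M[id(b)] + R[id(u)]
            new_Dv = D[id(v)] - M[id(c)] + M[id(b)]
            total = ((rest_u + M[id(c)] + _minplus(new_Dv)).min(axis=1) @ w)
            delta = int(total) - current
            if delta < best_delta:
                best_delta, best_move = delta, (u, b, v, c)
        if best_move is None:
            break
        _apply_swap(*best_move)
        current += best_delta
        log.append((start, "nni", current))
    return current


def _spr_round(tree: PhyloTree, eng: _Engine, current: int,
               log: list, start: int) -> tuple[PhyloTree, int, bool]:
    """One sweep of subtree prune and regraft (best improving move)."""
    w = eng.weights
    edges = tree.edges()
    best = (0, None)  # (delta, (prune_idx, regraft_idx))
    for pi, sub in enumerate(edges):
        parent = sub.parent
        if parent is tree.root and len(tree.root.children) <= 3 and sub.is_leaf:
            pass  # still valid: remaining tree keeps >= 2 other lineages
        # detach on a scratch copy
        work = tree.copy()
        w_edges = work.edges()
        wsub = w_edges[pi]
        wpar = wsub.parent
        wpar.remove_child(wsub)
        work.suppress_unifurcations()
        if work.n_leaves() < 3 or wsub is work.root:
            continue
        Dsub, _ = eng.down(wsub)
        Mx = _minplus(Dsub[id(wsub)])
        totals = eng.insertion_totals(work, Mx)
        ri = int(np.argmin(totals))
        delta = int(totals[ri]) - current
        if delta < best[0]:
            best = (delta, (pi, ri))
    if best[1] is None:
        return tree, current, False
    pi, ri = best[1]
    work = tree.copy()
    wsub = work.edges()[pi]
    wsub.parent.remove_child(wsub)
    work.suppress_unifurcations()
    _attach_on_edge(work, work.edges()[ri], wsub)
    if not work.rooted and len(work.root.children) == 2:
        work = work.unroot()  # re-collapse the hub if pruning emptied it
    current += best[0]
    log.append((start, "spr", current))
    return work, current, True


def heuristic_search(m: CodedMatrix, config: Optional[SearchConfig] = None,
                     seed: int = 0) -> SearchResult:
    """Maximum-parsimony tree search.

    Each start builds a greedy stepwise-addition tree from a random
    taxon-addition order, then hill-climbs with NNI (and SPR rounds when
    enabled) until no move shortens the tree.  Deterministic given
    ``seed``.  Returns the best (unrooted, binary) tree found.
    """
    if m.n_taxa < 4:
        raise ValueError("heuristic search requires at least 4 taxa")
    config = config or SearchConfig()
    rng = np.random.default_rng(seed)
    eng = _Engine(m)
    best_tree, best_len = None, None
    start_lengths, log = [], []
    for s in range(config.n_starts):
        order = list(m.taxa)
        rng.shuffle(order)
        tree = _stepwise_addition(m, order, eng)
        length = eng.length(tree)
        start_lengths.append(length)
        log.append((s, "start", length))
        length = _nni_hill_climb(tree, eng, config.max_nni_sweeps, log, s)
        if config.use_spr:
            for _ in range(config.max_spr_rounds):
                tree, length, moved = _spr_round(tree, eng, length, log, s)
                if not moved:
                    break
                length = _nni_hill_climb(tree, eng, config.max_nni_sweeps,
                                         log, s)
        if best_len is None or length < best_len:
            best_tree, best_len = tree, length
    return SearchResult(tree=best_tree, length=best_len,
                        start_lengths=start_lengths, log=log)


def random_topology(labels: Sequence[str], rng: np.random.Generator) -> PhyloTree:
    """Uniform random unrooted binary topology via sequential addition
    to a uniformly chosen edge."""
    labels = list(labels)
    tree = _hub_tree(labels[:3])
    for label in labels[3:]:
        edges = tree.edges()
        child = edges[rng.integers(len(edges))]
        _attach_on_edge(tree, child, Node(label))
    return tree


# ----------------------------------------------------------------------
# bootstrap
# ----------------------------------------------------------------------
def bootstrap_support(m: CodedMatrix, tree: PhyloTree,
                      n_replicates: int = 1000, seed: int = 0,
                      config: Optional[SearchConfig] = None) -> dict:
    """Character bootstrap: percent of replicate trees containing each
    non-trivial bipartition of ``tree``.

    Replicate searches use reduced effort (one random-addition start plus
    NNI) for tractability; resampling is implemented as integer character
    weights.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    config = config or SearchConfig(n_starts=1, use_spr=False)
    rng = np.random.default_rng(seed)
    target = {bp: 0 for bp in (tree.unroot() if tree.rooted else tree).bipartitions()}
    for _ in range(n_replicates):
        weights = rng.multinomial(m.n_characters,
                                  np.full(m.n_characters, 1.0 / m.n_characters))
        eng = _Engine(m, weights=weights)
        order = list(m.taxa)
        rng.shuffle(order)
        rep_tree = _stepwise_addition(m, order, eng)
        _nni_hill_climb(rep_tree, eng, config.max_nni_sweeps, [], 0)
        rep_bps = rep_tree.bipartitions()
        for bp in target:
            if bp in rep_bps:
                target[bp] += 1
    return {bp: 100.0 * n / n_replicates for bp, n in target.items()}


# ----------------------------------------------------------------------
# fit statistics
# ----------------------------------------------------------------------
def fit_statistics(tree: PhyloTree, m: CodedMatrix,
                   n_random_trees: int = 1000, seed: int = 0) -> FitStatistics:
    """Tree length, ensemble retention index over informative characters,
    and the g1 skewness of the length distribution of uniformly random
    topologies.

    RI = (sum G - sum S) / (sum G - sum M) with S the observed steps, M
    the character's minimum on any tree (its state range) and G its
    maximum (star-tree length).  RI is reported as ``None`` when G = M
    for every informative character.
    """
    per_char = per_character_lengths(tree, m)
    mask = informative_mask(m)
    M = _char_min_steps(m)
    G = _char_max_steps(m)
    denom = int((G[mask] - M[mask]).sum())
    ri = None
    if denom > 0:
        ri = float((G[mask] - per_char[mask]).sum() / denom)

    rng = np.random.default_rng(seed)
    eng = _Engine(m)
    lengths = np.empty(n_random_trees, dtype=np.int64)
    for i in range(n_random_trees):
        lengths[i] = eng.length(random_topology(m.taxa, rng))
    # skewness is undefined for a constant length distribution
    g1 = float(sps.skew(lengths)) if np.ptp(lengths) > 0 else None
    return FitStatistics(tree_length=int(per_char.sum()),
                         per_char_lengths=per_char, ri=ri, g1=g1,
                         n_informative=int(mask.sum()))


# ----------------------------------------------------------------------
# misc
# ----------------------------------------------------------------------
def prune_to_taxa(tree: PhyloTree, keep) -> PhyloTree:
    """Induced subtree on ``keep`` with degree-2 nodes suppressed (the
    root is kept while it still separates two surviving lineages)."""
    return tree.prune_to(keep)


def name_internal_nodes(tree: PhyloTree, prefix: str = "N") -> PhyloTree:
    """Assign deterministic pre-order names to unlabeled internal nodes
    (in place); returns the tree for chaining."""
    i = 0
    for n in tree.preorder():
        if not n.is_leaf and not n.label:
            n.label = f"{prefix}{i}"
            i += 1
    return tree
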
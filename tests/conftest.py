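"""Shared fixtures and independent brute-force oracles.

The oracles enumerate internal-state assignments or whole topologies
directly and never touch the dynamic-programming code they are used to
check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from domevo.census import CodedMatrix, build_abundance_matrix
from domevo.trees import Node, PhyloTree

ABC = "0123456789ABCDEFGHIJKLMN"


# ----------------------------------------------------------------------
# brute-force oracles
# ----------------------------------------------------------------------
def _enumerated_costs(tree: PhyloTree, leaf_states: dict, k: int):
    """Total length of every internal-state assignment, by exhaustive
    enumeration (vectorized over the k^n_internal grid)."""
    internals = [n for n in tree.postorder() if not n.is_leaf]
    idx = {id(n): i for i, n in enumerate(internals)}
    grid = np.indices((k,) * len(internals)).reshape(len(internals), -1)
    total = np.zeros(grid.shape[1], dtype=np.int64)
    for v in tree.edges():
        child = (np.full(grid.shape[1], leaf_states[v.label])
                 if v.is_leaf else grid[idx[id(v)]])
        total += np.abs(child - grid[idx[id(v.parent)]])
    return internals, grid, total


def brute_wagner_length(tree: PhyloTree, leaf_states: dict, k: int) -> int:
    """Minimal total |state difference| over all internal assignments."""
    _, _, total = _enumerated_costs(tree, leaf_states, k)
    return int(total.min())


def brute_minimal_assignments(tree: PhyloTree, leaf_states: dict, k: int):
    """All internal assignments achieving the minimal length; each is a
    dict node-id -> state (leaves included)."""
    internals, grid, total = _enumerated_costs(tree, leaf_states, k)
    best = int(total.min())
    out = []
    for col in np.nonzero(total == best)[0]:
        amap = {id(n): int(grid[i, col]) for i, n in enumerate(internals)}
        for n in tree.postorder():
            if n.is_leaf:
                amap[id(n)] = leaf_states[n.label]
        out.append(amap)
    return best, out


def all_unrooted_topologies(labels):
    """Every unrooted binary topology on the given labels (3 -> 1 tree,
    4 -> 3, 5 -> 15, 6 -> 105)."""
    from domevo.parsimony import _attach_on_edge, _hub_tree

    trees = [_hub_tree(labels[:3])]
    for label in labels[3:]:
        nxt = []
        for t in trees:
            for i in range(len(t.edges())):
                c = t.copy()
                _attach_on_edge(c, c.edges()[i], Node(label))
                nxt.append(c)
        trees = nxt
    return trees


def single_char_matrix(states: dict, k: int) -> CodedMatrix:
    taxa = sorted(states)
    return CodedMatrix(taxa=taxa, characters=["c1"],
                       states=np.array([[states[t]] for t in taxa]),
                       k=k, symbols=ABC[:k])


def multi_char_matrix(states: np.ndarray, k: int,
                      taxa=None) -> CodedMatrix:
    states = np.asarray(states)
    taxa = taxa or [f"t{i}" for i in range(states.shape[0])]
    return CodedMatrix(taxa=list(taxa),
                       characters=[f"c{j}" for j in range(states.shape[1])],
                       states=states, k=k, symbols=ABC[:k])


# ----------------------------------------------------------------------
# fixtures
# ----------------------------------------------------------------------
@pytest.fixture()
def assignment_frame():
    """Small three-superkingdom census in long format."""
    rows = [
        ("arc1", "A", "c.37.1.12", 5), ("arc1", "A", "d.122.1.1", 1),
        ("arc2", "A", "c.37.1.12", 3), ("arc2", "A", "a.1.1.2", 2),
        ("bac1", "B", "c.37.1.12", 2), ("bac1", "B", "b.40.4.5", 7),
        ("bac2", "B", "b.40.4.5", 4), ("bac2", "B", "a.1.1.2", 1),
        ("euk1", "E", "c.37.1.12", 9), ("euk1", "E", "d.122.1.1", 6),
        ("euk2", "E", "d.122.1.1", 2), ("euk2", "E", "b.40.4.5", 1),
    ]
    return pd.DataFrame(rows, columns=["proteome_id", "superkingdom",
                                       "css", "count"])


@pytest.fixture()
def small_matrix(assignment_frame):
    return build_abundance_matrix(assignment_frame)


@pytest.fixture()
def assignment_tsv(tmp_path, assignment_frame):
    path = tmp_path / "assignments.tsv"
    assignment_frame.to_csv(path, sep="\t", index=False)
    return path


@pytest.fixture(scope="session")
def sim_small():
    """A small simulated dataset shared across tests (12 taxa, 60 FFs)."""
    from domevo.simulate import SimulationConfig, simulate_dataset
    cfg = SimulationConfig(seed=42, n_taxa=(4, 4, 4), n_ffs=60)
    tree, matrix, truth = simulate_dataset(cfg)
    return tree, matrix, truth
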
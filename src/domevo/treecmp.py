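"""Topological congruence between trees via nodal RMSD.

For two trees on the same taxa, each unordered leaf pair contributes the
difference between its path lengths (counted in edges; in rooted trees a
path may run through the root, which therefore contributes to the
distance) in the two trees:

    RMSD = sqrt( sum_pairs (d1 - d2)^2 / n_pairs )

RMSD is 0 for identical trees and grows with incongruence.  Significance
is assessed with a guided randomization test: leaf labels of one tree
are permuted uniformly while the topology is kept, the RMSD is
recomputed per replicate, and the observed value is compared with the
mean of the resulting null distribution (observed below the mean =
more congruent than chance).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .trees import PhyloTree

__all__ = ["ComparisonResult", "leaf_distance_matrix", "nodal_rmsd",
           "guided_randomization_test"]


@dataclass
class ComparisonResult:
    rmsd: float
    random_mean: Optional[float] = None
    random_sd: Optional[float] = None
    n_replicates: Optional[int] = None
    empirical_p: Optional[float] = None
    significant: Optional[bool] = None  # observed below the random mean

    def to_dict(self) -> dict:
        return {"rmsd": self.rmsd, "random_mean": self.random_mean,
                "random_sd": self.random_sd,
                "n_replicates": self.n_replicates,
                "empirical_p": self.empirical_p,
                "significant": self.significant}


def leaf_distance_matrix(tree: PhyloTree) -> tuple[list, np.ndarray]:
    """Pairwise leaf path lengths in edge counts, labels sorted."""
    adj: dict[int, list] = {}
    nodes = list(tree.postorder())
    for n in nodes:
        adj.setdefault(id(n), [])
        for c in n.children:
            adj[id(n)].append(c)
            adj.setdefault(id(c), []).append(n)
    leaves = sorted(tree.leaves(), key=lambda n: n.label)
    labels = [n.label for n in leaves]
    index = {id(n): i for i, n in enumerate(leaves)}
    n_leaves = len(leaves)
    D = np.zeros((n_leaves, n_leaves), dtype=np.int64)
    for i, src in enumerate(leaves):
        dist = {id(src): 0}
        queue = deque([src])
        while queue:
            u = queue.popleft()
            for v in adj[id(u)]:
                if id(v) not in dist:
                    dist[id(v)] = dist[id(u)] + 1
                    queue.append(v)
        for nid, d in dist.items():
            j = index.get(nid)
            if j is not None:
                D[i, j] = d
    return labels, D


def _rmsd(D1: np.ndarray, D2: np.ndarray) -> float:
    n = D1.shape[0]
    iu = np.triu_indices(n, k=1)
    diff = D1[iu].astype(float) - D2[iu].astype(float)
    return float(np.sqrt(np.mean(diff ** 2)))


def nodal_rmsd(t1: PhyloTree, t2: PhyloTree) -> ComparisonResult:
    """Observed nodal RMSD between two trees on identical leaf sets."""
    l1, D1 = leaf_distance_matrix(t1)
    l2, D2 = leaf_distance_matrix(t2)
    if l1 != l2:
        only1 = sorted(set(l1) - set(l2))
        only2 = sorted(set(l2) - set(l1))
        raise ValueError(f"leaf sets differ; only in first: {only1}, "
                         f"only in second: {only2}")
    return ComparisonResult(rmsd=_rmsd(D1, D2))


def guided_randomization_test(t1: PhyloTree, t2: PhyloTree,
                              reps: int = 100, seed: int = 0) -> ComparisonResult:
    """Randomization test of the observed nodal RMSD.

    Per replicate the leaf labels of the second tree are permuted
    uniformly (the topology is unchanged; permuting one tree is
    equivalent in distribution to permuting both).  The empirical p uses
    add-one smoothing: p = (1 + #{random RMSD <= observed}) / (reps + 1),
    so a perfect observed value reports 1/(reps+1) rather than 0.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    l1, D1 = leaf_distance_matrix(t1)
    l2, D2 = leaf_distance_matrix(t2)
    if l1 != l2:
        raise ValueError("leaf sets differ between the two trees")
    observed = _rmsd(D1, D2)
    rng = np.random.default_rng(seed)
    n = len(l1)
    randoms = np.empty(reps)
    for r in range(reps):
        perm = rng.permutation(n)
        randoms[r] = _rmsd(D1, D2[np.ix_(perm, perm)])
    mean = float(randoms.mean())
    sd = float(randoms.std(ddof=1)) if reps > 1 else 0.0
    p = float((1 + np.sum(randoms <= observed)) / (reps + 1))
    return ComparisonResult(rmsd=observed, random_mean=mean, random_sd=sd,
                            n_replicates=reps, empirical_p=p,
                            significant=observed < mean)
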
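"""Synthetic fold-family censuses with known evolutionary histories.

A random rooted species tree with three labeled superkingdom clades is
generated, and each fold family then evolves along it by three
processes, giving ground truth for every stage of the pipeline:

* **origination** — each family arises exactly once, on a branch drawn
  from a two-component origination process that mirrors real censuses:
  an *ancient* component concentrated near the root (including the stem
  lineage above it, whose families are ancestrally universal — the
  analogue of the fold families shared by all superkingdoms) and a
  *recent* component weighted toward the tips (the analogue of
  late-appearing superkingdom-specific novelty);
* **duplication** — on each branch where the family is present with
  ``a`` copies, its copy number increases by a
  Poisson(duplication_rate * a) draw: duplication acts per existing
  copy, so old families accumulate abundance multiplicatively, the
  feature real censuses show (and the one the tree-of-domains timeline
  exploits);
* **loss** — likewise decreases by a Poisson(loss_rate * a) draw,
  floored at zero; a family whose count reaches zero is extinct in that
  lineage and stays absent below it.

Branches have unit length (the downstream parsimony trees are
unitless), so rates are events per branch per family.  Superkingdom
rate multipliers apply to branches lying entirely inside one
superkingdom clade.

Ground truth records the origination branch and depth of every family,
every per-branch copy-number change, and the final abundance of every
(taxon, family) cell; replaying the events reproduces the emitted
census exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd

from .census import AbundanceMatrix, build_abundance_matrix
from .parsimony import name_internal_nodes
from .trees import Node, PhyloTree

__all__ = ["SimulationConfig", "SimTruth", "simulate_taxon_tree",
           "simulate_domain_histories", "simulate_dataset", "emit_dataset"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic census.

    Defaults: 50 taxa split 17/17/16 across Archaea/Bacteria/Eukarya on
    ladder-shaped clades (published domain-census trees of life are
    strongly ladderized), 200 fold families.  Duplication acts per copy
    at 0.7 per branch against a loss rate of 0.14, a gain-biased regime
    that compounds into the strong old-family abundance excess real
    censuses show.  Originations are a 45/55 mixture of a root-biased
    ancient component and a tip-biased recent component, mirroring the
    real split between broadly shared ancient families and late,
    lineage-specific novelty.
    """

    seed: int
    n_taxa: tuple = (17, 17, 16)  # per superkingdom, A/B/E order
    n_ffs: int = 200
    origination_rate: float = 1.0
    duplication_rate: float = 0.7
    loss_rate: float = 0.14
    ancient_fraction: float = 0.45  # share of root-biased originations
    depth_bias: float = 1.5         # root-ward decay, ancient component
    recent_bias: float = 2.0        # tip-ward growth, recent component
    tree_shape: str = "ladder"      # "ladder" | "balanced" clades
    sk_multipliers: tuple = (1.0, 1.0, 1.0)  # A, B, E rate multipliers

    def __post_init__(self):
        if min(self.origination_rate, self.duplication_rate,
               self.loss_rate) < 0:
            raise ValueError("rates must be non-negative")
        if len(self.n_taxa) != 3:
            raise ValueError("n_taxa must give counts for A, B, E")
        if not 0 <= self.ancient_fraction <= 1:
            raise ValueError("ancient_fraction must lie in [0, 1]")
        if self.tree_shape not in ("ladder", "balanced"):
            raise ValueError("tree_shape must be 'ladder' or 'balanced'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SimTruth:
    """Complete event-level history behind a simulated census."""

    tree: PhyloTree  # rooted, internal nodes named
    origins: pd.DataFrame    # ff, branch (child label), depth, rel_depth
    events: pd.DataFrame     # ff, parent, child, n_dup, n_loss, delta
    abundance: pd.DataFrame  # taxa x ff, including zeros
    config: SimulationConfig

    def replay(self) -> pd.DataFrame:
        """Recompute leaf abundances from the recorded events; equality
        with ``abundance`` is the core bookkeeping invariant."""
        origin_of = dict(zip(self.origins["ff"], self.origins["branch"]))
        deltas = {(r.ff, r.child): r.delta
                  for r in self.events.itertuples(index=False)}
        out = pd.DataFrame(0, index=self.abundance.index,
                           columns=self.abundance.columns)
        order = [n for n in self.tree.preorder() if n.parent is not None]
        for ff in self.abundance.columns:
            stem = origin_of[ff] == self.tree.root.label
            values = {self.tree.root.label: 1 if stem else 0}
            for n in order:
                parent_val = values[n.parent.label]
                if n.label == origin_of[ff]:
                    v = 1  # origination fixes the copy number at one
                elif parent_val == 0:
                    v = 0  # absent or extinct above: stays absent
                else:
                    v = parent_val + deltas.get((ff, n.label), 0)
                values[n.label] = v
                if n.is_leaf:
                    out.loc[n.label, ff] = v
        return out

    def true_branch_net(self) -> pd.Series:
        """Branch-counted net change per family: branches with a copy
        number increase (the origination branch included) minus branches
        with a decrease."""
        gains = (self.events["delta"] > 0).groupby(self.events["ff"]).sum()
        losses = (self.events["delta"] < 0).groupby(self.events["ff"]).sum()
        ffs = self.origins["ff"]
        net = (gains.reindex(ffs, fill_value=0)
               - losses.reindex(ffs, fill_value=0) + 1)
        net.index = ffs
        return net

    def relative_origination(self) -> pd.Series:
        return self.origins.set_index("ff")["rel_depth"]


# ----------------------------------------------------------------------
def _balanced_clade(labels, rng: np.random.Generator) -> Node:
    """Random rooted binary clade by sequential random joins."""
    nodes = [Node(l) for l in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = Node()
        parent.add_child(a)
        parent.add_child(b)
        nodes.append(parent)
    return nodes[0]


def _ladder_clade(labels, rng: np.random.Generator) -> Node:
    """Fully pectinate clade with a random leaf order."""
    labels = list(labels)
    rng.shuffle(labels)
    node = Node(labels[0])
    for label in labels[1:]:
        parent = Node()
        parent.add_child(Node(label))
        parent.add_child(node)
        node = parent
    return node


def simulate_taxon_tree(config: SimulationConfig) -> PhyloTree:
    """Random rooted species tree with monophyletic A, B and E clades
    (arranged as (A,(B,E)), echoing a basal archaeal position)."""
    if min(config.n_taxa) < 4:
        raise ValueError("need at least 4 taxa per superkingdom")
    rng = np.random.default_rng(config.seed)
    width = len(str(max(config.n_taxa)))
    make = _ladder_clade if config.tree_shape == "ladder" else _balanced_clade
    clades = {}
    for sk, n in zip("ABE", config.n_taxa):
        labels = [f"{sk}{i+1:0{width}d}" for i in range(n)]
        clades[sk] = make(labels, rng)
    root = Node()
    inner = Node()
    inner.add_child(clades["B"])
    inner.add_child(clades["E"])
    root.add_child(clades["A"])
    root.add_child(inner)
    tree = PhyloTree(root, rooted=True)
    name_internal_nodes(tree, prefix="n")
    return tree


def _branch_superkingdom(tree: PhyloTree) -> dict:
    """Superkingdom index (0/1/2) for branches entirely inside one
    clade, None for inter-superkingdom branches; keyed by child label."""
    out = {}
    below: dict[int, set] = {}
    for n in tree.postorder():
        if n.is_leaf:
            below[id(n)] = {n.label[0]}
        else:
            below[id(n)] = set().union(*(below[id(c)] for c in n.children))
        if n.parent is not None:
            sks = below[id(n)]
            out[n.label] = "ABE".index(next(iter(sks))) if len(sks) == 1 else None
    return out


def simulate_domain_histories(tree: PhyloTree, config: SimulationConfig
                              ) -> tuple[AbundanceMatrix, SimTruth]:
    """Evolve fold-family copy numbers along ``tree``; see module
    docstring for the event model."""
    rng = np.random.default_rng(config.seed + 1)
    name_internal_nodes(tree, prefix="n")
    branches = tree.edges()  # post-order, child-identified
    depth = {id(tree.root): 0}
    for n in tree.preorder():
        if n.parent is not None:
            depth[id(n)] = depth[id(n.parent)] + 1
    max_leaf_depth = max(depth[id(l)] for l in tree.leaves())
    sk_of_branch = _branch_superkingdom(tree)

    # origination sites: the stem lineage above the root (index 0), then
    # every branch; two-component weighting (see module docstring)
    sites = [tree.root] + branches
    d = np.array([depth[id(b)] for b in sites], dtype=float)
    ancient = np.exp(-config.depth_bias * d)
    recent = np.exp(config.recent_bias * (d - d.max()))
    recent[0] = 0.0  # the recent component never hits the stem
    weights = (config.ancient_fraction * ancient / ancient.sum()
               + (1 - config.ancient_fraction) * recent / recent.sum())
    weights /= weights.sum()

    ffs = [f"a.{i+1}.1.1" for i in range(config.n_ffs)]  # synthetic css
    origin_rows, event_rows = [], []
    leaf_vals: dict[tuple, int] = {}
    leaves = tree.leaves()

    for fi, ff in enumerate(ffs):
        bi = rng.choice(len(sites), p=weights)
        origin = sites[bi]
        origin_rows.append({
            "ff": ff, "branch": origin.label,
            "depth": depth[id(origin)],
            "rel_depth": depth[id(origin)] / max_leaf_depth,
        })
        # evolve below the origination node
        values = {id(origin): 1}
        stack = [origin]
        while stack:
            p = stack.pop()
            for c in p.children:
                a = values[id(p)]
                if a == 0:
                    values[id(c)] = 0
                    continue
                sk = sk_of_branch.get(c.label)
                mult = config.sk_multipliers[sk] if sk is not None else 1.0
                n_dup = rng.poisson(config.duplication_rate * mult * a)
                n_loss = rng.poisson(config.loss_rate * mult * a)
                new = max(0, a + n_dup - n_loss)
                values[id(c)] = new
                if new != a:
                    event_rows.append({"ff": ff, "parent": p.label,
                                       "child": c.label, "n_dup": int(n_dup),
                                       "n_loss": int(n_loss),
                                       "delta": int(new - a)})
                stack.append(c)
        for leaf in leaves:
            leaf_vals[(leaf.label, ff)] = values.get(id(leaf), 0)

    abundance = pd.DataFrame(
        [[leaf_vals[(l.label, ff)] for ff in ffs] for l in leaves],
        index=[l.label for l in leaves], columns=ffs).sort_index()
    if abundance.to_numpy().max() == 0:
        raise ValueError("simulation produced an all-zero census; "
                         "increase rates or tree size")

    long = abundance.rename_axis("proteome_id").reset_index().melt(
        id_vars="proteome_id", var_name="css", value_name="count")
    long["superkingdom"] = long["proteome_id"].str[0]
    # keep positive cells; keep one zero row per taxon so every proteome
    # stays in the census even if it carries nothing
    keep = long["count"] > 0
    empty_taxa = set(abundance.index) - set(long.loc[keep, "proteome_id"])
    keep |= long["proteome_id"].isin(empty_taxa) & (long["css"] == ffs[0])
    matrix = build_abundance_matrix(long[keep])

    truth = SimTruth(tree=tree,
                     origins=pd.DataFrame(origin_rows),
                     events=pd.DataFrame(
                         event_rows, columns=["ff", "parent", "child",
                                              "n_dup", "n_loss", "delta"]),
                     abundance=abundance, config=config)
    return matrix, truth


def simulate_dataset(config: SimulationConfig
                     ) -> tuple[PhyloTree, AbundanceMatrix, SimTruth]:
    tree = simulate_taxon_tree(config)
    matrix, truth = simulate_domain_histories(tree, config)
    return tree, matrix, truth


def emit_dataset(m: AbundanceMatrix, truth: SimTruth, outdir) -> dict:
    """Write the assignment TSV, true tree, truth tables and a manifest;
    returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "assignments": outdir / "assignments.tsv",
        "tree": outdir / "true_tree.nwk",
        "origins": outdir / "truth_origins.tsv",
        "events": outdir / "truth_events.tsv",
        "manifest": outdir / "manifest.json",
    }
    long = (m.counts.rename_axis("proteome_id").reset_index()
            .melt(id_vars="proteome_id", var_name="css", value_name="count"))
    long["superkingdom"] = long["proteome_id"].str[0]
    long = long[long["count"] > 0].sort_values(["proteome_id", "css"])
    # every taxon must survive the round trip, with its superkingdom
    missing = set(m.counts.index) - set(long["proteome_id"])
    if missing:
        pad = pd.DataFrame({"proteome_id": sorted(missing),
                            "css": m.css_list[0], "count": 0})
        pad["superkingdom"] = pad["proteome_id"].str[0]
        long = pd.concat([long, pad], ignore_index=True)
    long[["proteome_id", "superkingdom", "css", "count"]].to_csv(
        paths["assignments"], sep="\t", index=False)
    truth.tree.to_newick(str(paths["tree"]))
    truth.origins.to_csv(paths["origins"], sep="\t", index=False)
    truth.events.to_csv(paths["events"], sep="\t", index=False)
    paths["manifest"].write_text(json.dumps(
        {"config": truth.config.to_dict()}, indent=2) + "\n")
    return paths
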
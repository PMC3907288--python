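"""Domain age timelines, distribution indices and persistence metrics.

A *tree of domains* (ToD) is built from the transposed character matrix
(fold families as taxa, proteomes as characters) and Lundberg-rooted
with an all-maximal-state hypothetical ancestor: under the assumption
that family abundance accumulates with time, the most ancestral
condition is maximal abundance in all proteomes.  Each family's relative
age is its node distance

    nd = (d - d_min) / (d_max - d_min)  in [0, 1]

where ``d`` counts the internal nodes on the root-to-leaf path; 0 is the
most ancient family, 1 the most recent.  A linear molecular clock maps
nd to geological age in Gy (billions of years before present).

Per-family distribution statistics: the f-value (fraction of proteomes
encoding the family) and the Venn taxonomic group (which of the seven
presence patterns across Archaea/Bacteria/Eukarya the family shows).
Per-proteome persistence metrics: economy (distinct families),
flexibility (summed abundance) and robustness (their ratio).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

from .census import AbundanceMatrix, CodedMatrix, SUPERKINGDOMS
from .gainloss import EpochBoundaries
from .parsimony import SearchConfig, heuristic_search, lundberg_root
from .trees import PhyloTree

__all__ = [
    "ClockCalibration",
    "VennSummary",
    "DEFAULT_CLOCK_ANCHORS",
    "VENN_GROUPS",
    "build_tod",
    "node_distances",
    "replicate_node_distances",
    "calibrate_age",
    "default_clock",
    "assign_epoch",
    "f_values",
    "venn_classify",
    "venn_totals",
    "persistence_metrics",
    "timeline_table",
]

logger = logging.getLogger(__name__)

#: Anchor points (nd, Gy before present) tying the relative timeline to
#: geological time: the archaeal streamlining event, the rise of
#: superkingdom-specific bacterial families, and the rise of Eukarya.
DEFAULT_CLOCK_ANCHORS = ((0.15, 3.2), (0.26, 2.8), (0.55, 1.6))

VENN_GROUPS = ("A", "B", "E", "AB", "AE", "BE", "ABE")


@dataclass
class ClockCalibration:
    """Linear map from relative age nd to geological age in Gy.

    ``age(nd) = intercept + slope * nd`` fitted by least squares through
    the anchor points; ages are clipped below at 0 Gy.  The slope must
    be negative (age decreases as nd grows).
    """

    anchors: tuple
    slope: float
    intercept: float

    @classmethod
    def fit(cls, anchors) -> "ClockCalibration":
        anchors = tuple((float(a), float(b)) for a, b in anchors)
        if len(anchors) < 2:
            raise ValueError("need at least two anchor points")
        nd = np.array([a for a, _ in anchors])
        gy = np.array([b for _, b in anchors])
        slope, intercept = np.polyfit(nd, gy, 1)
        if slope >= 0:
            raise ValueError("clock slope must be negative "
                             "(age decreasing in nd)")
        return cls(anchors=anchors, slope=float(slope),
                   intercept=float(intercept))

    def age(self, nd: Union[float, np.ndarray]) -> Union[float, np.ndarray]:
        out = self.intercept + self.slope * np.asarray(nd, dtype=float)
        out = np.clip(out, 0.0, None)
        return float(out) if out.ndim == 0 else out


def default_clock() -> ClockCalibration:
    return ClockCalibration.fit(DEFAULT_CLOCK_ANCHORS)


def calibrate_age(nd, clock: Optional[ClockCalibration] = None):
    """Geological age (Gy before present) for relative age(s) ``nd``."""
    if clock is None:
        clock = default_clock()
    return clock.age(nd)


def assign_epoch(nd: float, epochs: Optional[EpochBoundaries] = None) -> str:
    """Early / intermediate / late; both cut points belong to the later
    interval (left-closed intervals on the nd axis)."""
    return (epochs or EpochBoundaries()).epoch_of(nd)


# ----------------------------------------------------------------------
# trees of domains
# ----------------------------------------------------------------------
#: Default ToD search effort: transposed matrices have one leaf per
#: fold family (hundreds of tips), and the timeline statistic is
#: averaged over replicate searches, so each replicate uses a single
#: random-addition start refined by NNI only.
TOD_SEARCH_DEFAULT = SearchConfig(n_starts=1, use_spr=False)


def build_tod(m_t: CodedMatrix, config: Optional[SearchConfig] = None,
              seed: int = 0) -> PhyloTree:
    """Heuristic-search tree on the transposed matrix (families as
    taxa), Lundberg-rooted with the all-maximal-state ancestor
    (state k-1: 23 for abundance coding, 1 for occurrence)."""
    result = heuristic_search(m_t, config=config or TOD_SEARCH_DEFAULT,
                              seed=seed)
    return lundberg_root(result.tree, m_t, ancestor_state=m_t.k - 1).tree


def replicate_node_distances(m_t: CodedMatrix,
                             config: Optional[SearchConfig] = None,
                             seed: int = 0, n_replicates: int = 3
                             ) -> pd.Series:
    """Relative ages averaged over independent ToD search replicates.

    Near-optimal parsimony trees can differ substantially in node-depth
    structure while being almost equally short, so the nd of a single
    heuristic tree carries topology noise; averaging nd over a few
    replicate searches (seeds ``seed .. seed + n_replicates - 1``) is a
    plain variance-reduction device for the timeline.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    reps = [node_distances(build_tod(m_t, config=config, seed=seed + i))
            for i in range(n_replicates)]
    return pd.concat(reps, axis=1).mean(axis=1).rename("nd")


def node_distances(tod: PhyloTree) -> pd.Series:
    """Relative age nd per leaf of a rooted tree.

    The raw distance of a leaf is the number of internal nodes on its
    root-to-leaf path (the root counts; the leaf does not); nd rescales
    to [0, 1].  A perfectly depth-balanced tree is degenerate (all
    distances equal): every nd is reported as 0 with a warning.
    """
    if not tod.rooted:
        raise ValueError("node distances require a rooted tree")
    depths = {}
    d = {id(tod.root): 1}
    for n in tod.preorder():
        if n.parent is not None:
            d[id(n)] = d[id(n.parent)] + (0 if n.is_leaf else 1)
        if n.is_leaf:
            depths[n.label] = d[id(n)]
    s = pd.Series(depths, dtype=float).sort_index()
    d_min, d_max = s.min(), s.max()
    if d_max == d_min:
        logger.warning("all leaves equidistant from the root; "
                       "nd degenerates to 0 for every family")
        return s * 0.0
    return (s - d_min) / (d_max - d_min)


# ----------------------------------------------------------------------
# distribution statistics
# ----------------------------------------------------------------------
def f_values(m: AbundanceMatrix) -> pd.Series:
    """Distribution index per family: fraction of proteomes encoding it."""
    present = (m.counts > 0).sum(axis=0)
    return (present / m.shape[0]).rename("f_value")


@dataclass
class VennSummary:
    group_sizes: dict  # group -> number of FFs
    totals: dict       # superkingdom -> total FFs present in it

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"group": list(self.group_sizes),
                             "n_ffs": list(self.group_sizes.values())})


def venn_totals(group_sizes: Mapping[str, int]) -> dict:
    """Per-superkingdom totals from the seven Venn group sizes:
    total(X) = sum of the sizes of every group whose pattern contains X."""
    return {sk: int(sum(n for g, n in group_sizes.items() if sk in g))
            for sk in SUPERKINGDOMS}


def venn_classify(m: AbundanceMatrix) -> tuple[pd.Series, VennSummary]:
    """Venn taxonomic group of every family (the superkingdoms, in
    A,B,E order, with at least one proteome encoding it), plus summary
    counts.  The seven groups partition the family set."""
    present = m.counts > 0
    sk = m.proteomes["superkingdom"]
    by_sk = {s: present.loc[sk[sk == s].index].any(axis=0)
             for s in SUPERKINGDOMS}
    groups = pd.Series("", index=m.counts.columns, dtype=object)
    for s in SUPERKINGDOMS:
        groups.loc[by_sk[s]] += s
    groups = groups.rename("venn_group")
    sizes = {g: int((groups == g).sum()) for g in VENN_GROUPS}
    return groups, VennSummary(group_sizes=sizes, totals=venn_totals(sizes))


def persistence_metrics(m: AbundanceMatrix) -> pd.DataFrame:
    """Per-proteome economy (distinct families), flexibility (total
    domain count) and robustness (flexibility / economy)."""
    economy = (m.counts > 0).sum(axis=1)
    flexibility = m.counts.sum(axis=1)
    empty = economy[economy == 0]
    if len(empty):
        raise ValueError(f"proteome(s) with no fold families: "
                         f"{list(empty.index)}")
    df = pd.DataFrame({
        "superkingdom": m.proteomes["superkingdom"],
        "economy": economy.astype(int),
        "flexibility": flexibility.astype(int),
    })
    df["robustness"] = df["flexibility"] / df["economy"]
    return df.rename_axis("proteome_id")


# ----------------------------------------------------------------------
# the assembled timeline
# ----------------------------------------------------------------------
def timeline_table(m: AbundanceMatrix, nd: Mapping[str, float],
                   clock: Optional[ClockCalibration] = None,
                   epochs: Optional[EpochBoundaries] = None) -> pd.DataFrame:
    """Per-family timeline: css, name, nd, geological age, epoch,
    f-value and Venn group, sorted by nd (most ancient first)."""
    clock = clock or default_clock()
    epochs = epochs or EpochBoundaries()
    nd = pd.Series(dict(nd), dtype=float)
    missing = set(m.css_list) - set(nd.index)
    if missing:
        raise ValueError(f"nd missing for {len(missing)} families, "
                         f"e.g. {sorted(missing)[:5]}")
    groups, _ = venn_classify(m)
    f = f_values(m)
    df = pd.DataFrame({
        "css": m.css_list,
        "name": [m.ff_names.get(c) for c in m.css_list],
        "nd": nd.reindex(m.css_list).to_numpy(),
    })
    df["age_gy"] = clock.age(df["nd"].to_numpy())
    df["epoch"] = [epochs.epoch_of(x) for x in df["nd"]]
    df["f_value"] = f.reindex(m.css_list).to_numpy()
    df["venn_group"] = groups.reindex(m.css_list).to_numpy()
    return df.sort_values("nd", kind="stable").reset_index(drop=True)
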
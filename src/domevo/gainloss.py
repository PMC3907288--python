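"""Branch-wise gain/loss tracing and aggregate statistics.

Given a minimal ancestral-state reconstruction on a rooted tree, every
(character, branch) pair where the child state differs from the parent
state is an event: a *gain* when abundance/occurrence increased along the
branch, a *loss* when it decreased.  Per fold family, the number of gain
and loss events is tallied (branch-counting — one event per changed
branch regardless of the jump size; magnitude weighting is available as a
sensitivity option) and the family is classified *gained* (net > 0),
*lost* (net < 0) or *unchanged* (net = 0; the tie class is reported
separately from the other two).

The module also reproduces the aggregate statistics built on these
tallies: global and per-superkingdom gain-to-loss ratios, ratios binned
into the early / intermediate / late epochs of the domain timeline, the
equal-sampling experiment, and the two-model consensus sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .census import CodedMatrix, SUPERKINGDOMS
from .parsimony import (Reconstruction, SearchConfig, ancestral_states,
                        heuristic_search, lundberg_root, name_internal_nodes,
                        prune_to_taxa)
from .trees import PhyloTree

__all__ = [
    "EpochBoundaries",
    "RatioSummary",
    "SuperkingdomResult",
    "trace_changes",
    "tally_gain_loss",
    "classification_sets",
    "ratio_summary",
    "superkingdom_analysis",
    "equal_sampling_experiment",
    "consensus_sets",
    "percent",
]

logger = logging.getLogger(__name__)

EVENT_COLUMNS = ["ff", "parent", "child", "from_state", "to_state",
                 "direction", "magnitude"]
RECORD_COLUMNS = ["ff", "gains", "losses", "net", "classification"]


@dataclass(frozen=True)
class EpochBoundaries:
    """Epoch cut points on the relative domain age (nd) axis.

    early: 0 <= nd < early_end; intermediate: early_end <= nd <
    late_start; late: late_start <= nd <= 1 (both cut points belong to
    the later interval).
    """

    early_end: float = 0.15
    late_start: float = 0.55

    def __post_init__(self):
        if not (0 < self.early_end < self.late_start <= 1):
            raise ValueError("need 0 < early_end < late_start <= 1")

    def epoch_of(self, nd: float) -> str:
        if not 0 <= nd <= 1:
            raise ValueError(f"nd must lie in [0, 1], got {nd}")
        if nd < self.early_end:
            return "early"
        if nd < self.late_start:
            return "intermediate"
        return "late"


@dataclass
class RatioSummary:
    """Total gains, losses and their ratio, optionally per epoch.

    When no losses were observed, ``ratio`` is None and
    ``infinite_ratio`` is set rather than reporting a number.
    """

    total_gains: int
    total_losses: int
    ratio: Optional[float] = None
    infinite_ratio: bool = False
    per_epoch: Optional[dict] = None  # epoch -> (gains, losses, ratio|None)

    @classmethod
    def from_totals(cls, gains: int, losses: int,
                    per_epoch: Optional[dict] = None) -> "RatioSummary":
        if losses > 0:
            return cls(total_gains=int(gains), total_losses=int(losses),
                       ratio=gains / losses, per_epoch=per_epoch)
        return cls(total_gains=int(gains), total_losses=int(losses),
                   ratio=None, infinite_ratio=True, per_epoch=per_epoch)

    def to_dict(self) -> dict:
        d = {"total_gains": self.total_gains,
             "total_losses": self.total_losses,
             "ratio": self.ratio, "infinite_ratio": self.infinite_ratio}
        if self.per_epoch is not None:
            d["per_epoch"] = {e: {"gains": g, "losses": l, "ratio": r}
                              for e, (g, l, r) in self.per_epoch.items()}
        return d


@dataclass
class SuperkingdomResult:
    superkingdom: str
    tree: PhyloTree
    records: pd.DataFrame
    summary: RatioSummary
    reconstruction: Reconstruction = field(repr=False, default=None)


# ----------------------------------------------------------------------
# event tracing
# ----------------------------------------------------------------------
def trace_changes(rec: Reconstruction,
                  include_root_edge: bool = False) -> pd.DataFrame:
    """One row per (character, branch) whose child state differs from the
    parent state.

    The virtual edge from the polarization ancestor to the root is
    excluded unless ``include_root_edge`` is set (then reported with
    parent label ``ANCESTOR``, using the reconstruction's ancestor
    state).
    """
    name_internal_nodes(rec.tree)
    chars = np.asarray(rec.matrix.characters)
    rows = []

    def emit(parent_label, child_label, ps, cs):
        idx = np.nonzero(cs != ps)[0]
        if not len(idx):
            return
        delta = cs[idx] - ps[idx]
        rows.append(pd.DataFrame({
            "ff": chars[idx],
            "parent": parent_label,
            "child": child_label,
            "from_state": ps[idx],
            "to_state": cs[idx],
            "direction": np.where(delta > 0, "gain", "loss"),
            "magnitude": np.abs(delta),
        }))

    if include_root_edge and rec.ancestor_state is not None:
        anc = np.full(len(chars), rec.ancestor_state, dtype=np.int64)
        emit("ANCESTOR", rec.tree.root.label, anc, rec.states[rec.tree.root])
    for v in rec.tree.edges():
        emit(v.parent.label, v.label, rec.states[v.parent], rec.states[v])

    if not rows:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    return pd.concat(rows, ignore_index=True)[EVENT_COLUMNS]


def tally_gain_loss(events: pd.DataFrame,
                    ffs: Optional[Iterable[str]] = None,
                    magnitude_weighted: bool = False) -> pd.DataFrame:
    """Per-FF gain/loss record table.

    ``gains``/``losses`` count events (branches); with
    ``magnitude_weighted`` they sum ``|state jump|`` instead.  Passing
    ``ffs`` includes event-free families as ``unchanged`` rows.
    """
    if magnitude_weighted:
        agg = events.groupby(["ff", "direction"])["magnitude"].sum()
    else:
        agg = events.groupby(["ff", "direction"]).size()
    table = agg.unstack("direction", fill_value=0) if len(events) else \
        pd.DataFrame(columns=["gain", "loss"], dtype=np.int64)
    for col in ("gain", "loss"):
        if col not in table.columns:
            table[col] = 0
    if ffs is not None:
        table = table.reindex(list(ffs), fill_value=0)
    table = table.fillna(0).astype(int)
    out = pd.DataFrame({
        "ff": table.index,
        "gains": table["gain"].to_numpy(),
        "losses": table["loss"].to_numpy(),
    })
    out["net"] = out["gains"] - out["losses"]
    out["classification"] = np.select(
        [out["net"] > 0, out["net"] < 0], ["gained", "lost"], "unchanged")
    return out.reset_index(drop=True)


def classification_sets(records: pd.DataFrame) -> dict:
    return {cls: set(records.loc[records["classification"] == cls, "ff"])
            for cls in ("gained", "lost", "unchanged")}


def percent(part: float, whole: float, ndigits: int = 0) -> float:
    """Percentage of ``part`` in ``whole`` rounded to ``ndigits``."""
    if whole == 0:
        raise ValueError("whole must be nonzero")
    return round(100.0 * part / whole, ndigits)


# ----------------------------------------------------------------------
# ratios
# ----------------------------------------------------------------------
def ratio_summary(records: pd.DataFrame,
                  nd_map: Optional[Mapping[str, float]] = None,
                  epochs: Optional[EpochBoundaries] = None) -> RatioSummary:
    """Totals over all FFs and, when ``nd_map`` is given, per-epoch bins.

    Epoch binning attributes *all* of a family's events to the epoch of
    the family's nd age (families, not branches, carry the age).  The
    merged ratio is the quotient of summed counts, never a mean of
    ratios.
    """
    total_g = int(records["gains"].sum())
    total_l = int(records["losses"].sum())
    per_epoch = None
    if nd_map is not None:
        epochs = epochs or EpochBoundaries()
        missing = set(records["ff"]) - set(nd_map)
        if missing:
            raise ValueError(
                f"nd missing for {len(missing)} fold families, e.g. "
                f"{sorted(missing)[:5]}")
        labels = records["ff"].map(lambda f: epochs.epoch_of(nd_map[f]))
        per_epoch = {}
        for epoch in ("early", "intermediate", "late"):
            sub = records[labels == epoch]
            g, l = int(sub["gains"].sum()), int(sub["losses"].sum())
            per_epoch[epoch] = (g, l, (g / l) if l > 0 else None)
    return RatioSummary.from_totals(total_g, total_l, per_epoch=per_epoch)


# ----------------------------------------------------------------------
# superkingdom analyses
# ----------------------------------------------------------------------
def superkingdom_analysis(m: CodedMatrix, tree: PhyloTree, sk: str,
                          mode: str = "reuse_topology",
                          policy: str = "acctran",
                          search_config: Optional[SearchConfig] = None,
                          seed: int = 0,
                          nd_map: Optional[Mapping[str, float]] = None,
                          epochs: Optional[EpochBoundaries] = None,
                          magnitude_weighted: bool = False) -> SuperkingdomResult:
    """Gain/loss tallies recomputed on a single-superkingdom tree.

    ``m`` must carry superkingdom metadata (as produced by the encoders)
    and ``tree`` must be the rooted global tree of life.  With the
    default ``reuse_topology`` the pruned tree is the induced subtree of
    the global topology; ``re_search`` runs a fresh heuristic search on
    the reduced matrix, Lundberg-rooted with the all-zero ancestor.
    Fold-family columns absent from every kept taxon are dropped.
    """
    if m.meta is None or "superkingdom" not in m.meta.columns:
        raise ValueError("matrix lacks superkingdom metadata")
    if sk not in SUPERKINGDOMS:
        raise ValueError(f"superkingdom must be one of {SUPERKINGDOMS}")
    keep = [t for t in m.taxa if m.meta.loc[t, "superkingdom"] == sk]
    if len(keep) < 4:
        raise ValueError(f"superkingdom {sk} has {len(keep)} taxa; need >= 4")
    sub = m.subset_taxa(keep)
    present = sub.states.max(axis=0) > 0
    dropped = int((~present).sum())
    if dropped:
        logger.info("superkingdom %s: dropping %d absent FF column(s)",
                    sk, dropped)
    sub = sub.subset_characters(
        [c for c, p in zip(sub.characters, present) if p])

    if mode == "reuse_topology":
        sk_tree = prune_to_taxa(tree, keep)
    elif mode == "re_search":
        result = heuristic_search(sub, config=search_config, seed=seed)
        sk_tree = lundberg_root(result.tree, sub, ancestor_state=0).tree
    else:
        raise ValueError(f"unknown mode {mode!r}")

    rec = ancestral_states(sk_tree, sub, policy=policy, ancestor_state=0)
    events = trace_changes(rec)
    records = tally_gain_loss(events, ffs=sub.characters,
                              magnitude_weighted=magnitude_weighted)
    nd_sub = None
    if nd_map is not None:
        nd_sub = {f: nd_map[f] for f in sub.characters if f in nd_map}
        if len(nd_sub) < len(sub.characters):
            nd_sub = None  # pruned matrix has FFs outside the age map
    summary = ratio_summary(records, nd_map=nd_sub, epochs=epochs)
    return SuperkingdomResult(superkingdom=sk, tree=sk_tree, records=records,
                              summary=summary, reconstruction=rec)


def equal_sampling_experiment(m: CodedMatrix, k: int = 34, reps: int = 100,
                              seed: int = 0,
                              search_config: Optional[SearchConfig] = None,
                              policy: str = "acctran") -> pd.DataFrame:
    """Gain-to-loss ratios from repeated equal-size sampling.

    Per replicate, ``k`` taxa are sampled without replacement from each
    superkingdom, a tree is built on the sample (configurable effort,
    Lundberg-rooted at the all-zero ancestor) and per-superkingdom
    tallies are recomputed on the induced subtrees.  Returns one row per
    (replicate, superkingdom) with gains, losses and ratio; medians are
    available via ``df.groupby('superkingdom')['ratio'].median()``.
    """
    if m.meta is None:
        raise ValueError("matrix lacks superkingdom metadata")
    rng = np.random.default_rng(seed)
    by_sk = {sk: [t for t in m.taxa if m.meta.loc[t, "superkingdom"] == sk]
             for sk in SUPERKINGDOMS}
    for sk, taxa in by_sk.items():
        if len(taxa) < k:
            raise ValueError(f"superkingdom {sk} has only {len(taxa)} taxa; "
                             f"cannot sample {k}")
    search_config = search_config or SearchConfig(n_starts=1, use_spr=False)
    rows = []
    for rep in range(reps):
        sample = []
        for sk in SUPERKINGDOMS:
            chosen = rng.choice(len(by_sk[sk]), size=k, replace=False)
            sample.extend(by_sk[sk][i] for i in sorted(chosen))
        sub = m.subset_taxa(sorted(sample))
        present = sub.states.max(axis=0) > 0
        sub = sub.subset_characters(
            [c for c, p in zip(sub.characters, present) if p])
        rep_seed = int(rng.integers(2**31))
        result = heuristic_search(sub, config=search_config, seed=rep_seed)
        rooted = lundberg_root(result.tree, sub, ancestor_state=0).tree
        for sk in SUPERKINGDOMS:
            res = superkingdom_analysis(sub, rooted, sk, policy=policy)
            rows.append({"replicate": rep, "superkingdom": sk,
                         "gains": res.summary.total_gains,
                         "losses": res.summary.total_losses,
                         "ratio": res.summary.ratio})
    return pd.DataFrame(rows)


def consensus_sets(abundance_records: pd.DataFrame,
                   occurrence_records: pd.DataFrame) -> tuple[set, set]:
    """Families gained under both codings, and lost under both; families
    whose classifications disagree are excluded from both sets."""
    a = classification_sets(abundance_records)
    o = classification_sets(occurrence_records)
    return a["gained"] & o["gained"], a["lost"] & o["lost"]
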
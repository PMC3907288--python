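"""End-to-end orchestration: census -> coding -> tree search -> rooting
-> ancestral states -> gain/loss tallies -> timelines -> tree comparison
-> report tables.

A single :class:`RunConfig` (optionally loaded from flat YAML) drives
the whole analysis.  One global seed fans out to per-stage seeds through
a fixed affine derivation (see :func:`stage_seed`), so every stage is
independently reproducible and a rerun with the same config reproduces
every artifact byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import census as census_mod
from . import gainloss as gl
from . import timeline as tl
from . import treecmp
from .census import (AbundanceMatrix, CodedMatrix, encode_abundance,
                     encode_occurrence, read_assignment_table,
                     transpose_for_tod, write_character_matrix)
from .gainloss import EpochBoundaries, RatioSummary
from .parsimony import (FitStatistics, Reconstruction, SearchConfig,
                        ancestral_states, fit_statistics, heuristic_search,
                        lundberg_root, name_internal_nodes)
from .trees import PhyloTree

__all__ = ["RunConfig", "ModelResult", "RunBundle", "PipelineError",
           "run_pipeline", "report_tables", "stage_seed"]

logger = logging.getLogger(__name__)

MODELS = ("abundance", "occurrence")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage.  Artifacts written
    by earlier stages are left in place."""


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed: an affine hash of the stage name
    folded into 31 bits."""
    h = 0
    for ch in stage:
        h = (h * 131 + ord(ch)) % 1_000_003
    return (seed * 1_000_003 + h) % (2**31)


@dataclass
class RunConfig:
    input_table: str
    outdir: str = "domevo_out"
    model: str = "both"  # abundance | occurrence | both
    k: int = 24
    tie_policy: str = "acctran"
    early_end: float = 0.15
    late_start: float = 0.55
    n_starts: int = 3
    use_spr: bool = True
    tod_n_starts: int = 1
    tod_use_spr: bool = False
    tod_replicates: int = 3  # nd averaged over replicate ToD searches
    bootstrap_replicates: int = 0
    n_random_trees: int = 200
    compare_reps: int = 100
    superkingdom_analyses: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def epochs(self) -> EpochBoundaries:
        return EpochBoundaries(early_end=self.early_end,
                               late_start=self.late_start)

    def models(self) -> list[str]:
        if self.model == "both":
            return list(MODELS)
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS + ('both',)}")
        return [self.model]


@dataclass
class ModelResult:
    model: str
    coded: CodedMatrix
    tol: PhyloTree
    tol_stats: FitStatistics
    lundberg_increase: int
    reconstruction: Reconstruction = field(repr=False, default=None)
    events: pd.DataFrame = None
    records: pd.DataFrame = None
    summary: RatioSummary = None
    tod: PhyloTree = None
    nd: pd.Series = None
    timeline: pd.DataFrame = None
    sk_results: dict = field(default_factory=dict)
    bootstrap: Optional[dict] = None


@dataclass
class RunBundle:
    config: RunConfig
    matrix: AbundanceMatrix
    models: dict  # model name -> ModelResult
    persistence: pd.DataFrame = None
    venn: tl.VennSummary = None
    comparison: Optional[treecmp.ComparisonResult] = None
    consensus: Optional[tuple] = None  # (gained_both, lost_both)
    outdir: Optional[Path] = None


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as e:
                raise PipelineError(f"stage '{name}' failed: {e}") from e
        return wrapper
    return deco


def _run_model(model: str, matrix: AbundanceMatrix, cfg: RunConfig,
               outdir: Path) -> ModelResult:
    coded = (encode_abundance(matrix, k=cfg.k) if model == "abundance"
             else encode_occurrence(matrix))
    write_character_matrix(coded, "nexus", outdir / f"matrix_{model}.nex")

    search_cfg = SearchConfig(n_starts=cfg.n_starts, use_spr=cfg.use_spr)
    res = heuristic_search(coded, config=search_cfg,
                           seed=stage_seed(cfg.seed, f"search_{model}"))
    lb = lundberg_root(res.tree, coded, ancestor_state=0)
    tol = name_internal_nodes(lb.tree)
    tol.to_newick(str(outdir / f"tol_{model}.nwk"))
    stats = fit_statistics(tol, coded, n_random_trees=cfg.n_random_trees,
                           seed=stage_seed(cfg.seed, f"g1_{model}"))

    rec = ancestral_states(tol, coded, policy=cfg.tie_policy,
                           ancestor_state=0)
    events = gl.trace_changes(rec)
    records = gl.tally_gain_loss(events, ffs=coded.characters)

    tod_cfg = SearchConfig(n_starts=cfg.tod_n_starts, use_spr=cfg.tod_use_spr)
    tod_seed = stage_seed(cfg.seed, f"tod_{model}")
    m_t = transpose_for_tod(coded)
    tod = tl.build_tod(m_t, config=tod_cfg, seed=tod_seed)
    tod.to_newick(str(outdir / f"tod_{model}.nwk"))
    if cfg.tod_replicates > 1:
        nd = tl.replicate_node_distances(m_t, config=tod_cfg, seed=tod_seed,
                                         n_replicates=cfg.tod_replicates)
    else:
        nd = tl.node_distances(tod)
    summary = gl.ratio_summary(records, nd_map=nd.to_dict(),
                               epochs=cfg.epochs)
    timeline = tl.timeline_table(matrix, nd, epochs=cfg.epochs)
    timeline.to_csv(outdir / f"timeline_{model}.tsv", sep="\t", index=False)

    result = ModelResult(model=model, coded=coded, tol=tol, tol_stats=stats,
                         lundberg_increase=lb.length_increase,
                         reconstruction=rec, events=events, records=records,
                         summary=summary, tod=tod, nd=nd, timeline=timeline)

    if cfg.superkingdom_analyses:
        counts = matrix.proteomes["superkingdom"].value_counts()
        for sk in census_mod.SUPERKINGDOMS:
            if counts.get(sk, 0) < 4:
                logger.info("skipping superkingdom %s (%d taxa)", sk,
                            counts.get(sk, 0))
                continue
            result.sk_results[sk] = gl.superkingdom_analysis(
                coded, tol, sk, policy=cfg.tie_policy)

    if cfg.bootstrap_replicates > 0:
        from .parsimony import bootstrap_support
        result.bootstrap = bootstrap_support(
            coded, tol, n_replicates=cfg.bootstrap_replicates,
            seed=stage_seed(cfg.seed, f"bootstrap_{model}"))

    # per-FF report mirroring the supplementary gain/loss datasets
    rep = records.copy()
    rep.insert(0, "name", rep["ff"].map(matrix.ff_names).fillna(""))
    rep = rep.rename(columns={"ff": "css"})
    rep["model"] = model
    rep.to_csv(outdir / f"gainloss_{model}.tsv", sep="\t", index=False)
    return result


def run_pipeline(cfg: RunConfig) -> RunBundle:
    """Execute the full analysis described by ``cfg``; artifacts are
    written under ``cfg.outdir`` as they are produced."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    matrix = _stage("census")(read_assignment_table)(cfg.input_table)
    bundle = RunBundle(config=cfg, matrix=matrix, models={}, outdir=outdir)

    bundle.persistence = _stage("persistence")(tl.persistence_metrics)(matrix)
    bundle.persistence.to_csv(outdir / "persistence.tsv", sep="\t")
    _, bundle.venn = _stage("venn")(tl.venn_classify)(matrix)

    for model in cfg.models():
        bundle.models[model] = _stage(f"model_{model}")(_run_model)(
            model, matrix, cfg, outdir)

    if len(bundle.models) == 2:
        ab, oc = bundle.models["abundance"], bundle.models["occurrence"]
        bundle.comparison = _stage("compare")(treecmp.guided_randomization_test)(
            ab.tol, oc.tol, reps=cfg.compare_reps,
            seed=stage_seed(cfg.seed, "compare"))
        bundle.consensus = gl.consensus_sets(ab.records, oc.records)

    manifest = {
        "config": cfg.to_dict(),
        "n_proteomes": matrix.shape[0],
        "n_ffs": matrix.shape[1],
        "venn": {"group_sizes": bundle.venn.group_sizes,
                 "totals": bundle.venn.totals},
        "models": {},
    }
    for model, r in bundle.models.items():
        manifest["models"][model] = {
            "tree_length": r.tol_stats.tree_length,
            "ri": r.tol_stats.ri,
            "g1": r.tol_stats.g1,
            "n_informative": r.tol_stats.n_informative,
            "lundberg_increase": r.lundberg_increase,
            "tie_policy": cfg.tie_policy,
            "summary": r.summary.to_dict(),
            "superkingdoms": {sk: res.summary.to_dict()
                              for sk, res in r.sk_results.items()},
        }
    if bundle.comparison is not None:
        manifest["comparison"] = bundle.comparison.to_dict()
    if bundle.consensus is not None:
        manifest["consensus"] = {
            "gained_both": sorted(bundle.consensus[0]),
            "lost_both": sorted(bundle.consensus[1])}
    (outdir / "summary.json").write_text(json.dumps(manifest, indent=2,
                                                    default=str) + "\n")
    return bundle


def report_tables(bundle: RunBundle) -> dict:
    """Assemble the report tables from a completed bundle: per-FF
    gain/loss tables per model, Venn summary, persistence metrics and
    the per-epoch ratio table."""
    absent = [name for name, value in
              [("models", bundle.models), ("venn", bundle.venn),
               ("persistence", bundle.persistence)]
              if value is None or (name == "models" and not value)]
    if absent:
        raise ValueError(f"incomplete bundle; missing artifacts: {absent}")
    tables = {
        "venn_summary": bundle.venn.to_frame(),
        "persistence": bundle.persistence.reset_index(),
    }
    epoch_rows = []
    for model, r in bundle.models.items():
        rep = r.records.copy()
        rep.insert(0, "name",
                   rep["ff"].map(bundle.matrix.ff_names).fillna(""))
        rep = rep.rename(columns={"ff": "css"})
        rep["model"] = model
        tables[f"gainloss_{model}"] = rep
        tables[f"timeline_{model}"] = r.timeline
        if r.summary.per_epoch:
            for epoch, (g, l, ratio) in r.summary.per_epoch.items():
                epoch_rows.append({"model": model, "epoch": epoch,
                                   "gains": g, "losses": l, "ratio": ratio})
    if epoch_rows:
        tables["epoch_ratios"] = pd.DataFrame(epoch_rows)
    return tables
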
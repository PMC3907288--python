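# domevo

Phylogenomic tracing of protein domain gain and loss across the three
superkingdoms of life.

`domevo` is for molecular evolution researchers who study proteomes as
collections of structural domains. Its unit of analysis is the SCOP
**fold family (FF)** — domains sharing >30% pairwise sequence identity,
identified by a concise classification string (css) such as
`c.37.1.12`. Starting from a genome census (how many domains of each FF
each proteome encodes), the package reconstructs the evolutionary
history of domain repertoires: which families were gained on which
branches of the tree of life, which were lost, when each family first
appeared, and how gain and loss balance through evolutionary time.

## The method

**Character coding.** The census is a matrix of counts `g_ab`
(proteome *a*, family *b*). Two codings turn it into phylogenetic
characters:

- *abundance*: counts are log-rescaled onto 24 ordered states written
  `0-9A-N`,

  `state = round( ln(g_ab + 1) / ln(g_max + 1) x 23 )`,

  with `g_max` the largest count in the matrix — this tames the huge
  spread of family sizes while preserving order;
- *occurrence*: binary presence/absence (`0`/`1`).

**Trees of life (ToLs).** Proteomes are taxa and families are
characters. Trees are sought under Wagner (ordered-state) parsimony —
cost `|i - j|` between states, changes allowed in both directions —
with random-addition starts and NNI/SPR hill climbing, then rooted by
the **Lundberg method**: a hypothetical all-zero ancestor (the
minimal progenote repertoire) is attached to the branch that increases
total length least. Ancestral states at every node then yield, for
each family and branch, gain events (state increased) and loss events
(state decreased), tallied per family into a net classification
(gained / lost / unchanged) and global gain-to-loss ratios, optionally
per superkingdom (pruned trees) and per evolutionary epoch.

**Trees of domains (ToDs) and the timeline.** Transposing the matrix
makes families the taxa. ToDs are rooted with the all-maximal-state
ancestor (`N`), following the axiom that abundance accumulates with
age. Each family's relative age is its **node distance** `nd` in
[0, 1] (0 = most ancient); a linear molecular clock maps `nd` to
geological age (Gy), and the axis splits into the *early* (nd < 0.15),
*intermediate* (0.15 <= nd < 0.55) and *late* (nd >= 0.55) epochs.
Per-family distribution statistics (the f-value: fraction of proteomes
encoding the family; the seven-group Venn classification across
Archaea/Bacteria/Eukarya) and per-proteome persistence metrics
(economy, flexibility, robustness) complete the timeline.

**Tree comparison.** Congruence between trees is the nodal RMSD over
leaf-pair path lengths, with a guided randomization test (label
permutations at fixed topology) for significance.

**Synthetic data.** A fully ground-truthed generator evolves family
repertoires along a known species tree with three superkingdom clades
(origination, per-copy duplication, per-copy loss), so every stage of
the pipeline can be validated against a known history.

## Worked example

```python
from domevo import (SimulationConfig, simulate_dataset, emit_dataset,
                    RunConfig, run_pipeline)

cfg = SimulationConfig(seed=7, n_taxa=(5, 5, 5), n_ffs=40)
tree, matrix, truth = simulate_dataset(cfg)
paths = emit_dataset(matrix, truth, "demo")

run = RunConfig(input_table=str(paths["assignments"]),
                outdir="demo_out", seed=3)
bundle = run_pipeline(run)

for model, r in bundle.models.items():
    s = r.summary
    print(f"{model}: tree length {r.tol_stats.tree_length}, "
          f"RI {r.tol_stats.ri:.2f}, g1 {r.tol_stats.g1:.2f}, "
          f"{s.total_gains} gains vs {s.total_losses} losses "
          f"(ratio {s.ratio:.2f})")
cmp = bundle.comparison
print(f"ToL congruence: RMSD {cmp.rmsd:.2f} vs chance {cmp.random_mean:.2f} "
      f"(p = {cmp.empirical_p:.3f})")
print(bundle.models["abundance"].timeline.head(5).to_string(index=False))
```

prints

```
abundance: tree length 469, RI 0.74, g1 -0.72, 111 gains vs 52 losses (ratio 2.13)
occurrence: tree length 31, RI 1.00, g1 -1.11, 29 gains vs 2 losses (ratio 14.50)
ToL congruence: RMSD 2.43 vs chance 3.70 (p = 0.010)
     css name       nd   age_gy epoch  f_value venn_group
a.10.1.1 None 0.000000 3.822326 early 1.000000        ABE
a.32.1.1 None 0.000000 3.822326 early 0.666667         BE
 a.7.1.1 None 0.000000 3.822326 early 1.000000        ABE
a.38.1.1 None 0.042582 3.650800 early 1.000000        ABE
a.35.1.1 None 0.085165 3.479274 early 1.000000        ABE
```

Reading this: both codings recover trees with strong signal (retention
index 0.74 and 1.00; left-skewed random-length distributions, g1 < 0).
Gains outnumber losses under both codings — the expected signature of
a growing simulated repertoire. The two trees of life are more
congruent than chance (RMSD 2.43 against a null mean of 3.70). The
timeline lists the most ancient families first: universal (`ABE`)
families with the highest f-values dominate the early epoch, exactly
the pattern the age axiom predicts.

The same analysis is available from the shell:

```bash
domevo simulate --seed 7 --n-taxa 5 5 5 --n-ffs 40 --out demo
domevo run --config run.yaml        # flat YAML mirroring RunConfig
domevo compare --tree1 demo_out/tol_abundance.nwk \
               --tree2 demo_out/tol_occurrence.nwk --reps 100 --seed 1
```

Input censuses are plain TSV (`proteome_id`, `superkingdom` in
`{A,B,E}`, `css`, `count`); character matrices are written as
PAUP*-compatible NEXUS (with the exact `SYMBOLS` alphabet) or relaxed
PHYLIP, trees as Newick.

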
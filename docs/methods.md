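# Methods

This note documents the models, conventions and numerical choices
behind `domevo`, in the spirit of a statistical software methods
appendix. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Character coding

Raw census counts `g_ab` are coded as ordered multistate characters.
The abundance coding is

    state(g) = round( ln(g + 1) / ln(g_max + 1) * (k - 1) ),  k = 24,

with `g_max` the single global maximum of the matrix (not per-family or
per-proteome). The `+1` offset pins `g = 0` exactly to state 0, which
the zero-state polarization of the trees of life requires; because the
formula is a ratio of logarithms, the choice of base is immaterial.
Rounding is half-away-from-zero and centralized in one helper
(`census._round_half_up`) so the convention can be swapped; note that
`numpy.round` (half-to-even) is deliberately *not* used. States are
written with the alphanumeric alphabet `0-9A-N`; occurrence coding is
the binary collapse `state = (g > 0)`.

On-disk formats are NEXUS (DATA block declaring NTAX, NCHAR and the
exact SYMBOLS alphabet, as PAUP* expects) and relaxed PHYLIP. The NEXUS
writer is our own because the symbol *order* in the alphabet is
meaningful for ordered characters and must round-trip verbatim; reading
uses dendropy. The `?` symbol is accepted on read (treated as absence)
and never written.

## Wagner parsimony

Characters are ordered integers with linear cost `|i - j|`; changes are
allowed in both directions and carry equal weight. Scoring is the
Sankoff dynamic programme; with linear costs the per-node min-plus
transform reduces to a forward and a backward cumulative pass in O(k),
vectorized across characters with integer arithmetic throughout (no
floating-point tolerances anywhere in the scoring path). Scores are
invariant to root placement; the test suite checks the implementation
against exhaustive enumeration over internal-state assignments.

*Parsimony informativeness.* An ordered character is informative iff
its minimal length varies across topologies. We use the exact
characterization: star-tree length (the best single median state)
strictly greater than the state range. This rule was verified by
exhaustive enumeration over all topologies for thousands of random
small cases and is re-verified by a property test.

*Ancestral states.* The down-pass computes exact cost vectors; the
top-down pass picks at each node a state minimizing
`D[node][s] + |s - parent_state|`. Any such choice preserves global
optimality, so tie resolution is a policy:

- `acctran` (default): among admissible states take the one farthest
  from the parent, accelerating changes onto the earliest possible
  branch. This matches the default optimization of the classic
  parsimony software this workflow is modeled on, and on simulated
  histories it recovers true per-family net change markedly better,
  because the alternative systematically splits one deep gain into
  several parallel shallow gains.
- `closest_to_parent` (alias `deltran`): stay near the parent state,
  delaying changes tipward.

At the root, ties break toward the polarization ancestor (state 0 for
trees of life, `k-1` for trees of domains). The ancestor influences
*only* tie-breaking, never the root cost, so the reconstruction length
equals the rooting-invariant Wagner length under every policy (a tested
contract).

*Lundberg rooting.* A hypothetical ancestor fixed at the ancestral
state for every character is attached, in turn, to every branch; the
branch minimizing the total length increase wins, ties going to the
first branch in post-order enumeration (logged). The computation uses
inside-outside cost vectors, giving all-branch evaluation in one tree
pass rather than one rescoring per branch.

*Search.* Random-addition stepwise insertion (scored incrementally with
the same inside-outside vectors) followed by steepest-descent NNI, with
optional SPR rounds (each candidate prune is rescored exactly;
reinsertion points are scored in one pass). Defaults: 5 starts with SPR
for trees of life; a single NNI-only start per replicate for trees of
domains, whose matrices have one leaf per family (hundreds of tips) and
whose statistic is replicate-averaged (below). Bootstrap replicates
resample characters as integer weights and use one start plus NNI, a
deliberate effort reduction documented here. `g1` uses uniformly random
labeled topologies via sequential addition to a uniform random edge;
skewness is the standard biased sample skewness; the retention index is
the ensemble form `(sum G - sum S) / (sum G - sum M)` over informative
characters with `M` the state range and `G` the star-tree length.

## Gain/loss tracing

One event per (family, branch) whose child state differs from its
parent state; gains increase the state. Events are branch-counted by
default — one event regardless of the jump size — with a
magnitude-weighted mode for sensitivity analysis. The virtual edge from
the polarization ancestor to the root is excluded by default and
available by flag; recovery experiments include it, because families
arising on the stem lineage land their origination gain exactly there.
Net = gains − losses classifies each family as gained (> 0), lost
(< 0) or unchanged (= 0); ties form an explicit third class. Ratio
summaries are quotients of summed counts — never means of ratios — and
a zero-loss denominator is reported as an infinite-ratio flag rather
than a number. Epoch binning assigns *all* of a family's events to the
epoch of the family's age, since age is a family property, not a branch
property.

Pruned-superkingdom analyses reuse the induced subtree of the global
tree by default (re-search optional); family columns absent from every
kept proteome are dropped first. The equal-sampling experiment draws k
proteomes per superkingdom without replacement, rebuilds a tree per
replicate at configurable effort, and reports per-superkingdom ratio
distributions.

## Timeline

Trees of domains are Lundberg-rooted with the all-maximal-state
ancestor, under the axiom that family abundance and spread accumulate
with age, so the maximal condition is ancestral. A family's relative
age `nd` is its root-to-leaf internal-node count rescaled to [0, 1]
(node counts, not branch lengths, which parsimony trees lack). If all
leaves are equidistant the timeline is degenerate and every `nd` is 0
with a warning.

Near-optimal parsimony trees can differ substantially in node-depth
structure while being nearly equally short, so the `nd` of a single
heuristic tree carries topology noise. The timeline therefore averages
`nd` over a few (default 3) independent replicate searches
(`replicate_node_distances`); this is plain variance reduction and is
the pipeline default.

The molecular clock is linear, fitted by least squares through three
anchor points (nd, Gy) = (0.15, 3.2), (0.26, 2.8), (0.55, 1.6), giving
`age(nd) = 3.822 - 4.028 nd`, which reproduces every anchor within
0.1 Gy; ages are clipped below at 0 Gy and the anchors are
configurable. Epochs are left-closed: nd = 0.15 is intermediate,
nd = 0.55 is late. The f-value is the fraction of proteomes encoding
the family; the Venn group is the concatenation (A, B, E order) of
superkingdoms with at least one encoding proteome, with no prevalence
floor; economy/flexibility/robustness are distinct families, summed
counts, and their ratio per proteome.

**Known limitation.** The `nd` axis is a valid age proxy only for
families whose abundance accumulates along the shared line of descent
(the rooting axiom). For a family block confined to one clade, the
locally cheapest junction to the rest of the tree passes through the
block's *sparsest* — youngest — member, so Wagner trees of domains
systematically invert the within-block age order of clade-restricted
families. Real censuses are dominated by broadly shared families plus
late lineage-specific novelty, which is why the method works there and
why the synthetic generator's origination mixture (below) is the
appropriate validation regime.

## Tree comparison

Nodal distances are leaf-pair path lengths in edge counts; rooted trees
are compared as rooted, so paths through the root count its two
incident edges. RMSD is the root mean square of pairwise differences
over all unordered leaf pairs. The guided randomization test permutes
the leaf labels of one tree uniformly (equivalent in distribution to
permuting both), keeping topology fixed; significance is observed RMSD
below the null mean, and the empirical p uses add-one smoothing,
`p = (1 + #{null <= observed}) / (reps + 1)`, so a perfect observation
reports `1/(reps+1)`, not 0.

## Synthetic data generator

The generator emulates the kind of census the analysis is designed
for: three labeled superkingdom clades (A, (B, E)), each clade
ladder-shaped by default because published domain-census trees of life
are strongly ladderized ("balanced" random-join clades are available).
Branches have unit length; all rates are per branch.

Each family originates exactly once. Origination sites are drawn from
a two-component mixture over the stem lineage (above the root) and all
branches: an *ancient* component decaying with depth
(`exp(-depth_bias * d)`, default bias 1.5, fraction 0.45 — the
multi-superkingdom share of real Venn partitions) and a *recent*
component growing toward the tips (`exp(recent_bias * (d - d_max))`,
default bias 2.0), mirroring the real pattern of a broadly shared
ancient core plus late lineage-specific novelty. After origination at
one copy, each branch applies Poisson(duplication_rate x copies) gains
and Poisson(loss_rate x copies) losses, floored at zero; extinction in
a lineage is absorbing. Duplication acting per copy makes abundance
growth multiplicative, producing the strong old-family abundance
excess (maxima in the thousands) that real censuses show and that the
timeline method exploits. Defaults: 50 taxa (17/17/16), 200 families,
duplication 0.7 and loss 0.14 per copy per branch — a gain-biased
regime with modest per-branch event probability for young families.
Superkingdom rate multipliers apply to branches wholly inside one
clade.

Ground truth records every origination (branch and depth), every
per-branch copy-number change, and the final census; replaying the
events reproduces the census bit-exactly (a tested invariant). What
the generator does **not** emulate: horizontal transfer (a family
never jumps between lineages), sequence evolution, correlated rates
across families, and SCOP semantics (synthetic css strings are
syntactically valid placeholders). Passing recovery tests therefore
demonstrate correctness of the inference machinery under the stated
birth-duplication-loss model, not robustness to reticulate histories.

## Validation design and problem sizes

The acceptance suite checks, at sizes chosen for quick desk runs:
published-summary arithmetic identities (instant); exact agreement of
scores, reconstructions and tallies with brute-force enumeration on
200 random cases with up to 6 leaves and 6 states; search optimality
against all 15 five-taxon topologies on 100 random matrices;
ground-truth recovery at the generator defaults over seeds 1-5
(inferred losses exactly 0 when the loss rate is 0, under occurrence
coding, where uniqueness of the minimal reconstruction makes this a
theorem; rank correlation of inferred vs true net change, and of
replicate-averaged `nd` vs true origination depth); and the tree
comparison worked examples. Note that under 24-state abundance coding
a loss-free history can legitimately yield inferred losses: two
independent duplications may be more parsimoniously explained as one
loss — a property of parsimony, not a defect.

## Reproducibility

Every stochastic operation takes an explicit seed. The pipeline fans a
single global seed out to stages through a fixed affine hash of the
stage name (`pipeline.stage_seed`), so any stage can be re-run in
isolation; re-running a config reproduces every artifact byte for
byte. Axis orders are sorted at construction, and all tie-breaks
(edge enumeration, state choice) are deterministic and documented
above.
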
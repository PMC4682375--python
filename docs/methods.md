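# Methods

This note documents the statistical procedure, the synthetic study
conditions, and the numerical and design choices behind `comirnet`.

## Model and assumptions

The pipeline treats cooperative miRNA regulation as a set-overlap
problem. Its assumptions, stage by stage:

**Differential expression.** Expression values are log2-scale
intensities with approximately gaussian within-group noise. Each gene is
tested with a two-sample t-statistic whose per-gene pooled variance
s_g² (df = n₁+n₂−2) is shrunk toward the mean pooled variance s₀²
across genes:

    s̃_g² = (d₀·s₀² + df·s_g²) / (d₀ + df),   t referred to t(d₀ + df)

with a fixed prior weight of d₀ = 4 pseudo-degrees of freedom. This is
an empirical-Bayes moderation in the spirit of the standard microarray
moderated t: with few samples per group it stabilises variance estimates
without an external dependency; with moderation disabled
(`moderate_variance=False`) a Welch test is used instead. Degenerate
genes (zero standard error) get p = 1 when the group means also agree
and the smallest positive float otherwise; both cases are logged.
P-values are BH-adjusted per dataset; DE at adjusted p < 0.05 (strict
inequality throughout the package, since all thresholds are stated as
"less than"). No fold-change cutoff accompanies the adjusted-p
threshold. Direction-consistent calls are intersected across all
datasets; a shared gene-id namespace across platforms is assumed
(probe-to-gene mapping is out of scope).

**Normalization policy.** Quantile normalization maps every column to
the vector of row-rank means; ties receive the mean of the reference
values at the tied positions, which makes the operation idempotent. By
default (`normalize="auto"`) it is applied only when the
cross-comparability diagnostic fails — maximum pairwise difference of
per-sample medians above 0.25 log2 units — mirroring how public series
are normalized only when their value distributions are not already
comparable. `always`/`never` override.

**Interaction filtering.** Validated evidence is accepted outright;
predicted interactions need ≥ 2 of the 3 prediction sources, counting
distinct source ids (duplicate records within one source add no
evidence). Identifier matching is exact after whitespace trimming. The
marker-list filter defaults to `require_listed` — keeping only miRNAs
recognized in the official identifier list — because the list's role is
the universe of valid identifiers; the literal "remove listed miRNAs"
reading is available as `exclude_listed`.

**Reliable-regulator screen.** Right-sided Fisher exact test per miRNA
per direction, BH across miRNAs within a direction (two independent
families, since the up- and down-regulation networks are built
separately). The default test universe is the intersection of all
platform gene universes restricted to genes targeted by at least one
retained miRNA: a gene that is neither measurable everywhere nor
targetable cannot inform the test. Passing `universe` explicitly
supports the all-marker-genes alternative.

**Overlap network.** The pairwise overlap p-value is the upper
hypergeometric tail P(X ≥ m) with population N (the direction's DE
universe after the interaction-universe restriction, not the pooled
two-direction count), computed via `scipy.stats.hypergeom.sf`. BH runs
over all C(n,2) tested pairs within one direction; pairs where either
miRNA has no DE target are skipped and logged. Edge weight is
exclusively the Jaccard score — p-values vary over too many orders of
magnitude to serve as weights and are retained only as edge attributes.
By default the Jaccard is computed on the direction-specific DE target
sets, consistent with the DE counts entering the overlap test; because
the overlap score's original definition is stated on target sets
without qualification, `jaccard_mode="all_targets"` computes it on the
full filtered target sets instead.

**MCODE.** Vertex weight = k_max × density of the highest k-core of the
closed neighbourhood, where the highest k-core is the induced subgraph
on vertices whose core number equals the neighbourhood's maximum core
index; vertices below the degree cutoff weigh 0. Greedy expansion seeds
from the highest-weight unvisited vertex and admits unvisited
neighbours with weight ≥ seed_weight × (1 − node_score_cutoff) — the
seed's weight, not the parent's, holds for the whole complex — breadth
first to max_depth. Post-processing discards complexes without a
2-core, then haircuts vertices of induced degree < 2; the optional
fluff step (off by default) adds boundary neighbours whose closed
neighbourhood density exceeds the fluff cutoff and may place a vertex
in several modules. Parameters default to the Cytoscape MCODE v1 plugin
defaults (degree cutoff 2, node score cutoff 0.2, k-core 2, haircut on,
fluff off, max depth 100); the plugin version behind published default
settings is generally unstated, so v1 defaults are adopted explicitly.
Module score is density × size = 2E/(V−1), reported rounded half-up to
3 decimals with trailing zeros trimmed. All ties (seed selection,
ranking) break lexicographically on vertex id, making the output
invariant to vertex and edge input order.

## Synthetic study conditions

The generator emulates the real inputs at desk scale. Defaults — used
by the acceptance suite — are: 5 datasets, 2000 genes, 60 miRNAs, 6
samples per group, 5% of genes up-DE and 5% down-DE with a ±4 log2
shift, homoscedastic gaussian noise sd 0.5, per-platform gene dropout
5%, 4 planted cooperative groups of 6 miRNAs sharing a 15-gene DE pool
(pools disjoint, drawn half from the up- and half from the down-set;
an odd group count leans up), background targets per (miRNA, gene) at
rate 0.01, and 30% of planted interactions labelled validated (the rest
appear under ≥ 2 prediction sources, so every planted target survives
filtering). Decoy interactions never overlap planted target sets; each
appears under exactly one prediction source with probability 0.5 (and
is then removed by the consensus filter) or under two sources otherwise.
Baseline expression is normal on the log2 scale (mean 7, sd 1.5),
resembling microarray intensity distributions and keeping quantile
normalization non-trivial. All randomness derives from one integer seed
through per-stage child generator streams, so a fixed configuration
reproduces every artifact byte-for-byte.

Scale choices: 2000 genes × 5 platforms keeps a full pipeline run under
a second, while 100 DE genes per direction leave the planted 15-gene
pools a minority of the DE universe — necessary for the overlap test to
have power, since when shared targets exhaust the DE universe a high
overlap is expected by chance and the hypergeometric tail is 1. The
fast unit-test fixture (600 genes, 3 platforms) raises the DE fraction
to 10% and the background rate to 0.03 for the same reason.

What the generator does **not** emulate: probe-level artifacts, batch
effects, heteroscedastic or intensity-dependent noise, correlated
genes, miRNA expression profiles, and realistic identifier vocabularies.
Passing tests therefore demonstrate correctness of the statistical
machinery and recoverability under idealised noise, not performance on
real microarray series.

## Evaluation

`recovery.match_modules` scores recovered modules against planted
groups by greedy one-to-one matching on descending membership Jaccard
(adequate at these group counts and simple to audit; the optimal
Hungarian assignment is available via `optimal=True`). Acceptance-level
expectations under the default conditions: zero reliable miRNAs and
zero modules in ≥ 95% of null (effect size 0) seeds, and mean
best-match Jaccard ≥ 0.8 over 20 strong-signal seeds.

## Numerical notes

- Hypergeometric tails (overlap test, Fisher, ORA) use
  `scipy.stats.hypergeom.sf`; tests verify them against exact rational
  arithmetic and literal subset enumeration to 1e-12.
- BH adjustment is the standard step-up with stable ordering for ties.
- `overlap_score` returns 0 by convention (logged) when both sets are
  empty and i ≠ j; the i = j case is defined as 1.
- Empty-graph/edgeless inputs yield no complexes; complexes below 2
  vertices are discarded before post-processing.
- All writers are atomic (temp-then-rename), so interrupted runs leave
  no partial outputs.

## Known limitations

- The moderated test fixes d₀ = 4 rather than estimating the prior
  degrees of freedom from the data; with many samples the two coincide
  asymptotically, with very few samples the fixed prior is a pragmatic
  compromise.
- BH families: the per-direction choice for both the screen and the
  network is a modelling decision; a joint two-direction family would
  be slightly more conservative.
- Greedy module matching can understate recovery when modules split a
  planted group; the optimal matcher bounds this from above.
- The pipeline assumes gene-level, uniquely-identified inputs; it does
  not model probe mapping or cross-platform identifier conflicts.
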
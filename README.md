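# comirnet

Cooperative miRNA network inference for two-group expression studies.

MicroRNAs rarely act alone: in LPS-stimulated mouse macrophages (and in
inflammatory signalling generally), sets of miRNAs co-regulate shared
pools of target mRNAs. `comirnet` infers these cooperative miRNA groups
by combining multi-platform gene-expression data with multi-source
miRNA–target interaction tables. It is aimed at systems-biology
practitioners who have several public two-group (control vs treated)
expression series and a consensus target database, and want a tested,
reproducible alternative to stitching the analysis together by hand.

## The method

1. **Differential expression.** Each genes × samples matrix (log2 scale)
   is checked for cross-sample comparability (median spread of the
   per-sample distributions) and quantile-normalized when needed. A
   two-sample t-test with empirical-Bayes variance moderation calls
   per-gene DE status at BH-adjusted *p* < 0.05; up- and down-regulated
   sets are intersected across all datasets and restricted to genes that
   appear in the interaction data.
2. **Interaction filtering.** A (miRNA, gene) pair is *reliable* when it
   has validated evidence or is predicted by ≥ 2 of 3 prediction
   sources. An official marker list optionally restricts the miRNA set.
3. **Reliable-regulator screen.** Per miRNA and direction, a 2×2 table
   (target vs non-target × DE vs non-DE) is tested with the right-sided
   Fisher exact test; BH across miRNAs; reliable at adjusted *p* < 0.05.
4. **Cooperative miRNA network (CMN).** Every pair *(i, j)* of reliable
   miRNAs is tested for excess overlap of DE targets,

   P_overlap = Σ_{k=m}^{min(Ni,Nj)} C(Ni,k) · C(N−Ni, Nj−k) / C(N, Nj),

   with N_i, N_j the DE-target counts, N the direction's DE universe and
   m the shared DE targets. Pairs at BH-adjusted *p* < 0.01 become edges
   weighted by the Jaccard target-overlap score
   S_overlap = |Targets(i) ∩ Targets(j)| / |Targets(i) ∪ Targets(j)|.
   The up- and down-regulation networks are superimposed with node
   classes `up_only` / `down_only` / `both`.
5. **Module extraction.** A from-scratch MCODE implementation
   (core-clustering-coefficient vertex weights, greedy seed expansion,
   2-core filter + haircut post-processing, all defaults) extracts
   cooperative miRNA modules, scored by density × size = 2E/(V−1).

A synthetic-data module generates multi-platform expression with planted
up/down DE genes, consensus-style interaction tables and planted
cooperative miRNA groups, so the full pipeline is testable end to end
with known ground truth and no downloads.

## Worked example

```python
from comirnet import CooperativeMirnaModel, SimulationConfig
from comirnet.synthetic import generate_study

study = generate_study(SimulationConfig(seed=1))   # 5 platforms, 2000 genes,
res = CooperativeMirnaModel(                       # 4 planted groups of 6 miRNAs
    study.datasets, study.interactions
).fit()
print(res.summary())
```

```
Cooperative miRNA network pipeline
==================================================
datasets:                5
DE per dataset (up/down): 100/93, 93/94, 90/101, 97/101, 98/96
intersection up/down:    73/73
after universe filter:   56/53
interactions retained:   2129 pairs
miRNAs retained:         60
reliable miRNAs up/down: 12/12
CMN up:    12 nodes / 30 edges
CMN down:  12 nodes / 30 edges
CMN merged:24 nodes / 60 edges (0 both-direction)
modules up/down:         2/2

Top up-regulation modules (score = 2E/(V-1)):
 cluster score  nodes  edges                                   mirnas
       1     6      6     15 Mir10, Mir13, Mir39, Mir46, Mir59, Mir60
       2     6      6     15   Mir22, Mir28, Mir32, Mir41, Mir8, Mir9
```

Reading this: each platform calls ~95 of the 100 planted DE genes per
direction; the five-platform intersection keeps 73 (platform dropout
removes the rest), and 56/53 of those are targeted by at least one
miRNA. The screen flags exactly the 24 planted cooperative miRNAs
(12 per direction) as reliable, the overlap test connects each planted
group into a 6-clique (15 edges, score 2·15/5 = 6), and MCODE returns
the four planted groups as the four modules.

The same pipeline is scriptable from the shell:

```bash
comirnet simulate --out data/ --seed 1
comirnet run-all --data-dir data/ --out results/
comirnet evaluate --truth data/truth.tsv --modules results/modules_up.tsv --out recovery.json
```

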
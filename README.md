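# coexdiff

Differential gene-coexpression-network analysis for two-condition expression
studies, built around the question: *which genes keep their expression
change but change their network neighbourhood between conditions?*  The
motivating setting is low- (10 cGy) versus high-dose (100 cGy) ionising
radiation in a skin tissue model assayed on bead arrays, but every stage is
generic over a dose × time × replicate design.

The pipeline:

1. **Variance stabilisation.**  Raw probe intensities *y* follow a
   two-component error model *y* = α + μ·e^η + ε (multiplicative noise on
   bright probes, additive noise on dim ones).  The generalised-log
   transform

   g(y) = ln((y − α) + √((y − α)² + λ))

   with (λ, α) estimated by profile maximum likelihood renders the
   measurement SD approximately constant; quantile normalisation then
   equalises the sample distributions, and probes never detected
   (detection p > 0.05 in every sample) are removed.

2. **Differential expression.**  A saturated cell-means ANOVA per gene
   (one mean per dose × time cell, gene-specific pooled MSE — 12 residual
   df on the full 3×4×2 design), *t* contrasts of each dose against the
   0 cGy control at each time, Benjamini–Hochberg FDR at q = 0.10.  The
   *common DE genes* — the intersection of the low- and high-dose DE sets
   at a time point — are the nodes of the condition-specific networks.

3. **Coexpression networks.**  Genes *i*, *j* are linked iff
   (1) PCC(i,j) ≥ 0.3 and one gene is in the other's top-3 most-correlated
   list, or (2) PCC(i,j) ≥ 0.9 and one is in the other's top-50.  The
   result is a sparse, binary, undirected network.

4. **Cross-network topology.**  For a gene with neighbour sets X, Y and
   degrees d₁, d₂ in the two networks, the topological overlap

   TO = |X ∩ Y| / max(d₁, d₂)

   measures neighbourhood conservation; genes with TO ≤ 0.1 are
   *condition-rewired* candidates, with significance judged against a
   degree-preserving random-rewiring null (double-edge swaps, one-sided
   *t* statistic over the null replicates).  Differential connectivity
   (|d₁ − d₂| ≥ 10 links) gives the complementary hub-shift view, and the
   cross-level intersection combines the selections made in the
   common-gene networks and in the all-DE-gene networks.

A synthetic-data generator with planted ground truth (DE shifts in g-log
units, latent-factor coexpression modules, genes rewired to a different
module at the high dose) makes every stage testable without any external
download.

## Worked example

```bash
python examples/06_full_pipeline.py
```

prints (seed 42, 2000 probes):

```
g-log: lambda=9396 alpha=52.4; 1800 probes after detection filtering
T0h: DE 266/270, common 122 (29.5%); netAB1 vs netAB2: 5 low-TO genes (4.1%), 36 high-conn-diff; cross-level intersection 28  [early time point - interpret with caution]
T3h: DE 294/274, common 138 (32.1%); netCD1 vs netCD2: 5 low-TO genes (3.6%), 58 high-conn-diff; cross-level intersection 46
T8h: DE 232/240, common 103 (27.9%); netEF1 vs netEF2: 3 low-TO genes (2.9%), 40 high-conn-diff; cross-level intersection 33
T24h: DE 256/254, common 109 (27.2%); netGH1 vs netGH2: 3 low-TO genes (2.8%), 30 high-conn-diff; cross-level intersection 20
```

Per time point: the number of DE genes at each dose, the size (and
union-percentage) of their intersection, how many shared genes have
TO ≤ 0.1 between the two dose networks, how many shift by ≥ 10 links, and
how many genes pass the connectivity screen at both network levels.  The
recovery examples (`examples/05_network_comparison.py`) additionally score
these calls against the generator's planted truth — planted rewired genes
show a mean TO of ~0.08 versus ~0.34 for faithful module genes and are
strongly enriched among the significant set.

The other example scripts cover each capability in isolation: simulation
(01), variance stabilisation (02), ANOVA DE calling (03), network
construction (04) and network comparison (05).  A thin CLI mirrors the
stages (`coexdiff simulate | preprocess | de | network | compare | run`).

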
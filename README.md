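# keystonetaxa

Keystone-taxon inference for gut microbiome count tables.

Amplicon studies of livestock gut communities routinely ask two linked
questions: *which taxa hold the community together* (keystone taxa), and
*which taxa predict a host phenotype* such as growth rate. `keystonetaxa`
implements the full analysis chain used to answer both from a taxa-by-sample
count table and a per-animal trait table:

1. **Prep** — prevalence filtering (taxa detected in ≥ 50% of samples),
   relative abundance with genus/family roll-up, mean-abundance floors
   (> 0.1% genus, > 1.0% family), bias-corrected Chao1 and Shannon
   diversity.
2. **Community contrast** — Bray-Curtis distance, principal-coordinate
   analysis, and ANOSIM with seeded label permutation (999 permutations).
3. **Screens** — per-taxon Wilcoxon rank-sum between groups, Spearman
   correlation of taxa against continuous traits (growth rate, SCFA
   concentrations, serum immune measures), each screen one
   Benjamini-Hochberg FDR family; genus-level Spearman co-occurrence
   networks at adjusted *P* < 0.05.
4. **RMT network** — a co-occurrence network whose similarity cut-off is
   chosen by random-matrix theory: the |Pearson *r*| matrix is thresholded
   along a grid and the threshold is placed where the eigenvalue
   nearest-neighbour spacing distribution (NNSD) transitions from GOE
   (Wigner, noise-dominated) to Poisson (independent signal blocks)
   statistics.
5. **Node roles** — fast-greedy modularity modules, within-module degree
   *Zi* and participation coefficient *Pi* = 1 − Σ(k\_is/k)², and the
   four-way role classification (peripheral *Zi* ≤ 2.5, *Pi* ≤ 0.62;
   connector *Pi* > 0.62; module hub *Zi* > 2.5; network hub both).
   Connectors and hubs are the keystone candidates. Module summary profiles
   are correlated against host traits (Pearson by default).
6. **Biomarker panel** — a random-forest classifier of host group with
   rfcv-style cross-validated feature-count curves, out-of-bag permutation
   importance (mean decrease accuracy, MDA), an MDA > 2.0 panel, and
   out-of-fold ROC/AUC.

A synthetic community generator with planted ground truth (correlation
modules, multi-module connector taxa, group abundance shifts, trait
couplings) drives the test suite, so every stage is scored against known
truth.

## Worked example

Simulate a study (300 genera, two groups of 10 animals, 6 planted
correlation modules, planted differential taxa and trait couplings), then
run the stages from the shell:

```console
$ keystonetaxa simulate --out demo/fx --seed 1
wrote demo/fx/counts.tsv, demo/fx/traits.tsv, demo/fx/truth.json, demo/fx/taxonomy.tsv

$ keystonetaxa network --counts demo/fx/counts.tsv --out demo/net
threshold 0.68: 161 nodes, 362 edges, Q = 0.753, 98.8% peripherals

$ keystonetaxa ordinate --counts demo/fx/counts.tsv --traits demo/fx/traits.tsv --out demo/ord --seed 1
ANOSIM R = 0.157, p = 0.0260 (999 permutations)

$ keystonetaxa classify --counts demo/fx/counts.tsv --traits demo/fx/traits.tsv --out demo/rf --seed 1
8 features with MDA > 2.0; out-of-fold panel AUC = 0.990
```

Reading the output: the RMT scan picked |r| ≥ 0.68 as the noise/signal
boundary, leaving a strongly modular network (modularity Q = 0.753) in
which almost every node is a peripheral — keystone roles are rare by
construction, exactly as in real gut networks. ANOSIM confirms the two
growth-rate groups differ in community composition (R > 0, p < 0.05), and
a small panel of genera selected at MDA > 2.0 separates the groups almost
perfectly on held-out folds (AUC 0.99). `demo/net/node_roles.tsv` lists
every taxon's module, Zi, Pi and role; `demo/rf/rf_importance.tsv` ranks
genera by MDA with their single-genus AUCs.

The same chain is available as one call (`keystonetaxa run-all`) or from
Python:

```python
from keystonetaxa import SyntheticSpec, generate_dataset, RunConfig, run_pipeline

counts, traits, truth = generate_dataset(SyntheticSpec(seed=1))
run_pipeline(RunConfig(seed=1), "demo/run", counts=counts, traits=traits)
```

Every run writes a `manifest.json` capturing versions, per-stage seeds, the
selected threshold and all analysis settings.

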
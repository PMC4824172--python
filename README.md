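# dupsel

**Duplication-aware selection analysis and gene-family turnover on phylogenies.**

`dupsel` is for molecular evolutionists studying how gene duplication
reshapes selection in a gene family — the motivating case being arthropod
Argonaute genes (Ago1, Ago2, Ago3, Piwi/Aub), where paralogs arising from
duplication can shift to new functions and evolutionary rates. It provides,
in one tested package:

- **Reconciliation**: parsimony (LCA) mapping of a rooted gene tree onto a
  rooted species tree; a gene-tree node is a duplication iff its species
  mapping equals that of one of its children.
- **Duplication-aware codon models** (Goldman–Yang style, 61 sense codons):
  M0 (one ω = dN/dS), multi-ratio branch models on *branch partitions* —
  **Immediate** (only the two branches produced by each duplication get
  their own ω), **All descendants** (every branch descending from a
  duplication does), and per-event **asymmetric/symmetric** lineage
  partitions — plus the **M8/M8a** site models (8-category discretized
  beta plus a selected class with ω_s ≥ 1, or ω_s = 1 under the null).
- **Model comparison**: Akaike weights
  w_i = exp(−Δ_i/2)/Σ_j exp(−Δ_j/2) with Δ_i = AIC_i − min AIC,
  chi-square LRTs with warm-started nesting, and the fixed-ω procedure
  (refit each dataset with ω pinned at another subclade's estimate).
- **Site scans**: per-site class posteriors, E[ω | data], and a
  positive-selection flag at P(ω > 1) > 0.95, via plug-in empirical Bayes
  or a grid integration over site-model parameter uncertainty.
- **Gene-family turnover**: linear birth–death model on a dated
  (ultrametric) species tree — λ gains-or-losses per gene per million
  years (or separate gain/loss rates) — fitted to families × species count
  tables by pruning over a truncated count space, with a Monte Carlo
  resampling p-value for rate differences between families, and the
  completeness filter (keep only species with ≥ 1 gene in every subclade).
- **Simulators** for all of the above, so every estimator can be closed-loop
  tested (simulate → refit) without any external data.

Everything is exposed both as a library (statsmodels-style
`CodonModel(...).fit() -> CodonFitResult`, `GeneFamilyTurnover(...).fit()
-> TurnoverResults`) and as a thin `dupsel` command-line tool
(`reconcile`, `partition`, `fit`, `screen`, `sites`, `turnover`,
`simulate`, `pipeline`).

## Worked example

Simulate a gene family in which the first daughter clade of a duplication
(stem branch included) evolves at ω = 0.22 while the rest of the tree
evolves at ω = 0.13, then refit the two-ratio model and run the
duplication-model screen:

```python
import dupsel as d

fx = d.make_fixtures()
tree = fx["gene_tree"]          # 8 genes, one duplication, branch lengths 0.3

part = d.partition_event(tree, fx["duplication_node"],
                         "all_descendants").merge_classes({2: 0})
spec = d.CodonModelSpec(family="BRANCH", kappa=2.0,
                        omega=[0.13, 0.22], freq_model="UNIFORM")
aln, _ = d.simulate_codon_alignment(tree, part, spec, nsites=1000, seed=1)

fit = d.CodonModel(aln, tree, part, family="BRANCH", freq_model="UNIFORM").fit(seed=0)
print(fit.summary())
screen = d.duplication_model_screen(aln, tree, [fx["focal_clade"]],
                                    freq_model="UNIFORM", seed=0)
print(screen.to_frame().round(3).to_string(index=False))
```

which prints

```
Codon model: BRANCH   lnL = -16752.8770   k = 3   AIC = 33511.7540
frequencies: UNIFORM   converged: True
parameter         estimate     std err
kappa               2.2172      0.0885
omega0             0.13348     0.00778
omega1             0.24449      0.0131

          model        lnL  k       AIC   dAIC  weight
             M0 -16780.845  2 33565.689 53.868     0.0
      Immediate -16775.118  3 33556.236 44.415     0.0
All descendants -16752.911  3 33511.821  0.000     1.0
```

The two-ratio fit recovers the simulated background and post-duplication
rates (0.133 ± 0.008 and 0.244 ± 0.013 at this alignment length; the
median over replicates sits on the truth), and the Akaike-weight screen
puts all support (weight 1.000 to 3 d.p.) on the All-descendants model
that generated the data — the same signature a sustained post-duplication
rate shift leaves in real subclades.

Turnover works the same way on the 16-taxon dated fixture tree (root age
245 My, calibrated internal nodes at 200/150/70 My):

```python
model = d.TurnoverModel(mode="equal", lam=0.0022, nmax=25,
                        root_prior="fixed", root_count=2)
counts = d.simulate_family_counts(fx["species_tree"], model, 2000, root=2, seed=5)
res = d.GeneFamilyTurnover(counts, fx["species_tree"],
                           root_prior="fixed", root_count=2).fit()
print(res.summary())
```

```
Gene-family turnover (equal rates)   lnL = -45403.9434   Nmax = 40
rate            estimate     std err   [per gene per My]
lam           0.00220214    2.05e-05
```

## Layout

```
src/dupsel/trees.py        rooted / dated trees, Newick IO, pruning utilities
src/dupsel/alignments.py   codon alignments (61-state alphabet, masks)
src/dupsel/tables.py       count tables, completeness filter, domain intervals
src/dupsel/reconcile.py    LCA reconciliation and branch partitions
src/dupsel/codon/          rate matrices, pruning likelihood, model fitting,
                           site posteriors
src/dupsel/compare.py      LRTs, Akaike weights, screening procedures
src/dupsel/turnover.py     birth-death turnover model and resampling test
src/dupsel/simulate.py     alignment / count-table simulators, fixtures
src/dupsel/pipeline.py     per-subclade orchestration, domain projection
src/dupsel/cli.py          command-line interface
```

See `docs/methods.md` for the models, numerical choices and limitations.
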
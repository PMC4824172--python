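# Methods

This note records the models implemented in `dupsel`, their assumptions,
the numerical choices behind the fits, what the synthetic-data generators
do and do not emulate, and the package's known limitations.

## Codon substitution models

All codon models act on the 61 sense codons of the standard nuclear
genetic code (stop codons and ambiguous/gapped codons are treated as
missing data). The instantaneous rate between codons *i* and *j* is

    q_ij = 0                               if i and j differ at >1 position
         = pi_j                            synonymous transversion
         = kappa * pi_j                    synonymous transition
         = omega * pi_j                    nonsynonymous transversion
         = omega * kappa * pi_j            nonsynonymous transition

with the diagonal set so rows sum to zero. Each generator is rescaled so
that one unit of branch length equals one expected substitution per codon
site: for single-ratio and branch models every class is normalized by its
own mean rate −Σ_i π_i q_ii; for site-mixture models all classes share the
mixture-mean normalization, so a branch length is the expected number of
substitutions averaged over sites. The matrices are reversible with
respect to π, so transition probabilities are obtained from a symmetrized
eigendecomposition (one `eigh` per ω class per likelihood evaluation)
rather than repeated `expm` calls.

**Parameters and defaults.** κ (transition/transversion rate ratio,
bounds [0.1, 20], start 2.0); ω per branch class (dN/dS, bounds
[1e-4, 20], start 0.3); for site models p0 (proportion of beta-distributed
sites, bounds (0, 1), start 0.9), beta shapes p, q (bounds [0.02, 99]) and
the selected-class ω_s (≥ 1 under M8, exactly 1 under M8a). Codon
frequencies default to F3x4 (position-specific nucleotide frequencies of
the alignment); UNIFORM and F61 (empirical, 0.5 pseudocount) are options.
Frequencies are not counted as free parameters in AIC — they are constant
across the models compared on a dataset, so weights are unaffected.

**Branch partitions.** A partition assigns every branch (identified by its
child node) to an ω class; class 0 is the background. *Immediate* marks
exactly the child branches of each duplication node; *All descendants*
marks every branch whose path to the root passes through a duplication
node (the event's child branches and everything below — not the stem above
the event). For a single focal event the *asymmetric* partition gives each
daughter lineage its own class (child branch only under immediate mode,
the whole daughter clade including its stem under all-descendants mode)
and the *symmetric* partition pools them; merging the asymmetric classes
reproduces the symmetric partition exactly. Nested events are not
double-counted: class membership is binary. Polytomies are rejected.

**Likelihood and fitting.** Felsenstein pruning over compressed site
patterns with per-node rescaling (stable well beyond 20 taxa); missing
codons contribute a partial likelihood of one. Site models mix the
per-class site likelihoods with weights (p0/ncat, ..., 1−p0) via
logsumexp. Optimization is L-BFGS-B on transformed parameters (log for
positive parameters, logit for p0, log(ω_s − 1 + 1e-6) for the selected
class) with three-point finite-difference gradients (relative step 1e-6),
ftol 1e-12, and seeded multi-start (default 3 starts: the warm/default
start plus log-uniform draws within bounds). Refitting from a returned
MLE moves lnL by < 1e-6 in the tested regimes. Standard errors come from
the observed information: a central-difference Hessian at the MLE on the
raw parameter scale (relative step 1e-4), inverted; non-positive-definite
cases yield NaN with the convergence flag unaffected. Non-convergence is
flagged on the result and raised as a warning, never silent.

**Branch lengths** (expected substitutions per codon site) are by default
those of the input tree; `estimate_branch_lengths=True` adds them to the
free parameters, and the screening layer offers `branch_lengths="m0"` —
estimate once under M0, then condition every compared model on those
estimates, which stabilizes nested comparisons. The package's own
benchmark and test designs are simulation studies on trees whose lengths
are known exactly, so they condition on the true lengths; this is a
deliberate study-design choice, with the estimate-then-fix strategy
available and covered by its own test.

## Site posteriors and the positive-selection flag

For a fitted M8/M8a model the per-site posterior of class k is
proportional to (class weight) × (class site likelihood). Two estimators
are provided: `neb` plugs in the MLEs; `beb` (default) integrates over
uncertainty in the site-model parameters (p0, p, q and, under M8, ω_s) on
a 5-point-per-parameter grid spanning the MLE ± 2 SE (clipped to bounds;
±20% when an SE is unavailable) under a uniform grid prior, weighting
grid points by their marginal data likelihood. This is an empirical-Bayes
approximation in the spirit of the Bayes Empirical Bayes procedure, not a
re-implementation of it: the grid is rectangular and the prior uniform.
E[ω | site] averages class ω values over classes and grid points; a site
is flagged positively selected when P(ω > 1 | site) > 0.95. Under M8a the
extra class sits exactly at ω = 1, so nothing can be flagged. When ω
estimates are projected onto protein domains, trimmed (masked) residues
are excluded from domain means; the companion structure-mapping column
instead counts them as ω = 0 over all residues, and residue i corresponds
to codon column i (1-based).

## Model comparison

AIC = 2k − 2lnL with k the number of free parameters (branch lengths
included when estimated). Akaike weights are computed with
max-subtraction. LRT p-values use the plain chi-square upper tail; for
boundary nulls (M8a vs M8, df = 1) this is conservative and the output
notes it. Alternatives are warm-started at null MLEs so the nesting
inequality holds by construction; in the pipeline's M8-vs-M8a comparison
an explicit boundary start (ω_s = 1) is retried if the interior start
falls below the null, and residual optimizer slack below the null (the
boundary equality case) is rounded up to a zero statistic. The
duplication-model screen fits {M0, Immediate, All descendants} with a
shared branch-length strategy; with no duplication nodes the branch models
collapse to M0 and the screen reports a degenerate single-model table
rather than failing. The fixed-ω procedure refits M0 with ω pinned at
another dataset's estimate (k reduced by one) and compares {free, fixed}
by Akaike weights.

## Gene-family turnover

Counts evolve by a linear birth–death process on a dated species tree:
a family with *i* genes gains at rate i·λ_gain and loses at rate i·λ_loss
per million years; zero is absorbing (no de novo origination). λ is
therefore a per-gene rate, and with λ_gain = λ_loss the process is
critical: the expected tip count equals the root count (verified by
simulation). The state space is truncated at Nmax (default 2 × max
observed count + 10; births out of state Nmax are suppressed so rows still
sum to one); after every fit the likelihood is re-evaluated at Nmax + 10
and a shift above 1e-6 raises a warning. Transition matrices come from
`expm` of the truncated generator; the classical closed form for the
equal-rate case, with α = λt/(1+λt),

    P(c|s,t) = Σ_{j=0}^{min(s,c)} C(s,j) C(s+c−j−1, s−1) α^{s+c−2j} (1−2α)^j,

is implemented as an independent cross-check and agrees with the matrix
exponential to 1e-8 and with a Gillespie simulation within Monte Carlo
error. Family likelihoods are computed by pruning over count states,
vectorized across families; the root count is integrated over a uniform
prior on 1..Rmax (Rmax defaulting to the maximum observed count) or fixed
for simulation studies. Rates are estimated by bounded Brent (equal mode)
or L-BFGS-B on log rates (separate mode), with observed-information SEs.

**Resampling test.** To ask whether a family's rate differs from a
reference rate λ_fixed, `resample_rate_pvalue` simulates nrep (default
1000) count tables under λ_fixed, refits λ̂ on each, and returns the
two-sided add-one p-value
p = (1 + #{|λ̂ − λ_fixed| ≥ |λ_obs − λ_fixed|}) / (nrep + 1).
The resampled statistic is the refitted λ̂ per replicate table; this is a
documented stand-in for (not a clone of) the resampling procedure in
turnover software whose internal statistic is unpublished. Turnover
analyses should first apply `filter_complete_species`, which keeps only
species with at least one gene in every subclade table (the guard against
incomplete assemblies inflating loss rates); the species tree is pruned to
the retained species with path lengths preserved.

## Synthetic data and fixtures

`simulate_codon_alignment` draws root codons from π and evolves each site
down the tree with exact per-branch transition matrices (no Gillespie
stepping), under any model family the engine fits; site-class labels are
returned for M8/M8a so sensitivity can be scored against the truth.
`simulate_family_counts` evolves per-family counts by exact draws from the
branch transition matrices. Both are seed-deterministic (same seed, byte-
identical output). The fixture factory supplies a 16-taxon ultrametric
species tree of depth 245 My with named calibration nodes (Brachycera
200, Cyclorrhapha 150, Schizophora 70 My) and an 8-gene tree containing a
single duplication whose daughter clades span four species each, with all
branch lengths 0.3 substitutions per codon site — long enough to be
informative, short enough to avoid saturation.

What the simulators deliberately do **not** emulate: alignment error and
trimming decisions, indels, codon usage heterogeneity (simulation requires
an explicit π or the uniform model; empirical frequency models are
estimated from data, not simulated from), gene conversion between
paralogs, rate variation among synonymous sites, and genome/transcriptome
incompleteness (handled only through the completeness filter). Passing
recovery tests therefore demonstrates estimator correctness under the
model, not robustness to those real-data complications.

## Benchmark design

The recovery benchmarks (scripts/acceptance.py) use desk-scale problem
sizes chosen as the smallest designs at which the estimators are
comfortably stable: 500-codon alignments on the 8-taxon fixture tree with
κ = 2 and uniform frequencies for M0 recovery (20 replicates); 1,000- and
2,000-codon alignments for the two-ratio fit and the model screen; and
2,000-family count tables with a fixed root count of 2 on the 16-taxon
dated tree for λ recovery (11 replicates). Medians over replicates are
reported at the precision the corresponding published estimates are
printed at. All per-replicate seeds derive from the single `--seed`
argument via `numpy` SeedSequence spawning.

## Known limitations

- The BEB-style grid integration is an approximation (see above); NEB is
  available and agrees closely in informative datasets.
- Branch-model ω classes with no assigned branches (possible for
  degenerate partitions) are unidentifiable and show huge/NaN SEs; the
  screen reports such cases as degenerate instead of fitting them.
- No amino-acid or nucleotide models, no M1a/M2a or branch-site models,
  no saturation diagnostics, and no ancestral count reconstruction.
- The chi-square LRT for boundary nulls is conservative; no mixture
  chi-square correction is applied.
- `equal_rate_transition` is the untruncated closed form; it is a
  cross-check, and the truncated `expm` route is what likelihoods use.
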
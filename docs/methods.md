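# Methods

This note documents the models, defaults and numerical choices behind
`omicsnet`, and what the synthetic benchmarks do and do not demonstrate.

## Streamwise VIF regression

Each gene's expression is regressed on the pooled candidate set (all miRNA
expression, per-gene methylation and per-gene CNV features; other genes'
expression is *not* a candidate, but the target's own methylation and CNV
are).  The selection engine is a single streamwise pass:

* Candidates are visited in a uniformly random order drawn from the gene's
  own RNG (seeded by `(global_seed, crc32(gene))`, so batch order and worker
  count cannot change results).  The engine is order-sensitive by
  construction; randomizing the order avoids systematic layer bias.  The
  number of passes is configurable (`n_passes`, default 1).
* Candidate *z* is tested with the *t* statistic its coefficient would have
  in the enlarged model.  Writing r for the current residual and ρ̂² for the
  R² of *z* regressed on the current predictors — estimated on a fixed
  random subsample of `subsample_size` m = 200 rows (capped at n) — the
  candidate's partial sum of squares is ‖z‖²/VIF with VIF = 1/(1 − ρ̂²),
  and the error variance is taken from the model *including* the candidate
  (RSS − (zᵀr)²·VIF/‖z‖², divided by n − p − 2).  This is the exact
  added-variable t when m = n; for m < n the subsample makes it an O(m·p)
  approximation, which is the point of the VIF correction.  Two-sided
  p-values use the normal tail.
* Alpha-investing: wealth starts at `w0` = 0.50; test *i* spends
  αᵢ = wᵢ/(1 + i − f), where *f* is the index of the most recent acceptance
  (0 initially).  Wealth decreases by the spent αᵢ on a failure (so it can
  never go negative) and increases by `dw` = 0.05 on an acceptance.  This
  controls the marginal false discovery rate at roughly the w0 scale; it is
  deliberately liberal, trading a fraction of an expected false selection
  per gene (~0.5 at these defaults) for power.  Users wanting stricter
  selection should lower `w0`.
* Zero-variance candidates are skipped without spending a test.  A constant
  target yields an empty model with adjusted R² 0; genes with fewer than 10
  complete cases are flagged unusable.  Complete cases are determined per
  regression (target plus candidate matrix).
* After the pass, the selected set is refit jointly by OLS on the original
  scale; the reported adjusted R² = 1 − (1 − R²)(n − 1)/(n − p − 1) comes
  from this refit (a final-refit summary, not the running streamwise fit).
  A `max_selected` = 50 cap guards pathological runs.

## Network assembly

Models with adjusted R² ≥ 0.4 — the boundary is inclusive — contribute one
edge per selected regulator, weighted by the refit coefficient so that
repressive effects keep their sign.  No per-coefficient significance filter
and no multiple-testing correction across genes is applied beyond the R²
cutoff; this mirrors the assembly rule of the motivating analysis.

## Subnetwork extraction

"Direct regulators" are strict one-hop in-neighbors of the seed genes' mRNA
nodes.  Prior gene–gene regulations are mapped to mRNA nodes and retained
(they are the whitelist of the next stage).  Seed genes absent from both the
network and the prior are warned about and dropped; extraction fails only if
no seed gene is present at all.  Extraction is idempotent.

## Bayesian-network refinement

All four data types are modeled jointly as a linear-Gaussian Bayesian
network; GISTIC calls are treated as continuous, since mixed
discrete/continuous networks have no standard decomposable score and no
discretization rule is part of the pipeline's contract.  The local score of
node v with parents Pa is the OLS profile log-likelihood minus the BIC
penalty (|Pa| + 2)/2 · log n (coefficients, intercept, variance); a pure
log-likelihood score is available (`score="loglik_gaussian"`).

Search is hill-climbing over add/delete/reverse moves with `restarts` = 10
random restarts (restart k > 0 perturbs the whitelist-only start with up to
3 random edges), a `max_parents` = 5 cap, and deterministic tie-breaking
(moves enumerated in sorted order, strict improvement required).  Whitelist
edges can be neither deleted nor reversed, so every prior edge appears in
the learned DAG.  Acyclicity during the sweep is checked against
descendant sets recomputed once per sweep.

By default the search is **unrestricted** over the subnetwork's nodes.
This matters: the stage's purpose is to model regulation *between*
feature variables, which is exactly what lets it explain away a spurious
regulator → gene edge whose correlation is mediated by another regulator
(the mediated-confounder scenario in the benchmarks).  Restricting the
moves to VIF/prior edges and their reversals (`candidate_edges_only=True`)
is supported but removes that ability, because the mediating
regulator–regulator edge is then outside the search space.  An optional
`layer_blacklist` forbids edges into CNV and methylation nodes; it is off
by default because hard layer constraints are not part of the method's
contract.

The learned DAG is reduced to its Markov-equivalence class by the standard
compelled-edge labeling; whitelisted edges are then pinned directed and
their orientations propagated with Meek's rules R1–R4.  Compelled edges are
reported as directed regulations, reversible ones as undirected.  A
benchmark therefore counts a true regulator → gene edge as recovered if the
refined graph contains the pair either directed correctly or undirected;
an edge compelled in the *wrong* direction does not count.

## Survival analysis

Median dichotomization sends values strictly above the median to the high
group and ties to the low group (the rule is declared and tested; the
convention is arbitrary but fixed).  The Kaplan–Meier estimator steps only
at event times; subjects censored exactly at an event time are counted at
risk for that time.  The log-rank statistic accumulates, over distinct
event times, the group-1 observed events O, their hypergeometric
expectation E and variance V given the risk sets, with ties aggregated per
time; (O − E)²/V is referred to χ²(1).  With zero total events the test
returns statistic 0 and p = 1.  The implementation is first-principles;
the test suite cross-checks it against lifelines to ~1e-9.

## Synthetic-data generator

The generator emulates a TCGA-style integrated cohort at desk scale.
Defaults (chosen once as the study conditions): 200 genes, 50 miRNAs,
200 methylation features, 200 CNV features, 150 samples — 650 candidate
predictors against 150 samples preserves the p ≫ n character of the real
design while running in seconds.

* miRNA ~ Normal(6, 1.5²) (log2-like); methylation ~ Beta with per-feature
  shapes drawn from U(0.8, 4), so features differ in mean and spread; CNV
  categorical on {−2…2} with probabilities (0.05, 0.15, 0.60, 0.15, 0.05).
* Half the genes (`frac_regulated` = 0.5) are regulated by k ~ U{2, …, 5}
  regulators drawn uniformly without replacement across the three layers;
  the rest are pure noise, giving every run a built-in null stratum.
* Effect sizes are drawn on the **standardized-regulator scale** with
  magnitude U(0.8, 1.2), negative for miRNA/methylation and positive for
  CNV (overridable).  Drawing on the standardized scale makes each
  regulator's variance share comparable across layers; the reported true
  coefficient is mapped back to the regulator's native units.
* The noise SD is set from the realized signal variance so the population
  R² of every regulated gene equals `target_r2` = 0.6 exactly.
* Survival times are exponential with hazard
  λᵢ = λ₀ · exp(β · zᵢ), z the driver gene's standardized expression,
  λ₀ = 0.1, β = 1.0 per SD; censoring is independent exponential with rate
  λ₀·c/(1 − c) for censoring fraction c = 0.3 (c = 0 disables censoring).
* Everything is drawn from `numpy` Generators seeded from the config seed;
  the same seed reproduces the cohort bit-identically.

What the generator does **not** emulate: genomic coordinates and CNV
segment structure, probe-level methylation, miRNA target-site logic,
between-regulator correlation (regulators are mutually independent except
through chance), batch effects, and non-linear or interaction effects.
Passing benchmarks therefore show that the pipeline recovers sparse linear
structure under favorable, correctly specified conditions — a necessary
check, not evidence about real cohorts.

## Benchmark harnesses and problem sizes

`omicsnet.benchmarks` (used by the test suite and `scripts/acceptance.py`)
fixes the evaluation scales: 100 replicates of 20-candidate instances for
the streamwise-vs-exhaustive comparison (the exhaustive oracle maximizes
adjusted R² over subsets up to the true model size — an unrestricted
exhaustive search would provably include every noise variable whose partial
|t| exceeds 1, since such a variable raises adjusted R²); one default-scale
cohort for precision/recall; 100 noise genes for the null pass rate; 20/50
replicates for the Bayesian-network enumeration, independence and
mediated-confounder checks (3-node systems, n = 300–500, matching the
exhaustive 25-DAG oracle); 500 null replicates (two exponential groups of
100) for the log-rank level; and one end-to-end run whose seed pathway is
the first 32 regulated genes — a desk-scale stand-in for a ~50-gene KEGG
pathway, large enough that the recall estimate is not dominated by the luck
of which genes enter the pathway.

## Known limitations

* Alpha-investing at w0 = 0.5 accepts ~0.4–0.8 spurious regulators per gene
  by design; exact-support recovery should not be expected from a single
  streamwise pass at these defaults.
* Genes whose fitted model misses the 0.4 cutoff lose all their edges
  before refinement; refined-network recall is bounded by assembly recall.
* Hill-climbing with 10 restarts is a local search; on large subnetworks it
  finds high-scoring, not certified-optimal, structures.
* The Gaussian likelihood treats methylation (bounded) and CNV (ordinal)
  as continuous; with heavily skewed beta values or near-constant CNV
  columns the BIC comparisons become less calibrated.
* The log-rank implementation handles two groups only (the validation
  contract); no Cox adjustment is provided.
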
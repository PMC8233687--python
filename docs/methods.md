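# Methods

## The density statistic

For a gene *g* with annotated length *L<sub>g</sub>* nucleotides, a set of
populations *P*, a mutation-class scheme *S* and a generation cutoff *c*,
the observed-mutation count is

> *m<sub>g</sub>* = #{ records *r* : gene(*r*) = *g*, population(*r*) ∈ *P*,
> class(*r*) ∈ *S*, first-observation(*r*) ≤ *c* }

and the density is *d<sub>g</sub>* = *m<sub>g</sub>* / *L<sub>g</sub>*
(mutations per nucleotide). A record is one distinct allele ever detected in
one population's metagenomic time series, with the generation it was first
seen; it is never re-counted at later timepoints. The cutoff comparison is
inclusive, so counts are nondecreasing in *c* and the cumulative series at
(10k, …, 60k) generations ends in exactly the full-horizon table.

Conventions and edge cases:

* Coordinates are stored 0-based half-open internally (GFF3's 1-based
  inclusive ranges are converted on read), so length arithmetic is
  `end − start` with no adjustments.
* `nonsynonymous` means missense + nonsense, exactly. `all` includes every
  class assigned to a gene — indels and structural variants within gene
  boundaries included — with a `point_mutations_only` switch that restricts
  to {missense, nonsense, synonymous} for the narrower reading.
* The normalizer is the full annotated gene length, not a per-class target
  size; no synonymous/nonsynonymous site counting is performed.
* Intergenic records are read and retained but excluded from every
  gene-level statistic. A record naming an unannotated gene is a hard
  error, as are duplicate gene ids and non-positive lengths.
* The gene universe is exactly the annotation input; genes never mutated
  appear with *m<sub>g</sub>* = 0.

## Association tests

Spearman's rank correlation with two-sided tests against ρ = 0. Ties share
average ranks. For *n* ≥ 10 the p-value uses the t-approximation with
*n* − 2 degrees of freedom (the standard large-sample test, equivalent to
R's `cor.test`); for *n* < 10 the approximation is poor, so the p-value is
exact, by enumerating all *n*! permutations of one rank vector. The
crossover at *n* = 10 keeps full enumeration below 10! evaluations.

Each test's gene universe is the **intersection** of the density table and
the covariate. Missing covariate values are never imputed — an abundance
assay that does not cover a gene is not evidence of zero expression — and
genes absent from a PPI edge set are omitted rather than assigned degree 0
(`DegreeMap.with_zero_imputed` provides the alternative). Zeros policy:
`include` (default) keeps genes with *m<sub>g</sub>* = 0; `exclude` drops
them before testing, the usual sensitivity analysis for count-based
densities. Reported *n* is always the post-filter size. No multiple-testing
correction is applied across panels by default; `results_to_frame(...,
bh_adjust=True)` and `mutdens report --bh-adjust` append a
Benjamini–Hochberg q-value column.

Degenerate inputs fail loudly rather than silently: fewer than 3 shared
genes, or a constant vector on either side, raises `AssociationError` (in
the pipeline sweep such cells become NaN rows so the report keeps one row
per grid cell).

## The synthetic experiment generator

The generator emulates a long-term evolution experiment observed through
metagenomic sequencing, at the level of *observable* mutations rather than
full population dynamics.

**Genome.** `n_genes` (default 4,200) non-overlapping genes on one circular
reference; lengths log-normal (meanlog = ln 800, sdlog = 0.55 — median
~800 nt with a realistic right tail), rounded to positive codon multiples;
intergenic gaps geometric with mean ~100 nt.

**Abundances.** Log-normal per growth condition (default two conditions,
"exponential" and "stationary"; sdlog = 1.6, spanning roughly three orders
of magnitude as bacterial proteomes do), correlated across conditions
through a shared Gaussian factor (normal-scale correlation 0.8;
`condition_corr=1` forces identical ranks). The selection covariate is the
standardized mean log-abundance *z<sub>g</sub>*.

**PPI network.** Expected degree λ<sub>g</sub> ∝ exp(δ·z<sub>g</sub>),
scaled to mean degree 8; realized degrees Poisson(λ), paired by the
configuration model with self-loops and multi-edges rejected. δ = 0
decouples degree from abundance; an infeasible (all-zero) degree sequence
is resampled with a logged retry count.

**Mutations.** Candidate point mutations arise per hypermutator population
and gene as Poisson(μ<sub>h</sub>·L<sub>g</sub>) over the horizon, with
μ<sub>h</sub> = 6·10⁻⁴ per nt — about 2,300 candidates per population over
60,000 generations, the order observed in hypermutator lines of long-term
experiments. A candidate is synonymous with probability `frac_syn` = 0.25
(the approximate synonymous fraction of random coding changes), otherwise
nonsynonymous, split missense:nonsense 9:1. Purifying selection acts as
thinning: a nonsynonymous candidate is removed with probability
π<sub>g</sub> = expit(β·z<sub>g</sub>) — logistic because it is the minimal
bounded monotone link for a removal probability; the shape is a
configuration hook, the model requires only monotonicity. β = 0 gives
uniform π = ½ (no abundance coupling). Synonymous candidates arise at a
rate multiplied by 1 + γ·max(z<sub>g</sub>, 0), renormalized so the
genome-wide expected synonymous total is independent of γ — the bias is
purely distributional, isolating the correlation mechanism from a rate
confound. Surviving mutations receive first-observation generations
uniform on (0, horizon]: no clonal dynamics are simulated, so the rising
cumulative |ρ| arises purely from accumulating counts. Nonmutator
populations use μ<sub>n</sub> = μ<sub>h</sub>/100 with no selection
thinning, plus a positive-selection channel concentrating extra candidates
(50× rate) in 20 random target genes, mimicking parallel adaptive targets.

Defaults β = 2, γ = 1, δ = 1 define the standard study conditions used
throughout the tests; at these settings the full-size nonsynonymous
density–abundance correlation is ρ ≈ −0.5, a moderate-effect regime (the
couplings are phenomenological and not calibrated to any particular
empirical effect size). All randomness flows from a single seed through
per-stage substreams, so a dataset is byte-reproducible and replicate
mutation tables can be drawn over a fixed genome and covariates.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: allele-frequency trajectories and clonal
interference (appearance times are uniform by construction), mutation-rate
heterogeneity along the genome and spectrum biases, epistasis, operonic
correlation of expression, annotation errors, and the sharing of one real
reference genome across populations. Tests against the generator verify the
pipeline's statistical machinery and direction-of-effect recovery, not
empirical effect sizes.

## Numerical and design choices

* Counting is vectorized (pandas group-by) but pinned to a brute-force
  record-loop oracle on random small instances, including class-partition
  and population additivity.
* The Spearman implementation is pinned to an independent plain-Python
  ranks-then-Pearson oracle over all permutations of *n* = 5 and enumerated
  tie patterns at *n* ≤ 6, at 10⁻¹² tolerance, and its two-sided test is
  calibration-checked against the null simulation (β = γ = 0) at level
  0.05.
* Rank statistics are invariant under strictly monotone covariate
  transforms (checked to 10⁻¹²), so plotting-side square-root or log
  scaling never changes a reported ρ.
* Zeros-exclusion behavior in the simulator is subtle: removing unmutated
  genes raises |ρ| *on average* under the default conditions (zero-count
  genes are dominated by short genes whose density rank is noise), but not
  in every replicate — at β = 2 the zeros themselves carry selection signal
  (π<sub>g</sub> → 1 for the most abundant genes), and conditioning on
  survival flattens the gradient, most visibly for the nonsynonymous-only
  scheme. The suite asserts the mean effect.
* Pipeline reports are written at full float precision (rounding happens
  only in the human-readable `report` view), and the manifest records the
  config hash, seed and library versions needed to re-run bit-exactly.

## Known limitations

* The exact-permutation p-value is total enumeration; it is intended for
  the tiny-*n* regime only.
* The abundance generator's between-condition correlation is specified on
  the Gaussian (log) scale; the realized rank correlation is slightly
  smaller except at the ±1 limits.
* Degree imputation, confidence thresholds for weighted edge lists, and the
  point-mutations-only switch are provided but off by default; defaults
  follow the analysis conventions described above.
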
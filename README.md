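# mutdens

Per-gene mutation density and rank-correlation analysis for
experimental-evolution metagenomics.

## The problem

A universal pattern of molecular evolution is that highly expressed and
highly interacting proteins evolve slowly, usually attributed to purifying
selection. Evolution experiments with microbes make this testable on
decadal timescales: in metagenomic time series of evolving populations —
especially *hypermutator* lineages whose broken DNA repair floods the
population with nearly neutral mutations — the mutations that *ever* reach
an observable allele frequency trace out which genes tolerate change and
which do not.

`mutdens` implements that analysis for anyone working with processed
mutation tables from such experiments:

* **Mutation density.** For gene *g*, count the distinct mutations ever
  observed in it across a chosen set of populations, a mutation-class
  scheme (`all`, `nonsynonymous` = missense + nonsense, `synonymous`), and
  a generation cutoff, then normalize by gene length:
  *d<sub>g</sub> = m<sub>g</sub> / L<sub>g</sub>*. Every annotated gene
  appears, including those with *m<sub>g</sub>* = 0. Because a mutation
  counts once if it was ever seen, the statistic needs no phylogeny and is
  unaffected by clonal interference or frequency-dependent dynamics.
* **Association tests.** Two-sided Spearman rank correlations (average
  ranks for ties; t-approximation with *n* − 2 df, exact permutation for
  *n* < 10) between density and any gene-level covariate: mRNA or protein
  abundance per growth condition, or protein–protein-interaction (PPI)
  degree. Zeros-included (default) and zeros-excluded variants; cumulative
  time courses that recompute ρ at each successive generation cutoff.
* **A synthetic experiment generator.** Genome, abundances, PPI network
  and per-population mutation tables under an observable-mutation model
  with abundance-coupled purifying selection (removal probability
  π<sub>g</sub> = logistic(β·z<sub>g</sub>) on standardized log-abundance
  z<sub>g</sub>), an expression-coupled synonymous rate bias (γ), and an
  abundance–degree coupling (δ) — so every stage of the pipeline is
  testable at desk scale, with known ground truth.

## Worked example

```sh
python examples/02_abundance_correlations.py
```

simulates the default experiment (4,200 genes, 6 hypermutator + 6
nonmutator populations, 60,000 generations, β = 2, γ = 1) and prints:

```
           all vs abundance, zeros include: rho = -0.260, p = 5.45e-66, n = 4200
           all vs abundance, zeros exclude: rho = -0.265, p = 1.88e-54, n = 3320
 nonsynonymous vs abundance, zeros include: rho = -0.522, p = 8.51e-293, n = 4200
 nonsynonymous vs abundance, zeros exclude: rho = -0.395, p = 4.01e-90, n = 2385
    synonymous vs abundance, zeros include: rho = +0.224, p = 9.18e-49, n = 4200
    synonymous vs abundance, zeros exclude: rho = +0.225, p = 7.43e-26, n = 2138
```

Nonsynonymous density anticorrelates with abundance (the purifying-selection
signature), synonymous density correlates positively (the simulated
expression-coupled rate bias), and `n` is the number of genes entering each
test. The other examples cover density tables, the cumulative time course,
PPI degree, and the configuration-driven pipeline.

The same analyses run from the shell:

```sh
mutdens simulate --config sim.yaml --outdir data/
mutdens density --annotations data/annotations.tsv --mutations data/mutations.csv \
    --populations hypermutator --scheme nonsynonymous --out density.tsv
mutdens correlate --density density.tsv --abundances data/abundances.tsv \
    --ppi data/ppi.tsv --out assoc.tsv
mutdens run-all --config run.yaml     # full grid, manifest, reports
```

Real data plug in through the same readers: GFF3 or TSV gene annotations, a
flat one-row-per-ever-observed-allele mutation CSV, long-format abundance
TSVs, and two-column PPI edge lists.

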
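# crossqtl

An eQTL mapping toolkit for two-parent haploid crosses (segregant panels),
covering the full genetic analysis of transcript-level variation:

- **`crossqtl.synth`** — synthetic cross generator: recombinant genotype
  mosaics under a Haldane (Poisson crossover) model, planted expression
  phenotypes with additive eQTLs, trans hotspots, batch/growth nuisance
  effects, polygenic background and epistatic pairs, plus overdispersed
  (beta-binomial) allele-specific read counts.  Every simulation returns a
  ground-truth ledger for recovery testing.
- **`crossqtl.io`** — TSV I/O for genotype/expression/covariate tables,
  expression filters (read-count and low/invariant-transcript rules),
  perfect-LD marker collapsing, and OLS residualization.
- **`crossqtl.mixed`** — kinship construction (additive and Hadamard-square
  epistatic kernels), spectral REML variance components (heritability), and
  leave-one-chromosome-out (LOCO) polygenic residualization.
- **`crossqtl.scan`** — additive eQTL detection: background-effect screen
  (LOD > 3.5, three rounds), per-chromosome forward stepwise scans with a
  permutation-grid FDR criterion (LOD grid 1.5–9 by 0.05, shared permutation
  orderings), 1.5-LOD-drop confidence intervals with perfect-LD extension,
  local/distant classification, leave-one-batch-out cross-validated variance
  explained, and Monte-Carlo detection power.
- **`crossqtl.hotspot`** — multivariate trans-hotspot fine-mapping:
  residual-factor eigenvector covariates, per-chromosome trans score
  matrices via SVD with permutation-based rank selection, determinant LOD
  scans with 100-permutation thresholds, drop-one peak refinement (75 kb
  rule), ghost (two-locus) testing for very strong peaks, bootstrap
  confidence intervals over an 80-marker window, and targeted forward scans
  for hotspot target genes.
- **`crossqtl.epi`** — eQTL–eQTL interaction scans: high-correlation marker
  reduction, full 2-D product-term LOD scans with same-chromosome exclusion,
  permutation FDR (10%), marginal-scan restriction, and additive-pair
  F-tests.
- **`crossqtl.ase`** — allele-specific expression: hypergeometric
  downsampling, exact binomial tests with Bonferroni correction,
  beta-binomial overdispersion MLE, power grids and gene-matched power
  simulation, and standardized major axis (SMA) effect-size regression.
- **`crossqtl.stats`** — Storey π1 sharing estimates, G-tests, and 2×2
  Fisher enrichment.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (power, algebraic
identities, FDR calibration, parameter recovery, hotspot localization, REML
oracle equivalence) at reduced simulation scales.

## Command line

All subcommands share `--seed`, `--threads`, and `--log-level` global flags
and exchange TSV files:

```sh
# simulate a study (genotypes, map, expression, covariates, truth ledger)
crossqtl --seed 1 simulate --n-segregants 1012 --n-genes 500 --out-prefix study

# filters and perfect-LD collapsing
crossqtl filter --tpm tpm.tsv --read-totals totals.tsv --out expr.tsv
crossqtl collapse-ld --genotypes study.genotypes.tsv --map study.map.tsv --out-prefix collapsed

# heritability, additive eQTLs, hotspots, interactions, ASE
crossqtl h2 --genotypes ... --map ... --expression ... --out h2.tsv
crossqtl --seed 1 map-additive --genotypes ... --map ... --expression ... \
    --annotation study.annotation.tsv --covariates study.covariates.tsv --out eqtls.tsv
crossqtl --seed 1 map-hotspots --genotypes ... --map ... --expression ... \
    --eqtls eqtls.tsv --out hotspots.tsv
crossqtl --seed 1 map-epistasis --genotypes ... --map ... --expression ... \
    --eqtls eqtls.tsv --mode full --out interactions.tsv
crossqtl --seed 1 ase --counts ase_counts.tsv --out ase_results.tsv
```

## Conventions

- Genotypes are coded BY = −1, RM = +1; positive effects mean higher
  expression with the RM allele.
- Coordinates are 1-based bp, closed intervals.
- Univariate LOD = −n·ln(1−r²)/(2·ln 10); multivariate LOD =
  (n/2)·log10(|RSS₀|/|RSS|).
- All randomness flows from explicit seeds.
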
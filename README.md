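# snase

Allele-specific expression (ASE) analysis for droplet-based single-nucleus
RNA-seq, across many individuals.

In an individual heterozygous at a SNP, reads can be assigned to the
maternal or paternal copy of a gene; deviation from a 50:50 ratio
(allelic imbalance) is direct, within-individual evidence of
*cis*-regulatory variation. `snase` implements the computational path
from tagged alignments and a phased VCF to tested imbalance:

- **Counting** (`snase.ase_counting`): resolve each read to an allele from
  the heterozygous SNPs it covers (with the strict >95% majority rule for
  conflicting SNPs), collapse reads into molecules keyed by
  (cell barcode, UMI, feature), and tally reference / alternative /
  ambiguous molecules per cell or per individual at gene, SNP or peak
  level. Phased mode translates observations into haplotype 1/2 via the
  genotypes (`0|1` / `1|0`) so molecules not overlapping the anchor SNP
  still contribute. Also here: het-SNP calling from pileups
  (DP > 10, 0.1 < AD/DP < 0.9), region-category QC, CIGAR error
  profiles, hybrid-selection bait design, seeded downsampling.
- **Isoform assignment** (`snase.isoform_assign`): interval-tree lookup of
  candidate isoforms (including a per-gene *unspliced* pseudo-isoform for
  pre-mRNA), exon blocks trimmed to the read extent, candidates kept only
  when the base overlap reaches 95% of both the trimmed isoform and the
  read, largest overlap wins unless a runner-up is within 10 bp.
- **Statistics** (`snase.ase_stats`, `snase.betabin`): with reference-
  oriented counts y out of n per unit, the model is

      y ~ BetaBinomial(n, mu, rho),   logit(mu) = x'beta [+ b_j],
      b_j ~ Normal(0, sigma_b^2)

  where `rho` is the intra-unit correlation (`mu = a/(a+b)`,
  `rho = 1/(a+b+1)`). The intercept is the imbalance effect (log-odds of
  the reference-oriented allele; 0 means balanced) and is tested with a
  Wald z. The pseudobulk variant fits per-individual aggregates; the
  mixed variant fits cell-level counts with a per-individual random
  intercept integrated out by adaptive Gauss–Hermite quadrature.
  Differential imbalance adds a condition covariate; peak-vs-gene
  comparisons, Fisher 2x2 tests with FWER control, BH/Bonferroni
  adjustment, allele-permutation calibration and individual downsampling
  round out the layer.
- **Synthetic data** (`snase.simdata`): seeded generators for cell-level
  counts drawn from the model above and for complete read-level fixtures
  (toy GTF, phased VCF, tagged SAM) with truth tables.

## Worked example

```python
from snase import simdata, ase_stats

cfg = simdata.SimConfig(n_individuals=30, cells_per_individual=40, n_genes=3,
                        gene_effects={"GRIN2A": 0.8, "SNCA": 0.0, "LRRK2": -0.4},
                        sigma_b=0.5, rho=0.05, seed=11)
table, truth = simdata.simulate_counts(cfg)
res = ase_stats.test_allelic_imbalance(table, model="pseudobulk")
res["fdr"] = ase_stats.adjust_pvalues(res["p"], "BH")
print(res[["feature_id", "n_individuals", "n_total", "effect", "se", "p", "fdr"]])
```

```
feature_id  n_individuals  n_total  effect      se         p       fdr
    GRIN2A             30     5831  0.6545 0.09235 1.368e-12 4.104e-12
     LRRK2             30     5984 -0.4376 0.08993 1.137e-06 1.706e-06
      SNCA             30     5970  0.1271 0.09517    0.1819    0.1819
```

`effect` is the intercept on the logit scale: GRIN2A's 0.65 means the
reference-oriented allele carries about e^0.65 ≈ 1.9-fold the expression
of the other, recovered close to the simulated 0.8 and clearly
significant; the null gene SNCA is not. The cell-level mixed model on one
gene prints a statsmodels-style summary:

```python
mm = ase_stats.fit_betabin_mixed(table.df[table.df.feature_id == "GRIN2A"])
print(mm.summary())
```

```
BetaBinomialMixedModel  nobs=1102  llf=-1537.403
rho=0.04738  sigma_b=0.5047  converged=True
            coef  std err      z  P>|z|
Intercept 0.7042   0.0979 7.1909 0.0000
```

A thin CLI mirrors the library (`snase count`, `snase assign-isoforms`,
`snase test`, `snase call-het`, `snase design-baits`, `snase qc`,
`snase simulate`); run `snase --help`.

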
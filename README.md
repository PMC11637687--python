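# barrierscan

Do the loci behind **intraspecific mating-signal variation** (cricket song,
cuticular-hydrocarbon pheromones) coincide with **interspecific barrier
loci**? `barrierscan` is a Python toolkit for answering that question in a
pair of hybridizing sister species sampled across a contact zone. It
implements the full combinatorial framework as a library:

* **Divergence scans** — site-wise Weir–Cockerham F_ST
  (F_ST = a/(a+b+c) from the variance components), windowed π and d_XY with
  callable-site denominators, 99th-quantile outlier calling, and the five
  standard comparisons (between species overall / in allopatry / in
  sympatry, and allopatric-vs-sympatric within each species).
* **Introgression** — Patterson's D = (ABBA−BABA)/(ABBA+BABA) and f4 from
  population allele frequencies, block-jackknife Z-scores, exhaustive trio
  enumeration with the three-part significance rule (Z > 3, BH q < 0.05,
  D > 0.05).
* **Demographic model comparison** — joint-SFS fits of isolation,
  continuous-migration, ancestral-migration and secondary-contact models by
  Poisson composite likelihood with Monte Carlo coalescent expected spectra,
  multi-round Nelder–Mead optimization and AIC ranking.
* **Selective sweeps** — EHH decay and the integrated haplotype score
  iHS = ln(iHH_A/iHH_D), standardized within derived-frequency bins.
* **Trait association** — per-SNP linear mixed models
  y = Wα + xβ + u + ε, u ~ N(0, σ²_g K), with kinship K from centered
  genotypes, Wald tests, a multi-trait omnibus for CHC principal components,
  and BH/Bonferroni correction.
* **Genotype–environment association** — latent-factor (K-factor) ridge
  model of latitude/longitude effects with genomic-inflation calibration and
  the dual p < 0.001 criterion.
* **Structure** — LD pruning, genotype PCA, simplex-constrained ancestry
  fractions.
* **Synthetic data with planted truth** — a Balding–Nichols contact-zone
  SNP generator (with barrier loci, contact-zone introgression, QTLs,
  phenotypes), a forward Wright–Fisher haplotype simulator with hard
  sweeps, and a structured-coalescent joint-SFS sampler. Every analysis
  stage is validated against these generators and against brute-force
  oracles.

Standard formats are supported at the boundaries: VCF (via cyvcf2), BED3+
and minimal GFF3 gene intervals, tab-separated population maps
(`sample population species context lat lon`) and phenotype tables.

## A worked example

```python
from barrierscan import integration
from barrierscan.core_io import make_windows
from barrierscan.synthetic_data import SimulationConfig, simulate_snp_dataset

cfg = SimulationConfig(seed=7, n_sites=4000, barrier_fraction=0.0075,
                       barrier_f=0.6, outgroup_samples=0)
gm, popmap, truth = simulate_snp_dataset(cfg)
windows = make_windows({f"chr{i+1}": cfg.chrom_length for i in range(5)})
scan = integration.run_scan_plan(gm, popmap, windows, genes)  # genes: BED-like
for name, m in scan.fst_means.items():
    print(name, round(m["mean_of_ratios"], 4))
```

Running `python examples/divergence_scan.py` (which builds the gene table
too) prints:

```
species_all            mean F_ST = 0.0918 (weighted 0.1165)
species_allopatric     mean F_ST = 0.0935 (weighted 0.1204)
species_sympatric      mean F_ST = 0.0942 (weighted 0.1218)
within_A_contexts      mean F_ST = 0.0081 (weighted 0.0094)
within_B_contexts      mean F_ST = 0.0094 (weighted 0.0106)

99th-quantile outlier genes (between species): 9
planted barrier genes recovered: 8/8
```

Between-species differentiation sits near the drift parameter (0.10);
within-species context comparisons are an order of magnitude lower; and the
planted barrier loci dominate the 99th-quantile outlier gene set.
The other scripts in `examples/` walk through the introgression trios,
demographic model ranking, the sweep scan, the song GWAS, the environmental
clines, and filtering/structure, each printing the numbers it computes and
what they mean.

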
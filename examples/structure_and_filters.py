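"""Variant filtering, LD pruning, PCA and ancestry estimation.

Simulates a contact-zone SNP dataset, applies the standard filter cascade
(per-call depth, site quality, missingness, minor allele count, sample
missingness), LD-prunes, and summarizes structure with PCA and
simplex-constrained ancestry fractions at K=2.
"""

import numpy as np

from barrierscan.core_io import FilterParams, apply_filters
from barrierscan.structure import admixture_als, genotype_pca, ld_prune
from barrierscan.synthetic_data import SimulationConfig, simulate_snp_dataset

cfg = SimulationConfig(seed=9, n_sites=2000, f_between=0.2,
                       outgroup_samples=0, missing_rate=0.05)
gm, popmap, _ = simulate_snp_dataset(cfg)

filtered, report = apply_filters(gm, FilterParams())
print(f"sites in: {report.n_sites_in}  out: {report.n_sites_out} "
      f"(qual fail {report.n_sites_qual}, missing {report.n_sites_missing}, "
      f"MAC {report.n_sites_mac}); samples removed: {report.n_samples_removed}")

keep = ld_prune(filtered, window=50, step=10, r2_max=0.1)
pruned = filtered.take_sites(np.flatnonzero(keep))
print(f"LD pruning retained {pruned.n_sites}/{filtered.n_sites} SNPs")

scores, frac = genotype_pca(pruned, n_pcs=2)
species = popmap.loc[pruned.samples, "species"].to_numpy()
gapA = scores[species == "speciesA", 0]
gapB = scores[species == "speciesB", 0]
print(f"PC1 explains {100*frac[0]:.1f}% of variance; species separate on"
      f" PC1: {gapA.max() < gapB.min() or gapB.max() < gapA.min()}")

Q, F, obj = admixture_als(pruned, k=2, seed=0)
mean_q = {}
for sp in ("speciesA", "speciesB"):
    mean_q[sp] = Q[species == sp].mean(axis=0).round(2)
print(f"mean ancestry fractions at K=2: {mean_q}")
print("Each species should load almost entirely on its own cluster.")
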
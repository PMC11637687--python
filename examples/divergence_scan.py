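"""Divergence scan on a synthetic two-species contact zone.

Simulates unlinked SNPs for two sister species with 30 planted barrier loci,
runs the five-comparison site-wise F_ST scan plus windowed d_XY, calls
99th-quantile outliers and reports how well the planted loci are recovered.
"""


import pandas as pd

from barrierscan import integration
from barrierscan.core_io import make_windows, map_features
from barrierscan.synthetic_data import SimulationConfig, simulate_snp_dataset

cfg = SimulationConfig(seed=7, n_sites=4000, barrier_fraction=0.0075,
                       barrier_f=0.6, outgroup_samples=0)
gm, popmap, truth = simulate_snp_dataset(cfg)
windows = make_windows({f"chr{i+1}": cfg.chrom_length
                        for i in range(cfg.n_chroms)})

# one gene interval centred on every 8th SNP, so outliers can be named
rows = []
for i in range(0, gm.n_sites, 8):
    p0 = gm.sites["pos"].iloc[i] - 1
    rows.append((gm.sites["chrom"].iloc[i], max(0, p0 - 250), p0 + 250,
                 f"gene_{i}", "."))
genes = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id",
                                    "strand"])

scan = integration.run_scan_plan(gm, popmap, windows, genes)
for name, means in scan.fst_means.items():
    print(f"{name:22s} mean F_ST = {means['mean_of_ratios']:.4f} "
          f"(weighted {means['ratio_of_sums']:.4f})")

barrier = truth[truth["role"] == "barrier"]
bgenes = set(map_features(barrier[["chrom", "pos"]], genes, flank=0)["gene_id"])
out = scan.fst_outliers["species_all"]
print(f"\n99th-quantile outlier genes (between species): {len(out)}")
if bgenes:
    print(f"planted barrier genes recovered: {len(out & bgenes)}/{len(bgenes)}")
print("Mean F_ST tracks the drift parameter (0.10); barrier loci, planted at"
      " near-differential fixation, dominate the outlier set.")
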
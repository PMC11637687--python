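"""iHS selective-sweep scan on forward-simulated haplotypes.

Builds a small 'genome' of neutral Wright-Fisher regions plus one region
carrying a hard sweep (s=0.1, sampled near 90% frequency), runs the EHH/iHS
scan, standardizes within derived-frequency bins and reports where the swept
site ranks genome-wide.
"""


import pandas as pd

from barrierscan.selection import ihs_scan, standardize_ihs
from barrierscan.synthetic_data import simulate_forward_region

kw = dict(n_diploid=1500, region_bp=300_000, mu=2.5e-8, rec=4e-8,
          generations=6000)

scans = []
offset = 400_000
for k in range(8):  # neutral background regions
    reg = simulate_forward_region(**kw, seed=100 + k)
    sc = ihs_scan(reg.haplotypes, reg.positions)
    sc["gpos"] = sc["pos"] + offset
    offset += 400_000
    scans.append(sc)

sweep = simulate_forward_region(
    **kw, selection={"pos": 150_000, "s": 0.1, "f_target": 0.9}, seed=1,
)
sc = ihs_scan(sweep.haplotypes, sweep.positions)
sc["gpos"] = sc["pos"]
scans.append(sc)

std = standardize_ihs(pd.concat(scans, ignore_index=True), n_bins=20)
core = std.scans[std.scans["gpos"] == 150_000]
absstd = std.scans["ihs_std"].abs()
print(f"scanned sites: {len(std.scans)}  sweep final frequency: "
      f"{sweep.sweep_final_freq:.2f}")
if len(core):
    pct = float((absstd < abs(core['ihs_std'].iloc[0])).mean())
    print(f"swept site raw iHS = {core['ihs_raw'].iloc[0]:+.2f}, "
          f"standardized = {core['ihs_std'].iloc[0]:+.2f} "
          f"(|iHS| percentile {100*pct:.1f})")
print("Negative raw iHS = extended homozygosity on the derived background;"
      " the swept site sits in the left tail of its frequency bin. NB: with"
      " only 8 background regions the swept region's own hitchhikers dilute"
      " the bin statistics and understate the core's rank — the test suite"
      " uses a 60-region background, where the core lands in the top 1%.")
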
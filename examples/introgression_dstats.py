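"""ABBA-BABA introgression tests across all population trios.

Simulates a contact zone in which 20% allele-frequency mixing is confined to
sympatric populations, then tests every trio against the outgroup and
contrasts mean D between trios that do and do not contain contact-zone
populations — the signature of gene flow restricted to sympatry.
"""

from barrierscan import introgression
from barrierscan.synthetic_data import SimulationConfig, simulate_snp_dataset

cfg = SimulationConfig(seed=3, n_sites=5000, alpha=0.2, f_between=0.2)
gm, popmap, _ = simulate_snp_dataset(cfg)

pops = {p: popmap[popmap.population == p].index.tolist()
        for p in popmap["population"].unique()}
freqs = introgression.population_frequencies(gm, pops)
table = introgression.enumerate_trios(freqs, "outgroup", n_blocks=20)

ctx = popmap.groupby("population")["context"].first().to_dict()
has_symp = table.apply(
    lambda r: "sympatric" in {ctx[r.p1], ctx[r.p2], ctx[r.p3]}, axis=1
)
print(table[["p1", "p2", "p3", "d", "z", "q", "significant"]]
      .sort_values("d", ascending=False).head(8).to_string(index=False))
print(f"\ntrios tested: {len(table)}  flagged significant: "
      f"{int(table['significant'].sum())} (Z>3, BH q<0.05, D>0.05)")
print(f"mean D, trios with sympatric populations: "
      f"{table.loc[has_symp, 'd'].mean():.4f}")
print(f"mean D, allopatric-only trios:            "
      f"{table.loc[~has_symp, 'd'].mean():.4f}")
print("Contact-zone mixing elevates D specifically where sympatric"
      " populations are involved.")
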
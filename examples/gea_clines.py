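"""Latent-factor genotype-environment association (latitude + longitude).

Simulates structured genotypes plus 20 SNPs following a dual latitudinal and
longitudinal cline, fits the K=6 latent-factor model with ridge-regularized
environmental effects, calibrates p-values by the genomic inflation factor
and applies the conservative dual p<0.001 criterion.
"""

import numpy as np

from barrierscan.gea import fit_latent_factors, gea_scan

rng = np.random.default_rng(5)
S, npop, per = 5000, 6, 33
n = npop * per
u = rng.uniform(0.05, 0.95, S)
pf = rng.beta(u * 9, (1 - u) * 9, size=(npop, S))
G = np.concatenate(
    [rng.binomial(2, pf[p][None, :], size=(per, S)) for p in range(npop)]
).astype(float)
lat = rng.uniform(-35, -15, n)
lon = rng.uniform(145, 153, n)
zlat = (lat - lat.mean()) / lat.std()
zlon = (lon - lon.mean()) / lon.std()
planted = rng.choice(S, 20, replace=False)
for s in planted:
    G[:, s] = rng.binomial(2, 1 / (1 + np.exp(-1.5 * (zlat + zlon))))

X = np.column_stack([lat, lon])
model = fit_latent_factors(G.astype(np.int8).T, X, k=6)
scan = gea_scan(model, G.astype(np.int8).T, X)

hits = set(np.flatnonzero(scan["hit"]))
print(f"genomic inflation factors: lat {scan.attrs['gif']['lat']:.2f}, "
      f"lon {scan.attrs['gif']['lon']:.2f}")
print(f"dual-criterion hits: {len(hits)}  "
      f"planted clines recovered: {len(hits & set(planted))}/20  "
      f"false hits: {len(hits - set(planted))}")
print("GIF near 1 means the K factors absorbed the population structure;"
      " hits require calibrated p < 0.001 for BOTH environmental variables.")
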
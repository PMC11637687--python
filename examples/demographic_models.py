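"""Joint-SFS demographic model comparison.

Simulates a joint site-frequency spectrum under secondary contact (divergence
followed by recent gene flow), fits the no-migration and symmetric-migration
models by Poisson composite likelihood with Monte Carlo expected spectra, and
ranks them by AIC.
"""

from barrierscan.demography import compare_models, fit_model_sequence
from barrierscan.synthetic_data import simulate_joint_sfs

truth = {"nu1": 1.0, "nu2": 1.0, "T1": 2.0, "m": 5.0, "T2": 0.5}
sfs = simulate_joint_sfs("sec_contact", truth, n1=8, n2=8, n_loci=5000, seed=4)
print(f"observed spectrum: {sfs.n1}+{sfs.n2} haploid samples, "
      f"{sfs.total():.0f} segregating sites")

fits = fit_model_sequence(sfs, ["no_mig", "sym_mig", "sec_contact"],
                          rounds=[5, 10],
                          n_reps=1000, seed=1)
ranked = compare_models(fits)
print(ranked[["model", "n_params", "loglik", "aic", "delta_aic"]]
      .to_string(index=False))
print("\nData were generated with strong recent gene flow: the migration"
      " model should win by a wide AIC margin (delta AIC >> 10).")
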
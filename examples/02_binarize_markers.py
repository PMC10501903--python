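"""Derive binary amyloid positivity from continuous markers via a
two-component Gaussian mixture.

PET SUVr is abnormal when high, the CSF Ab42/Ab40 ratio when low; the
cutoff sits where the weighted component densities cross (equal posterior
membership probability).
"""

import twostep as ts
from twostep.binarization import apply_cutoff, derive_cutoff, fit_two_component_gmm

cohort = ts.generate_cohort(ts.biofinder_like(seed=7))

for column, direction in (("pet_suvr", "abnormal_high"), ("csf_ratio", "abnormal_low")):
    fit = fit_two_component_gmm(cohort[column])
    cutoff = derive_cutoff(fit, direction)
    labels = apply_cutoff(cohort[column], cutoff)
    agree = (labels == cohort["abeta_pet_positive"]).mean()
    print(f"{column}: components at {fit.means[0]:.3f} / {fit.means[1]:.3f}, "
          f"cutoff {cutoff.value:.3f} ({direction})")
    print(f"  GMM-binarized status agrees with true amyloid-PET status for "
          f"{100 * agree:.1f}% of participants")
print("-> mixture-based cutoffs recover the latent normal/abnormal split "
      "without any labelled training data.")
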
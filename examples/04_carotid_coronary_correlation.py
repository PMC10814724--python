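"""Carotid-coronary association: can the carotid artery predict CALs?

In treated animals a shared per-animal severity factor couples carotid
dilation and wall thickening to coronary dilation.  The analysis computes
Pearson correlations at day 28 on weight-adjusted values
((dimension / body weight) * 100), mirroring how surface vessels are used
as an accessible window on the coronary circulation.
"""

import kdecho as k

cfg = k.default_config(seed=3, n_per_group_per_day=30)
derived = k.derive_table(k.generate_cohort(cfg))
treated = derived[derived["group"] != "control"]

for x in ("carotid_outer_d_mm_wadj", "carotid_wall_mean_wadj"):
    res = k.pearson_corr(treated, x, "coronary_inner_d_mm_wadj", day=28)
    print(f"{x} vs coronary inner (day 28): "
          f"r = {res.r:.3f}, p = {res.p:.2e}, n = {res.n}")

print("\nPositive r with small p: carotid outer diameter and mean wall "
      "thickness track coronary dilation, so a superficial carotid scan "
      "is informative about coronary lesion status.")
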
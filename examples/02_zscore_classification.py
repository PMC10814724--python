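"""Fit the day-0 normative model and classify coronary lesions by Z > 3.

The reference model regresses the day-0 coronary inner diameter on the
square root of body-surface area (BSA = 9.8 * W^(2/3) cm^2 for a mouse of
weight W grams); the Z-score of any later observation is its residual in
units of the residual SD, and a coronary artery lesion (CAL) is flagged
when Z strictly exceeds 3.0.
"""

import kdecho as k

cfg = k.default_config(seed=1)
derived = k.derive_table(k.generate_cohort(cfg))

baseline = derived[derived["day"] == 0]
model = k.fit_normative(baseline, "coronary_inner_d_mm", mode="regression")
print(f"normative model ({model.mode}, n={model.n}):")
print(f"  predicted = {model.intercept:.4f} + {model.slope:.4f} * sqrt(BSA)")
print(f"  residual SD = {model.residual_sd:.4f} mm")

# score a single observation: a 0.35 mm coronary in a 22 g mouse
sqrt_bsa = k.bsa_from_weight(22.0) ** 0.5
res = k.z_score(model, observed=0.35, sqrt_bsa=sqrt_bsa)
print(f"\n0.35 mm coronary at 22 g: Z = {res.z:.2f}, CAL = {res.cal_flag}")
print("(a Z of ~4-5 means the vessel is far outside the day-0 reference "
      "range for this body size)")

# score the whole cohort and tabulate percent Z > 3 by group and day
scored = k.score_table(derived, model, cutoff=3.0)
table = k.percent_z_table(
    scored, "z_coronary_inner_d_mm", cutoff=3.0,
    groups=list(cfg.groups), days=list(cfg.days),
)
print("\npercent of animals with Z > 3.0 by dose group (rows) and day:")
print(table.round(1).to_string())
print("\nBy days 21-28 the high-dose row approaches 100% while the "
      "control row stays at 0% — the lesion classifier separates the "
      "dose groups without sacrificing any animal.")
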
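"""Covariate and genotype association analyses.

Simulates the full study (including the CYP3A4*22 effect on midazolam
AUC and the CYP3A5*1 effect on 4ß-OH-cholesterol), then runs the
pair-clustered covariate regression and the genotype median contrasts.
"""

from twinpk import (
    StudyConfig, simulate_study, nca_table, build_trait_table,
    covariate_regression, genotype_contrast, lean_body_weight,
)

print(f"lean body weight, 70 kg / 1.70 m male: "
      f"{lean_body_weight(70, 1.70, 'M'):.1f} kg\n")

config = StudyConfig(seed=1)
study = simulate_study(config)
pk = nca_table(study.concentrations, config.dose_ug)
table = build_trait_table(pk, study.endogenous, study.subjects)

res = covariate_regression(table, "midazolam_auc", log_scale=True)
print("log midazolam AUC ~ covariates (pair-clustered SEs):")
print(res.round(4).to_string(index=False))

if table.cyp3a4_22.sum() > 0:
    con = genotype_contrast(table, "midazolam_auc", "cyp3a4_22")
    print(f"\nCYP3A4*22 carriers (n={con.n1}) vs non-carriers (n={con.n0}): "
          f"median AUC {con.median1:.1f} vs {con.median0:.1f} ug*min/L "
          f"({con.percent_difference:+.1f}%, p = {con.p_value:.3f})")
# The generator plants a +35% *22 effect at a realistic carrier count
# (~4 of 114), so single simulated studies show it with varying clarity.
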
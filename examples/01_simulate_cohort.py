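"""Simulate a twin phenotyping study and look at what it produces.

The default configuration mirrors the analysed cohort: 43 MZ + 14 DZ
same-sex twin pairs, 0.2 mg IV midazolam over 2 min, 15 blood samples
over 24 h, three occasions, and four cross-correlated CYP3A biomarkers
with a known ACE variance structure on the log scale.
"""

import numpy as np

from twinpk import StudyConfig, simulate_study

config = StudyConfig()
study = simulate_study(config, seed=1)

print(f"subjects: {len(study.subjects)} "
      f"({(study.subjects.zygosity == 'MZ').sum()} MZ, "
      f"{(study.subjects.zygosity == 'DZ').sum()} DZ)")
print(f"concentration samples: {len(study.concentrations)} "
      f"({config.n_occasions} occasions x {len(config.sampling_times_min)} times x 2 analytes)")

med = study.concentrations.query("analyte == 'midazolam' & time_min == 15")
print(f"median midazolam concentration at 15 min: "
      f"{med.conc_ug_per_L.median():.2f} ug/L")

truth = study.truth
print("generating variance shares (h2 / c2 / e2):")
for t, h2, c2, e2 in zip(truth["traits"], truth["h2"], truth["c2"], truth["e2"]):
    print(f"  {t:<18s} {h2:.2f} / {c2:.2f} / {e2:.2f}")
# The shares are what the downstream twin models should recover; the
# concentrations and endogenous tables are the raw material they see.
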
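"""The whole pipeline in one call: simulate -> NCA -> occasion means ->
repeatability -> twin models -> multivariate -> covariates.

Writes every artifact (tidy CSVs, fit JSONs, a manifest with content
hashes) and a report juxtaposing estimates with the generating truth.
"""

import tempfile
from pathlib import Path

from twinpk import StudyConfig, run_pipeline

outdir = Path(tempfile.mkdtemp()) / "run"
manifest = run_pipeline(StudyConfig(), seed=1, outdir=outdir)

print(f"{len(manifest['outputs'])} artifacts in {outdir}:")
for name in sorted(manifest["outputs"]):
    print(f"  {name}")
print("\n--- report.txt ---")
print((outdir / "report.txt").read_text())
# Rerunning with the same config and seed reproduces identical hashes;
# the report's truth-vs-estimate lines are the quickest sanity check
# that the estimators see through the measurement pipeline.
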
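"""The complete study flow in one call.

Generates the cohort, assigns study groups, builds per-group networks,
ranks IMC cores, filters associations, screens tongue/pulse outliers and
fits per-group CCA — writing every table, Pajek network and a sha256
manifest to the output directory.
"""

import logging

from fatiguenet import StudyConfig, run_study

logging.basicConfig(level=logging.INFO, format="%(levelname)s: %(message)s")

report = run_study(StudyConfig(seed=1, out_dir="study_out"))

print("\nclassified group sizes:", report.group_sizes)
print("\ntongue-pulse CCA per group:")
print(report.cca_summary.to_string(index=False))
print("\nartifacts:", sorted(report.manifest["files"]))

# The sub-health group carries no planted tongue-pulse association, so its
# p-value is large; the healthy and disease groups recover their planted
# first canonical correlations (0.475 and 0.42) up to sampling noise and
# the attenuation induced by outlier trimming.
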
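"""Run the full simulated two-phantom accuracy study.

20 cranial + 16 body setups, each a random 6D motion within +/-3 degrees
and +/-10 mm, with voxel-scaled localization noise; three emulated
registration platforms are scored against the point-match gold standard.
"""

from fidreg import build_phantom, demo_platform_models, run_experiment, summarize
import pandas as pd

models = demo_platform_models()
reports = []
for site, n_setups in (("cranial", 20), ("body", 16)):
    phantom = build_phantom(site, seed=0)
    reports.append(run_experiment(phantom, n_setups, models, seed=2024))
report = pd.concat(reports, ignore_index=True)

table = summarize(report).table
rms = table[table.metric == "rms_tre"].pivot(index="method", columns="site", values="mean")
print("mean rmsTRE (mm) by method and site:")
print(rms.round(2).to_string())

ire = table[(table.metric == "ire_dt") & (table.axis == "mag")].pivot(
    index="method", columns="site", values="mean"
)
print("\nmean |IRE| translation (mm) by method and site:")
print(ire.round(2).to_string())
print()
print("The gold standard (PM) has the smallest rmsTRE; emulated platform")
print("errors propagate into both the held-out marker error and the 6D")
print("isocenter residual, mirroring how real platforms are evaluated.")
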
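"""Run the full subgroup study at a reduced scale.

Generates a 10,000-subject population, fits the four models to the full
sample, derives total-sample factor scores, forms the 63 overlapping
tertile subgroups, refits all four models within each subgroup (252
attempts), and reports how many subgroups pass the admissibility and
fit-threshold screen for at least one model. Tables are written as CSVs.
"""

from pathlib import Path

import pfactorlab as pf

config = pf.StudyConfig(sim=pf.SimulationConfig(n_subjects=10_000, seed=3))
report = pf.run_study(config)

print(f"fit attempts: {len(report.subgroup_fit_table)} (63 subgroups x 4 models)")
t = report.subgroup_fit_table
by_model = t[t["passes"].fillna(False)].groupby("model").size()
print("passing attempts per model:")
print(by_model.to_string())
print(f"\nsubgroups fitting at least one model: {report.pass_count} of 63")
print(f"(single-dataset reference value for comparison: {report.reference_pass_count})")

outdir = Path("example_output")
written = pf.emit_tables(report, outdir)
print(f"\ntables written to {outdir}/: " + ", ".join(p.name for p in written.values()))
# The realized pass count varies with the random dataset and the sample
# size; what is stable is the pattern: passers concentrate in the
# correlated factors model, the full bifactor never passes, and the
# matching-thirds thought-disorder variants favour the revised bifactor.
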
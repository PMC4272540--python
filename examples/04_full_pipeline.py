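"""Run the complete per-sex analysis and write every result table.

One call produces: size ANOVA, shape PCA, MANOVA on leading PCs, CVA,
the three allometric regressions, both angle tests and the CVA of the
non-allometric shape component, with all tables written as plain CSV.
"""

import tempfile
from pathlib import Path

from allomorph import AnalysisConfig, build_spec, run_full_analysis, simulate_dataset

dataset, _ = simulate_dataset(build_spec(angle_e_w=40.0, seed=11))

outdir = Path(tempfile.mkdtemp()) / "analysis"
config = AnalysisConfig(sexes=("female",), n_reps=10_000, seed=1, output_dir=str(outdir))
result = run_full_analysis(config, dataset)["female"]

s = result.summary
print(f"n = {s['n']}, populations = {s['n_populations']}")
print(f"size ANOVA: F = {s['anova_F']:.3f} (p = {s['anova_p']:.2e})")
print(f"shape MANOVA on PC1-PC{s['n_pcs_selected']}: "
      f"Wilks' Lambda = {s['wilks_lambda']:.3f}, F = {s['manova_F']:.3f}")
print(f"CV1 carries {100 * s['cv1_percent_among']:.1f}% of among-population variation")
print(f"allometry: evolutionary {100 * s['evolutionary_percent']:.2f}%, "
      f"within {100 * s['within_percent']:.2f}%")
print(f"evolutionary-vs-within angle: {s['evo_within_angle_deg']:.1f} degrees "
      f"(p = {s['evo_within_angle_p']:.2e})")
print(f"tables written to {outdir}")
# The angle near the generating 40 degrees and the highly significant
# ANOVA/MANOVA mirror a study design where body size drives most of the
# among-population shape divergence.
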
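"""The whole study in one call: simulate, analyze, read the results.

Builds an xla_like synthetic study (three cohorts of naive-Treg-like
samples, with the altered cohort given lower diversity, higher convergence,
shorter junctions and a strong-residue bias), runs the pipeline, and prints
which features separate the altered cohort from young controls.
"""

import tempfile
from pathlib import Path

from repfeat.pipeline import (
    XLA_EFFECT_DIRECTIONS,
    effect_direction_calls,
    make_fixture_study,
    run_pipeline,
)

workdir = Path(tempfile.mkdtemp(prefix="repfeat_demo_"))
config = make_fixture_study("xla_like", seed=1, out_dir=workdir)
report = run_pipeline(config)

print("outputs:", ", ".join(report.output_files))
print("V segments analyzed:", report.stage_counts["v_segments_selected"])

calls = effect_direction_calls(report.tables["tests"], pair=("XLA", "young"))
print(f"{'feature':<14}{'expected':>9}{'observed':>9}{'p_adj':>12}")
for feature, want in XLA_EFFECT_DIRECTIONS.items():
    c = calls[feature]
    arrow = {1: "up", -1: "down"}
    print(f"{feature:<14}{arrow[want]:>9}{arrow.get(c['direction'], '?'):>9}"
          f"{c['p_adj']:>12.2e}")

# Every injected effect should be recovered with the right sign: the
# altered cohort has lower Chao1/evenness (restricted, more clonal
# repertoire), higher convergence, shorter CDR3s with fewer added
# nucleotides, and a higher strongly-interacting-residue fraction.
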
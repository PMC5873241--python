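"""The complete analysis a field season would get, on synthetic records.

Runs the single-cell design (all index families at three classification
levels), the temporal-consistency comparison (one bout vs three pooled
bouts), and the single-resource subset analysis of size specialization.
"""

import warnings

from dietspec import (
    AnalysisConfig,
    SyntheticConfig,
    generate_population,
    run_single_cell_analysis,
    run_subset_size_analysis,
    run_temporal_analysis,
)

warnings.filterwarnings("ignore")

records = generate_population(
    SyntheticConfig(structure="nested", cells_per_individual=(3, 3), seed=9)
)
config = AnalysisConfig(replicates=999, seed=9, subset_resource="Nephila")

single = run_single_cell_analysis(records, config)
for name in ("individual_specialization", "clustering", "nestedness",
             "niche_width"):
    print(f"\n== {name} ==")
    print(single.tables[name].round(3).to_string(index=False))

temporal = run_temporal_analysis(records, config)
print("\n== temporal_consistency ==")
print(temporal.tables["temporal_consistency"].round(3).to_string(index=False))

subset = run_subset_size_analysis(records, config)
print("\n== subset_size_specialization ==")
print(subset.tables["subset_size_specialization"].round(3).to_string(index=False))

print(
    "\nReading the output: low IS with small P = individual specialization; "
    "C_ws near 0\nplus significant NODF = specialists nested inside "
    "generalist diets; WIC/TNW < 1\nwith small P = size specialization; a "
    "temporal mean difference near 0 or positive\n= females keep their "
    "specializations across foraging bouts."
)
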
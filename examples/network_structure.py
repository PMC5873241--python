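"""Diet-network structure: modular clusters or nested subsets?

C_ws compares the overlap network's clustering with its density: near 0
means no modularity, below 0 means discrete specialist groups.  NODF asks
whether specialists' diets are subsets of generalists' diets (0-100).
A nested population shows C_ws near 0 *with* significant NODF.
"""

from dietspec import (
    SyntheticConfig,
    build_diet_matrix,
    cws,
    generate_population,
    nodf_null_test,
    overlap_network,
)

for structure in ("nested", "modular"):
    records = generate_population(SyntheticConfig(structure=structure, seed=5))
    diet = build_diet_matrix(records, level="genus")
    network = overlap_network(diet)
    cw = cws(network, diet, replicates=999, seed=5)
    nd = nodf_null_test(diet, replicates=999, seed=5)
    print(f"{structure:>8}: C_ws = {cw.cws:+.3f} (P = {cw.p_value:.3f}); "
          f"NODF = {nd.nodf:.1f} vs null {nd.null_mean:.1f} "
          f"(P = {nd.p_value:.3f})")

print(
    "\nThe nested population keeps C_ws near zero while NODF beats its "
    "null (specialists\neat subsets of what generalists eat); the modular "
    "population drives C_ws negative\n(discrete groups on disjoint "
    "resources)."
)
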
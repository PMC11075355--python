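"""Fold-enrichment statistics of the SV footprint against genome features.

Fold = (feature bp inside the merged SV footprint / SV bp) divided by
(feature bp / genome bp); significance by Pearson chi-squared on the 2x2
base-pair table with Bonferroni control. QTLs longer than 1 Mb are dropped
and a trait needs fold > 2 at adjusted p < 0.01 to be called enriched.
"""

from svscape.enrichment import feature_family_enrichment, qtl_enrichment
from svscape.simulate import SimulationConfig, simulate_world

world = simulate_world(SimulationConfig(seed=1))
footprint = world.catalog.merged_intervals()

print("repeat-class enrichment in the SV footprint:")
for res in feature_family_enrichment(footprint, world.repeats, world.genome):
    flag = "*" if res.significant else " "
    print(f"  {res.label:10s} fold {res.fold:5.2f}  adj p {res.p_adjusted:.3g} {flag}")

results, tallies = qtl_enrichment(world.qtls, footprint, world.genome)
print(f"QTLs kept after the 1 Mb cap: {tallies['n_qtls']} "
      f"({tallies['n_qtls_dropped_length']} dropped)")
print(f"fraction of QTLs with >=1 bp SV overlap: "
      f"{tallies['frac_qtls_overlapped']:.2f}; "
      f"traits enriched (>2-fold, adj p<0.01): {tallies['n_traits_enriched']}")
# A fold of 1 means the feature occupies the same share of SV space as of
# the genome; folds above 1 with a starred flag indicate enrichment.
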
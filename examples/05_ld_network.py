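"""SV-SNP linkage disequilibrium tiers and the functional-variant network.

r2 is the squared Pearson correlation of dosages within a 1 Mb window;
pairs tier as linked (>=0.2), tagged (>=0.5), highly-tagged (>=0.8). The
network keeps linked SNPs that are e/sQTLs or genome-wide-significant GWAS
loci (p <= 5e-8), TWAS genes at FDR <= 0.05 that are also e/sGenes, and
SV-gene overlap edges (direct or within +-5 kb of the gene body).
"""

from svscape.model import GenotypeMatrix
from svscape.popgen import build_functional_network, ld_r2_window, network_summary, \
    tier_sets
from svscape.simulate import SimulationConfig, simulate_world

world = simulate_world(SimulationConfig(seed=1))
combined = GenotypeMatrix.concatenate(
    [world.catalog.genotype_matrix(), world.snps])
links = ld_r2_window(combined, window=1_000_000, kinds_a=("SV",), kinds_b=("SNP",))
tiers = tier_sets(links)
print(f"SV-SNP pairs with r2 > 0: {len(links)}")
for tier in ("linked", "tagged", "highly_tagged"):
    print(f"  {tier:14s} {len(tiers[tier]):4d} pairs")

graph = build_functional_network(world.catalog, links, world.functional,
                                 world.genes)
summary = network_summary(graph)
print(f"SVs linked to >=1 functional SNP: {summary['n_svs_linked_functional']} "
      f"(eQTL {summary['n_svs_eqtl']}, sQTL {summary['n_svs_sqtl']}, "
      f"GWAS {summary['n_svs_gwas']}; multi-kind {summary['n_svs_multi_kind']})")
# Tier sets are nested by construction: highly-tagged pairs are also tagged
# and linked, mirroring how tag SNPs proxy an SV's genotype.
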
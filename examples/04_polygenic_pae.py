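"""Polygenic ancestry enrichment with size-matched permutation nulls.

Plants a trait whose genes sit in an African-enriched interval and tests it
against random trait sets of the same size.
"""

from admixscan import enrichment_scan as es
from admixscan import polygenic as pg
from admixscan import synthetic_data as sd
from admixscan.ancestry_io import AncestryPalette

palette = AncestryPalette(("AFR", "EUR", "NAT"))
cfg = sd.CohortConfig(
    populations=(
        sd.PopulationSpec("POP_A", (0.25, 0.55, 0.20), 80),
        sd.PopulationSpec("POP_B", (0.25, 0.45, 0.30), 80),
    ),
    palette=palette,
    chrom_length_bp=100_000_000,
    gene_count=100,
    injections=(sd.Injection(40_000_000, 52_000_000, 0, 0.45),),
    seed=21,
)
genes = sd.generate_genes(cfg)
traits = sd.generate_trait_sets(
    cfg, genes, n_traits=10, set_size=6,
    enriched_trait="PLANTED", avoid_injections=True,
)
tables = [es.scan(sd.generate_panel(cfg, p.label), genes) for p in cfg.populations]

results = pg.pae_scan(tables, traits, n_perm=10_000, seed=2)
afr = results[(results.ancestry == "AFR")].sort_values("q")
print("Most significant trait x population PAE rows (African ancestry):")
cols = ["trait", "population", "n_genes_used", "pae_obs", "z_pae", "q"]
print(afr[cols].head(4).to_string(index=False))

consensus = pg.cross_population_traits(results, min_pops=2)
print("\nCross-population consensus hits:")
print(consensus.to_string(index=False))
print("\nPAE sums each trait gene's ancestry z-score; the planted trait's")
print("African PAE exceeds its size-matched permutation null in both")
print("populations, while random traits stay within the null envelope.")
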
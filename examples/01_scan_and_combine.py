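"""Single-locus ancestry-enrichment scan and cross-population combination.

Builds a small synthetic two-population cohort with one African-enriched
locus, scans each population for per-gene ancestry deviations, and combines
the evidence with Fisher's method.
"""

from admixscan import enrichment_scan as es
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
    injections=(sd.Injection(48_000_000, 52_000_000, 0, 0.45),),
    seed=11,
)
genes = sd.generate_genes(cfg)
tables = [es.scan(sd.generate_panel(cfg, p.label), genes) for p in cfg.populations]

for t in tables:
    print(f"{t.population}: mu_AFR = {t.mu_anc['AFR']:.3f}, "
          f"sigma_AFR = {t.sigma_anc['AFR']:.3f}")

universe = es.finalize_gene_universe(tables)
combined = es.fisher_combine(tables, universe, direction="enrich")
afr = combined.data[combined.data.ancestry == "AFR"]
top = afr.nsmallest(3, "p_chi2")
print("\nTop African-enrichment hits (gene, F_CS, chi2 p, BH q):")
for _, row in top.iterrows():
    print(f"  {row.gene}  F_CS={row.F_CS:6.2f}  p={row.p_chi2:.3g}  q={row.q:.3g}")
print("\nGenes near 50 Mb sit inside the injected interval; their combined")
print("African-enrichment p-values should dominate the genome-wide ranking.")
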
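"""Wright-Fisher forward simulation of an admixed population.

Simulates 10 generations of random mating from single-ancestry founders and
shows how drift in a small founding population spreads local ancestry
fractions around the genome-wide mean.
"""

import numpy as np

from admixscan import enrichment_scan as es
from admixscan import null_simulation as ns
from admixscan import synthetic_data as sd
from admixscan.ancestry_io import AncestryPalette

palette = AncestryPalette(("AFR", "EUR", "NAT"))
gene_cfg = sd.CohortConfig(
    populations=(sd.PopulationSpec("X", (0.3, 0.5, 0.2), 1),),
    palette=palette, gene_count=50,
)
genes = sd.generate_genes(gene_cfg)

for N in (100, 10_000):
    cfg = ns.WFConfig(
        N=N, generations=10, theta=(0.3, 0.5, 0.2), palette=palette,
        morgans=1.0, chrom_length_bp=100_000_000,
        sample_size=100, seed=3,
    )
    panel = ns.wright_fisher_sim(cfg)
    h_anc, h_tot = es.count_gene_ancestries(panel, genes)
    f_afr = h_anc[:, 0] / h_tot
    print(f"N = {N:>6}: per-gene AFR fraction mean = {f_afr.mean():.3f}, "
          f"SD = {f_afr.std(ddof=1):.3f}")

print("\nBoth populations keep the founding AFR fraction (0.30) on average,")
print("but the N = 100 bottleneck inflates the per-gene spread: drift in a")
print("small founding population mimics locus-level ancestry deviation, which")
print("is exactly why the screen calibrates against this null.")
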
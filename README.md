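# admixscan

A screen for **admixture-enabled selection**: post-admixture positive
selection acting on ancestry-specific haplotypes that admixture introduced at
intermediate frequency. Given local-ancestry calls for admixed cohorts (e.g.
RFMix-style output for Latin American populations with African, European and
Native American source ancestries), `admixscan` finds genes and polygenic
trait sets whose local ancestry deviates from the genome-wide background,
combines the evidence across populations, calibrates it against admixture
nulls, and translates the strongest deviations into selection coefficients.

It is aimed at population geneticists working with phased local-ancestry
panels who want a tested, reproducible implementation of the
ancestry-deviation scan — including the simulation machinery needed to
validate it without access to any real cohort.

## The statistics

**Single-locus scan.** For each gene and ancestry, count haplotypes whose
ancestry is uniform across the gene (`h_anc`) out of all ancestry-assigned
haplotypes (`h_tot`), form `f_anc = h_anc / h_tot`, and standardize against
the genome-wide distribution of gene-level fractions:

```
z_anc = (f_anc − μ_anc) / σ_anc
```

Genes whose `h_tot` deviates from the genome-wide mean by more than one
standard deviation are dropped. One-sided normal p-values (enrichment and
depletion) are combined across the k populations with Fisher's method,

```
F_CS = −2 Σᵢ ln(Pᵢ)   ~   χ²(2k) under the null,
```

followed by Benjamini–Hochberg FDR (q < 0.05).

**Admixture nulls.** Two routes: (i) gene-wise multinomial redraws of each
gene's haplotype ancestries from the genome-wide fractions, with z-scores
restandardized per replicate; (ii) a Wright–Fisher forward simulation
(default N = 100 diploids, 10 generations) of recombining ancestry tracts
from single-ancestry founders, which carries the drift and linkage structure
the multinomial null ignores. Both feed add-one empirical p-values and a
power analysis across cohort sizes (n = 10 to 10,000).

**Polygenic ancestry enrichment (PAE).** For a trait gene set,
`PAE = Σ z_anc` over the set, tested against 10,000 size-matched random gene
sets: `z_PAE = (PAE_obs − μ_PAE) / σ_PAE`, two-sided p, BH-FDR per
(population, ancestry), and a cross-population consensus of traits
significant with the same ancestry and direction in ≥ 2 populations.

**Selection model.** A tri-allelic recursion treats the three ancestry
components as alleles, with the favored one at multiplicative advantage
1 + s per generation: `p′ = p(1+s)/(1+sp)`. The map from s to terminal
enrichment z is strictly monotone and is inverted by root bracketing to
infer the s that reproduces an observed `z_anc` after t generations (an
upper-bound estimate, since all deviation is attributed to selection).

## Worked example

The `examples/` directory has one short script per capability. The full
screen on the seeded synthetic demo cohort — four admixed populations of 100
diploids, a common African background of 0.25, one injected African-enriched
locus at 45–51 Mb (local fraction 0.45) and one planted trait set:

```
$ python examples/06_full_demo.py
stages completed: load, scan, combine, null, pae, consensus, selection

top African-enrichment gene: GENE0099 (chi2 p = 8.28e-12, q = 1.69e-09, empirical p = 4.90e-05)

consensus PAE traits:
         trait ancestry  direction  n_populations
TRAIT_ENRICHED      AFR          1              4
TRAIT_ENRICHED      EUR         -1              4
TRAIT_ENRICHED      NAT         -1              4

selection fit at the top locus:
population     gene ancestry   z_obs    s_hat  t
  CLM_like GENE0099      AFR 3.38031 0.040775 20
  MXL_like GENE0099      AFR 3.86359 0.053589 20
  PEL_like GENE0099      AFR 3.70470 0.049507 20
  PUR_like GENE0099      AFR 3.27918 0.037954 20
      MEAN GENE0099      AFR      NaN 0.045456 20
```

GENE0099 sits inside the injected interval: the scan recovers the planted
locus as the genome-wide top African-enrichment hit, its combined score
exceeds all 20,000-odd gene-wise null draws (empirical p ≈ 5 × 10⁻⁵), the
planted trait is the only cross-population PAE consensus hit (African
enrichment mirrored by European/Native American depletion), and inverting
the observed z-scores gives a mean selection coefficient near 0.05 over 20
generations.

The same pipeline is scriptable from the shell:

```
admixscan make-demo --out demo_ws --seed 0
admixscan scan --msp demo_ws/CLM_like.msp.tsv --bed demo_ws/genes.bed --out scores.tsv
admixscan fit-selection --z-obs 3.5 --mu 0.25 --sigma 0.05 --t 20
```

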
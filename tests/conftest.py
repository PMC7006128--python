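import numpy as np
import pytest

from admixscan.ancestry_io import (
    UNASSIGNED,
    AncestryPalette,
    AncestryTract,
    GeneModel,
    HaplotypePanel,
    merge_tracts,
)


@pytest.fixture
def palette3() -> AncestryPalette:
    return AncestryPalette(("AFR", "EUR", "NAT"))


def build_panel(palette, hap_specs, span, chrom="chr1", population="TEST"):
    """Build a panel from [(cut_positions, ancestries), ...] per haplotype.

    ``cut_positions`` are the interior breakpoints; ``ancestries`` has one
    more entry than cuts.  Genetic positions use a constant 1 cM/Mb map.
    """
    lo, hi = span
    haplotypes = []
    for cuts, ancs in hap_specs:
        bounds = [lo, *cuts, hi]
        tracts = [
            AncestryTract(chrom, bounds[i], bounds[i + 1],
                          bounds[i] / 1e6, bounds[i + 1] / 1e6, ancs[i])
            for i in range(len(ancs))
        ]
        haplotypes.append(merge_tracts(tracts))
    if len(haplotypes) % 2:
        raise ValueError("need an even number of haplotypes")
    samples = [f"S{i}" for i in range(len(haplotypes) // 2)]
    return HaplotypePanel(
        population=population, samples=samples, haplotypes=haplotypes,
        palette=palette, chrom=chrom, chrom_span=span,
    )


def random_toy_panel(rng, palette, span=(0, 100), max_haps=10):
    """Small random panel with random switch points, incl. UNASSIGNED tracts."""
    lo, hi = span
    n_hap = 2 * int(rng.integers(1, max_haps // 2 + 1))
    specs = []
    for _ in range(n_hap):
        n_cuts = int(rng.integers(0, 5))
        cuts = sorted(set(int(c) for c in rng.integers(lo + 1, hi, size=n_cuts)))
        ancs = [
            int(rng.choice([UNASSIGNED, *range(palette.K)]))
            for _ in range(len(cuts) + 1)
        ]
        specs.append((cuts, ancs))
    return build_panel(palette, specs, span)


def random_toy_genes(rng, span=(0, 100), max_genes=5):
    lo, hi = span
    n = int(rng.integers(1, max_genes + 1))
    genes = []
    for i in range(n):
        a = int(rng.integers(lo, hi - 1))
        b = int(rng.integers(a + 1, hi + 1))
        genes.append(GeneModel("chr1", a, b, f"G{i}"))
    return genes


def brute_force_counts(panel, gene):
    """Per-base enumeration oracle for gene-haplotype ancestry assignment.

    A haplotype counts for ancestry A iff every base of the gene interval is
    covered by ancestry A (no switch, no unassigned base).
    """
    K = panel.palette.K
    h_anc = [0] * K
    for tracts in panel.haplotypes:
        seen = set()
        for bp in range(gene.start_bp, gene.end_bp):
            for t in tracts:
                if t.start_bp <= bp < t.end_bp:
                    seen.add(t.ancestry)
                    break
        if len(seen) == 1:
            a = next(iter(seen))
            if a != UNASSIGNED:
                h_anc[a] += 1
    return tuple(h_anc), sum(h_anc)


def chi2_even_df_sf(x, k):
    """Closed-form chi-square survival for even df = 2k:
    exp(-x/2) * sum_{j<k} (x/2)^j / j!  -- the independent Fisher oracle."""
    from math import exp, factorial

    half = x / 2.0
    return exp(-half) * sum(half**j / factorial(j) for j in range(k))
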
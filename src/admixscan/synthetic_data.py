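"""Synthetic admixed cohorts with known ground truth.

Generates local-ancestry panels under the pulse-admixture tract model: along a
haplotype, ancestry-switch breakpoints form a Poisson process of rate g per
Morgan (g = generations since admixture), and each tract's ancestry is drawn
independently from the population's genome-wide ancestry fractions theta.
This gives closed-form expectations (tract genetic lengths ~ Exp(g), local
ancestry fraction = theta everywhere) that downstream tests check against.

Known deviations from theta can be injected: inside a chosen interval the
target ancestry's draw probability is raised to f_target (other ancestries
rescaled proportionally), so the expected local fraction of the target
ancestry equals f_target at every position in the interval.  Tract boundaries
are forced at the interval edges so the signal is exactly localized.
Optionally each tract is relabelled UNASSIGNED with probability u, emulating
the removal of low-confidence local-ancestry calls.

The module also builds matching gene models (evenly spaced, non-overlapping)
and random trait gene sets, including an optional "enriched" trait whose
genes all lie inside injection intervals — the planted polygenic signal.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np

from .ancestry_io import (
    UNASSIGNED,
    AncestryPalette,
    AncestryTract,
    GeneModel,
    HaplotypePanel,
    TraitGeneSet,
    merge_tracts,
    write_msp,
)

__all__ = [
    "PopulationSpec",
    "Injection",
    "CohortConfig",
    "generate_panel",
    "generate_genes",
    "generate_trait_sets",
    "write_cohort",
    "demo_config",
]


@dataclass(frozen=True)
class PopulationSpec:
    label: str
    theta: tuple[float, ...]  # genome-wide ancestry fractions, sums to 1
    n_samples: int  # diploid individuals

    def __post_init__(self) -> None:
        th = tuple(float(x) for x in self.theta)
        if abs(sum(th) - 1.0) > 1e-12:
            raise ValueError(f"{self.label}: theta must sum to 1")
        if any(x < 0 for x in th):
            raise ValueError(f"{self.label}: negative theta component")
        if self.n_samples < 1:
            raise ValueError(f"{self.label}: need at least one sample")
        object.__setattr__(self, "theta", th)


@dataclass(frozen=True)
class Injection:
    start_bp: int
    end_bp: int
    ancestry: int  # palette code of the enriched ancestry
    f_target: float  # expected local fraction of that ancestry

    def __post_init__(self) -> None:
        if self.start_bp >= self.end_bp:
            raise ValueError("empty injection interval")
        if not 0.0 < self.f_target < 1.0:
            raise ValueError("f_target must lie in (0, 1)")


@dataclass(frozen=True)
class CohortConfig:
    populations: tuple[PopulationSpec, ...]
    palette: AncestryPalette
    generations: int = 10  # g: admixture age, sets tract-length scale
    chrom: str = "chr1"
    chrom_length_bp: int = 100_000_000
    cm_per_mb: float = 1.0
    gene_count: int = 200
    gene_width_bp: int = 20_000
    unassigned_rate: float = 0.0
    injections: tuple[Injection, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.generations < 1:
            raise ValueError("generations must be positive")
        if not 0.0 <= self.unassigned_rate < 1.0:
            raise ValueError("unassigned_rate must lie in [0, 1)")
        for pop in self.populations:
            if len(pop.theta) != self.palette.K:
                raise ValueError(f"{pop.label}: theta length != K")
        for inj in self.injections:
            if inj.start_bp < 0 or inj.end_bp > self.chrom_length_bp:
                raise ValueError("injection interval outside chromosome")
            if not 0 <= inj.ancestry < self.palette.K:
                raise ValueError("injection ancestry outside palette")
        object.__setattr__(self, "populations", tuple(self.populations))
        object.__setattr__(self, "injections", tuple(self.injections))

    @property
    def morgans(self) -> float:
        return self.chrom_length_bp * self.cm_per_mb / 1e8

    def population(self, label: str) -> PopulationSpec:
        for pop in self.populations:
            if pop.label == label:
                return pop
        raise KeyError(label)


def _injected_probs(theta: np.ndarray, inj: Injection) -> np.ndarray:
    """Tract-ancestry law inside an injection interval."""
    th = np.asarray(theta, dtype=float)
    if th[inj.ancestry] >= 1.0:
        raise ValueError("cannot inject into an ancestry already at frequency 1")
    probs = th * (1.0 - inj.f_target) / (1.0 - th[inj.ancestry])
    probs[inj.ancestry] = inj.f_target
    return probs


def generate_panel(cfg: CohortConfig, population: str) -> HaplotypePanel:
    """Simulate one population's local-ancestry panel.

    Breakpoints per haplotype: Poisson(g * L) with L the map length in
    Morgans, positions uniform (the genetic map is constant, so uniform in bp
    too); injection-interval edges are added as fixed boundaries.  Fully
    deterministic given (cfg.seed, population).
    """
    pop = cfg.population(population)
    pop_index = cfg.populations.index(pop)
    rng = np.random.default_rng([cfg.seed, 1, pop_index])
    L_bp = cfg.chrom_length_bp
    rate = cfg.generations * cfg.morgans  # expected breakpoints per haplotype

    theta = np.asarray(pop.theta, dtype=float)
    cum_plain = np.cumsum(theta)
    inj_edges = sorted({e for inj in cfg.injections for e in (inj.start_bp, inj.end_bp)}
                       - {0, L_bp})
    inj_probs = [(inj, np.cumsum(_injected_probs(theta, inj))) for inj in cfg.injections]

    haplotypes: list[list[AncestryTract]] = []
    for _ in range(2 * pop.n_samples):
        n_bk = rng.poisson(rate)
        cuts = np.sort(rng.integers(1, L_bp, size=n_bk))
        cuts = np.unique(np.concatenate([cuts, np.asarray(inj_edges, dtype=np.int64)]))
        starts = np.concatenate([[0], cuts])
        ends = np.concatenate([cuts, [L_bp]])
        u = rng.random(len(starts))
        anc = np.searchsorted(cum_plain, u * cum_plain[-1], side="right")
        anc = np.minimum(anc, cfg.palette.K - 1)
        for inj, cum in inj_probs:
            inside = (starts >= inj.start_bp) & (ends <= inj.end_bp)
            if inside.any():
                anc[inside] = np.minimum(
                    np.searchsorted(cum, u[inside] * cum[-1], side="right"),
                    cfg.palette.K - 1,
                )
        if cfg.unassigned_rate > 0.0:
            drop = rng.random(len(starts)) < cfg.unassigned_rate
            anc[drop] = UNASSIGNED
        tracts = [
            AncestryTract(
                cfg.chrom, int(s), int(e),
                s * cfg.cm_per_mb / 1e6, e * cfg.cm_per_mb / 1e6, int(a),
            )
            for s, e, a in zip(starts, ends, anc)
        ]
        haplotypes.append(merge_tracts(tracts))

    samples = [f"{pop.label}_S{i:04d}" for i in range(pop.n_samples)]
    return HaplotypePanel(
        population=pop.label,
        samples=samples,
        haplotypes=haplotypes,
        palette=cfg.palette,
        chrom=cfg.chrom,
        chrom_span=(0, L_bp),
    )


def generate_genes(cfg: CohortConfig) -> list[GeneModel]:
    """Evenly spaced, non-overlapping gene models across the chromosome."""
    m, w = cfg.gene_count, cfg.gene_width_bp
    if m * w > cfg.chrom_length_bp:
        raise ValueError("genes do not fit on the chromosome")
    spacing = cfg.chrom_length_bp // m
    offset = (spacing - w) // 2
    return [
        GeneModel(cfg.chrom, i * spacing + offset, i * spacing + offset + w,
                  f"GENE{i:04d}")
        for i in range(m)
    ]


def generate_trait_sets(
    cfg: CohortConfig,
    genes: list[GeneModel],
    n_traits: int,
    set_size: int,
    enriched_trait: str | None = None,
    avoid_injections: bool = False,
) -> list[TraitGeneSet]:
    """Random trait gene sets; optionally one planted enriched trait.

    Random traits are uniform draws without replacement from all genes (or,
    with ``avoid_injections``, from genes outside every injection interval,
    so they are genuine negative controls rather than accidental carriers of
    the planted signal).  The enriched trait (if requested) is drawn from
    genes overlapping injection intervals.
    """
    if set_size > len(genes):
        raise ValueError("set_size exceeds the number of genes")
    rng = np.random.default_rng([cfg.seed, 2])
    pool = [
        g.name for g in genes
        if not (avoid_injections and any(
            g.start_bp < inj.end_bp and g.end_bp > inj.start_bp
            for inj in cfg.injections))
    ]
    if set_size > len(pool):
        raise ValueError("set_size exceeds the number of eligible genes")
    names = np.array(pool)
    sets = [
        TraitGeneSet(
            f"TRAIT{i:03d}", "random trait set",
            frozenset(rng.choice(names, size=set_size, replace=False)),
        )
        for i in range(n_traits)
    ]
    if enriched_trait is not None:
        in_inj = [
            g.name for g in genes
            if any(g.start_bp < inj.end_bp and g.end_bp > inj.start_bp
                   for inj in cfg.injections)
        ]
        if len(in_inj) < set_size:
            raise ValueError(
                f"only {len(in_inj)} genes overlap injection intervals; "
                f"need {set_size} for the enriched trait"
            )
        chosen = rng.choice(np.array(in_inj), size=set_size, replace=False)
        sets.append(TraitGeneSet(enriched_trait, "planted enriched trait",
                                 frozenset(chosen)))
    return sets


def write_cohort(
    cfg: CohortConfig,
    out_dir: str,
    n_traits: int = 20,
    set_size: int = 8,
    enriched_trait: str | None = None,
    avoid_injections: bool = True,
) -> dict:
    """Write msp files (one per population), BED, GMT, and a ground-truth TSV.

    Returns a manifest dict with the written paths.
    """
    os.makedirs(out_dir, exist_ok=True)
    msp_paths = {}
    for pop in cfg.populations:
        panel = generate_panel(cfg, pop.label)
        path = os.path.join(out_dir, f"{pop.label}.msp.tsv")
        write_msp(panel, path)
        msp_paths[pop.label] = path

    genes = generate_genes(cfg)
    bed_path = os.path.join(out_dir, "genes.bed")
    with open(bed_path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start_bp}\t{g.end_bp}\t{g.name}\n")

    traits = generate_trait_sets(
        cfg, genes, n_traits, set_size, enriched_trait,
        avoid_injections=avoid_injections,
    )
    gmt_path = os.path.join(out_dir, "traits.gmt")
    with open(gmt_path, "w") as fh:
        for t in traits:
            fh.write("\t".join([t.trait, t.description, *sorted(t.genes)]) + "\n")

    truth_path = os.path.join(out_dir, "ground_truth.tsv")
    with open(truth_path, "w") as fh:
        fh.write("record\tpopulation\tancestry\tstart_bp\tend_bp\tvalue\n")
        for pop in cfg.populations:
            for a, lab in enumerate(cfg.palette.labels):
                fh.write(f"theta\t{pop.label}\t{lab}\t.\t.\t{pop.theta[a]}\n")
        for inj in cfg.injections:
            lab = cfg.palette.labels[inj.ancestry]
            fh.write(
                f"injection\t.\t{lab}\t{inj.start_bp}\t{inj.end_bp}\t{inj.f_target}\n"
            )
        fh.write(f"unassigned_rate\t.\t.\t.\t.\t{cfg.unassigned_rate}\n")

    return {
        "msp": msp_paths,
        "bed": bed_path,
        "gmt": gmt_path,
        "ground_truth": truth_path,
        "palette": list(cfg.palette.labels),
    }


def demo_config(seed: int = 0, n_samples: int = 100) -> CohortConfig:
    """The default four-population demo cohort.

    Four Latin-American-like populations with distinct European/Native
    American mixes and a common African fraction of 0.25, plus one injected
    African-enrichment locus (an MHC-like interval at 45-51 Mb raised to
    f_target = 0.45).  These defaults are package choices for a realistic
    admixture scenario, not estimates from any real cohort.

    The demo keeps every call assigned (unassigned_rate = 0): per-tract
    unassigned relabelling is spatially correlated over whole tract blocks,
    which makes the h_tot retention filter drop multi-megabase regions at
    random — a property worth studying via the generator's u parameter, but
    one that would make the planted demo signal irreproducible.
    """
    palette = AncestryPalette(("AFR", "EUR", "NAT"))
    pops = (
        PopulationSpec("CLM_like", (0.25, 0.55, 0.20), n_samples),
        PopulationSpec("MXL_like", (0.25, 0.45, 0.30), n_samples),
        PopulationSpec("PEL_like", (0.25, 0.35, 0.40), n_samples),
        PopulationSpec("PUR_like", (0.25, 0.60, 0.15), n_samples),
    )
    injection = Injection(45_000_000, 51_000_000, palette.code_of("AFR"), 0.45)
    return CohortConfig(
        populations=pops,
        palette=palette,
        generations=10,
        chrom="chr6",
        chrom_length_bp=100_000_000,
        cm_per_mb=1.0,
        gene_count=200,
        gene_width_bp=20_000,
        unassigned_rate=0.0,
        injections=(injection,),
        seed=seed,
    )
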
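"""Null distributions for the ancestry-enrichment scan.

Two complementary routes to the neutral expectation:

* **Gene-wise multinomial nulls** — each gene's h_tot haplotype ancestries are
  redrawn i.i.d. from the population's genome-wide ancestry fractions, the
  z-scores are recomputed within each replicate, and Fisher-combined scores
  are pooled into an ensemble.  This is the fast, exchangeable null that also
  powers the power analysis across cohort sizes.

* **Wright–Fisher forward simulation** — a discrete-generation, constant-size
  random-mating population of recombining ancestry haplotypes.  Generation 0
  is a set of single-ancestry founders in the genome-wide proportions; each
  offspring haplotype is a meiotic gamete of a uniformly chosen parent, with
  crossover counts Poisson in the map length (no interference) and crossover
  positions uniform on the genetic map.  This null carries the drift and
  linkage structure the multinomial null ignores: small founding populations
  inflate local-ancestry variance.

Empirical p-values use the add-one estimator (1 + #{null >= obs}) / (1 + R'),
which never returns zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ancestry_io import AncestryPalette, AncestryTract, GeneModel, HaplotypePanel, merge_tracts
from . import enrichment_scan

logger = logging.getLogger(__name__)

__all__ = [
    "NullEnsemble",
    "WFConfig",
    "genewise_null",
    "empirical_p",
    "power_analysis",
    "meiosis",
    "wright_fisher_sim",
    "chromosome_null",
]


@dataclass
class NullEnsemble:
    """Replicated null Fisher-combined scores.

    ``values`` has shape (R, genes, ancestries); NaN marks undefined cells
    (degenerate ancestries or filtered genes).  ``mode`` selects the pool
    used by :func:`empirical_p`: every finite value (``per_gene``) or each
    replicate's genome-wide maximum (``max_statistic``, family-wise control).
    """

    values: np.ndarray
    mode: str = "per_gene"
    seed: int | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3 or v.shape[0] < 1:
            raise ValueError("values must be (R, genes, ancestries) with R >= 1")
        if np.nanmin(v, initial=np.inf) < 0:
            raise ValueError("Fisher scores must be non-negative")
        if self.mode not in ("per_gene", "max_statistic"):
            raise ValueError(f"unknown ensemble mode {self.mode!r}")
        self.values = v

    @property
    def n_replicates(self) -> int:
        return self.values.shape[0]

    def pool(self) -> np.ndarray:
        if self.mode == "max_statistic":
            flat = np.nanmax(self.values.reshape(self.n_replicates, -1), axis=1)
        else:
            flat = self.values.ravel()
        return flat[np.isfinite(flat)]


def empirical_p(observed, ensemble: NullEnsemble, mode: str | None = None):
    """Add-one Monte-Carlo p-value of observed F_CS against the null pool."""
    if mode is not None and mode != ensemble.mode:
        raise ValueError(f"ensemble built in mode {ensemble.mode!r}, asked {mode!r}")
    pool = np.sort(ensemble.pool())
    if pool.size == 0:
        raise ValueError("empty null pool")
    obs = np.asarray(observed, dtype=float)
    n_ge = pool.size - np.searchsorted(pool, obs, side="left")
    p = (1.0 + n_ge) / (1.0 + pool.size)
    return float(p) if np.isscalar(observed) or obs.ndim == 0 else p


def _replicate_fisher(
    h_tot: np.ndarray,          # (G,) per-gene totals for one population
    theta: np.ndarray,          # (K,)
    rng: np.random.Generator,
    R: int,
) -> np.ndarray:
    """One population's null one-sided enrichment p-values, shape (R, G, K)."""
    G, K = len(h_tot), len(theta)
    draws = rng.multinomial(np.broadcast_to(h_tot, (R, G)), theta)  # (R, G, K)
    f = draws / h_tot[None, :, None]
    mu = f.mean(axis=1, keepdims=True)
    sigma = f.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (f - mu) / sigma
    z[np.broadcast_to(sigma == 0, z.shape)] = np.nan
    return stats.norm.sf(z)


def genewise_null(
    h_tot_per_pop: dict[str, np.ndarray],
    theta_per_pop: dict[str, np.ndarray],
    R: int,
    seed: int,
    mode: str = "per_gene",
) -> NullEnsemble:
    """Gene-wise multinomial null ensemble of Fisher-combined scores.

    For each replicate and population, every gene's h_tot haplotypes are
    drawn i.i.d. from that population's genome-wide fractions theta; z-scores
    are standardized within the replicate and enrichment p-values combined
    across populations exactly as in the observed scan.
    """
    pops = list(h_tot_per_pop)
    if set(pops) != set(theta_per_pop):
        raise ValueError("population keys differ between h_tot and theta")
    rng = np.random.default_rng([seed, 3])
    logF = None
    for pop in pops:
        h_tot = np.asarray(h_tot_per_pop[pop], dtype=np.int64)
        if np.any(h_tot < 1):
            raise ValueError(f"{pop}: every gene needs h_tot >= 1")
        theta = np.asarray(theta_per_pop[pop], dtype=float)
        if np.any((theta == 0) | (theta == 1)):
            logger.warning("%s: degenerate theta component; ancestry flagged", pop)
        P = _replicate_fisher(h_tot, theta, rng, R)
        with np.errstate(divide="ignore"):
            term = -2.0 * np.log(P)
        logF = term if logF is None else logF + term
    return NullEnsemble(values=logF, mode=mode, seed=seed)


def power_analysis(
    f_target: float,
    theta_per_pop: dict[str, np.ndarray],
    n_grid: list[int],
    R: int,
    alpha: float,
    seed: int,
    target_ancestry: int = 0,
    background_genes: int = 200,
) -> pd.DataFrame:
    """Detection power of the cross-population scan versus cohort size.

    For each diploid cohort size n, simulate R replicates in which one focal
    gene's haplotypes are drawn at local fraction f_target (other ancestries
    rescaled) while ``background_genes`` genes follow theta; power is the
    fraction of replicates whose focal-gene chi-square combined p-value falls
    below alpha.  Returns a frame with columns n, power.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if any(n < 1 for n in n_grid):
        raise ValueError("cohort sizes must be positive")
    rng = np.random.default_rng([seed, 4])
    pops = list(theta_per_pop)
    k = len(pops)
    rows = []
    for n in n_grid:
        h_tot = 2 * n
        logF_focal = np.zeros(R)
        for pop in pops:
            theta = np.asarray(theta_per_pop[pop], dtype=float)
            probs = theta * (1.0 - f_target) / (1.0 - theta[target_ancestry])
            probs[target_ancestry] = f_target
            bg = rng.multinomial(h_tot, theta, size=(R, background_genes))
            focal = rng.multinomial(h_tot, probs, size=(R, 1))
            f = np.concatenate([bg, focal], axis=1) / h_tot  # (R, G+1, K)
            mu = f.mean(axis=1, keepdims=True)
            sigma = f.std(axis=1, ddof=1, keepdims=True)
            z_focal = (f[:, -1, target_ancestry] - mu[:, 0, target_ancestry]) \
                / sigma[:, 0, target_ancestry]
            with np.errstate(divide="ignore"):
                logF_focal += -2.0 * np.log(stats.norm.sf(z_focal))
        p = stats.chi2.sf(logF_focal, df=2 * k)
        rows.append((n, float(np.mean(p < alpha))))
    return pd.DataFrame(rows, columns=["n", "power"])


# ---------------------------------------------------------------------------
# Wright-Fisher forward simulation


@dataclass(frozen=True)
class WFConfig:
    """Wright-Fisher simulation settings.

    ``N`` diploid individuals, ``generations`` discrete generations,
    founding ancestry proportions ``theta`` (single-ancestry founders in
    largest-remainder counts), a chromosome of ``morgans`` genetic length
    mapped linearly onto ``chrom_length_bp``, and a ``sample_size`` of
    diploids reported at the end.
    """

    N: int
    generations: int
    theta: tuple[float, ...]
    palette: AncestryPalette
    morgans: float = 1.0
    chrom: str = "chr1"
    chrom_length_bp: int = 100_000_000
    sample_size: int | None = None
    population: str = "WF"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("N must be at least 2")
        if self.generations < 0:
            raise ValueError("generations must be non-negative")
        th = tuple(float(x) for x in self.theta)
        if abs(sum(th) - 1.0) > 1e-12:
            raise ValueError("theta must sum to 1")
        if len(th) != self.palette.K:
            raise ValueError("theta length must equal palette size")
        if self.morgans <= 0:
            raise ValueError("map length must be positive")
        if self.sample_size is not None and self.sample_size > self.N:
            raise ValueError("sample size exceeds population size")
        object.__setattr__(self, "theta", th)


def largest_remainder_counts(N: int, theta) -> np.ndarray:
    """Deterministic integer split of N proportional to theta (sums to N)."""
    th = np.asarray(theta, dtype=float)
    raw = N * th
    base = np.floor(raw).astype(np.int64)
    short = N - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:short]] += 1
    return base


# haplotypes are (cuts, anc): interior breakpoints in Morgans (ascending) and
# per-segment ancestry codes, len(anc) == len(cuts) + 1

def _slice_hap(hap, a: float, b: float):
    cuts, anc = hap
    i0 = np.searchsorted(cuts, a, side="right")
    i1 = np.searchsorted(cuts, b, side="left")
    return cuts[i0:i1], anc[i0:i1 + 1]


def meiosis(rng: np.random.Generator, hap_a, hap_b, morgans: float):
    """One gamete from a parent's two haplotypes.

    Crossover count ~ Poisson(map length); crossover genetic positions i.i.d.
    uniform; the gamete alternates between the parental haplotypes starting
    from a uniformly chosen one (no crossover interference).
    """
    n_x = rng.poisson(morgans)
    cur = int(rng.integers(2))
    pair = (hap_a, hap_b)
    if n_x == 0:
        cuts, anc = pair[cur]
        return cuts.copy(), anc.copy()
    xs = np.sort(rng.uniform(0.0, morgans, size=n_x))
    edges = np.concatenate([[0.0], xs, [morgans]])
    cut_blocks: list[np.ndarray] = []
    anc_blocks: list[np.ndarray] = []
    for i in range(len(edges) - 1):
        c, a = _slice_hap(pair[(cur + i) % 2], edges[i], edges[i + 1])
        if i > 0:
            cut_blocks.append(edges[i:i + 1])  # junction at the crossover
        cut_blocks.append(c)
        anc_blocks.append(a)
    cuts_cat = np.concatenate(cut_blocks) if cut_blocks else np.empty(0)
    anc_cat = np.concatenate(anc_blocks)
    # merge adjacent equal-ancestry segments across junctions
    keep = anc_cat[1:] != anc_cat[:-1]
    return cuts_cat[keep], np.concatenate([anc_cat[:1], anc_cat[1:][keep]])


def wright_fisher_sim(cfg: WFConfig) -> HaplotypePanel:
    """Run the Wright-Fisher simulation and return the sampled panel.

    Every output haplotype exactly tiles the chromosome at every generation;
    with g = 0 the founders themselves are sampled.
    """
    rng = np.random.default_rng([cfg.seed, 5])
    counts = largest_remainder_counts(cfg.N, cfg.theta)
    L = cfg.morgans
    empty = np.empty(0)
    population = []
    for a, c in enumerate(counts):
        for _ in range(c):
            hap = (empty, np.array([a], dtype=np.int64))
            population.append((hap, (hap[0].copy(), hap[1].copy())))

    for _ in range(cfg.generations):
        parents_a = rng.integers(cfg.N, size=cfg.N)
        parents_b = rng.integers(cfg.N, size=cfg.N)
        nxt = []
        for pa, pb in zip(parents_a, parents_b):
            ga = meiosis(rng, *population[pa], L)
            gb = meiosis(rng, *population[pb], L)
            nxt.append((ga, gb))
        population = nxt

    n_out = cfg.sample_size if cfg.sample_size is not None else cfg.N
    chosen = rng.choice(cfg.N, size=n_out, replace=False)

    bp_per_morgan = cfg.chrom_length_bp / L
    haplotypes: list[list[AncestryTract]] = []
    for idx in chosen:
        for hap in population[idx]:
            cuts, anc = hap
            bounds_m = np.concatenate([[0.0], cuts, [L]])
            bounds_bp = np.round(bounds_m * bp_per_morgan).astype(np.int64)
            bounds_bp[0], bounds_bp[-1] = 0, cfg.chrom_length_bp
            # guard against bp collisions from rounding very short segments
            keep = np.concatenate([[True], np.diff(bounds_bp) > 0])
            bounds_bp = bounds_bp[keep]
            bounds_m = bounds_m[keep]
            # recover segment ancestries by genetic-midpoint lookup
            mids = (bounds_m[:-1] + bounds_m[1:]) / 2.0
            seg_idx = np.searchsorted(cuts, mids, side="right")
            seg_anc = anc[seg_idx]
            tracts = [
                AncestryTract(
                    cfg.chrom, int(bounds_bp[i]), int(bounds_bp[i + 1]),
                    bounds_m[i] * 100.0, bounds_m[i + 1] * 100.0, int(seg_anc[i]),
                )
                for i in range(len(seg_anc))
            ]
            haplotypes.append(merge_tracts(tracts))

    samples = [f"{cfg.population}_S{i:04d}" for i in range(n_out)]
    return HaplotypePanel(
        population=cfg.population,
        samples=samples,
        haplotypes=haplotypes,
        palette=cfg.palette,
        chrom=cfg.chrom,
        chrom_span=(0, cfg.chrom_length_bp),
    )


def chromosome_null(
    cfgs: dict[str, WFConfig],
    genes: list[GeneModel],
    R: int,
    seed: int,
    mode: str = "per_gene",
) -> NullEnsemble:
    """Wright-Fisher chromosome-scale null ensemble of Fisher scores.

    Per replicate: simulate each population forward, run the enrichment scan,
    and Fisher-combine enrichment p-values over the replicate's own retained
    gene universe; genes outside the universe are stored as NaN.
    """
    import dataclasses

    pops = list(cfgs)
    K = cfgs[pops[0]].palette.K
    gene_index = {g.name: i for i, g in enumerate(genes)}
    values = np.full((R, len(genes), K), np.nan)
    ss = np.random.SeedSequence([seed, 6])
    rep_seeds = ss.generate_state(R * len(pops)).reshape(R, len(pops))
    for r in range(R):
        tables = []
        for j, pop in enumerate(pops):
            cfg = dataclasses.replace(cfgs[pop], seed=int(rep_seeds[r, j] % 2**31))
            panel = wright_fisher_sim(cfg)
            tables.append(enrichment_scan.scan(panel, genes))
        universe = enrichment_scan.finalize_gene_universe(tables)
        combined = enrichment_scan.fisher_combine(tables, universe, "enrich")
        labels = list(cfgs[pops[0]].palette.labels)
        for _, row in combined.data.iterrows():
            values[r, gene_index[row["gene"]], labels.index(row["ancestry"])] = row["F_CS"]
    return NullEnsemble(values=values, mode=mode, seed=seed)
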
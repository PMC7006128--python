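"""Gene-level ancestry-enrichment scan and cross-population combination.

For every gene and ancestry the scan computes the fraction of ancestry-assigned
haplotypes ``f_anc = h_anc / h_tot``, standardizes it against the genome-wide
mean and standard deviation of gene-level fractions,

    z_anc = (f_anc - mu_anc) / sigma_anc,

and converts z to one-sided normal p-values (upper tail = enrichment, lower
tail = depletion).  Evidence is combined across populations with Fisher's
method, F_CS = -2 * sum_i ln(P_i), referred to a chi-square distribution with
2k degrees of freedom for k populations, followed by Benjamini-Hochberg FDR.

A haplotype counts toward a gene only when every tract overlapping the gene
interval has one and the same assigned ancestry; haplotypes with an ancestry
switch or an unassigned segment inside the gene contribute to neither h_anc
nor h_tot.  Genes whose h_tot deviates from the genome-wide mean by more than
one standard deviation are dropped from the analysis universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ancestry_io import UNASSIGNED, GeneModel, HaplotypePanel, ScoreTrack

logger = logging.getLogger(__name__)

__all__ = [
    "GeneAncestryCounts",
    "GeneScoreTable",
    "CombinedScoreTable",
    "assign_gene_ancestries",
    "count_gene_ancestries",
    "scan",
    "finalize_gene_universe",
    "fisher_combine",
    "bh_fdr",
    "overlay_scores",
]


@dataclass(frozen=True)
class GeneAncestryCounts:
    gene: str
    h_anc: tuple[int, ...]
    h_tot: int

    def __post_init__(self) -> None:
        if sum(self.h_anc) != self.h_tot:
            raise ValueError("ancestry counts must sum to h_tot")


@dataclass
class GeneScoreTable:
    """Per-population scan result.

    ``data`` is a long-format frame with one row per gene x ancestry:
    gene, ancestry, h_anc, h_tot, f_anc, z_anc, p_enrich, p_deplete, retained.
    ``mu_anc``/``sigma_anc`` map ancestry label -> genome-wide moments of
    f_anc over retained genes; undefined ancestries (sigma == 0) carry NaN.
    """

    population: str
    data: pd.DataFrame
    mu_anc: dict[str, float]
    sigma_anc: dict[str, float]
    mu_htot: float
    sigma_htot: float
    undefined_ancestries: tuple[str, ...] = ()

    @property
    def genes(self) -> list[str]:
        return list(dict.fromkeys(self.data["gene"]))

    @property
    def retained_genes(self) -> list[str]:
        d = self.data
        return list(dict.fromkeys(d.loc[d["retained"], "gene"]))

    def z_lookup(self, ancestry: str) -> pd.Series:
        d = self.data
        sub = d[d["ancestry"] == ancestry].set_index("gene")
        return sub["z_anc"]


@dataclass
class CombinedScoreTable:
    """Cross-population Fisher combination (one direction).

    ``data`` rows: gene, ancestry, F_CS, p_chi2, q, p_empirical, reject.
    """

    direction: str
    k: int
    data: pd.DataFrame


def count_gene_ancestries(
    panel: HaplotypePanel, genes: list[GeneModel]
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized haplotype counting for many genes at once.

    Returns (h_anc of shape (G, K), h_tot of shape (G,)).  A haplotype is
    counted for a gene iff a single assigned-ancestry tract covers the whole
    gene interval (tracts are maximal, so single-tract coverage is equivalent
    to uniform ancestry over the gene).
    """
    lo, hi = panel.chrom_span
    for g in genes:
        if g.chrom != panel.chrom or g.start_bp < lo or g.end_bp > hi:
            raise ValueError(f"gene {g.name} outside panel span {panel.chrom}:{lo}-{hi}")
    G, K = len(genes), panel.palette.K
    starts = np.array([g.start_bp for g in genes], dtype=np.int64)
    last_pos = np.array([g.end_bp - 1 for g in genes], dtype=np.int64)
    h_anc = np.zeros((G, K), dtype=np.int64)
    for h in range(panel.n_haplotypes):
        bounds, anc = panel.tract_arrays(h)
        first = np.searchsorted(bounds, starts, side="right") - 1
        last = np.searchsorted(bounds, last_pos, side="right") - 1
        ok = first == last
        a = anc[first[ok]]
        assigned = a != UNASSIGNED
        np.add.at(h_anc, (np.flatnonzero(ok)[assigned], a[assigned]), 1)
    return h_anc, h_anc.sum(axis=1)


def assign_gene_ancestries(panel: HaplotypePanel, gene: GeneModel) -> GeneAncestryCounts:
    """Count ancestry-assigned haplotypes for a single gene."""
    h_anc, h_tot = count_gene_ancestries(panel, [gene])
    return GeneAncestryCounts(gene.name, tuple(int(c) for c in h_anc[0]), int(h_tot[0]))


def scan(panel: HaplotypePanel, genes: list[GeneModel]) -> GeneScoreTable:
    """Run the single-population ancestry-enrichment scan.

    Genome-wide moments (mu_anc, sigma_anc) are computed over retained genes:
    those with h_tot within one standard deviation of the mean h_tot.  z and
    p columns are populated for all genes with h_tot > 0, retained or not.
    """
    h_anc, h_tot = count_gene_ancestries(panel, genes)
    covered = h_tot > 0
    if covered.sum() < 2:
        raise ValueError("scan needs at least 2 genes with h_tot > 0")

    mu_htot = float(h_tot[covered].mean())
    sigma_htot = float(h_tot[covered].std(ddof=1))
    retained = covered & (np.abs(h_tot - mu_htot) <= sigma_htot)

    K = panel.palette.K
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(covered[:, None], h_anc / np.maximum(h_tot, 1)[:, None], np.nan)
    mu = f[retained].mean(axis=0)
    sigma = f[retained].std(axis=0, ddof=1)

    undefined = []
    z = np.full_like(f, np.nan)
    p_enrich = np.full_like(f, np.nan)
    p_deplete = np.full_like(f, np.nan)
    for a in range(K):
        label = panel.palette.labels[a]
        if not np.isfinite(sigma[a]) or sigma[a] == 0.0:
            undefined.append(label)
            logger.warning(
                "population %s: ancestry %s has sigma_anc = 0; scores undefined",
                panel.population, label,
            )
            mu[a] = np.nan
            sigma[a] = np.nan
            continue
        z[:, a] = (f[:, a] - mu[a]) / sigma[a]
        p_enrich[:, a] = stats.norm.sf(z[:, a])
        p_deplete[:, a] = stats.norm.cdf(z[:, a])

    rows = {
        "gene": np.repeat([g.name for g in genes], K),
        "ancestry": np.tile(panel.palette.labels, len(genes)),
        "h_anc": h_anc.ravel(),
        "h_tot": np.repeat(h_tot, K),
        "f_anc": f.ravel(),
        "z_anc": z.ravel(),
        "p_enrich": p_enrich.ravel(),
        "p_deplete": p_deplete.ravel(),
        "retained": np.repeat(retained, K),
    }
    return GeneScoreTable(
        population=panel.population,
        data=pd.DataFrame(rows),
        mu_anc=dict(zip(panel.palette.labels, (float(x) for x in mu))),
        sigma_anc=dict(zip(panel.palette.labels, (float(x) for x in sigma))),
        mu_htot=mu_htot,
        sigma_htot=sigma_htot,
        undefined_ancestries=tuple(undefined),
    )


def finalize_gene_universe(tables: list[GeneScoreTable]) -> list[str]:
    """Intersect per-population retained sets into the analysis universe.

    A gene survives only if it passes the h_tot filter in every population;
    gene lists must be identical across tables.
    """
    gene_lists = [t.genes for t in tables]
    if any(set(gl) != set(gene_lists[0]) for gl in gene_lists[1:]):
        raise ValueError("gene lists differ across populations")
    universe = [g for g in gene_lists[0]
                if all(g in set(t.retained_genes) for t in tables)]
    if not universe:
        raise ValueError("empty gene universe after h_tot filtering")
    return universe


def bh_fdr(pvalues, q_threshold: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: returns (q-values, reject flags q < thr)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("bh_fdr needs at least one p-value")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q, q < q_threshold


def fisher_combine(
    tables: list[GeneScoreTable],
    universe: list[str],
    direction: str = "enrich",
    q_threshold: float = 0.05,
) -> CombinedScoreTable:
    """Combine one-sided per-population p-values with Fisher's method.

    F_CS = -2 * sum ln(P_i) over the k populations, referred to chi2 with 2k
    degrees of freedom; BH-FDR applied across all gene x ancestry rows.
    Ancestries undefined in any population are skipped with a warning.
    """
    if direction not in ("enrich", "deplete"):
        raise ValueError("direction must be 'enrich' or 'deplete'")
    if not tables:
        raise ValueError("no populations to combine")
    k = len(tables)
    col = "p_enrich" if direction == "enrich" else "p_deplete"

    labels = list(dict.fromkeys(tables[0].data["ancestry"]))
    skipped = set()
    for t in tables:
        skipped.update(t.undefined_ancestries)
    usable = [a for a in labels if a not in skipped]
    for a in sorted(skipped):
        logger.warning("ancestry %s undefined in some population; skipped", a)

    frames = []
    for t in tables:
        sub = t.data[t.data["gene"].isin(universe) & t.data["ancestry"].isin(usable)]
        piv = sub.pivot(index="gene", columns="ancestry", values=col)
        frames.append(piv.loc[universe, usable])
    P = np.stack([fr.to_numpy(dtype=float) for fr in frames])  # (k, G, A)
    if np.any(P == 0):
        raise ValueError("cannot combine a p-value of exactly 0")
    F = -2.0 * np.log(P).sum(axis=0)
    p_chi2 = stats.chi2.sf(F, df=2 * k)

    data = pd.DataFrame({
        "gene": np.repeat(universe, len(usable)),
        "ancestry": np.tile(usable, len(universe)),
        "F_CS": F.ravel(),
        "p_chi2": p_chi2.ravel(),
    })
    q, reject = bh_fdr(data["p_chi2"].to_numpy(), q_threshold)
    data["q"] = q
    data["reject"] = reject
    data["p_empirical"] = np.nan
    return CombinedScoreTable(direction=direction, k=k, data=data)


def overlay_scores(
    genes: list[GeneModel],
    track: ScoreTrack,
    threshold: float = 2.5,
    flank_bp: int = 0,
) -> pd.DataFrame:
    """Per-gene maximum |score| within gene +/- flank, and a threshold flag.

    Genes without any track point in range get max_abs_score = NaN and
    flag False.  The default threshold 2.5 is the conventional |iHS| cutoff
    for putative positive selection.
    """
    abs_scores = np.abs(track.scores)
    rows = []
    for g in genes:
        lo = np.searchsorted(track.positions, g.start_bp - flank_bp, side="left")
        hi = np.searchsorted(track.positions, g.end_bp + flank_bp, side="left")
        if hi > lo:
            m = float(abs_scores[lo:hi].max())
            rows.append((g.name, m, bool(m >= threshold)))
        else:
            rows.append((g.name, np.nan, False))
    return pd.DataFrame(rows, columns=["gene", "max_abs_score", "above_threshold"])
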
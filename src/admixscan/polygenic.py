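"""Polygenic ancestry enrichment (PAE) with size-matched permutation nulls.

For a trait's gene set, PAE is the sum of gene-level ancestry-enrichment
z-scores, PAE = sum(z_anc), computed per ancestry and per population.  Its
null distribution comes from random gene sets of the same size drawn without
replacement from the retained gene universe (default 10,000 permutations);
significance is the normal two-sided p of

    z_PAE = (PAE_obs - mu_PAE) / sigma_PAE,

with an empirical rank p reported alongside, and Benjamini-Hochberg FDR
applied within each (population, ancestry) family.  A trait is a cross-
population consensus hit when it is significant with the same ancestry and
the same direction in at least ``min_pops`` populations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ancestry_io import GeneModel, TraitGeneSet
from .enrichment_scan import GeneScoreTable, bh_fdr

logger = logging.getLogger(__name__)

__all__ = [
    "PAEResult",
    "compute_pae",
    "permutation_null",
    "pae_scan",
    "cross_population_traits",
    "distance_prune_geneset",
]


@dataclass(frozen=True)
class PAEResult:
    trait: str
    ancestry: str
    population: str
    n_genes_used: int
    pae_obs: float
    mu_pae: float
    sigma_pae: float
    z_pae: float
    p: float
    p_rank: float
    q: float
    direction: int  # sign of z_PAE


class DegenerateNullError(ValueError):
    """Permutation null has zero variance (e.g. all-equal z universe)."""


def _universe_z(table: GeneScoreTable, ancestry: str) -> pd.Series:
    d = table.data
    sub = d[(d["ancestry"] == ancestry) & d["retained"] & d["z_anc"].notna()]
    return sub.set_index("gene")["z_anc"]


def compute_pae(
    table: GeneScoreTable, trait: TraitGeneSet, ancestry: str
) -> tuple[float, int]:
    """Observed PAE: sum of z_anc over trait genes present in the universe.

    Trait genes missing from the retained universe are dropped; their number
    is reflected in the returned count.  Raises if no usable gene remains.
    """
    z = _universe_z(table, ancestry)
    usable = [g for g in trait.genes if g in z.index]
    if not usable:
        raise ValueError(
            f"trait {trait.trait}: no genes in the retained universe "
            f"({table.population}/{ancestry})"
        )
    return float(z.loc[usable].sum()), len(usable)


def permutation_null(
    table: GeneScoreTable,
    set_size: int,
    ancestry: str,
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[float, float, np.ndarray]:
    """Size-matched permutation null of PAE.

    Each permutation draws ``set_size`` genes uniformly without replacement
    from the retained universe and sums their z_anc.  Returns
    (mu_PAE, sigma_PAE, null sample).
    """
    z = _universe_z(table, ancestry).to_numpy()
    m = z.size
    if set_size > m:
        raise ValueError(f"set_size {set_size} exceeds universe size {m}")
    if n_perm < 2:
        raise DegenerateNullError("need at least 2 permutations for a sigma")
    rng = np.random.default_rng([seed, 11, set_size])
    # without-replacement draws: rank the first set_size of a random keying
    keys = rng.random((n_perm, m))
    idx = np.argpartition(keys, set_size - 1, axis=1)[:, :set_size]
    null = z[idx].sum(axis=1)
    mu = float(null.mean())
    sigma = float(null.std(ddof=1))
    if sigma == 0.0:
        raise DegenerateNullError(
            f"sigma_PAE = 0 for set_size {set_size} ({table.population}/{ancestry})"
        )
    return mu, sigma, null


def pae_scan(
    tables: list[GeneScoreTable],
    traits: list[TraitGeneSet],
    n_perm: int = 10_000,
    seed: int = 0,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """PAE for every trait x ancestry x population, with permutation nulls.

    Null moments are cached per (population, ancestry, effective set size),
    since the permutation distribution depends only on those.  Skipped traits
    (no usable genes, degenerate nulls) are recorded with NaN statistics.
    Returns a long-format frame of :class:`PAEResult` fields.
    """
    rows: list[dict] = []
    cache: dict[tuple[str, str, int], tuple[float, float, np.ndarray]] = {}
    for table in tables:
        labels = [a for a in dict.fromkeys(table.data["ancestry"])
                  if a not in table.undefined_ancestries]
        for ancestry in labels:
            for trait in traits:
                base = {
                    "trait": trait.trait, "ancestry": ancestry,
                    "population": table.population,
                }
                try:
                    pae_obs, n_used = compute_pae(table, trait, ancestry)
                    key = (table.population, ancestry, n_used)
                    if key not in cache:
                        cache[key] = permutation_null(
                            table, n_used, ancestry, n_perm=n_perm, seed=seed
                        )
                    mu, sigma, null = cache[key]
                except (ValueError, DegenerateNullError) as exc:
                    logger.warning("skipping %s/%s/%s: %s",
                                   trait.trait, table.population, ancestry, exc)
                    rows.append({**base, "n_genes_used": 0, "pae_obs": np.nan,
                                 "mu_pae": np.nan, "sigma_pae": np.nan,
                                 "z_pae": np.nan, "p": np.nan, "p_rank": np.nan,
                                 "direction": 0})
                    continue
                z_pae = (pae_obs - mu) / sigma
                p = 2.0 * stats.norm.sf(abs(z_pae))
                p_rank = (1.0 + np.sum(np.abs(null - mu) >= abs(pae_obs - mu))) \
                    / (1.0 + null.size)
                rows.append({**base, "n_genes_used": n_used, "pae_obs": pae_obs,
                             "mu_pae": mu, "sigma_pae": sigma, "z_pae": z_pae,
                             "p": p, "p_rank": float(p_rank),
                             "direction": int(np.sign(z_pae))})
    df = pd.DataFrame(rows)
    df["q"] = np.nan
    df["reject"] = False
    for (_, _), grp in df.groupby(["population", "ancestry"]):
        ok = grp["p"].notna()
        if ok.any():
            q, rej = bh_fdr(grp.loc[ok, "p"].to_numpy(), q_threshold)
            df.loc[grp.index[ok], "q"] = q
            df.loc[grp.index[ok], "reject"] = rej
    return df


def cross_population_traits(
    results: pd.DataFrame, min_pops: int = 2, q_threshold: float = 0.05
) -> pd.DataFrame:
    """Traits significant with the same ancestry and direction in >= min_pops.

    Returns one row per (trait, ancestry) consensus hit listing the
    supporting populations and their signed z_PAE values.
    """
    if results["population"].nunique() < 2:
        raise ValueError("consensus requires results from at least 2 populations")
    hits = results[(results["q"] < q_threshold) & results["q"].notna()]
    rows = []
    for (trait, ancestry), grp in hits.groupby(["trait", "ancestry"]):
        for sign in (1, -1):
            sub = grp[grp["direction"] == sign]
            if sub["population"].nunique() >= min_pops:
                rows.append({
                    "trait": trait,
                    "ancestry": ancestry,
                    "direction": sign,
                    "n_populations": int(sub["population"].nunique()),
                    "populations": ",".join(sorted(sub["population"])),
                    "z_pae_values": ",".join(
                        f"{z:.4f}" for z in sub.sort_values("population")["z_pae"]
                    ),
                })
    return pd.DataFrame(
        rows, columns=["trait", "ancestry", "direction", "n_populations",
                       "populations", "z_pae_values"],
    )


def distance_prune_geneset(
    trait: TraitGeneSet, genes: list[GeneModel], min_gap_bp: int = 250_000
) -> TraitGeneSet:
    """Greedy left-to-right physical-distance pruning of a trait gene set.

    Walking genes in coordinate order per chromosome, a gene is dropped when
    it starts within ``min_gap_bp`` of the previously retained gene's end — a
    coordinate-based stand-in for genotype LD pruning, which keeps clusters
    of physically linked genes from dominating a PAE sum.  Trait genes
    without coordinates are retained with a warning.
    """
    coord = {g.name: g for g in genes}
    with_pos = sorted(
        (coord[n] for n in trait.genes if n in coord),
        key=lambda g: (g.chrom, g.start_bp),
    )
    missing = sorted(n for n in trait.genes if n not in coord)
    if missing:
        logger.warning("trait %s: %d genes lack coordinates; retained",
                       trait.trait, len(missing))
    kept: list[GeneModel] = []
    for g in with_pos:
        if kept and g.chrom == kept[-1].chrom \
                and g.start_bp < kept[-1].end_bp + min_gap_bp:
            continue
        kept.append(g)
    return TraitGeneSet(trait.trait, trait.description,
                        frozenset([g.name for g in kept] + missing))
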
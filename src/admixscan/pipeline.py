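"""End-to-end orchestration of the admixture-selection screen.

``run_all`` drives the full analysis from a single config: per-population
enrichment scans, gene-universe finalization, Fisher combination with BH-FDR
(both directions), optional simulation-based empirical p-values, the
polygenic PAE scan with cross-population consensus, an optional score-track
overlay, and an optional selection-coefficient fit on the top combined hit.
All stage outputs are written as tab-separated tables plus a JSON manifest
recording parameters, per-stage seeds, row counts and warnings, so a run is
reproducible from the manifest alone.

Per-stage seeds are derived deterministically from the single global seed and
the stage name, so stages are individually reproducible and do not share
random streams.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
import zlib
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import enrichment_scan, null_simulation, polygenic, selection_model, synthetic_data
from .ancestry_io import AncestryPalette, read_bed, read_gmt, read_msp, read_score_track

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "stage_seed", "run_all", "make_demo"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31 (global seed + stage name)."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunConfig:
    msp_paths: dict[str, str]  # population label -> msp file
    bed_path: str
    gmt_path: str | None = None
    score_track_path: str | None = None
    score_track_dialect: str = "generic_tsv"
    ihs_threshold: float = 2.5
    q_threshold: float = 0.05
    null_mode: str | None = None  # None, "genewise" or "wf"
    null_replicates: int = 100
    n_perm: int = 10_000
    min_pops: int = 2
    selection_t: int = 20
    selection_ancestry: str | None = None  # fit s for the top hit of this ancestry
    seed: int = 0
    out_dir: str = "admixscan_out"

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if not self.msp_paths:
            raise ValueError("no msp files configured")
        for pop, path in self.msp_paths.items():
            if not os.path.exists(path):
                raise ValueError(f"msp file for {pop} not found: {path}")
        if not os.path.exists(self.bed_path):
            raise ValueError(f"BED file not found: {self.bed_path}")
        if self.null_mode not in (None, "genewise", "wf"):
            raise ValueError(f"unknown null mode {self.null_mode!r}")


def _write_tsv(df, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_all(cfg: RunConfig) -> dict:
    """Execute every configured stage; returns (and writes) the manifest."""
    cfg.validate()
    os.makedirs(cfg.out_dir, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(cfg),
        "stages": {},
        "warnings": [],
    }

    def done(stage: str, **info) -> None:
        manifest["stages"][stage] = {"completed": True, **info}

    t0 = time.time()
    panels = {
        pop: read_msp(path, population=pop) for pop, path in cfg.msp_paths.items()
    }
    genes = read_bed(cfg.bed_path)
    done("load", populations=list(panels), n_genes=len(genes))

    tables = []
    for pop, panel in panels.items():
        table = enrichment_scan.scan(panel, genes)
        tables.append(table)
        path = os.path.join(cfg.out_dir, f"scores_{pop}.tsv")
        _write_tsv(table.data, path)
        for a in table.undefined_ancestries:
            manifest["warnings"].append(f"scan:{pop}: ancestry {a} undefined (sigma=0)")
    done("scan", n_tables=len(tables))

    combined = {}
    universe: list[str] | None = None
    if len(tables) >= 2:
        universe = enrichment_scan.finalize_gene_universe(tables)
        for direction in ("enrich", "deplete"):
            ct = enrichment_scan.fisher_combine(
                tables, universe, direction, cfg.q_threshold
            )
            combined[direction] = ct
        done("combine", universe_size=len(universe))
    else:
        manifest["warnings"].append(
            "combine: single population configured; combination stages skipped"
        )
        done("combine", skipped=True)

    if cfg.null_mode and combined:
        seed = stage_seed(cfg.seed, "null")
        if cfg.null_mode == "genewise":
            h_tot_per_pop, theta_per_pop = {}, {}
            for table in tables:
                sub = table.data[table.data["gene"].isin(universe)]
                piv = sub.pivot(index="gene", columns="ancestry", values="h_tot")
                h_tot_per_pop[table.population] = \
                    piv.loc[universe].iloc[:, 0].to_numpy(dtype=np.int64)
                theta_per_pop[table.population] = np.array(
                    [table.mu_anc[a] for a in dict.fromkeys(table.data["ancestry"])]
                )
            ensemble = null_simulation.genewise_null(
                h_tot_per_pop, theta_per_pop, cfg.null_replicates, seed
            )
            ct = combined["enrich"]
            ct.data["p_empirical"] = null_simulation.empirical_p(
                ct.data["F_CS"].to_numpy(), ensemble
            )
            done("null", mode="genewise", replicates=cfg.null_replicates, seed=seed)
        else:
            manifest["warnings"].append(
                "null: wf mode needs per-population WFConfig; use the library API "
                "(null_simulation.chromosome_null) for full control"
            )
            done("null", skipped=True)
    for direction, ct in combined.items():
        _write_tsv(ct.data, os.path.join(cfg.out_dir, f"combined_{direction}.tsv"))

    if cfg.score_track_path:
        track = read_score_track(cfg.score_track_path, cfg.score_track_dialect)
        overlay = enrichment_scan.overlay_scores(genes, track, cfg.ihs_threshold)
        _write_tsv(overlay, os.path.join(cfg.out_dir, "score_overlay.tsv"))
        done("overlay", n_flagged=int(overlay["above_threshold"].sum()))

    if cfg.gmt_path:
        traits = read_gmt(cfg.gmt_path)
        pae = polygenic.pae_scan(
            tables, traits, n_perm=cfg.n_perm,
            seed=stage_seed(cfg.seed, "pae"), q_threshold=cfg.q_threshold,
        )
        _write_tsv(pae, os.path.join(cfg.out_dir, "pae.tsv"))
        done("pae", n_rows=len(pae))
        if len(tables) >= 2:
            consensus = polygenic.cross_population_traits(
                pae, cfg.min_pops, cfg.q_threshold
            )
            _write_tsv(consensus, os.path.join(cfg.out_dir, "pae_consensus.tsv"))
            done("consensus", n_traits=len(consensus))

    if cfg.selection_ancestry and combined:
        anc = cfg.selection_ancestry
        ct = combined["enrich"].data
        sub = ct[ct["ancestry"] == anc]
        fit = None
        if sub.empty:
            manifest["warnings"].append(f"selection: ancestry {anc} has no combined rows")
        else:
            top_gene = sub.loc[sub["p_chi2"].idxmin(), "gene"]
            z_obs, mu, sigma = {}, {}, {}
            for table in tables:
                z_obs[table.population] = float(table.z_lookup(anc).loc[top_gene])
                mu[table.population] = table.mu_anc[anc]
                sigma[table.population] = table.sigma_anc[anc]
            try:
                fit = selection_model.fit_populations(
                    z_obs, mu, sigma, t=cfg.selection_t
                )
            except ValueError as exc:
                manifest["warnings"].append(f"selection: {exc}")
        if fit is not None:
            rows = [
                {"population": pop, "gene": top_gene, "ancestry": anc,
                 "z_obs": z_obs[pop], "s_hat": fit.s_hat[pop], "t": fit.t}
                for pop in fit.populations
            ]
            rows.append({"population": "MEAN", "gene": top_gene, "ancestry": anc,
                         "z_obs": float("nan"), "s_hat": fit.s_mean, "t": fit.t})
            import pandas as pd
            _write_tsv(pd.DataFrame(rows),
                       os.path.join(cfg.out_dir, "selection_fit.tsv"))
            done("selection", gene=top_gene, s_mean=fit.s_mean, note=fit.note)

    manifest["elapsed_s"] = round(time.time() - t0, 2)
    with open(os.path.join(cfg.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def make_demo(out_dir: str, seed: int = 0, n_samples: int = 100) -> RunConfig:
    """Materialize the demo workspace: synthetic cohort files plus a config.

    Generates the four-population cohort with one injected African-enrichment
    locus and one planted enriched trait, writes msp/BED/GMT/ground-truth
    files and a ready-to-run YAML config, and returns the parsed RunConfig.
    """
    cohort = synthetic_data.demo_config(seed=seed, n_samples=n_samples)
    paths = synthetic_data.write_cohort(
        cohort, out_dir, n_traits=20, set_size=8, enriched_trait="TRAIT_ENRICHED"
    )
    cfg = RunConfig(
        msp_paths=paths["msp"],
        bed_path=paths["bed"],
        gmt_path=paths["gmt"],
        null_mode="genewise",
        null_replicates=100,
        n_perm=10_000,
        selection_ancestry="AFR",
        selection_t=20,
        seed=seed,
        out_dir=os.path.join(out_dir, "results"),
    )
    with open(os.path.join(out_dir, "config.yaml"), "w") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=False)
    return cfg
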
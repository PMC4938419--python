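"""End-to-end orchestration: the power-analysis harness and the full
analysis pipeline.

``run_power_study`` replays the simulation power study: for each selection
scenario and replicate it simulates a dataset, runs step-1 GST inference,
fits the hierarchical model (or the single-site model for within-site
rows), calls outliers at the 1% and 5% thresholds and scores the calls
against the simulation truth. Simulation truth is consumed only by the
scoring step, never by inference.

``run_real_pipeline`` runs the whole analysis on a genotype dataset:
GST matrix, hierarchical partitioning, per-site single-site models, outlier
calls and GEA tests, writing every artifact plus a machine-readable run
manifest.
"""

from __future__ import annotations

import json
import logging
import platform
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .gea import GeaConfig, gea_test
from .gst import gst_median_matrix
from .models import HierarchicalGstModel, McmcConfig, SingleSiteGstModel
from .outliers import call_outliers, score_calls
from .popdata import (
    GenotypeDataset,
    HierarchyAssignment,
    ValidationError,
    filter_monomorphic,
)
from .simulate import ScenarioConfig, scenario_from_table2, simulate

log = logging.getLogger("hiergst")


@dataclass
class PowerRow:
    """One power-study scenario: selection type, number of selected loci
    and strength spec (float, (lo, hi) range, or None)."""

    selection_type: str
    n_selected: object
    s_spec: object
    within_site: bool = False

    def label(self) -> str:
        return f"{self.selection_type}|{self.n_selected}|{self.s_spec}" + (
            "|within-site" if self.within_site else ""
        )


def _spawn_seeds(seed, n):
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(n)]


def run_power_study(
    rows,
    replicates: int = 10,
    cfg: McmcConfig | None = None,
    seed=None,
    n_samples_step1: int = 2000,
) -> pd.DataFrame:
    """Power table over scenarios x replicates.

    Returns one row per scenario, replicate and method (HBM-5%, HBM-1% for
    multi-site rows; SBM-1% for within-site rows) with N_detected, FDR and
    FNR in percent, mirroring the power-study table layout.
    """
    cfg = cfg or McmcConfig()
    out = []
    rep_seed_lists = _spawn_seeds(seed, len(rows))
    for row, row_seed in zip(rows, rep_seed_lists):
        rep_seeds = _spawn_seeds(row_seed, replicates)
        for rep, rseed in enumerate(rep_seeds):
            t0 = time.time()
            metrics = _one_power_replicate(row, rseed, cfg, n_samples_step1)
            for method, pm in metrics.items():
                out.append(
                    {
                        "selection_type": row.selection_type,
                        "n_selected": str(row.n_selected),
                        "s": str(row.s_spec),
                        "within_site": row.within_site,
                        "method": method,
                        "replicate": rep,
                        "seed": rseed,
                        "N_detected": pm.R,
                        "FDR_pct": float("nan") if pm.fdr is None else 100 * pm.fdr,
                        "FNR_pct": 100 * pm.fnr,
                        "m": pm.m,
                    }
                )
            log.info("scenario %s replicate %d done in %.1fs", row.label(), rep, time.time() - t0)
    return pd.DataFrame(out)


def _one_power_replicate(row: PowerRow, rseed: int, cfg: McmcConfig, n_samples_step1: int):
    sub = np.random.SeedSequence(rseed).spawn(3)
    s_sim, s_gst, s_mcmc = (int(s.generate_state(1)[0] % (2**31)) for s in sub)
    scenario = scenario_from_table2(
        row.selection_type, row.n_selected, row.s_spec,
        within_site=row.within_site, seed=s_sim,
    )
    sim = simulate(scenario)
    ds, dropped = filter_monomorphic(sim.dataset)
    truth = sim.selected_loci & set(ds.loci)
    gst = gst_median_matrix(ds, n_samples=n_samples_step1, seed=s_gst)
    results = {}
    if row.within_site:
        fit = SingleSiteGstModel(gst).fit(
            McmcConfig(cfg.n_iter, cfg.n_burnin, cfg.thin, cfg.n_chains, s_mcmc)
        )
        results["SBM-1%"] = score_calls(fit.call_outliers(0.01), truth)
    else:
        fit = HierarchicalGstModel(gst, sim.hierarchy).fit(
            McmcConfig(cfg.n_iter, cfg.n_burnin, cfg.thin, cfg.n_chains, s_mcmc)
        )
        results["HBM-1%"] = score_calls(fit.call_outliers(0.01), truth)
        results["HBM-5%"] = score_calls(fit.call_outliers(0.05), truth)
    return results


def summarize_power(table: pd.DataFrame) -> pd.DataFrame:
    """Median-over-replicates summary of a power table."""
    keys = ["selection_type", "n_selected", "s", "within_site", "method"]
    return (
        table.groupby(keys, sort=False)
        .agg(
            N_detected=("N_detected", "median"),
            FDR_pct=("FDR_pct", "median"),
            FNR_pct=("FNR_pct", "median"),
            replicates=("replicate", "count"),
        )
        .reset_index()
    )


def _drop_incomplete_loci(ds: GenotypeDataset):
    """Drop loci not genotyped in every population (N = 0 somewhere)."""
    _, _, N = ds.counts_matrix()
    keep = (N > 0).all(axis=0)
    kept = [loc for loc, k in zip(ds.loci, keep) if k]
    dropped = [loc for loc, k in zip(ds.loci, keep) if not k]
    return ds.subset(loci=kept), dropped


def run_real_pipeline(
    ds: GenotypeDataset,
    hierarchy: HierarchyAssignment,
    outdir,
    cfg: McmcConfig | None = None,
    gea_cfg: GeaConfig | None = None,
    seed=None,
    n_samples_step1: int = 2000,
    site_of: dict | None = None,
) -> dict:
    """Full analysis of a genotype dataset; writes artifacts + manifest.

    Sites are inferred as (cluster, subcluster, elevation-pair) groups
    unless ``site_of`` maps populations to site labels explicitly. The
    hierarchical model requires at least two sites; with a single site it
    is skipped (with a logged explanation) while the single-site models and
    the GEA tests still run.
    """
    cfg = cfg or McmcConfig(n_iter=10000, n_burnin=5000)
    gea_cfg = gea_cfg or GeaConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _spawn_seeds(seed, 4)
    manifest: dict = {
        "package": "hiergst",
        "version": __version__,
        "python": platform.python_version(),
        "seed": seed,
        "mcmc": {"n_iter": cfg.n_iter, "n_burnin": cfg.n_burnin, "thin": cfg.thin,
                 "n_chains": cfg.n_chains},
        "n_samples_step1": n_samples_step1,
        "stages": [],
    }

    def stage(name, **info):
        manifest["stages"].append({"stage": name, **info})
        log.info("stage %s: %s", name, info)

    ds2, dropped = _drop_incomplete_loci(ds)
    ds2, mono = filter_monomorphic(ds2)
    stage("filter", dropped_incomplete=dropped, dropped_monomorphic=mono,
          n_loci=ds2.n_loci, n_individuals=ds2.n_individuals)

    gst = gst_median_matrix(ds2, n_samples=n_samples_step1, seed=seeds[0])
    gst.write(outdir / "gst_matrix.tsv")
    stage("gst", n_pairs=len(gst.pairs), n_loci=len(gst.loci), out="gst_matrix.tsv")

    if site_of is None:
        site_of = {}
        for p in hierarchy.populations:
            site_of[p] = f"{hierarchy.cluster_of[p]}|{hierarchy.subcluster_of[p]}"
    sites: dict[str, list[str]] = {}
    for p in ds2.populations:
        sites.setdefault(site_of[p], []).append(p)

    # hierarchical (multi-site) model
    if len(sites) >= 2:
        hbm = HierarchicalGstModel(gst, hierarchy).fit(
            McmcConfig(cfg.n_iter, cfg.n_burnin, cfg.thin, cfg.n_chains, seeds[1])
        )
        hbm.write_summary(outdir / "hbm_summary.tsv")
        calls = hbm.call_outliers(0.01)
        calls.write(outdir / "hbm_outliers.tsv")
        stage("hbm", out="hbm_summary.tsv", outliers=calls.flagged,
              max_rhat=float(hbm.rhat.max()))
    else:
        hbm = None
        stage("hbm", skipped="the hierarchical model needs at least two sites; "
                             "single-site models and GEA still run")

    # per-site single-site models + GEA
    sbm_outliers, gea_counts = {}, {}
    for k, (site, pops) in enumerate(sorted(sites.items())):
        if len(pops) != 2:
            stage("sbm", site=site, skipped=f"site has {len(pops)} populations, need 2")
            continue
        site_ds, _ = filter_monomorphic(ds2.subset(populations=pops))
        if site_ds.n_loci < 3:
            stage("sbm", site=site, skipped="fewer than 3 polymorphic loci")
            continue
        sgst = gst_median_matrix(site_ds, n_samples=n_samples_step1,
                                 seed=seeds[2] + k)
        sfit = SingleSiteGstModel(sgst).fit(
            McmcConfig(cfg.n_iter, cfg.n_burnin, cfg.thin, cfg.n_chains, seeds[2] + k)
        )
        scalls = sfit.call_outliers(0.01)
        safe = site.replace("|", "_").replace("/", "_")
        scalls.write(outdir / f"sbm_outliers_{safe}.tsv")
        sbm_outliers[site] = scalls.flagged
        gea = gea_test(site_ds, GeaConfig(
            n1=gea_cfg.n1, n2=gea_cfg.n2, N_pop=gea_cfg.N_pop, N_sub=gea_cfg.N_sub,
            alpha=gea_cfg.alpha, seed=seeds[3] + k,
        ))
        gea.write(outdir / f"gea_{safe}.tsv")
        gea_counts[site] = int((gea.table["sign"] != "ns").sum())
        stage("site", site=site, sbm_outliers=scalls.flagged,
              gea_significant=gea_counts[site])

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return {"manifest": manifest, "hbm": hbm, "sbm_outliers": sbm_outliers,
            "gea_significant": gea_counts, "gst": gst}


#: the scenarios of the published power study (selection type, count, s)
TABLE2_ROWS = [
    PowerRow("no selection", 0, None),
    PowerRow("divergent", 1, 0.05), PowerRow("divergent", 5, 0.05), PowerRow("divergent", 10, 0.05),
    PowerRow("divergent", 1, 0.075), PowerRow("divergent", 5, 0.075), PowerRow("divergent", 10, 0.075),
    PowerRow("divergent", 1, 0.1), PowerRow("divergent", 5, 0.1), PowerRow("divergent", 10, 0.1),
    PowerRow("divergent", 1, 0.5), PowerRow("divergent", 5, 0.5), PowerRow("divergent", 10, 0.5),
    PowerRow("divergent", 1, 0.99), PowerRow("divergent", 5, 0.99), PowerRow("divergent", 10, 0.99),
    PowerRow("divergent", 10, (0.06, 0.15)), PowerRow("divergent", 10, (0.16, 0.25)),
    PowerRow("divergent", 10, (0.06, 0.24)),
    PowerRow("homogenizing", 5, 0.1),
    PowerRow("homogenizing/divergent", (2, 2), 0.1),
]
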
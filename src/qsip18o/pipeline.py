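"""Pipeline orchestration: filter -> profiles -> bootstrap -> growth -> summaries.

`run_pipeline` executes the full analysis on a validated bundle in the order
the estimates depend on each other: replicate-presence filter, per-tube
taxon profiles (WAD, totals), bootstrap APE with activity calls, growth
potential, treatment comparisons (APE ratios, phylum signed-rank tests),
diversity of total vs active communities, and growth efficiency.  All result
tables are returned (and optionally written with a run manifest).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import IsotopeConstants, growth_potential, tube_taxon_profiles
from .community import (
    gross_growth_by_group,
    growth_efficiency,
    percent_reduction,
    tube_diversity,
)
from .data_io import ExperimentBundle, treatment_label, write_results
from .stats import (
    bootstrap_ape_table,
    enrichment_inputs,
    filter_replicate_presence,
    phylum_ratio_test,
    ratio_table,
    top_phyla,
    treatment_median_ape,
)

log = logging.getLogger("qsip18o")

__all__ = ["default_comparisons", "run_pipeline"]


def default_comparisons(bundle: ExperimentBundle) -> list[tuple[str, str, str]]:
    """Standard comparison set: limited vs replete within each fungal level,
    and each fungus vs uninoculated within water-limited soil."""
    fungal_levels = list(dict.fromkeys(bundle.samples["fungal"]))
    moistures = set(bundle.samples["moisture"])
    comps = []
    if {"limited", "replete"} <= moistures:
        for f in fungal_levels:
            comps.append((f"{f}:limited_vs_replete",
                          treatment_label(f, "limited"), treatment_label(f, "replete")))
        if "uninoculated" in fungal_levels:
            for f in fungal_levels:
                if f != "uninoculated":
                    comps.append((f"{f}_vs_uninoculated:limited",
                                  treatment_label(f, "limited"),
                                  treatment_label("uninoculated", "limited")))
    return comps


def _growth_table(estimates: pd.DataFrame, inputs: pd.DataFrame,
                  constants: IsotopeConstants) -> pd.DataFrame:
    ntot = {(r.treatment, r.asv_id): (float(np.mean(r.n_total)),
                                      float(np.mean(r.n_t0)) if len(r.n_t0) else np.nan)
            for r in inputs.itertuples(index=False)}
    rows = []
    for rec in estimates.itertuples(index=False):
        n_total, n_t0 = ntot[(rec.treatment, rec.asv_id)]
        est = growth_potential(
            n_total, rec.ape_median / 100.0,
            asv_id=rec.asv_id, treatment=rec.treatment, n_t0=n_t0,
            constants=constants,
        )
        rows.append(vars(est))
    cols = ["asv_id", "treatment", "ape", "n_total", "n_light", "b",
            "cells_b", "t", "n_t0"]
    return pd.DataFrame(rows, columns=cols)


def run_pipeline(
    bundle: ExperimentBundle,
    constants: IsotopeConstants | None = None,
    n_boot: int = 1000,
    ci_level: float = 0.90,
    seed: int = 0,
    comparisons: list[tuple[str, str, str]] | None = None,
    top_n_phyla: int = 10,
    out_dir: str | Path | None = None,
) -> dict:
    """Run the full qSIP analysis; returns a dict of result tables.

    Keys: enrichment, growth, median_ape, ratios_asv, ratios_phylum,
    diversity, growth_by_phylum, efficiency, efficiency_reduction, and (when
    ``out_dir`` is given) manifest.  Deterministic for fixed ``seed``.
    """
    c = constants or IsotopeConstants()
    timings = {}
    t0 = time.perf_counter()

    def tick(stage):
        nonlocal t0
        now = time.perf_counter()
        timings[stage] = round(now - t0, 3)
        log.debug("stage %s: %.3fs", stage, now - t0)
        t0 = now

    whitelist = filter_replicate_presence(bundle)
    tick("filter_replicate_presence")
    profiles = tube_taxon_profiles(bundle.counts, bundle.fractions)
    tick("tube_taxon_profiles")
    inputs = enrichment_inputs(profiles, bundle.samples, whitelist)
    tick("enrichment_inputs")
    estimates = bootstrap_ape_table(inputs, c, n_iter=n_boot,
                                    ci_level=ci_level, seed=seed)
    tick("bootstrap_ape")
    growth = _growth_table(estimates, inputs, c)
    tick("growth_potential")

    median_ape = treatment_median_ape(estimates, active_only=True)

    phyla = top_phyla(bundle.counts, bundle.taxonomy, n=top_n_phyla)
    comparisons = default_comparisons(bundle) if comparisons is None else comparisons
    ratio_frames, phylum_frames = [], []
    for name, tr_a, tr_b in comparisons:
        r = ratio_table(estimates, tr_a, tr_b, comparison=name)
        ratio_frames.append(r)
        if len(r):
            phylum_frames.append(phylum_ratio_test(r, bundle.taxonomy, phyla=phyla))
    ratios_asv = (pd.concat(ratio_frames, ignore_index=True) if ratio_frames
                  else pd.DataFrame(columns=["asv_id", "comparison", "ape_a", "ape_b", "ratio"]))
    ratios_phylum = (pd.concat(phylum_frames, ignore_index=True) if phylum_frames
                     else pd.DataFrame(columns=["phylum", "comparison", "mean_ratio", "se",
                                                "n_asvs", "p_raw", "p_adj", "significant"]))
    tick("ratios")

    diversity = tube_diversity(profiles, bundle.samples, estimates)
    tick("diversity")

    active_growth = growth.merge(
        estimates.loc[estimates["active"], ["treatment", "asv_id"]],
        on=["treatment", "asv_id"])
    growth_by_phylum = gross_growth_by_group(active_growth, bundle.taxonomy,
                                             level="phylum", t=c.t_days, groups=phyla)
    gross_all = active_growth.assign(gross=active_growth["b"] * c.t_days) \
                             .groupby("treatment")["gross"].sum().to_dict()
    if bundle.co2 is not None and len(bundle.co2):
        efficiency = growth_efficiency(gross_all, bundle.co2)
        eff = efficiency.set_index("treatment")["efficiency"]
        red_rows = []
        for f in dict.fromkeys(bundle.samples["fungal"]):
            tr_r, tr_l = treatment_label(f, "replete"), treatment_label(f, "limited")
            if tr_r in eff.index and tr_l in eff.index:
                red_rows.append({
                    "fungal": f,
                    "efficiency_replete": float(eff[tr_r]),
                    "efficiency_limited": float(eff[tr_l]),
                    "pct_reduction": percent_reduction(eff[tr_r], eff[tr_l]),
                })
        efficiency_reduction = pd.DataFrame(
            red_rows, columns=["fungal", "efficiency_replete",
                               "efficiency_limited", "pct_reduction"])
    else:
        efficiency = pd.DataFrame(columns=["treatment", "gross_growth", "co2_efflux",
                                           "efficiency", "unit"])
        efficiency_reduction = pd.DataFrame(columns=["fungal", "efficiency_replete",
                                                     "efficiency_limited", "pct_reduction"])
    tick("efficiency")

    tables = {
        "enrichment": estimates,
        "growth": growth,
        "median_ape": median_ape,
        "ratios_asv": ratios_asv,
        "ratios_phylum": ratios_phylum,
        "diversity": diversity,
        "growth_by_phylum": growth_by_phylum,
        "efficiency": efficiency,
        "efficiency_reduction": efficiency_reduction,
    }

    if out_dir is not None:
        out = Path(out_dir)
        manifest_df = write_results(tables, out)
        run_config = {
            "seed": seed, "n_boot": n_boot, "ci_level": ci_level,
            "top_n_phyla": top_n_phyla,
            "comparisons": [list(x) for x in comparisons],
            "constants": {k: getattr(c, k) for k in (
                "gc_intercept", "gc_slope", "mw_gc_slope", "mw_intercept",
                "delta_mw_max_18o", "natural_abundance_18o",
                "atom_fraction_water_18o", "copies_per_cell", "t_days")},
        }
        cfg_json = json.dumps(run_config, sort_keys=True)
        checksums = {}
        for f in sorted(out.glob("*.tsv")):
            checksums[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()[:16]
        manifest = {
            "package_version": __version__,
            "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest()[:16],
            "config": run_config,
            "seed": seed,
            "stage_timings_s": timings,
            "outputs": manifest_df.to_dict(orient="records"),
            "checksums": checksums,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        tables["manifest"] = manifest
    return tables
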
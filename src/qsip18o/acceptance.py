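"""Recompute the package's headline quantities from scratch on synthetic data.

Runs the default simulated experiment (the full study design: 6 fungal x
moisture treatments, 3 replicates, T0/T7 and both isotopes, 22 fractions per
tube), executes the complete analysis pipeline, scores the estimates against
the simulator's ground-truth ledger, and adds a null (all-inactive)
false-positive check.  Returns a flat mapping of descriptive metric names to
``{"value": number, "n": problem size}``.
"""

from __future__ import annotations

import numpy as np

from .core import IsotopeConstants
from .pipeline import run_pipeline
from .simulate import DesignConfig, generate_experiment, truth_recovery_report
from .data_io import treatment_label

N_TAXA = 300
N_BOOT = 1000


def run_acceptance(seed: int = 1) -> dict:
    ss = np.random.SeedSequence(seed)
    main_ss, null_ss, boot_seed, null_boot_seed = ss.spawn(4)
    c = IsotopeConstants()
    results: dict[str, dict] = {}

    def put(name, value, n):
        results[name] = {"value": float(np.round(float(value), 6)), "n": int(n)}

    # --- design fidelity: the default simulated experiment ---------------
    design = DesignConfig(n_taxa=N_TAXA)
    bundle, truth = generate_experiment(design, seed=main_ss)
    n_tubes = len(bundle.tube_ids)
    put("n_tubes", n_tubes, n_tubes)
    put("n_treatments", len(bundle.treatments()), n_tubes)
    put("n_replicates_per_treatment",
        bundle.samples.groupby(["fungal", "moisture"])["replicate"].nunique().iloc[0],
        n_tubes)
    frac_counts = bundle.fractions.groupby("tube_id").size()
    put("fractions_per_tube", frac_counts.iloc[0], n_tubes)
    seq_per_tube = (bundle.fractions.groupby("tube_id")["sequenced"].sum())
    put("median_sequenced_fractions_per_tube", seq_per_tube.median(), n_tubes)

    # --- full pipeline + truth recovery ----------------------------------
    tables = run_pipeline(bundle, c, n_boot=N_BOOT,
                          seed=int(boot_seed.generate_state(1)[0] % 2**31))
    est = tables["enrichment"]
    put("n_asv_treatment_estimates", len(est), len(est))
    put("pct_estimates_active", 100.0 * est["active"].mean(), len(est))
    active = est[est["active"]]
    put("median_ape_active", active["ape_median"].median(), len(active))
    put("max_ape", est["ape_median"].max(), len(est))

    rec = truth_recovery_report(truth, est, tables["growth"], c)
    put("median_abs_ape_error_active", rec["median_abs_ape_error_active"],
        rec["n_truly_active"])
    put("ci_coverage_pct", 100.0 * rec["ci_coverage"], rec["n_estimates"])
    put("active_call_sensitivity_pct", 100.0 * rec["sensitivity"], rec["n_truly_active"])
    put("median_rel_growth_error_pct",
        100.0 * rec.get("median_rel_b_error_active", np.nan), rec["n_truly_active"])

    red = tables["efficiency_reduction"].set_index("fungal")["pct_reduction"]
    for fungal in ("uninoculated", "R_irregularis", "S_bescii"):
        if fungal in red.index:
            put(f"efficiency_reduction_pct_{fungal}", red[fungal], len(est))

    # --- null control: all-inactive community -----------------------------
    null_design = DesignConfig(
        n_taxa=N_TAXA, frac_active=0.0,
        fungal_levels=("uninoculated",), moisture_levels=("replete",),
        ape_scale={treatment_label("uninoculated", "replete"): 1.0},
        co2_means={treatment_label("uninoculated", "replete"): 6.0},
    )
    null_bundle, null_truth = generate_experiment(null_design, seed=null_ss)
    null_tables = run_pipeline(null_bundle, c, n_boot=N_BOOT,
                               seed=int(null_boot_seed.generate_state(1)[0] % 2**31))
    null_rec = truth_recovery_report(null_truth, null_tables["enrichment"])
    put("null_false_positive_pct", 100.0 * null_rec["false_positive_rate"],
        null_rec["n_estimates"])
    return results
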
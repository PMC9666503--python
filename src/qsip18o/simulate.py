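"""Forward simulator of the H2-18O qSIP experiment with known ground truth.

The generator emulates the full study design: three fungal inoculum
conditions (uninoculated, R. irregularis, S. bescii) x two moisture regimes
(replete, limited) x three replicate microcosms, each contributing a T0
H2-16O tube and T7 H2-16O / H2-18O tube pair — 54 tubes in all, 22 density
fractions per tube.

Physics.  Each taxon's DNA bands as a Gaussian (sd ``band_sd``) in the CsCl
density axis.  Its unlabeled band centers at the GC-determined density; in a
labeled tube the taxon's DNA is a two-component mixture — "old" DNA at the
unlabeled center and "new" DNA (fraction p_new = APE/100 / a_sat of the
pool) at the fully water-labeled center — so the taxon's mass-weighted
density shift reproduces its true APE exactly under the inference model.
Fraction bins partition the density axis; per-fraction DNA concentration and
qPCR totals derive from the binned mass with lognormal noise, fractions
above the concentration cutoff are "sequenced" and receive multinomial read
counts.  With ``noise=False`` expected values are emitted instead of draws,
making the pipeline's estimates exact up to density-bin discretization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .core import IsotopeConstants, labeled_density_for_afe, unlabeled_density_from_gc
from .data_io import (
    ExperimentBundle,
    FUNGAL_LEVELS,
    MOISTURE_LEVELS,
    treatment_label,
)

__all__ = [
    "DesignConfig",
    "GradientConfig",
    "SimulationTruth",
    "make_taxa",
    "simulate_tube",
    "generate_experiment",
    "truth_recovery_report",
]

# soil phyla used for simulated lineages, roughly by prevalence
_PHYLA = (
    "Proteobacteria", "Actinobacteria", "Acidobacteria", "Bacteroidetes",
    "Chloroflexi", "Firmicutes", "Verrucomicrobia", "Planctomycetes",
    "Gemmatimonadetes", "Myxococcota", "Nitrospirae", "Armatimonadetes",
)
_PHYLUM_WEIGHTS = (0.25, 0.18, 0.12, 0.10, 0.08, 0.07, 0.06, 0.05, 0.04, 0.02, 0.02, 0.01)


@dataclass(frozen=True)
class GradientConfig:
    """Gradient fractionation, qPCR and sequencing parameters."""

    n_fractions: int = 22
    band_sd: float = 0.005          # g/mL Gaussian band width per taxon
    density_min: float = 1.620      # g/mL, lightest collected density
    density_max: float = 1.800      # g/mL, densest collected density
    read_depth: int = 10_000        # reads per sequenced fraction
    qpcr_cv: float = 0.15           # lognormal CV of per-fraction qPCR totals
    conc_cv: float = 0.05           # lognormal CV of DNA concentration assay
    conc_cutoff: float = 1.0        # ng/uL sequencing threshold
    total_dna_ng: float = 5000.0    # DNA loaded per tube (5 ug)
    resuspension_ul: float = 40.0   # fraction resuspension volume
    copies_per_ng: float = 1.0e6    # 16S copies per ng community DNA
    noise: bool = True

    def __post_init__(self):
        if self.n_fractions < 3:
            raise ValueError("need at least 3 fractions")
        if self.band_sd <= 0:
            raise ValueError("band_sd must be positive")

    def edges(self) -> np.ndarray:
        return np.linspace(self.density_min, self.density_max, self.n_fractions + 1)


def _default_ape_scale() -> dict:
    # emulated treatment effects: strong suppression by moisture limitation in
    # uninoculated soil, weak in fungal-inoculated soil
    return {
        treatment_label("uninoculated", "replete"): 1.00,
        treatment_label("uninoculated", "limited"): 0.45,
        treatment_label("R_irregularis", "replete"): 0.95,
        treatment_label("R_irregularis", "limited"): 0.90,
        treatment_label("S_bescii", "replete"): 0.85,
        treatment_label("S_bescii", "limited"): 0.75,
    }


def _default_co2_means() -> dict:
    # ug CO2 per mg soil C over the assay; S. bescii respires most
    return {
        treatment_label("uninoculated", "replete"): 6.0,
        treatment_label("uninoculated", "limited"): 5.8,
        treatment_label("R_irregularis", "replete"): 5.5,
        treatment_label("R_irregularis", "limited"): 5.2,
        treatment_label("S_bescii", "replete"): 8.0,
        treatment_label("S_bescii", "limited"): 7.0,
    }


@dataclass(frozen=True)
class DesignConfig:
    """Experimental design and ground-truth distribution parameters."""

    fungal_levels: tuple = FUNGAL_LEVELS
    moisture_levels: tuple = MOISTURE_LEVELS
    n_replicates: int = 3
    n_taxa: int = 300
    frac_active: float = 0.4        # P(taxon active) per treatment
    ape_max: float = 65.0           # active taxa: APE ~ U(0, ape_max * scale)
    gc_range: tuple = (0.3, 0.7)
    abundance_alpha: float = 0.5    # Dirichlet concentration of base abundances
    treatment_abund_sd: float = 0.5  # lognormal sd of treatment-level abundance shifts
    replicate_abund_sd: float = 0.3  # lognormal sd of replicate multipliers
    ape_scale: dict = field(default_factory=_default_ape_scale)
    co2_means: dict = field(default_factory=_default_co2_means)
    co2_cv: float = 0.15

    def treatments(self) -> list[str]:
        return [treatment_label(f, m)
                for f in self.fungal_levels for m in self.moisture_levels]


@dataclass
class SimulationTruth:
    """Ground-truth ledger emitted by the simulator."""

    taxa: pd.DataFrame        # asv_id, gc, w_light, domain..genus
    ape: pd.DataFrame         # asv_id, treatment, true_ape, active
    abundance: pd.DataFrame   # asv_id, treatment, rel_abundance
    rep_effects: pd.DataFrame  # asv_id, treatment, replicate, multiplier
    design: DesignConfig = None
    gradient: GradientConfig = None

    def to_frame(self) -> pd.DataFrame:
        """Long truth table (one row per taxon x treatment) for truth.tsv."""
        df = self.ape.merge(self.abundance, on=["asv_id", "treatment"])
        return df.merge(self.taxa, on="asv_id")

    def true_b(self, constants: IsotopeConstants | None = None) -> pd.DataFrame:
        """Expected per-taxon growth rate implied by the truth ledger."""
        c = constants or IsotopeConstants()
        g = self.gradient or GradientConfig()
        df = self.ape.merge(self.abundance, on=["asv_id", "treatment"])
        n_total = g.total_dna_ng * g.copies_per_ng * df["rel_abundance"]
        p_new = df["true_ape"] / 100.0 / c.a_sat
        df["true_n_total"] = n_total
        df["true_b"] = n_total * p_new / c.t_days
        return df[["asv_id", "treatment", "true_ape", "true_n_total", "true_b"]]


def _lineage_frame(asv_ids, phyla, rng) -> pd.DataFrame:
    classes = [f"{p}_cls{rng.integers(1, 4)}" for p in phyla]
    return pd.DataFrame({
        "asv_id": asv_ids,
        "domain": "Bacteria",
        "phylum": phyla,
        "class": classes,
        "order": [f"{c}_ord" for c in classes],
        "family": [f"{c}_fam" for c in classes],
        "genus": [f"{c}_gen{rng.integers(1, 10)}" for c in classes],
    })


def make_taxa(
    n_taxa: int,
    design: DesignConfig | None = None,
    seed: int | np.random.SeedSequence = 0,
    constants: IsotopeConstants | None = None,
) -> SimulationTruth:
    """Draw the ground-truth taxa: GC, per-treatment APE, abundances, lineages.

    GC is uniform over ``gc_range``; per (taxon, treatment) the true APE is a
    mixture of a point mass at exactly 0 (inactive, probability
    1 - ``frac_active``) and U(0, ape_max * treatment scale).  Abundances are
    Dirichlet at the base, perturbed per treatment and per replicate by
    lognormal multipliers.  Fully reproducible under ``seed``.
    """
    design = design or DesignConfig()
    if n_taxa < 1:
        raise ValueError("need at least one taxon")
    if not 0.0 <= design.frac_active <= 1.0:
        raise ValueError("frac_active must be a probability")
    c = constants or IsotopeConstants()
    rng = np.random.default_rng(seed)
    asv_ids = [f"ASV{i:05d}" for i in range(1, n_taxa + 1)]

    gc = rng.uniform(*design.gc_range, size=n_taxa)
    phyla = rng.choice(_PHYLA, size=n_taxa, p=np.asarray(_PHYLUM_WEIGHTS))
    taxa = _lineage_frame(asv_ids, phyla, rng)
    taxa.insert(1, "gc", gc)
    taxa.insert(2, "w_light", unlabeled_density_from_gc(gc, c))

    treatments = design.treatments()
    base = rng.dirichlet(np.full(n_taxa, design.abundance_alpha))
    ape_rows, ab_rows, rep_rows = [], [], []
    for tr in treatments:
        scale = design.ape_scale.get(tr, 1.0)
        active = rng.random(n_taxa) < design.frac_active
        ape = np.where(active, rng.uniform(0.0, design.ape_max * scale, n_taxa), 0.0)
        shift = rng.lognormal(0.0, design.treatment_abund_sd, n_taxa)
        ab = base * shift
        ab = ab / ab.sum()
        ape_rows.append(pd.DataFrame({"asv_id": asv_ids, "treatment": tr,
                                      "true_ape": ape, "active": active}))
        ab_rows.append(pd.DataFrame({"asv_id": asv_ids, "treatment": tr,
                                     "rel_abundance": ab}))
        for rep in range(1, design.n_replicates + 1):
            mult = rng.lognormal(0.0, design.replicate_abund_sd, n_taxa)
            rep_rows.append(pd.DataFrame({"asv_id": asv_ids, "treatment": tr,
                                          "replicate": rep, "multiplier": mult}))
    return SimulationTruth(
        taxa=taxa,
        ape=pd.concat(ape_rows, ignore_index=True),
        abundance=pd.concat(ab_rows, ignore_index=True),
        rep_effects=pd.concat(rep_rows, ignore_index=True),
        design=design,
    )


def simulate_tube(
    truth: SimulationTruth,
    treatment: str,
    isotope: str,
    replicate: int,
    tube_id: str,
    gradient: GradientConfig | None = None,
    constants: IsotopeConstants | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one ultracentrifuge tube: fraction records plus read counts.

    Returns ``(fractions, counts)`` in the data-model schemas.  Fraction 1 is
    the densest.  For a 16O tube the labeled component has zero mass.
    """
    g = gradient or GradientConfig()
    c = constants or IsotopeConstants()
    rng = rng or np.random.default_rng()

    tax = truth.taxa
    ape = truth.ape[truth.ape["treatment"] == treatment].set_index("asv_id")
    ab = truth.abundance[truth.abundance["treatment"] == treatment].set_index("asv_id")
    if ape.empty:
        raise ValueError(f"truth has no treatment {treatment!r}")
    asv_ids = tax["asv_id"].to_numpy()
    w_light = tax["w_light"].to_numpy()
    true_ape = ape.loc[asv_ids, "true_ape"].to_numpy()
    rel_ab = ab.loc[asv_ids, "rel_abundance"].to_numpy()

    re = truth.rep_effects
    mult = (re[(re["treatment"] == treatment) & (re["replicate"] == replicate)]
            .set_index("asv_id").loc[asv_ids, "multiplier"].to_numpy())
    p = rel_ab * (mult if g.noise else 1.0)
    p = p / p.sum()
    mass = g.total_dna_ng * p  # ng per taxon

    if isotope == "18O":
        p_new = (true_ape / 100.0) / c.a_sat
    elif isotope == "16O":
        p_new = np.zeros_like(true_ape)
    else:
        raise ValueError(f"unknown isotope {isotope!r}")
    w_new = np.asarray(labeled_density_for_afe(c.a_sat, w_light, c))

    edges = g.edges()
    # bin each Gaussian component: rows = taxa, cols = fractions (ascending density)
    def binned(mu, comp_mass):
        z = (edges[None, :] - mu[:, None]) / g.band_sd
        cdf = norm.cdf(z)
        inside = cdf[:, 1:] - cdf[:, :-1]
        lost = comp_mass * (1.0 - (cdf[:, -1] - cdf[:, 0]))
        return comp_mass[:, None] * inside, float(lost.sum())

    old_m, lost_old = binned(w_light, mass * (1.0 - p_new))
    new_m, lost_new = binned(w_new, mass * p_new)
    lost = lost_old + lost_new
    if lost > 1e-6 * g.total_dna_ng:
        warnings.warn(
            f"{tube_id}: {lost:.3g} ng of DNA bands outside the collected "
            f"gradient [{g.density_min}, {g.density_max}] and was truncated",
            stacklevel=2,
        )
    mass_tf = old_m + new_m                     # (n_taxa, n_fractions)
    mass_f = mass_tf.sum(axis=0)                # per-fraction DNA mass, ng

    conc = mass_f / g.resuspension_ul
    copies = mass_f * g.copies_per_ng
    if g.noise:
        conc = conc * rng.lognormal(0.0, g.conc_cv, size=conc.shape)
        copies = copies * rng.lognormal(0.0, g.qpcr_cv, size=copies.shape)
    sequenced = conc > g.conc_cutoff

    mids = (edges[:-1] + edges[1:]) / 2.0
    n = g.n_fractions
    frac_index = n - np.arange(n)               # densest bin -> fraction 1
    fractions = pd.DataFrame({
        "tube_id": tube_id,
        "fraction_index": frac_index,
        "density_g_ml": mids,
        "dna_conc_ng_ul": conc,
        "total_16s_copies": copies,
        "sequenced": sequenced,
    }).sort_values("fraction_index", ignore_index=True)

    count_rows = []
    for k in np.flatnonzero(sequenced):
        share = mass_tf[:, k]
        tot = share.sum()
        if tot <= 0:
            continue
        pk = share / tot
        if g.noise:
            reads = rng.multinomial(g.read_depth, pk)
        else:
            reads = pk * g.read_depth
        nz = reads > 0
        count_rows.append(pd.DataFrame({
            "tube_id": tube_id,
            "fraction_index": frac_index[k],
            "asv_id": asv_ids[nz],
            "count": reads[nz],
        }))
    counts = (pd.concat(count_rows, ignore_index=True) if count_rows
              else pd.DataFrame(columns=["tube_id", "fraction_index", "asv_id", "count"]))
    return fractions, counts


def generate_experiment(
    design: DesignConfig | None = None,
    gradient: GradientConfig | None = None,
    constants: IsotopeConstants | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[ExperimentBundle, SimulationTruth]:
    """Simulate the full experiment: bundle of tubes plus the truth ledger.

    Per treatment and replicate three tubes are produced: T0 16O, T7 16O and
    T7 18O (default design: 6 treatments x 3 replicates = 54 tubes).  All
    randomness flows from ``seed`` through named substreams, one per tube, so
    any tube is reproducible independently of the others.
    """
    design = design or DesignConfig()
    gradient = gradient or GradientConfig()
    c = constants or IsotopeConstants()
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    taxa_ss, co2_ss, tubes_ss = ss.spawn(3)
    truth = make_taxa(design.n_taxa, design, seed=taxa_ss, constants=c)
    truth.gradient = gradient

    frames_f, frames_c, meta_rows = [], [], []
    tube_specs = []
    for fungal in design.fungal_levels:
        for moisture in design.moisture_levels:
            for rep in range(1, design.n_replicates + 1):
                for timepoint, isotope in (("T0", "16O"), ("T7", "16O"), ("T7", "18O")):
                    tube_specs.append((fungal, moisture, rep, timepoint, isotope))
    child_seeds = tubes_ss.spawn(len(tube_specs))
    for (fungal, moisture, rep, timepoint, isotope), child in zip(tube_specs, child_seeds):
        treatment = treatment_label(fungal, moisture)
        tube_id = f"{fungal}.{moisture}.R{rep}.{timepoint}.{isotope}"
        rng = np.random.default_rng(child)
        fr, cn = simulate_tube(truth, treatment, isotope, rep, tube_id,
                               gradient, c, rng)
        frames_f.append(fr)
        frames_c.append(cn)
        meta_rows.append({
            "tube_id": tube_id,
            "microcosm_id": f"{fungal}.{moisture}.R{rep}",
            "fungal": fungal, "moisture": moisture,
            "isotope": isotope, "timepoint": timepoint, "replicate": rep,
        })

    co2_rng = np.random.default_rng(co2_ss)
    co2_rows = []
    for fungal in design.fungal_levels:
        for moisture in design.moisture_levels:
            mean = design.co2_means.get(treatment_label(fungal, moisture), 6.0)
            for rep in range(1, design.n_replicates + 1):
                val = mean * (co2_rng.lognormal(0.0, design.co2_cv) if gradient.noise else 1.0)
                co2_rows.append({"fungal": fungal, "moisture": moisture,
                                 "replicate": rep, "co2_efflux": val})

    bundle = ExperimentBundle(
        fractions=pd.concat(frames_f, ignore_index=True),
        samples=pd.DataFrame(meta_rows),
        counts=pd.concat(frames_c, ignore_index=True),
        taxonomy=truth.taxa.drop(columns=["gc", "w_light"]),
        co2=pd.DataFrame(co2_rows),
        config={"seed": int(ss.entropy) if isinstance(ss.entropy, int) else str(ss.entropy),
                "cutoff_ng_ul": gradient.conc_cutoff,
                "density_orientation": "heavy_first",
                "copies_basis": "copies per g dry soil per fraction"},
    ).validate()
    return bundle, truth


def truth_recovery_report(
    truth: SimulationTruth,
    estimates: pd.DataFrame,
    growth: pd.DataFrame | None = None,
    constants: IsotopeConstants | None = None,
) -> dict:
    """Compare pipeline estimates against the simulator's truth ledger.

    Returns a dict of error metrics: median absolute APE error among truly
    active taxa, CI coverage of the true APE, the active-call confusion
    matrix and false-positive rate, and (when ``growth`` is given) the median
    relative error of b among truly active taxa.  Estimated ASVs missing from
    the ledger raise an error.
    """
    merged = estimates.merge(truth.ape, on=["asv_id", "treatment"],
                             how="left", suffixes=("", "_true"))
    if merged["true_ape"].isna().any():
        bad = merged.loc[merged["true_ape"].isna(), "asv_id"].unique()
        raise ValueError(f"estimates for ASVs absent from truth ledger: {bad[:5]}")
    merged["ape_error"] = merged["ape_median"] - merged["true_ape"]
    truly_active = merged["true_ape"] > 0
    covered = (merged["ci_low"] <= merged["true_ape"]) & (merged["true_ape"] <= merged["ci_high"])
    tp = int((truly_active & merged["active"]).sum())
    fp = int((~truly_active & merged["active"]).sum())
    fn = int((truly_active & ~merged["active"]).sum())
    tn = int((~truly_active & ~merged["active"]).sum())
    report = {
        "n_estimates": int(len(merged)),
        "n_truly_active": int(truly_active.sum()),
        "median_abs_ape_error_active": float(
            merged.loc[truly_active, "ape_error"].abs().median()) if truly_active.any() else np.nan,
        "max_abs_ape_error": float(merged["ape_error"].abs().max()) if len(merged) else np.nan,
        "ci_coverage": float(covered.mean()) if len(merged) else np.nan,
        "confusion": {"tp": tp, "fp": fp, "fn": fn, "tn": tn},
        "false_positive_rate": fp / (fp + tn) if (fp + tn) else np.nan,
        "sensitivity": tp / (tp + fn) if (tp + fn) else np.nan,
    }
    if growth is not None:
        tb = truth.true_b(constants)
        gm = growth.merge(tb, on=["asv_id", "treatment"])
        act = gm["true_b"] > 0
        if act.any():
            rel = ((gm.loc[act, "b"] - gm.loc[act, "true_b"]) / gm.loc[act, "true_b"]).abs()
            report["median_rel_b_error_active"] = float(rel.median())
    return report
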
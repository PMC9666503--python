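"""Community-level views: qSIP-filtered diversity, phylum growth, efficiency.

The "active" community of a sample is the total community with every taxon
removed whose lower 90% bootstrap CI on APE did not clear zero; abundances
are renormalized after filtering.  Alpha diversity is the Inverse Simpson
index D = 1 / sum(p_i^2) on copy-number-scaled abundances pooled per tube
over its sequenced fractions.

Gross growth per group is the sum of b_i * t over member taxa (new gene
copies per g soil over the assay); growth efficiency divides a treatment's
gross growth by its CO2 efflux.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_io import treatment_label

__all__ = [
    "inverse_simpson",
    "qsip_filter_community",
    "tube_diversity",
    "gross_growth_by_group",
    "growth_efficiency",
    "percent_reduction",
]

EFFICIENCY_UNIT = "16S copies g-1 soil per (ug CO2 mg-1 soil C)"


def inverse_simpson(rel_abundances) -> float:
    """Inverse Simpson diversity D = 1 / sum(p_i^2); renormalizes internally."""
    p = np.asarray(rel_abundances, dtype=float)
    p = p[p > 0]
    if p.size == 0 or p.sum() <= 0:
        raise ValueError("inverse Simpson undefined for an empty community")
    p = p / p.sum()
    return float(1.0 / np.sum(p**2))


def qsip_filter_community(
    abundances: pd.Series | dict,
    active_asvs: set | None = None,
    mode: str = "total",
) -> pd.Series:
    """Relative-abundance view of a community, optionally active-only.

    ``abundances`` maps asv_id -> abundance (any non-negative scale).  In
    ``active`` mode only taxa in ``active_asvs`` are kept and abundances are
    renormalized.  Returns an empty Series (flag for downstream handling)
    when no active taxa remain.
    """
    s = pd.Series(abundances, dtype=float)
    s = s[s > 0]
    if mode == "active":
        if active_asvs is None:
            raise ValueError("active mode requires the active ASV set")
        s = s[s.index.isin(active_asvs)]
    elif mode != "total":
        raise ValueError(f"unknown community mode: {mode!r}")
    total = s.sum()
    return s / total if total > 0 else s


def tube_diversity(
    profiles: pd.DataFrame,
    samples: pd.DataFrame,
    estimates: pd.DataFrame,
    timepoint: str = "T7",
) -> pd.DataFrame:
    """Per-tube Inverse Simpson diversity of total and active communities.

    Abundances are each taxon's total copies in the tube (pooled over
    sequenced fractions, from :func:`qsip18o.core.tube_taxon_profiles`); the
    active set is the tube's treatment's active ASVs.  Empty active
    communities yield NaN with richness 0.
    """
    active_sets = {
        t: set(grp.loc[grp["active"], "asv_id"])
        for t, grp in estimates.groupby("treatment")
    }
    meta = samples[samples["timepoint"] == timepoint]
    df = profiles.merge(meta[["tube_id", "fungal", "moisture"]], on="tube_id")
    rows = []
    for tube, grp in df.groupby("tube_id"):
        fungal = grp["fungal"].iloc[0]
        moisture = grp["moisture"].iloc[0]
        treatment = treatment_label(fungal, moisture)
        ab = pd.Series(grp["n_total"].values, index=grp["asv_id"].values)
        for mode in ("total", "active"):
            view = qsip_filter_community(ab, active_sets.get(treatment, set()), mode)
            rows.append({
                "tube_id": tube,
                "treatment": treatment,
                "mode": mode,
                "richness": int(len(view)),
                "inverse_simpson": inverse_simpson(view) if len(view) else np.nan,
            })
    return pd.DataFrame(rows, columns=["tube_id", "treatment", "mode",
                                       "richness", "inverse_simpson"])


def gross_growth_by_group(
    growth: pd.DataFrame,
    taxonomy: pd.DataFrame,
    level: str = "phylum",
    t: float = 7.0,
    groups: list[str] | None = None,
) -> pd.DataFrame:
    """Gross growth (new copies per g over the assay) summed by taxonomic group.

    Group total = sum over member ASVs of b_i * t.  ASVs with no entry at the
    requested rank fall into "unclassified".  ``groups`` restricts reporting
    (e.g. the ten most abundant phyla); group totals over all groups remain
    additive with the per-ASV totals.
    """
    if level not in taxonomy.columns:
        tax = taxonomy[["asv_id"]].assign(**{level: "unclassified"})
    else:
        tax = taxonomy[["asv_id", level]]
    df = growth.merge(tax, on="asv_id", how="left")
    df[level] = df[level].fillna("unclassified")
    df["gross"] = df["b"] * t
    agg = df.groupby(["treatment", level], as_index=False).agg(
        gross_growth=("gross", "sum"), n_asvs=("asv_id", "size"))
    agg = agg.rename(columns={level: "phylum" if level == "phylum" else level})
    key = "phylum" if level == "phylum" else level
    if groups is not None:
        agg = agg[agg[key].isin(groups)]
    return agg[[key, "treatment", "gross_growth", "n_asvs"]].reset_index(drop=True)


def growth_efficiency(
    gross_growth: pd.DataFrame | dict,
    co2: pd.DataFrame,
) -> pd.DataFrame:
    """Growth-efficiency proxy per treatment: gross growth / CO2 efflux.

    ``gross_growth`` maps treatment -> total new copies per g over the assay
    (or is a DataFrame with columns treatment, gross_growth); ``co2`` has
    columns (fungal, moisture, replicate, co2_efflux) and is averaged over
    replicates.  Treatments with CO2 <= 0 get NaN efficiency (flagged).
    """
    if isinstance(gross_growth, pd.DataFrame):
        gg = gross_growth.groupby("treatment")["gross_growth"].sum().to_dict()
    else:
        gg = dict(gross_growth)
    co2 = co2.copy()
    co2["treatment"] = [treatment_label(f, m)
                        for f, m in zip(co2["fungal"], co2["moisture"])]
    co2_mean = co2.groupby("treatment")["co2_efflux"].mean()
    rows = []
    for treatment in sorted(gg):
        c = float(co2_mean.get(treatment, np.nan))
        g = float(gg[treatment])
        eff = g / c if c > 0 else np.nan
        rows.append({"treatment": treatment, "gross_growth": g,
                     "co2_efflux": c, "efficiency": eff, "unit": EFFICIENCY_UNIT})
    return pd.DataFrame(rows, columns=["treatment", "gross_growth", "co2_efflux",
                                       "efficiency", "unit"])


def percent_reduction(eff_reference: float, eff_other: float) -> float:
    """Percent reduction of efficiency relative to a reference condition.

    100 * (1 - eff_other / eff_reference); e.g. reference = water-replete,
    other = water-limited.
    """
    if eff_reference == 0 or not np.isfinite(eff_reference):
        return float("nan")
    return 100.0 * (1.0 - eff_other / eff_reference)
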
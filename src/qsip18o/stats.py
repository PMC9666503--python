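"""Replicate filtering, bootstrap confidence intervals, activity calls, ratio tests.

Uncertainty in per-taxon 18O atom percent excess (APE) is quantified by a
replicate-level bootstrap: each iteration resamples the replicate tube WADs
with replacement, independently on the unlabeled (16O) and labeled (18O)
sides, averages each side, and converts the pair to an atom fraction excess.
The point estimate is the median of the bootstrap draws; the 90% CI the
(5th, 95th) percentiles.  A taxon is called actively growing when the lower
CI bound is strictly above zero.

Treatment comparisons use APE ratios of taxa active under both conditions;
phylum-level means of these ratios are tested against 1 with a Wilcoxon
signed-rank test and Benjamini-Hochberg correction across phyla.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .core import IsotopeConstants, atom_fraction_excess_18o
from .data_io import ExperimentBundle, treatment_label

__all__ = [
    "filter_replicate_presence",
    "enrichment_inputs",
    "bootstrap_ape",
    "bootstrap_ape_table",
    "classify_active",
    "ape_ratio",
    "ratio_table",
    "top_phyla",
    "phylum_ratio_test",
    "treatment_median_ape",
]


def filter_replicate_presence(bundle: ExperimentBundle) -> pd.DataFrame:
    """Per-treatment whitelist of ASVs recovered from every replicate.

    An ASV is retained for a treatment iff it has at least one read in every
    replicate of that treatment's qSIP tube set (the T7 16O and 18O tubes;
    any sequenced fraction, either isotope, counts as presence for that
    replicate).  Returns a DataFrame (treatment, asv_id).
    """
    s = bundle.samples
    t7 = s[s["timepoint"] == "T7"]
    if t7.empty:
        raise ValueError("no T7 tubes in experiment")
    rows = []
    for (fungal, moisture), grp in t7.groupby(["fungal", "moisture"]):
        treatment = treatment_label(fungal, moisture)
        reps = sorted(grp["replicate"].unique())
        if len(reps) == 0:
            raise ValueError(f"treatment {treatment} has no replicates")
        present_sets = []
        for rep in reps:
            tubes = set(grp.loc[grp["replicate"] == rep, "tube_id"])
            asvs = set(bundle.counts.loc[
                bundle.counts["tube_id"].isin(tubes) & (bundle.counts["count"] > 0),
                "asv_id"])
            present_sets.append(asvs)
        kept = set.intersection(*present_sets) if present_sets else set()
        rows.extend({"treatment": treatment, "asv_id": a} for a in sorted(kept))
    return pd.DataFrame(rows, columns=["treatment", "asv_id"])


def enrichment_inputs(
    profiles: pd.DataFrame,
    samples: pd.DataFrame,
    whitelist: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble per-(treatment, ASV) replicate WAD/abundance vectors.

    ``profiles`` is the per-(tube, ASV) table from
    :func:`qsip18o.core.tube_taxon_profiles`.  For each treatment and ASV the
    result row carries, as lists ordered by replicate: unlabeled T7 WADs
    (``wad_light``), labeled T7 WADs (``wad_labeled``), per-replicate T7
    totals (mean of the replicate's 16O and 18O tube totals, ``n_total``),
    and T0 totals (``n_t0``, context only).  Rows without at least one WAD on
    each side are dropped with a reason code in the companion ``skipped``
    attribute (``attrs['skipped']``).
    """
    meta = samples[["tube_id", "fungal", "moisture", "isotope", "timepoint", "replicate"]]
    df = profiles.merge(meta, on="tube_id")
    df["treatment"] = [treatment_label(f, m) for f, m in zip(df["fungal"], df["moisture"])]
    if whitelist is not None:
        df = df.merge(whitelist, on=["treatment", "asv_id"])

    rows, skipped = [], []
    t7 = df[df["timepoint"] == "T7"]
    t0 = df[df["timepoint"] == "T0"]
    t0_map: dict[tuple, list] = {}
    for (treatment, asv), grp in (
        t0.groupby(["treatment", "asv_id", "replicate"])["n_total"].mean()
          .reset_index().groupby(["treatment", "asv_id"])
    ):
        t0_map[(treatment, asv)] = list(grp["n_total"].values)
    for (treatment, asv), grp in t7.groupby(["treatment", "asv_id"], sort=True):
        light = grp[grp["isotope"] == "16O"].sort_values("replicate")
        lab = grp[grp["isotope"] == "18O"].sort_values("replicate")
        if light.empty or lab.empty:
            skipped.append({"treatment": treatment, "asv_id": asv,
                            "reason": "missing_16O_side" if light.empty else "missing_18O_side"})
            continue
        ntot = grp.groupby("replicate")["n_total"].mean()
        nt0_list = t0_map.get((treatment, asv), [])
        rows.append({
            "treatment": treatment,
            "asv_id": asv,
            "wad_light": list(light["wad"].values),
            "wad_labeled": list(lab["wad"].values),
            "n_total": list(ntot.values),
            "n_t0": nt0_list,
        })
    out = pd.DataFrame(rows, columns=["treatment", "asv_id", "wad_light",
                                      "wad_labeled", "n_total", "n_t0"])
    out.attrs["skipped"] = pd.DataFrame(skipped, columns=["treatment", "asv_id", "reason"])
    return out


def bootstrap_ape(
    wad_light_reps,
    wad_labeled_reps,
    constants: IsotopeConstants | None = None,
    n_iter: int = 1000,
    ci_level: float = 0.90,
    rng: np.random.Generator | None = None,
) -> dict:
    """Bootstrap the APE of one taxon in one treatment from replicate WADs.

    Returns a dict with ``ape_median``, ``ci_low``, ``ci_high`` (APE points),
    ``n_boot`` and ``active``.  Deterministic for a fixed generator state.
    """
    c = constants or IsotopeConstants()
    rng = rng or np.random.default_rng()
    light = np.asarray(wad_light_reps, dtype=float)
    lab = np.asarray(wad_labeled_reps, dtype=float)
    light = light[~np.isnan(light)]
    lab = lab[~np.isnan(lab)]
    if light.size == 0 or lab.size == 0:
        raise ValueError("need at least one replicate WAD on each side")
    li = rng.integers(0, light.size, size=(n_iter, light.size))
    bi = rng.integers(0, lab.size, size=(n_iter, lab.size))
    w_light = light[li].mean(axis=1)
    w_lab = lab[bi].mean(axis=1)
    draws = 100.0 * np.asarray(atom_fraction_excess_18o(w_lab, w_light, c))
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.percentile(draws, [100 * alpha, 100 * (1 - alpha)])
    med = float(np.median(draws))
    return {
        "ape_median": med,
        "ci_low": float(lo),
        "ci_high": float(hi),
        "n_boot": int(n_iter),
        "active": bool(lo > 0),
    }


def bootstrap_ape_table(
    inputs: pd.DataFrame,
    constants: IsotopeConstants | None = None,
    n_iter: int = 1000,
    ci_level: float = 0.90,
    seed: int | np.random.SeedSequence | None = 0,
) -> pd.DataFrame:
    """Bootstrap APE for every row of an :func:`enrichment_inputs` table.

    One generator drives the whole table in sorted (treatment, asv_id) order,
    so a fixed seed reproduces every estimate bit-for-bit.
    """
    c = constants or IsotopeConstants()
    rng = np.random.default_rng(seed)
    inputs = inputs.sort_values(["treatment", "asv_id"], kind="mergesort")
    rows = []
    for rec in inputs.itertuples(index=False):
        est = bootstrap_ape(rec.wad_light, rec.wad_labeled, c,
                            n_iter=n_iter, ci_level=ci_level, rng=rng)
        rows.append({
            "asv_id": rec.asv_id,
            "treatment": rec.treatment,
            **est,
            "n_reps_light": int(np.sum(~np.isnan(np.asarray(rec.wad_light, dtype=float)))),
            "n_reps_labeled": int(np.sum(~np.isnan(np.asarray(rec.wad_labeled, dtype=float)))),
        })
    return pd.DataFrame(rows, columns=["asv_id", "treatment", "ape_median", "ci_low",
                                       "ci_high", "n_boot", "active",
                                       "n_reps_light", "n_reps_labeled"])


def classify_active(ci_low: float) -> bool:
    """Active growth call: lower CI bound strictly greater than zero."""
    return bool(ci_low > 0)


def ape_ratio(ape_a: float, ape_b: float) -> float:
    """APE ratio between two conditions; > 1 means higher growth under a."""
    return ape_a / ape_b


def ratio_table(
    estimates: pd.DataFrame,
    treatment_a: str,
    treatment_b: str,
    comparison: str | None = None,
) -> pd.DataFrame:
    """Per-ASV APE ratios (a / b) for taxa active under both treatments."""
    comparison = comparison or f"{treatment_a}_vs_{treatment_b}"
    a = estimates[(estimates["treatment"] == treatment_a) & estimates["active"]]
    b = estimates[(estimates["treatment"] == treatment_b) & estimates["active"]]
    merged = a.merge(b, on="asv_id", suffixes=("_a", "_b"))
    out = pd.DataFrame({
        "asv_id": merged["asv_id"],
        "comparison": comparison,
        "ape_a": merged["ape_median_a"],
        "ape_b": merged["ape_median_b"],
    })
    out["ratio"] = out["ape_a"] / out["ape_b"]
    return out.sort_values("asv_id", kind="mergesort").reset_index(drop=True)


def top_phyla(counts: pd.DataFrame, taxonomy: pd.DataFrame, n: int = 10) -> list[str]:
    """The ``n`` most abundant phyla by total read count."""
    df = counts.merge(taxonomy[["asv_id", "phylum"]], on="asv_id", how="left")
    df["phylum"] = df["phylum"].fillna("unclassified")
    totals = df.groupby("phylum")["count"].sum().sort_values(ascending=False)
    return list(totals.index[:n])


def _wilcoxon_vs_one(ratios: np.ndarray) -> float:
    """Two-sided signed-rank p-value of ratios against 1; all-ties -> p = 1."""
    d = np.asarray(ratios, dtype=float) - 1.0
    d = d[d != 0.0]
    if d.size == 0:
        return 1.0
    return float(sps.wilcoxon(d, alternative="two-sided", method="auto").pvalue)


def phylum_ratio_test(
    ratios: pd.DataFrame,
    taxonomy: pd.DataFrame,
    phyla: list[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Phylum-level mean APE ratios with signed-rank tests and BH correction.

    Ratios are averaged unweighted over member ASVs.  The Wilcoxon
    signed-rank test (exact null distribution for small n without ties,
    normal approximation otherwise; zero differences dropped) asks whether
    the phylum's ratios differ from 1.  BH adjustment runs across the phyla
    of one comparison family; ``significant`` flags adjusted p < ``alpha``.
    """
    df = ratios.merge(taxonomy[["asv_id", "phylum"]], on="asv_id", how="left")
    df["phylum"] = df["phylum"].fillna("unclassified")
    if phyla is not None:
        df = df[df["phylum"].isin(phyla)]
    out_frames = []
    for comparison, sub in df.groupby("comparison"):
        rows = []
        for phylum, grp in sub.groupby("phylum"):
            r = grp["ratio"].to_numpy(dtype=float)
            rows.append({
                "phylum": phylum,
                "comparison": comparison,
                "mean_ratio": float(r.mean()),
                "se": float(r.std(ddof=1) / np.sqrt(r.size)) if r.size > 1 else np.nan,
                "n_asvs": int(r.size),
                "p_raw": _wilcoxon_vs_one(r),
            })
        res = pd.DataFrame(rows)
        if len(res):
            res["p_adj"] = multipletests(res["p_raw"].to_numpy(), method="fdr_bh")[1]
            res["significant"] = res["p_adj"] < alpha
        out_frames.append(res)
    cols = ["phylum", "comparison", "mean_ratio", "se", "n_asvs",
            "p_raw", "p_adj", "significant"]
    if not out_frames:
        return pd.DataFrame(columns=cols)
    return pd.concat(out_frames, ignore_index=True)[cols]


def treatment_median_ape(estimates: pd.DataFrame, active_only: bool = True) -> pd.DataFrame:
    """Median APE per treatment over retained (optionally active-only) ASVs."""
    df = estimates
    if active_only:
        df = df[df["active"]]
    rows = []
    for treatment, grp in df.groupby("treatment"):
        rows.append({
            "treatment": treatment,
            "median_ape": float(grp["ape_median"].median()) if len(grp) else np.nan,
            "n_asvs": int(len(grp)),
        })
    return pd.DataFrame(rows, columns=["treatment", "median_ape", "n_asvs"])
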
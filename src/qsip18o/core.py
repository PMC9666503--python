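"""Core qSIP model: buoyant density, GC baseline, 18O atom fraction excess, growth.

The quantitative stable isotope probing (qSIP) model infers taxon-specific
isotope incorporation from the shift in a taxon's DNA buoyant density between
tubes incubated with natural-abundance water (H2-16O) and heavy water
(H2-18O).  Density varies with GC content even without labeling, so each
taxon's unlabeled weighted-average density (WAD) serves as its own baseline:
WAD -> GC -> unlabeled molecular weight -> labeled molecular weight (from the
relative density shift) -> 18O atom fraction excess (AFE; x100 = atom percent
excess, APE).  Under the linear-growth assumption the excess translates into
the fraction of the DNA pool that is newly synthesized, and hence into an
absolute growth rate b = (N_total - N_light) / t in gene copies per gram soil
per day.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "IsotopeConstants",
    "GrowthEstimate",
    "fraction_absolute_abundance",
    "weighted_average_density",
    "gc_from_unlabeled_density",
    "unlabeled_density_from_gc",
    "molecular_weight_unlabeled",
    "atom_fraction_excess_18o",
    "labeled_density_for_afe",
    "growth_potential",
    "tube_taxon_profiles",
]


@dataclass(frozen=True)
class IsotopeConstants:
    """Calibration constants of the 18O qSIP density model.

    The GC-density line maps unlabeled buoyant density W (g/mL) to GC
    fraction G; the molecular-weight line maps G to the mean nucleotide
    molecular weight of unlabeled DNA.  ``delta_mw_max_18o`` is the maximum
    per-nucleotide mass gain at full 18O substitution, and
    ``natural_abundance_18o`` the background 18O atom fraction subtracted in
    excess calculations.

    ``atom_fraction_water_18o`` is the 18O atom fraction of the incubation
    water (0.7876 for this assay design); new DNA is assumed to be
    synthesized at that enrichment, so the saturating atom fraction excess is
    ``a_sat = atom_fraction_water_18o - natural_abundance_18o``.
    """

    gc_intercept: float = 1.646057        # g/mL at G = 0
    gc_slope: float = 0.083506            # g/mL per unit GC fraction
    mw_gc_slope: float = 0.496            # g/mol per unit GC fraction
    mw_intercept: float = 307.691         # g/mol at G = 0
    delta_mw_max_18o: float = 12.07747    # g/mol gained at 100% 18O
    natural_abundance_18o: float = 0.002000429
    atom_fraction_water_18o: float = 0.7876
    copies_per_cell: float = 6.0          # average 16S rRNA gene copies per cell
    t_days: float = 7.0                   # assay duration

    @property
    def a_sat(self) -> float:
        """Atom fraction excess of DNA synthesized entirely from assay water."""
        return self.atom_fraction_water_18o - self.natural_abundance_18o

    def with_overrides(self, **kwargs) -> "IsotopeConstants":
        return replace(self, **kwargs)


@dataclass
class GrowthEstimate:
    """Per (ASV, treatment) growth-potential estimate under linear growth."""

    asv_id: str
    treatment: str
    ape: float            # atom percent excess (percentage points)
    n_total: float        # 16S copies / g at end of assay
    n_light: float        # unlabeled copies / g
    b: float              # copies / g / day
    cells_b: float        # cells / g / day
    t: float = 7.0
    n_t0: float = field(default=np.nan)  # context only; not used in b


def fraction_absolute_abundance(counts, total_16s_copies: float) -> np.ndarray:
    """Scale one fraction's ASV read counts to absolute 16S copy numbers.

    copies_i = (count_i / sum(counts)) * total_16s_copies.  An all-zero count
    vector yields all-zero copies (empty-fraction convention).
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("read counts must be non-negative")
    if total_16s_copies < 0:
        raise ValueError("total 16S copy number must be non-negative")
    total_reads = counts.sum()
    if total_reads == 0:
        return np.zeros_like(counts)
    return counts / total_reads * total_16s_copies


def weighted_average_density(copies_per_fraction, densities) -> float:
    """Abundance-weighted mean buoyant density (WAD) of a taxon in one tube.

    Returns NaN when the taxon has zero copies across all sequenced fractions
    (WAD undefined: taxon absent from the tube).
    """
    copies = np.asarray(copies_per_fraction, dtype=float)
    dens = np.asarray(densities, dtype=float)
    if copies.shape != dens.shape:
        raise ValueError("copies and densities must be aligned")
    total = copies.sum()
    if total <= 0:
        return float("nan")
    return float(np.dot(dens, copies) / total)


def gc_from_unlabeled_density(w_light, constants: IsotopeConstants | None = None):
    """GC fraction from unlabeled WAD via the linear GC-density calibration."""
    c = constants or IsotopeConstants()
    g = (np.asarray(w_light, dtype=float) - c.gc_intercept) / c.gc_slope
    if np.any((g < 0) | (g > 1)):
        warnings.warn(
            "GC estimate outside [0, 1]; unlabeled WAD outside the calibrated range",
            stacklevel=2,
        )
    return g if g.ndim else float(g)


def unlabeled_density_from_gc(gc, constants: IsotopeConstants | None = None):
    """Inverse of :func:`gc_from_unlabeled_density` (used by the simulator)."""
    c = constants or IsotopeConstants()
    w = c.gc_intercept + c.gc_slope * np.asarray(gc, dtype=float)
    return w if w.ndim else float(w)


def molecular_weight_unlabeled(gc, constants: IsotopeConstants | None = None):
    """Mean nucleotide molecular weight of unlabeled DNA at GC fraction ``gc``."""
    c = constants or IsotopeConstants()
    m = c.mw_gc_slope * np.asarray(gc, dtype=float) + c.mw_intercept
    return m if m.ndim else float(m)


def atom_fraction_excess_18o(w_labeled, w_light, constants: IsotopeConstants | None = None):
    """18O atom fraction excess from the labeled/unlabeled density pair.

    M_light follows from the GC baseline; the labeled molecular weight scales
    with the relative density shift, M_lab = M_light * (W_labeled / W_light);
    the excess is (M_lab - M_light) / delta_mw_max * (1 - natural abundance).
    Negative values (noise) are retained.  Multiply by 100 for APE.
    """
    c = constants or IsotopeConstants()
    w_lab = np.asarray(w_labeled, dtype=float)
    w_li = np.asarray(w_light, dtype=float)
    g = (w_li - c.gc_intercept) / c.gc_slope
    m_light = c.mw_gc_slope * g + c.mw_intercept
    m_lab = m_light * (w_lab / w_li)
    a = (m_lab - m_light) / c.delta_mw_max_18o * (1.0 - c.natural_abundance_18o)
    return a if a.ndim else float(a)


def labeled_density_for_afe(afe, w_light, constants: IsotopeConstants | None = None):
    """Labeled WAD that produces atom fraction excess ``afe`` at baseline ``w_light``.

    Exact inverse of :func:`atom_fraction_excess_18o`; the simulator uses it
    to place labeled DNA bands.
    """
    c = constants or IsotopeConstants()
    a = np.asarray(afe, dtype=float)
    w_li = np.asarray(w_light, dtype=float)
    g = (w_li - c.gc_intercept) / c.gc_slope
    m_light = c.mw_gc_slope * g + c.mw_intercept
    m_lab = m_light + a * c.delta_mw_max_18o / (1.0 - c.natural_abundance_18o)
    w = w_li * m_lab / m_light
    return w if w.ndim else float(w)


def growth_potential(
    n_total_t7: float,
    afe: float,
    a_sat: float | None = None,
    t: float | None = None,
    copies_per_cell: float | None = None,
    *,
    asv_id: str = "",
    treatment: str = "",
    n_t0: float = np.nan,
    constants: IsotopeConstants | None = None,
) -> GrowthEstimate:
    """Absolute growth potential b = (N_total - N_light) / t under linear growth.

    The fraction of the DNA pool that is newly synthesized is
    p_new = afe / a_sat (new DNA carries the water's 18O enrichment), so
    N_light = N_total * (1 - p_new).  Negative excess propagates to negative
    b, un-clamped; significance screening is the CI filter's job.  Estimates
    with p_new > 1 (super-saturated, physically impossible) are retained with
    a warning.
    """
    c = constants or IsotopeConstants()
    a_sat = c.a_sat if a_sat is None else a_sat
    t = c.t_days if t is None else t
    copies_per_cell = c.copies_per_cell if copies_per_cell is None else copies_per_cell
    if t <= 0:
        raise ValueError("assay duration t must be positive")
    if a_sat <= 0:
        raise ValueError("saturating atom fraction excess must be positive")
    p_new = afe / a_sat
    if p_new > 1:
        warnings.warn(
            f"super-saturated estimate (p_new = {p_new:.3f} > 1) retained", stacklevel=2
        )
    n_light = n_total_t7 * (1.0 - p_new)
    b = (n_total_t7 - n_light) / t
    return GrowthEstimate(
        asv_id=asv_id,
        treatment=treatment,
        ape=100.0 * afe,
        n_total=n_total_t7,
        n_light=n_light,
        b=b,
        cells_b=b / copies_per_cell,
        t=t,
        n_t0=n_t0,
    )


def tube_taxon_profiles(counts: pd.DataFrame, fractions: pd.DataFrame) -> pd.DataFrame:
    """Per-(tube, ASV) weighted-average density and total copies.

    ``counts`` is the long ASV table (tube_id, fraction_index, asv_id, count);
    ``fractions`` the fraction table with density and qPCR totals.  Only
    sequenced fractions contribute.  Read counts are scaled to absolute
    copies within each fraction by the fraction's total 16S qPCR count, then
    aggregated per taxon: WAD = sum(density * copies) / sum(copies),
    n_total = sum(copies).

    Returns a DataFrame (tube_id, asv_id, wad, n_total); taxa absent from a
    tube simply do not appear.
    """
    seq = fractions.loc[fractions["sequenced"].astype(bool),
                        ["tube_id", "fraction_index", "density_g_ml", "total_16s_copies"]]
    df = counts.merge(seq, on=["tube_id", "fraction_index"], how="inner")
    frac_reads = df.groupby(["tube_id", "fraction_index"])["count"].transform("sum")
    with np.errstate(invalid="ignore"):
        share = np.where(frac_reads > 0, df["count"] / frac_reads, 0.0)
    df = df.assign(copies=share * df["total_16s_copies"])
    df["wx"] = df["copies"] * df["density_g_ml"]
    agg = df.groupby(["tube_id", "asv_id"], as_index=False, sort=True).agg(
        n_total=("copies", "sum"), wx=("wx", "sum")
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        agg["wad"] = np.where(agg["n_total"] > 0, agg["wx"] / agg["n_total"], np.nan)
    return agg.loc[agg["n_total"] > 0, ["tube_id", "asv_id", "wad", "n_total"]].reset_index(drop=True)
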
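"""Experiment data model, input readers/validators, and result writers.

The experiment is carried as an :class:`ExperimentBundle` of five flat
tables:

``fractions``
    one row per gradient fraction of one ultracentrifuge tube
    (tube_id, fraction_index, density_g_ml, dna_conc_ng_ul,
    total_16s_copies, sequenced).
``samples``
    tube metadata (tube_id, microcosm_id, fungal, moisture, isotope,
    timepoint, replicate).
``counts``
    long ASV read-count table (tube_id, fraction_index, asv_id, count).
``taxonomy``
    lineage per ASV (asv_id, domain..genus).
``co2``
    CO2 efflux per (fungal, moisture, replicate).

Fraction 1 is the densest fraction (collected first from the tube bottom);
the ``density_orientation`` config flag can flip this.  The ``sequenced``
flag defaults to dna_conc > cutoff (1.0 ng/uL) where not given explicitly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

FUNGAL_LEVELS = ("uninoculated", "R_irregularis", "S_bescii")
MOISTURE_LEVELS = ("replete", "limited")
ISOTOPE_LEVELS = ("16O", "18O")
TIMEPOINT_LEVELS = ("T0", "T7")

TAXONOMY_RANKS = ("domain", "phylum", "class", "order", "family", "genus")

_FRACTION_COLS = ["tube_id", "fraction_index", "density_g_ml",
                  "dna_conc_ng_ul", "total_16s_copies", "sequenced"]
_SAMPLE_COLS = ["tube_id", "microcosm_id", "fungal", "moisture",
                "isotope", "timepoint", "replicate"]
_COUNT_COLS = ["tube_id", "fraction_index", "asv_id", "count"]
_CO2_COLS = ["fungal", "moisture", "replicate", "co2_efflux"]

DENSITY_RANGE = (1.55, 1.85)


class SchemaError(ValueError):
    """An input table is missing a required column or has an invalid value."""


class ReferentialError(ValueError):
    """Cross-table reference broken (e.g. counts for a tube absent from metadata)."""


def treatment_label(fungal: str, moisture: str) -> str:
    return f"{fungal}|{moisture}"


@dataclass
class ExperimentBundle:
    """Validated container for one qSIP experiment."""

    fractions: pd.DataFrame
    samples: pd.DataFrame
    counts: pd.DataFrame
    taxonomy: pd.DataFrame
    co2: pd.DataFrame | None = None
    config: dict = field(default_factory=dict)

    @property
    def tube_ids(self) -> list[str]:
        return sorted(self.samples["tube_id"].unique())

    def treatments(self) -> list[str]:
        s = self.samples
        return sorted({treatment_label(f, m) for f, m in zip(s["fungal"], s["moisture"])})

    def tubes_for(self, fungal=None, moisture=None, isotope=None, timepoint=None) -> pd.DataFrame:
        s = self.samples
        mask = pd.Series(True, index=s.index)
        for col, val in (("fungal", fungal), ("moisture", moisture),
                         ("isotope", isotope), ("timepoint", timepoint)):
            if val is not None:
                mask &= s[col] == val
        return s.loc[mask]

    def validate(self) -> "ExperimentBundle":
        _require_cols(self.fractions, _FRACTION_COLS, "fractions")
        _require_cols(self.samples, _SAMPLE_COLS, "samples")
        _require_cols(self.counts, _COUNT_COLS, "counts")
        _require_cols(self.taxonomy, ["asv_id"], "taxonomy")

        fr = self.fractions
        lo, hi = DENSITY_RANGE
        bad = fr[(fr["density_g_ml"] < lo) | (fr["density_g_ml"] > hi)]
        if len(bad):
            raise SchemaError(
                f"fraction densities outside [{lo}, {hi}] g/mL for tubes "
                f"{sorted(bad['tube_id'].unique())}"
            )
        dup = fr.duplicated(["tube_id", "fraction_index"])
        if dup.any():
            raise SchemaError("duplicate (tube_id, fraction_index) in fractions table")
        if (self.counts["count"] < 0).any():
            raise SchemaError("negative read counts")

        meta_tubes = set(self.samples["tube_id"])
        for name, df in (("fractions", fr), ("counts", self.counts)):
            orphans = set(df["tube_id"]) - meta_tubes
            if orphans:
                raise ReferentialError(f"tubes in {name} absent from samples: {sorted(orphans)}")

        # counts may exist only for sequenced fractions
        seq_keys = set(map(tuple, fr.loc[fr["sequenced"].astype(bool),
                                         ["tube_id", "fraction_index"]].itertuples(index=False)))
        count_keys = set(map(tuple, self.counts[["tube_id", "fraction_index"]]
                             .drop_duplicates().itertuples(index=False)))
        stray = count_keys - seq_keys
        if stray:
            tube, frac = sorted(stray)[0]
            raise ReferentialError(
                f"ASV counts present for unsequenced fraction (tube {tube}, fraction {frac})"
            )

        known_asvs = set(self.taxonomy["asv_id"])
        missing_tax = set(self.counts["asv_id"]) - known_asvs
        if missing_tax:
            raise ReferentialError(f"ASVs without taxonomy: {sorted(missing_tax)[:5]} ...")

        # every labeled T7 tube needs an unlabeled T7 partner in its treatment
        s = self.samples
        t7 = s[s["timepoint"] == "T7"]
        for (f, m), grp in t7.groupby(["fungal", "moisture"]):
            if "18O" in set(grp["isotope"]) and "16O" not in set(grp["isotope"]):
                raise ReferentialError(
                    f"treatment {treatment_label(f, m)} has labeled tubes but no "
                    "unlabeled T7 tubes"
                )
        # density monotone within tube (in fraction order) — warn and sort only
        for tube, grp in fr.groupby("tube_id"):
            d = grp.sort_values("fraction_index")["density_g_ml"].to_numpy()
            if len(d) > 1 and not (np.all(np.diff(d) <= 0) or np.all(np.diff(d) >= 0)):
                warnings.warn(f"non-monotone densities within tube {tube}; check orientation",
                              stacklevel=2)
        return self


def _require_cols(df: pd.DataFrame, cols, table: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"table '{table}' is missing column(s): {missing}")


def _read_table(path: Path) -> pd.DataFrame:
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep)


def read_biom_v1(path: Path) -> pd.DataFrame:
    """Read a BIOM v1 (JSON) table into long (sample_id, asv_id, count) form.

    Sample ids are expected as ``{tube_id}:{fraction_index}``.
    """
    with open(path) as fh:
        doc = json.load(fh)
    obs_ids = [o["id"] for o in doc["rows"]]
    sample_ids = [s["id"] for s in doc["columns"]]
    rows = []
    if doc.get("matrix_type") == "sparse":
        for i, j, v in doc["data"]:
            rows.append((sample_ids[j], obs_ids[i], v))
    else:
        for i, row in enumerate(doc["data"]):
            for j, v in enumerate(row):
                if v:
                    rows.append((sample_ids[j], obs_ids[i], v))
    df = pd.DataFrame(rows, columns=["sample", "asv_id", "count"])
    split = df["sample"].str.rsplit(":", n=1, expand=True)
    df["tube_id"] = split[0]
    df["fraction_index"] = split[1].astype(int)
    return df[["tube_id", "fraction_index", "asv_id", "count"]]


def read_experiment(paths: dict, config: dict | None = None) -> ExperimentBundle:
    """Read and validate the experiment tables.

    ``paths`` maps table names (fractions, samples, counts, taxonomy, co2) to
    delimited-text files (TSV default, CSV by extension); counts may instead
    be a BIOM v1 JSON file (``.biom``).  ``config`` keys: ``cutoff_ng_ul``
    (default 1.0), ``density_orientation`` ("heavy_first" default or
    "light_first"), ``copies_basis`` (recorded string).
    """
    config = dict(config or {})
    cutoff = float(config.setdefault("cutoff_ng_ul", 1.0))
    config.setdefault("density_orientation", "heavy_first")
    config.setdefault("copies_basis", "copies per g dry soil per fraction")

    fractions = _read_table(Path(paths["fractions"]))
    samples = _read_table(Path(paths["samples"]))
    taxonomy = _read_table(Path(paths["taxonomy"]))
    counts_path = Path(paths["counts"])
    counts = (read_biom_v1(counts_path) if counts_path.suffix == ".biom"
              else _read_table(counts_path))
    co2 = _read_table(Path(paths["co2"])) if "co2" in paths and paths["co2"] else None

    if "sequenced" not in fractions.columns:
        if "dna_conc_ng_ul" not in fractions.columns:
            raise SchemaError("fractions table needs 'sequenced' or 'dna_conc_ng_ul'")
        fractions["sequenced"] = fractions["dna_conc_ng_ul"] > cutoff
    else:
        fractions["sequenced"] = fractions["sequenced"].astype(bool)
    if "dna_conc_ng_ul" not in fractions.columns:
        fractions["dna_conc_ng_ul"] = np.nan

    if config["density_orientation"] == "light_first":
        # renumber so index 1 is densest, the pipeline-internal convention;
        # counts reference fraction_index and must be renumbered in step
        fractions = fractions.copy()
        n_by_tube = fractions.groupby("tube_id")["fraction_index"].max()
        fmax = fractions["tube_id"].map(n_by_tube)
        fractions["fraction_index"] = fmax - fractions["fraction_index"] + 1
        counts = counts.copy()
        counts["fraction_index"] = (counts["tube_id"].map(n_by_tube)
                                    - counts["fraction_index"] + 1)

    bundle = ExperimentBundle(fractions=fractions, samples=samples, counts=counts,
                              taxonomy=taxonomy, co2=co2, config=config)
    return bundle.validate()


# ---------------------------------------------------------------------------
# writers

INPUT_FILES = {
    "fractions": "fractions.tsv",
    "samples": "samples.tsv",
    "counts": "counts.tsv",
    "taxonomy": "taxonomy.tsv",
    "co2": "co2.tsv",
}

RESULT_COLUMN_ORDER = {
    "enrichment": ["asv_id", "treatment", "ape_median", "ci_low", "ci_high",
                   "n_boot", "active", "n_reps_light", "n_reps_labeled"],
    "growth": ["asv_id", "treatment", "ape", "n_total", "n_light", "b",
               "cells_b", "t", "n_t0"],
    "ratios_asv": ["asv_id", "comparison", "ape_a", "ape_b", "ratio"],
    "ratios_phylum": ["phylum", "comparison", "mean_ratio", "se", "n_asvs",
                      "p_raw", "p_adj", "significant"],
    "diversity": ["tube_id", "treatment", "mode", "richness", "inverse_simpson"],
    "growth_by_phylum": ["phylum", "treatment", "gross_growth", "n_asvs"],
    "efficiency": ["treatment", "gross_growth", "co2_efflux", "efficiency", "unit"],
    "truth": None,
}


def write_results(tables: dict[str, pd.DataFrame], out_dir) -> pd.DataFrame:
    """Write result tables as TSV with deterministic column order.

    Returns the manifest DataFrame (file, rows) and writes it as
    ``manifest.tsv`` alongside the tables.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = []
    for name, df in tables.items():
        order = RESULT_COLUMN_ORDER.get(name)
        if order is not None:
            cols = [c for c in order if c in df.columns]
            cols += [c for c in df.columns if c not in cols]
            df = df[cols]
        path = out / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False, float_format="%.12g")
        records.append({"file": path.name, "rows": len(df)})
    manifest = pd.DataFrame(records, columns=["file", "rows"])
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    return manifest


def write_input_files(bundle: ExperimentBundle, out_dir) -> dict[str, Path]:
    """Write a bundle back out as the five canonical input files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    tables = {
        "fractions": bundle.fractions,
        "samples": bundle.samples,
        "counts": bundle.counts,
        "taxonomy": bundle.taxonomy,
    }
    if bundle.co2 is not None:
        tables["co2"] = bundle.co2
    for name, df in tables.items():
        p = out / INPUT_FILES[name]
        df.to_csv(p, sep="\t", index=False, float_format="%.12g")
        paths[name] = p
    return paths
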
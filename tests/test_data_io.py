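"""Input validation, round-trip I/O, and result-writing tests."""

import json

import numpy as np
import pandas as pd
import pytest

from qsip18o.data_io import (
    ExperimentBundle,
    ReferentialError,
    SchemaError,
    read_biom_v1,
    read_experiment,
    write_input_files,
    write_results,
)


def _roundtrip(bundle, tmp_path, config=None):
    write_input_files(bundle, tmp_path)
    paths = {name: tmp_path / f"{name}.tsv"
             for name in ("fractions", "samples", "counts", "taxonomy", "co2")}
    return read_experiment(paths, config)


class TestReadExperiment:
    def test_identity_roundtrip(self, minimal_bundle, tmp_path):
        back = _roundtrip(minimal_bundle, tmp_path)
        assert sorted(back.tube_ids) == sorted(minimal_bundle.tube_ids)
        assert len(back.fractions) == 6
        pd.testing.assert_frame_equal(
            back.counts.sort_values(["tube_id", "fraction_index", "asv_id"],
                                    ignore_index=True),
            minimal_bundle.counts.sort_values(["tube_id", "fraction_index", "asv_id"],
                                              ignore_index=True),
            check_dtype=False)

    def test_counts_on_unsequenced_fraction_rejected(self, minimal_bundle, tmp_path):
        bad = minimal_bundle
        bad.fractions.loc[
            (bad.fractions.tube_id == "tubeA.16O") & (bad.fractions.fraction_index == 2),
            "sequenced"] = False
        write_input_files(bad, tmp_path)
        paths = {n: tmp_path / f"{n}.tsv"
                 for n in ("fractions", "samples", "counts", "taxonomy", "co2")}
        with pytest.raises(ReferentialError, match="tubeA.16O.*2"):
            read_experiment(paths)

    def test_missing_column_names_the_column(self, minimal_bundle, tmp_path):
        write_input_files(minimal_bundle, tmp_path)
        df = pd.read_csv(tmp_path / "fractions.tsv", sep="\t")
        df.drop(columns=["density_g_ml"]).to_csv(tmp_path / "fractions.tsv",
                                                 sep="\t", index=False)
        paths = {n: tmp_path / f"{n}.tsv"
                 for n in ("fractions", "samples", "counts", "taxonomy", "co2")}
        with pytest.raises(SchemaError, match="density_g_ml"):
            read_experiment(paths)

    def test_tube_missing_from_meta_is_referential_error(self, minimal_bundle, tmp_path):
        write_input_files(minimal_bundle, tmp_path)
        df = pd.read_csv(tmp_path / "samples.tsv", sep="\t")
        df[df.tube_id != "tubeB.18O"].to_csv(tmp_path / "samples.tsv", sep="\t", index=False)
        paths = {n: tmp_path / f"{n}.tsv"
                 for n in ("fractions", "samples", "counts", "taxonomy", "co2")}
        with pytest.raises(ReferentialError, match="tubeB.18O"):
            read_experiment(paths)

    def test_cutoff_derives_sequenced_flag(self, minimal_bundle, tmp_path):
        # drop the stored flag and one fraction's counts; set that fraction's
        # concentration below the cutoff -> flag must be derived per fraction
        low = (minimal_bundle.fractions.tube_id == "tubeA.16O") & \
              (minimal_bundle.fractions.fraction_index == 3)
        minimal_bundle.fractions.loc[low, "dna_conc_ng_ul"] = 0.5
        c = minimal_bundle.counts
        minimal_bundle.counts = c[~((c.tube_id == "tubeA.16O") &
                                    (c.fraction_index == 3))]
        write_input_files(minimal_bundle, tmp_path)
        df = pd.read_csv(tmp_path / "fractions.tsv", sep="\t").drop(columns=["sequenced"])
        df.to_csv(tmp_path / "fractions.tsv", sep="\t", index=False)
        paths = {n: tmp_path / f"{n}.tsv"
                 for n in ("fractions", "samples", "counts", "taxonomy", "co2")}
        bundle = read_experiment(paths, {"cutoff_ng_ul": 1.0})
        seq = bundle.fractions.set_index(["tube_id", "fraction_index"])["sequenced"]
        assert not seq.loc[("tubeA.16O", 3)]
        assert seq.drop(("tubeA.16O", 3)).all()

    def test_orientation_flip_renumbers_fractions(self, minimal_bundle, tmp_path):
        write_input_files(minimal_bundle, tmp_path)
        # rewrite fractions in light-first numbering (fraction 1 = lightest)
        df = pd.read_csv(tmp_path / "fractions.tsv", sep="\t")
        fmax = df.groupby("tube_id")["fraction_index"].transform("max")
        df["fraction_index"] = fmax - df["fraction_index"] + 1
        df.to_csv(tmp_path / "fractions.tsv", sep="\t", index=False)
        cdf = pd.read_csv(tmp_path / "counts.tsv", sep="\t")
        cmax = cdf.groupby("tube_id")["fraction_index"].transform("max")
        cdf["fraction_index"] = 3 - cdf["fraction_index"] + 1
        cdf.to_csv(tmp_path / "counts.tsv", sep="\t", index=False)
        paths = {n: tmp_path / f"{n}.tsv"
                 for n in ("fractions", "samples", "counts", "taxonomy", "co2")}
        back = read_experiment(paths, {"density_orientation": "light_first"})
        # internally fraction 1 must end up densest after renumbering
        for tube, grp in back.fractions.groupby("tube_id"):
            ordered = grp.sort_values("fraction_index")["density_g_ml"].to_numpy()
            assert ordered[0] == grp["density_g_ml"].max()

    def test_density_out_of_physical_range_rejected(self, minimal_bundle, tmp_path):
        minimal_bundle.fractions.loc[0, "density_g_ml"] = 1.95
        write_input_files(minimal_bundle, tmp_path)
        paths = {n: tmp_path / f"{n}.tsv"
                 for n in ("fractions", "samples", "counts", "taxonomy", "co2")}
        with pytest.raises(SchemaError, match="densities"):
            read_experiment(paths)

    def test_default_synthetic_experiment_is_54_tubes(self, tiny_experiment):
        bundle, _ = tiny_experiment
        assert len(bundle.tube_ids) == 54


class TestBiomReader:
    def test_sparse_biom_v1(self, tmp_path):
        doc = {
            "id": "x", "format": "Biological Observation Matrix 1.0.0",
            "matrix_type": "sparse", "shape": [2, 2],
            "rows": [{"id": "ASV1", "metadata": None}, {"id": "ASV2", "metadata": None}],
            "columns": [{"id": "tubeA:1", "metadata": None},
                        {"id": "tubeA:2", "metadata": None}],
            "data": [[0, 0, 5], [1, 1, 7]],
        }
        p = tmp_path / "c.biom"
        p.write_text(json.dumps(doc))
        df = read_biom_v1(p)
        assert len(df) == 2
        row = df[df.asv_id == "ASV2"].iloc[0]
        assert row.tube_id == "tubeA" and row.fraction_index == 2 and row["count"] == 7


class TestWriteResults:
    def test_empty_table_header_only(self, tmp_path):
        manifest = write_results(
            {"enrichment": pd.DataFrame(columns=["asv_id", "treatment", "ape_median"])},
            tmp_path)
        assert manifest.loc[0, "rows"] == 0
        lines = (tmp_path / "enrichment.tsv").read_text().strip().splitlines()
        assert len(lines) == 1

    def test_row_counts_in_manifest(self, tmp_path):
        df = pd.DataFrame({"asv_id": list("abc"), "treatment": "t",
                           "ape_median": [1.0, 2.0, 3.0]})
        manifest = write_results({"enrichment": df}, tmp_path)
        assert manifest.loc[0, "rows"] == 3

    def test_numeric_roundtrip_12_significant_digits(self, tmp_path):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({
            "asv_id": [f"a{i}" for i in range(20)],
            "treatment": "t",
            "ape_median": rng.uniform(-5, 60, 20),
            "ci_low": rng.uniform(-10, 0, 20),
            "ci_high": rng.uniform(0, 70, 20),
        })
        write_results({"enrichment": df}, tmp_path)
        back = pd.read_csv(tmp_path / "enrichment.tsv", sep="\t")
        for col in ("ape_median", "ci_low", "ci_high"):
            np.testing.assert_allclose(back[col], df[col], rtol=1e-11)
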
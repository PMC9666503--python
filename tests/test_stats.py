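"""Bootstrap, activity classification, ratio and phylum-test behavior."""

from itertools import product

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qsip18o.core import IsotopeConstants, atom_fraction_excess_18o
from qsip18o.stats import (
    ape_ratio,
    bootstrap_ape,
    bootstrap_ape_table,
    classify_active,
    filter_replicate_presence,
    phylum_ratio_test,
    ratio_table,
    top_phyla,
    treatment_median_ape,
)

C = IsotopeConstants()


class TestReplicateFilter:
    def _bundle_with_occupancy(self, occupancy):
        """Build a minimal 3-replicate bundle; occupancy[asv] = replicates present."""
        from qsip18o.data_io import ExperimentBundle
        fr_rows, cn_rows, meta = [], [], []
        for rep in (1, 2, 3):
            for iso in ("16O", "18O"):
                tube = f"T{rep}.{iso}"
                meta.append({"tube_id": tube, "microcosm_id": f"m{rep}",
                             "fungal": "uninoculated", "moisture": "replete",
                             "isotope": iso, "timepoint": "T7", "replicate": rep})
                fr_rows.append({"tube_id": tube, "fraction_index": 1,
                                "density_g_ml": 1.70, "dna_conc_ng_ul": 5.0,
                                "total_16s_copies": 1e6, "sequenced": True})
                for asv, reps in occupancy.items():
                    if rep in reps and iso == "16O":
                        cn_rows.append({"tube_id": tube, "fraction_index": 1,
                                        "asv_id": asv, "count": 3})
        tax = pd.DataFrame({"asv_id": list(occupancy), "phylum": "P"})
        return ExperimentBundle(
            fractions=pd.DataFrame(fr_rows), samples=pd.DataFrame(meta),
            counts=pd.DataFrame(cn_rows), taxonomy=tax).validate()

    def test_full_presence_kept_partial_dropped(self):
        bundle = self._bundle_with_occupancy({"a": {1, 2, 3}, "b": {1, 2}, "c": {2}})
        wl = filter_replicate_presence(bundle)
        assert set(wl["asv_id"]) == {"a"}

    def test_matches_brute_force_set_intersection(self, tiny_experiment):
        bundle, _ = tiny_experiment
        wl = filter_replicate_presence(bundle)
        s = bundle.samples
        t7 = s[s.timepoint == "T7"]
        for (f, m), grp in t7.groupby(["fungal", "moisture"]):
            sets = []
            for rep in sorted(grp.replicate.unique()):
                tubes = set(grp.loc[grp.replicate == rep, "tube_id"])
                c = bundle.counts
                sets.append(set(c.loc[c.tube_id.isin(tubes) & (c["count"] > 0), "asv_id"]))
            expected = set.intersection(*sets)
            got = set(wl.loc[wl.treatment == f"{f}|{m}", "asv_id"])
            assert got == expected


class TestBootstrap:
    def test_degenerate_replicates_zero_width_ci(self):
        rng = np.random.default_rng(0)
        est = bootstrap_ape([1.70] * 3, [1.705] * 3, C, n_iter=500, rng=rng)
        assert est["ci_low"] == est["ape_median"] == est["ci_high"]
        assert est["ape_median"] == pytest.approx(7.48586977411204, rel=1e-9)

    def test_deterministic_under_seed(self):
        light, lab = [1.700, 1.7005, 1.6995], [1.704, 1.706, 1.705]
        a = bootstrap_ape(light, lab, C, rng=np.random.default_rng(7))
        b = bootstrap_ape(light, lab, C, rng=np.random.default_rng(7))
        assert a == b

    def test_defaults_carry_through(self):
        inputs = pd.DataFrame([{
            "treatment": "t", "asv_id": "a",
            "wad_light": [1.700, 1.7005, 1.6995],
            "wad_labeled": [1.704, 1.706, 1.705],
            "n_total": [1e6] * 3, "n_t0": [],
        }])
        out = bootstrap_ape_table(inputs, C, seed=1)
        row = out.iloc[0]
        assert row.n_boot == 1000
        assert row.ci_low <= row.ape_median <= row.ci_high

    def test_matches_exhaustive_enumeration(self):
        """For 3+3 replicates the bootstrap distribution has 27x27 equally
        likely atoms; large-n bootstrap percentiles must match enumeration."""
        light = np.array([1.6995, 1.7002, 1.7010])
        lab = np.array([1.7035, 1.7048, 1.7060])
        idx = np.array(list(product(range(3), repeat=3)))
        lm = light[idx].mean(axis=1)
        bm = lab[idx].mean(axis=1)
        atoms = 100.0 * np.array([
            atom_fraction_excess_18o(b, l) for l in lm for b in bm])
        lo_exact, hi_exact = np.percentile(atoms, [5, 95])
        est = bootstrap_ape(light, lab, C, n_iter=100_000,
                            rng=np.random.default_rng(12))
        assert est["ci_low"] == pytest.approx(lo_exact, abs=0.1)
        assert est["ci_high"] == pytest.approx(hi_exact, abs=0.1)
        assert est["ape_median"] == pytest.approx(np.median(atoms), abs=0.1)


class TestActivityAndRatios:
    def test_strict_boundary(self):
        assert classify_active(0.5)
        assert not classify_active(0.0)
        assert not classify_active(-0.1)

    @pytest.mark.parametrize("a,b,expected", [(6.0, 3.0, 2.0), (4.2, 4.2, 1.0)])
    def test_ratio_values(self, a, b, expected):
        assert ape_ratio(a, b) == pytest.approx(expected)

    @given(st.floats(0.5, 60), st.floats(0.5, 60))
    @settings(max_examples=40, deadline=None)
    def test_ratio_antisymmetry(self, a, b):
        assert ape_ratio(a, b) * ape_ratio(b, a) == pytest.approx(1.0, rel=1e-12)

    def test_ratio_table_active_only_element_wise(self):
        est = pd.DataFrame({
            "asv_id": ["a", "b", "c", "a", "b", "c"],
            "treatment": ["x"] * 3 + ["y"] * 3,
            "ape_median": [6.0, 10.0, 3.0, 3.0, 5.0, 2.0],
            "ci_low": [1, 1, -1, 1, 1, 1],
            "ci_high": [9, 12, 5, 5, 7, 4],
            "active": [True, True, False, True, True, True],
        })
        r = ratio_table(est, "x", "y")
        assert list(r.asv_id) == ["a", "b"]  # c inactive under x
        np.testing.assert_allclose(r.ratio, [2.0, 2.0])


class TestPhylumRatioTest:
    def _ratios(self, values, phylum="P"):
        return pd.DataFrame({
            "asv_id": [f"a{i}" for i in range(len(values))],
            "comparison": "cmp", "ape_a": 1.0, "ape_b": 1.0,
            "ratio": values,
        })

    def _tax(self, n, phylum="P"):
        return pd.DataFrame({"asv_id": [f"a{i}" for i in range(n)], "phylum": phylum})

    def test_all_ratios_one_gives_p_one(self):
        res = phylum_ratio_test(self._ratios([1.0] * 6), self._tax(6))
        assert res.iloc[0].p_raw == 1.0
        assert not res.iloc[0].significant

    def test_exact_two_sided_p_for_five_same_sign(self):
        # all 5 ratios above 1 -> extreme signed-rank statistic; exact
        # two-sided p = 2 * (1/2^5) = 0.0625
        res = phylum_ratio_test(self._ratios([1.2, 1.5, 1.3, 2.0, 1.1]), self._tax(5))
        assert res.iloc[0].p_raw == pytest.approx(0.0625, abs=1e-12)

    def test_mean_and_se_unweighted(self):
        vals = [2.0, 4.0]
        res = phylum_ratio_test(self._ratios(vals), self._tax(2))
        assert res.iloc[0].mean_ratio == pytest.approx(3.0)
        assert res.iloc[0].se == pytest.approx(np.std(vals, ddof=1) / np.sqrt(2))

    @given(st.lists(st.floats(0.2, 5.0), min_size=4, max_size=8, unique=True),
           st.lists(st.floats(0.2, 5.0), min_size=4, max_size=8, unique=True))
    @settings(max_examples=25, deadline=None)
    def test_bh_adjustment_monotone_and_above_raw(self, r1, r2):
        ratios = pd.concat([
            self._ratios(r1).assign(asv_id=[f"x{i}" for i in range(len(r1))]),
            self._ratios(r2).assign(asv_id=[f"y{i}" for i in range(len(r2))]),
        ], ignore_index=True)
        tax = pd.DataFrame({
            "asv_id": [f"x{i}" for i in range(len(r1))] + [f"y{i}" for i in range(len(r2))],
            "phylum": ["P1"] * len(r1) + ["P2"] * len(r2),
        })
        res = phylum_ratio_test(ratios, tax)
        assert (res.p_adj >= res.p_raw - 1e-15).all()
        srt = res.sort_values("p_raw")
        assert srt.p_adj.is_monotonic_increasing


class TestTreatmentMedian:
    def test_single_and_odd_median(self):
        est = pd.DataFrame({
            "asv_id": list("abc"), "treatment": "t",
            "ape_median": [2.0, 6.0, 10.0], "ci_low": [1, 1, 1],
            "ci_high": [3, 7, 11], "active": True,
        })
        out = treatment_median_ape(est)
        assert out.iloc[0].median_ape == pytest.approx(6.0)
        one = treatment_median_ape(est.iloc[[1]])
        assert one.iloc[0].median_ape == pytest.approx(6.0)

    def test_known_distribution_matches_sorting_oracle(self):
        rng = np.random.default_rng(3)
        apes = rng.uniform(0, 30, 21)
        est = pd.DataFrame({
            "asv_id": [f"a{i}" for i in range(21)], "treatment": "t",
            "ape_median": apes, "ci_low": 0.5, "ci_high": 40.0, "active": True,
        })
        out = treatment_median_ape(est)
        assert out.iloc[0].median_ape == pytest.approx(sorted(apes)[10])


def test_top_phyla_by_read_count():
    counts = pd.DataFrame({
        "tube_id": "T", "fraction_index": 1,
        "asv_id": ["a", "b", "c"], "count": [100, 10, 1],
    })
    tax = pd.DataFrame({"asv_id": ["a", "b", "c"], "phylum": ["X", "Y", "Z"]})
    assert top_phyla(counts, tax, n=2) == ["X", "Y"]
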
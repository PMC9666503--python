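import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from qsip18o.core import IsotopeConstants
from qsip18o.data_io import ExperimentBundle, treatment_label
from qsip18o.simulate import DesignConfig, GradientConfig, generate_experiment


@pytest.fixture(scope="session")
def constants():
    return IsotopeConstants()


def _minimal_bundle():
    """Two T7 tubes (16O + 18O), one treatment, 3 sequenced fractions each."""
    fractions = []
    counts = []
    for tube, dens in (("tubeA.16O", (1.72, 1.70, 1.68)),
                       ("tubeB.18O", (1.72, 1.70, 1.68))):
        for i, d in enumerate(dens, start=1):
            fractions.append({"tube_id": tube, "fraction_index": i,
                              "density_g_ml": d, "dna_conc_ng_ul": 5.0,
                              "total_16s_copies": 1e6, "sequenced": True})
            counts.append({"tube_id": tube, "fraction_index": i,
                           "asv_id": "ASV00001", "count": 10 * i})
            counts.append({"tube_id": tube, "fraction_index": i,
                           "asv_id": "ASV00002", "count": 5})
    samples = pd.DataFrame([
        {"tube_id": "tubeA.16O", "microcosm_id": "m1", "fungal": "uninoculated",
         "moisture": "replete", "isotope": "16O", "timepoint": "T7", "replicate": 1},
        {"tube_id": "tubeB.18O", "microcosm_id": "m1", "fungal": "uninoculated",
         "moisture": "replete", "isotope": "18O", "timepoint": "T7", "replicate": 1},
    ])
    taxonomy = pd.DataFrame({
        "asv_id": ["ASV00001", "ASV00002"],
        "domain": "Bacteria",
        "phylum": ["Actinobacteria", "Proteobacteria"],
        "class": ["c1", "c2"], "order": ["o1", "o2"],
        "family": ["f1", "f2"], "genus": ["g1", "g2"],
    })
    co2 = pd.DataFrame([{"fungal": "uninoculated", "moisture": "replete",
                         "replicate": 1, "co2_efflux": 6.0}])
    return ExperimentBundle(
        fractions=pd.DataFrame(fractions), samples=samples,
        counts=pd.DataFrame(counts), taxonomy=taxonomy, co2=co2,
        config={"cutoff_ng_ul": 1.0, "density_orientation": "heavy_first",
                "copies_basis": "copies per g dry soil per fraction"},
    ).validate()


@pytest.fixture()
def minimal_bundle():
    return _minimal_bundle()


@pytest.fixture(scope="session")
def tiny_experiment():
    """Small but complete simulated experiment (all 6 treatments, 54 tubes)."""
    design = DesignConfig(n_taxa=40)
    return generate_experiment(design, seed=11)


def single_treatment_design(n_taxa=300, frac_active=0.4, seed=None):
    tr = treatment_label("uninoculated", "replete")
    return DesignConfig(
        n_taxa=n_taxa, frac_active=frac_active,
        fungal_levels=("uninoculated",), moisture_levels=("replete",),
        ape_scale={tr: 1.0}, co2_means={tr: 6.0},
    )


@pytest.fixture(scope="session")
def noise_free_gradient():
    return GradientConfig(noise=False, conc_cutoff=0.0)


def manual_truth(apes, gcs, treatment=treatment_label("uninoculated", "replete"),
                 n_replicates=1):
    """Hand-built simulation truth with prescribed per-taxon APE and GC."""
    from qsip18o.core import unlabeled_density_from_gc
    from qsip18o.simulate import SimulationTruth

    n = len(apes)
    asv_ids = [f"ASV{i + 1:05d}" for i in range(n)]
    taxa = pd.DataFrame({
        "asv_id": asv_ids, "gc": gcs,
        "w_light": [unlabeled_density_from_gc(g) for g in gcs],
        "domain": "Bacteria", "phylum": "Proteobacteria", "class": "c",
        "order": "o", "family": "f", "genus": "g",
    })
    ape = pd.DataFrame({"asv_id": asv_ids, "treatment": treatment,
                        "true_ape": apes, "active": [a > 0 for a in apes]})
    ab = pd.DataFrame({"asv_id": asv_ids, "treatment": treatment,
                       "rel_abundance": 1.0 / n})
    reps = pd.concat([
        pd.DataFrame({"asv_id": asv_ids, "treatment": treatment,
                      "replicate": r, "multiplier": 1.0})
        for r in range(1, n_replicates + 1)], ignore_index=True)
    return SimulationTruth(taxa=taxa, ape=ape, abundance=ab, rep_effects=reps)
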
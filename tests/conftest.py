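import numpy as np
import pytest

from dischargedx.cohort import Cohort, Hospitalization, zscore_panels
from dischargedx.icd import ICDHierarchy, ICDSimilarityMatrix, parse_icd
from dischargedx.model import icd_similarity_pair
from dischargedx.similarity import build_similarity_set
from dischargedx.simulate import (GeneratorConfig, generate_cohort,
                                  generate_corpus, toy_hierarchy)


@pytest.fixture(scope="session")
def real_hierarchy():
    """Standard ICD-9-CM chapter/block hierarchy over a handful of codes."""
    codes = [parse_icd(c) for c in
             ["428", "427", "410", "250", "296", "V45", "36", "37", "45"]]
    return ICDHierarchy.default(codes)


@pytest.fixture(scope="session")
def toy_cfg():
    """Small, fast synthetic configuration (signal defaults, 150 admissions)."""
    return GeneratorConfig(n_hospitalizations=300, n_corpus_patients=300)


@pytest.fixture(scope="session")
def toy_hier(toy_cfg):
    return toy_hierarchy(toy_cfg)


@pytest.fixture(scope="session")
def small_cohort(toy_cfg):
    return zscore_panels(generate_cohort(toy_cfg, seed=0))


@pytest.fixture(scope="session")
def small_icd_sims(toy_cfg, toy_hier, small_cohort):
    corpus = generate_corpus(toy_cfg, seed=1)
    return icd_similarity_pair(toy_hier, small_cohort.code_universe(),
                               corpus, n_shuffles=20, seed=0)


@pytest.fixture(scope="session")
def small_sims(small_cohort, small_icd_sims):
    return build_similarity_set(small_cohort, small_icd_sims)


def make_micro_cohort(with_ecg: bool = False) -> Cohort:
    """Five hand-built hospitalizations over codes 428/427/410/250."""
    z = {  # already z-scaled lab values; 4 tests a..d
        "H1": {"a": 1.0, "b": 0.0, "c": -1.0, "d": 0.5},
        "H2": {"a": 1.2, "b": 0.1, "c": -0.8, "d": 0.4},
        "H3": {"a": -2.0, "b": 2.0, "c": 0.0, "d": 0.0},
        "H4": {"a": 0.0, "b": 0.0, "c": 0.0},
        "H5": {"a": 3.0, "b": -1.0, "c": 1.0, "d": -2.0},
    }
    hist = {  # patient-level: H1 and H5 share patient P1, hence one history
        "H1": {"428", "250"}, "H2": {"428"}, "H3": {"410"},
        "H4": {"427", "410"}, "H5": {"428", "250"},
    }
    discharge = {
        "H1": ("428",), "H2": ("428", "250"), "H3": ("410",),
        "H4": ("427",), "H5": ("250",),
    }
    patients = {"H1": "P1", "H2": "P2", "H3": "P3", "H4": "P4", "H5": "P1"}
    ages = {"H1": 50.0, "H2": 60.0, "H3": 30.0, "H4": 80.0, "H5": 55.0}
    genders = {"H1": "F", "H2": "F", "H3": "M", "H4": "M", "H5": "F"}
    hosps = [
        Hospitalization(
            hosp_id=h, patient_id=patients[h], admission_ordinal=float(i),
            age=ages[h], gender=genders[h], history=frozenset(hist[h]),
            discharge_codes=discharge[h], lab_panel=z[h],
            ecg_panel=dict(z[h]) if with_ecg else {})
        for i, h in enumerate(["H1", "H2", "H3", "H4", "H5"], start=1)
    ]
    return Cohort(hosps, retained_tests=["a", "b", "c", "d"])


@pytest.fixture()
def micro_cohort():
    return make_micro_cohort()


@pytest.fixture(scope="session")
def micro_icd_sims():
    codes = [parse_icd(c) for c in ["428", "427", "410", "250"]]
    h = ICDHierarchy.default(codes)
    hier = ICDSimilarityMatrix.from_hierarchy(h)
    emp = ICDSimilarityMatrix(hier.codes, np.eye(len(hier.codes)), "empirical")
    return {"hierarchy": hier, "empirical": emp}
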
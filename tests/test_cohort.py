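import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dischargedx.cohort import (Cohort, EmptyPanelError, Hospitalization,
                                bh_fdr, filter_tests, load_cohort,
                                select_first_measurements, write_cohort,
                                zscore_panels)
from dischargedx.simulate import GeneratorConfig, generate_cohort


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def test_roundtrip_write_load(tmp_path, micro_cohort):
    write_cohort(micro_cohort, tmp_path)
    loaded = load_cohort(tmp_path)
    assert loaded.hosp_ids == micro_cohort.hosp_ids
    for a, b in zip(micro_cohort, loaded):
        assert a.patient_id == b.patient_id
        assert a.discharge_codes == b.discharge_codes
        assert a.history == b.history
        assert a.lab_panel == pytest.approx(b.lab_panel)
        assert (a.age, a.gender) == (b.age, b.gender)


def test_history_union_of_three_sources(tmp_path, micro_cohort):
    write_cohort(micro_cohort, tmp_path)
    pd.DataFrame([
        {"patient_id": "P3", "icd_code": "428", "source": "encounter"},
        {"patient_id": "P3", "icd_code": "250.0", "source": "past_discharge"},
        {"patient_id": "P3", "icd_code": "V45", "source": "personal_history"},
        {"patient_id": "P3", "icd_code": "E880", "source": "encounter"},  # filtered
    ]).to_csv(tmp_path / "history.tsv", sep="\t", index=False)
    loaded = load_cohort(tmp_path)
    h3 = next(h for h in loaded if h.hosp_id == "H3")
    assert h3.history == {"428", "250", "V45"}


def test_empty_labs_file_ok(tmp_path, micro_cohort):
    write_cohort(micro_cohort, tmp_path)
    (tmp_path / "labs.tsv").write_text("hosp_id\ttest_name\tday_offset\tvalue\n")
    loaded = load_cohort(tmp_path)
    assert all(h.lab_panel == {} for h in loaded)


def test_missing_column_schema_error(tmp_path, micro_cohort):
    write_cohort(micro_cohort, tmp_path)
    (tmp_path / "discharge.tsv").write_text("hosp_id\ticd_code\n1\t428\n")
    with pytest.raises(ValueError, match="rank"):
        load_cohort(tmp_path)


# ---------------------------------------------------------------------------
# First measurements
# ---------------------------------------------------------------------------

class TestFirstMeasurements:
    def _events(self, rows):
        return pd.DataFrame(rows, columns=["hosp_id", "test_name", "day_offset", "value"])

    def test_first_of_repeated_kept(self):
        ev = self._events([("H1", "x", 2, 9.0), ("H1", "x", 1, 5.0)])
        assert select_first_measurements(ev) == {"H1": {"x": 5.0}}

    def test_outside_window_dropped(self):
        ev = self._events([("H1", "x", 4, 9.0)])
        assert select_first_measurements(ev, window_days=3) == {}

    def test_same_timestamp_different_tests(self):
        ev = self._events([("H1", "x", 0, 1.0), ("H1", "y", 0, 2.0)])
        assert select_first_measurements(ev) == {"H1": {"x": 1.0, "y": 2.0}}

    def test_negative_timestamp_rejected(self):
        ev = self._events([("H1", "x", -1, 1.0)])
        with pytest.raises(ValueError):
            select_first_measurements(ev)


# ---------------------------------------------------------------------------
# Test filtering
# ---------------------------------------------------------------------------

def _filter_fixture(seed=0, n=200, shift=3.0, n_noise=9, prev_rare=0.02,
                    n_planted=1):
    """Planted (test, code) shift(s) + noise tests + one rare test."""
    rng = np.random.default_rng(seed)
    hosps = []
    for i in range(n):
        carrier = i < n // 2
        labs = {}
        for j in range(n_planted):
            name = "planted" if n_planted == 1 else f"planted{j}"
            labs[name] = float(rng.normal(shift if carrier else 0.0, 1.0))
        for j in range(n_noise):
            labs[f"noise{j}"] = float(rng.normal(0.0, 1.0))
        if rng.random() < prev_rare:
            labs["rare"] = float(rng.normal(0.0, 1.0))
        hosps.append(Hospitalization(
            hosp_id=f"H{i}", patient_id=f"P{i}", admission_ordinal=float(i),
            age=50.0, gender="F",
            discharge_codes=("428",) if carrier else ("250",),
            lab_panel=labs))
    return Cohort(hosps)


def test_filter_drops_rare_and_keeps_planted():
    cohort = _filter_fixture()
    retained, stats = filter_tests(cohort)
    assert "planted" in retained
    assert "rare" not in retained            # 2% prevalence < 5%
    assert stats.min_pvalue["planted"] < 1e-10


def test_filter_noise_rejection_rate_consistent_with_fdr():
    kept_noise = 0
    for seed in range(5):
        cohort = _filter_fixture(seed=seed)
        retained, _ = filter_tests(cohort)
        kept_noise += sum(1 for t in retained if t.startswith("noise"))
    assert kept_noise <= 2  # 45 null comparisons at FDR 0.01


def test_filter_order_invariant():
    cohort = _filter_fixture()
    reversed_cohort = Cohort(list(reversed(cohort.hospitalizations)))
    r1, _ = filter_tests(cohort)
    r2, _ = filter_tests(reversed_cohort)
    assert set(r1) == set(r2)


def test_filter_raises_when_nothing_survives():
    rng = np.random.default_rng(0)
    hosps = [Hospitalization(
        hosp_id=f"H{i}", patient_id=f"P{i}", admission_ordinal=float(i),
        age=50.0, gender="M", discharge_codes=("428",) if i % 2 else ("250",),
        lab_panel={"x": float(rng.normal())}) for i in range(100)]
    with pytest.raises(EmptyPanelError):
        filter_tests(Cohort(hosps), fdr_q=1e-12)


# ---------------------------------------------------------------------------
# z-scoring
# ---------------------------------------------------------------------------

def test_zscore_means_and_sds():
    cohort = zscore_panels(_filter_fixture(n_planted=3))
    for t in cohort.retained_tests:
        vals = np.array([h.lab_panel[t] for h in cohort if t in h.lab_panel])
        assert abs(vals.mean()) < 1e-9
        assert vals.std(ddof=1) == pytest.approx(1.0)


def test_zscore_drops_sparse_hospitalizations():
    cohort = _filter_fixture(n_planted=3)
    sparse = Hospitalization(
        hosp_id="SPARSE", patient_id="PS", admission_ordinal=999.0, age=40.0,
        gender="M", discharge_codes=("428",),
        lab_panel={"planted0": 1.0, "planted1": 0.5})
    cohort = Cohort(cohort.hospitalizations + [sparse])
    out = zscore_panels(cohort)
    assert "SPARSE" not in out.hosp_ids


def test_ecg_passes_through_same_machinery():
    """ECG panels are filtered and z-scored by the identical code path."""
    cfg = GeneratorConfig(n_hospitalizations=200, ecg=True)
    cohort = zscore_panels(generate_cohort(cfg, 3))
    assert cohort.retained_ecg
    for t in cohort.retained_ecg:
        vals = np.array([h.ecg_panel[t] for h in cohort if t in h.ecg_panel])
        assert abs(vals.mean()) < 1e-9


# ---------------------------------------------------------------------------
# BH-FDR
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("pvals, q, expected", [
    ([0.01, 0.02, 0.04], 0.05, [True, True, True]),
    ([1.0, 1.0, 1.0], 0.05, [False, False, False]),
    ([0.005], 0.01, [True]),
    ([], 0.05, []),
])
def test_bh_fdr_examples(pvals, q, expected):
    assert bh_fdr(pvals, q).tolist() == expected


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40),
       st.sampled_from([0.01, 0.05, 0.1]))
def test_bh_fdr_matches_statsmodels(pvals, q):
    from statsmodels.stats.multitest import multipletests
    ours = bh_fdr(pvals, q)
    theirs = multipletests(pvals, alpha=q, method="fdr_bh")[0]
    assert ours.tolist() == theirs.tolist()
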
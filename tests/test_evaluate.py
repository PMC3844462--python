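import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

from dischargedx.cohort import Cohort, Hospitalization
from dischargedx.evaluate import (best_f1, cross_validate,
                                  extreme_lab_enrichment,
                                  per_code_significance, positive_rows,
                                  prospective_validate,
                                  sample_negatives_postadmission,
                                  sample_negatives_preadmission,
                                  split_by_admission, topk_precision,
                                  train_classifier)
from dischargedx.features import build_feature_table
from dischargedx.icd import ICDHierarchy, parse_icd


# ---------------------------------------------------------------------------
# Negative sampling
# ---------------------------------------------------------------------------

class TestPreAdmissionNegatives:
    def test_never_intersects_patient_truth(self, small_cohort):
        neg = sample_negatives_preadmission(
            small_cohort, small_cohort.code_universe(), seed=0)
        truth = small_cohort.patient_true_codes()
        pat = {h.hosp_id: h.patient_id for h in small_cohort}
        for _, row in neg.iterrows():
            assert row["code"] not in truth[pat[row["hosp_id"]]]

    def test_deterministic_and_sized(self, small_cohort):
        uni = small_cohort.code_universe()
        n1 = sample_negatives_preadmission(small_cohort, uni, seed=5)
        n2 = sample_negatives_preadmission(small_cohort, uni, seed=5)
        pd.testing.assert_frame_equal(n1, n2)
        assert len(n1) == len(positive_rows(small_cohort))

    def test_ratio_scales_count(self, small_cohort):
        uni = small_cohort.code_universe()
        n5 = sample_negatives_preadmission(small_cohort, uni, seed=5, ratio=5.0)
        assert len(n5) == 5 * len(positive_rows(small_cohort))


def _post_fixture():
    def mk(hid, pid, admission, discharge):
        return Hospitalization(
            hosp_id=hid, patient_id=pid, admission_ordinal=1.0, age=50.0,
            gender="F", admission_codes=frozenset(admission),
            discharge_codes=tuple(discharge))
    return Cohort([
        mk("H1", "P1", {"780"}, ["410"]),       # chest-pain admit
        mk("H2", "P2", {"780"}, ["428", "427"]),
        mk("H3", "P3", {"780"}, ["250"]),
        mk("H4", "P4", {"781"}, ["296"]),       # unique admission code
    ])


class TestPostAdmissionNegatives:
    def test_pool_is_shared_admission_discharges(self):
        cohort = _post_fixture()
        neg = sample_negatives_postadmission(cohort, seed=0, ratio=10.0)
        h1 = set(neg.loc[neg["hosp_id"] == "H1", "code"])
        # everything discharged by other 780-admits, minus H1's own codes
        assert h1 == {"428", "427", "250"}

    def test_unique_admission_code_skipped(self):
        neg = sample_negatives_postadmission(_post_fixture(), seed=0, ratio=10.0)
        assert "H4" not in set(neg["hosp_id"])

    def test_never_contains_own_truth(self):
        neg = sample_negatives_postadmission(_post_fixture(), seed=1, ratio=10.0)
        truth = _post_fixture().patient_true_codes()
        pat = {h.hosp_id: h.patient_id for h in _post_fixture()}
        for _, row in neg.iterrows():
            assert row["code"] not in truth[pat[row["hosp_id"]]]

    def test_requires_admission_codes(self, small_cohort):
        cohort = Cohort([h for h in _post_fixture()][:0] or [])
        from dataclasses import replace
        stripped = Cohort([replace(h, admission_codes=frozenset())
                           for h in _post_fixture()])
        with pytest.raises(ValueError, match="admission"):
            sample_negatives_postadmission(stripped, seed=0)


# ---------------------------------------------------------------------------
# Classifier
# ---------------------------------------------------------------------------

class TestClassifier:
    def _table(self, x, y):
        return pd.DataFrame({"hierarchy|AGE": x, "label": y})

    def test_separable_orders_correctly(self):
        table = self._table([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        clf = train_classifier(table)
        scores = clf.predict_proba(table)
        assert np.all(scores[2:] > scores[:2].max())
        assert np.all((scores >= 0) & (scores <= 1))

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            train_classifier(self._table([0.1, 0.2], [1, 1]))

    def test_label_permutation_gives_chance_auc(self):
        rng = np.random.default_rng(0)
        x = rng.random(2000)
        y = rng.integers(0, 2, 2000)  # labels independent of x
        clf = train_classifier(self._table(x, y))
        auc = roc_auc_score(y, clf.predict_proba(self._table(x, y)))
        assert 0.45 < auc < 0.55


def test_auc_rank_statistic_equals_trapezoid():
    """sklearn's trapezoidal ROC AUC equals the Mann-Whitney rank statistic."""
    rng = np.random.default_rng(3)
    y = rng.integers(0, 2, 500)
    s = rng.normal(size=500) + 0.8 * y
    u = sps.mannwhitneyu(s[y == 1], s[y == 0], alternative="two-sided").statistic
    rank_auc = u / ((y == 1).sum() * (y == 0).sum())
    assert roc_auc_score(y, s) == pytest.approx(rank_auc, abs=1e-9)


def test_best_f1_sweep():
    y = np.array([0, 0, 1, 1])
    s = np.array([0.1, 0.6, 0.4, 0.9])
    # threshold at 0.4: prec 2/3, rec 1 -> F1 = 0.8 is the max
    assert best_f1(y, s) == pytest.approx(0.8)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

class TestCrossValidate:
    def test_reproducible_given_seed(self, small_cohort, small_sims):
        r1 = cross_validate(small_cohort, small_sims, folds=4, runs=2, seed=9)
        r2 = cross_validate(small_cohort, small_sims, folds=4, runs=2, seed=9)
        assert r1.run_aucs == r2.run_aucs
        assert r1.f1_mean == r2.f1_mean

    def test_signal_cohort_beats_chance(self, small_cohort, small_sims):
        rep = cross_validate(small_cohort, small_sims, folds=5, runs=1, seed=0)
        assert rep.auc_mean > 0.7

    def test_too_few_rows_raises(self, micro_cohort, micro_icd_sims):
        from dischargedx.similarity import build_similarity_set
        sims = build_similarity_set(micro_cohort, micro_icd_sims)
        with pytest.raises(ValueError):
            cross_validate(micro_cohort, sims, folds=50, runs=1, seed=0)


def test_no_leakage_from_held_out_rows(small_cohort, small_sims):
    """Training features depend only on training positives: removing a
    held-out row never changes them."""
    pos = positive_rows(small_cohort)
    train, held_out = pos.iloc[:-5], pos.iloc[-5:]
    known = [tuple(r) for r in train[["hosp_id", "code"]].itertuples(index=False)]
    t1 = build_feature_table(small_cohort, small_sims, train, known)
    t2 = build_feature_table(small_cohort, small_sims, train, known)
    pd.testing.assert_frame_equal(t1, t2)  # held_out never entered at all
    assert len(held_out) == 5


# ---------------------------------------------------------------------------
# Prospective validation and top-k precision
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def hand_hierarchy():
    return ICDHierarchy.default([parse_icd(c) for c in
                                 ["428", "427", "410", "250", "296"]])


class TestTopkPrecision:
    def test_hand_computed_fixture(self, hand_hierarchy):
        ranked = pd.DataFrame({
            "hosp_id": ["A"] * 3 + ["B"] * 3 + ["C"] * 3,
            "code": ["428", "250", "410", "250", "296", "428", "296", "427", "410"],
            "score": [0.9, 0.8, 0.7] * 3,
            "rank": [1, 2, 3] * 3,
        })
        truth = {"A": {"410"}, "B": {"250"}, "C": {"428"}}
        out = topk_precision(ranked, truth, hand_hierarchy, k_max=3)
        # level 3: A hits at k=3, B at k=1, C never
        assert out["level3"].tolist() == pytest.approx([1 / 3, 1 / 3, 2 / 3])
        # level 2 (block): C's truth 428 shares block 420-429 with 427 at k=2
        assert out["level2"].tolist() == pytest.approx([1 / 3, 2 / 3, 1.0])
        # level 1 (chapter): A's 410 chapter-matches 428 at k=1
        assert out["level1"].tolist() == pytest.approx([2 / 3, 1.0, 1.0])

    def test_monotone_in_k_and_level(self, small_cohort, small_sims, toy_hier):
        rep = prospective_validate(small_cohort, small_sims, seed=0,
                                   hierarchy=toy_hier, k_max=8)
        tk = rep.topk
        for col in tk.columns:
            assert np.all(np.diff(tk[col].to_numpy()) >= 0)
        assert np.all(tk["level1"].to_numpy() >= tk["level2"].to_numpy())
        assert np.all(tk["level2"].to_numpy() >= tk["level3"].to_numpy())


def test_split_by_admission_is_chronological(small_cohort):
    train, valid = split_by_admission(small_cohort, 2 / 3)
    ords = {h.hosp_id: h.admission_ordinal for h in small_cohort}
    assert max(ords[h] for h in train) <= min(ords[h] for h in valid)
    assert len(train) + len(valid) == len(small_cohort)


# ---------------------------------------------------------------------------
# Per-code significance
# ---------------------------------------------------------------------------

class TestPerCodeSignificance:
    def test_consistently_correct_code_is_significant(self):
        rng = np.random.default_rng(0)
        codes = [str(100 + i) for i in range(12)]
        truth, preds = {}, {}
        for i in range(60):
            h = f"H{i}"
            truth[h] = {codes[0]} if i < 30 else {rng.choice(codes[1:])}
            # predictions nail code[0] carriers, miss everything else
            preds[h] = {codes[0]} if i < 30 else {codes[1]} - truth[h]
        ranked = pd.DataFrame([
            {"hosp_id": h, "code": c, "score": 1.0, "rank": 1}
            for h, cs in preds.items() for c in cs])
        # add-one p floor is 1/(n_shuffles+1); 500 shuffles clears BH rank 1
        out = per_code_significance(ranked, truth, n_shuffles=500, seed=1)
        row = out.set_index("code").loc[codes[0]]
        assert row["significant"]
        assert row["pvalue"] < 0.01

    def test_never_correct_code_p_one(self):
        truth = {"H1": {"101"}, "H2": {"102"}, "H3": {"101", "103"}}
        ranked = pd.DataFrame([  # predictions never match truth
            {"hosp_id": h, "code": "104", "score": 1.0, "rank": 1}
            for h in truth])
        out = per_code_significance(ranked, truth, n_shuffles=50, seed=0)
        assert (out["pvalue"] == 1.0).all()
        assert not out["significant"].any()

    def test_pvalues_in_unit_interval_add_one(self):
        truth = {"H1": {"101"}, "H2": {"102"}}
        ranked = pd.DataFrame([{"hosp_id": "H1", "code": "101",
                                "score": 1.0, "rank": 1}])
        out = per_code_significance(ranked, truth, n_shuffles=20, seed=0)
        assert ((out["pvalue"] > 0) & (out["pvalue"] <= 1)).all()


# ---------------------------------------------------------------------------
# Extreme-lab enrichment
# ---------------------------------------------------------------------------

class TestEnrichment:
    def _planted_cohort(self, seed=0, n=300, shift=3.0):
        rng = np.random.default_rng(seed)
        hosps = []
        for i in range(n):
            carrier = rng.random() < 0.3
            labs = {"marker": float(rng.normal(shift if carrier else 0, 1)),
                    "noise_a": float(rng.normal()),
                    "noise_b": float(rng.normal())}
            hosps.append(Hospitalization(
                hosp_id=f"H{i}", patient_id=f"P{i}", admission_ordinal=float(i),
                age=60.0, gender="M",
                discharge_codes=("428",) if carrier else ("250",),
                lab_panel=labs))
        cohort = Cohort(hosps, retained_tests=["marker", "noise_a", "noise_b"])
        from dischargedx.cohort import zscore_panels
        return zscore_panels(cohort, min_tests=1, lab_kwargs={"fdr_q": 1.0})

    def test_planted_pair_recovered(self):
        out = extreme_lab_enrichment(self._planted_cohort(), z_cut=1.5)
        hits = out[out["significant"]]
        assert (("marker", "428") in
                set(zip(hits["test"], hits["code"])))

    def test_null_pairs_rarely_rejected(self):
        out = extreme_lab_enrichment(self._planted_cohort(), z_cut=1.5)
        noise = out[out["test"].str.startswith("noise")]
        assert noise["significant"].sum() <= 1
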
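"""Training and evaluation: negative sampling, logistic classification,
cross-validation, prospective (date-split) validation, top-k hierarchical
precision, per-code significance against shuffled associations, and the
extreme-lab-value enrichment sanity check.

Leakage control: feature scores for any row are always computed against the
positive associations of the training partition only, and similarities to
other hospitalizations of the same patient are masked inside the feature
maximum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import precision_recall_curve, roc_auc_score
from sklearn.model_selection import KFold

from .cohort import Cohort, bh_fdr
from .features import build_feature_table, feature_names
from .icd import ICDHierarchy, shuffle_corpus, CooccurrenceCorpus
from .similarity import SimilaritySet

logger = logging.getLogger(__name__)

__all__ = [
    "TrainedClassifier",
    "EvalReport",
    "positive_rows",
    "sample_negatives_preadmission",
    "sample_negatives_postadmission",
    "train_classifier",
    "cross_validate",
    "prospective_validate",
    "topk_precision",
    "per_code_significance",
    "extreme_lab_enrichment",
]


# ---------------------------------------------------------------------------
# Association rows
# ---------------------------------------------------------------------------

def positive_rows(cohort: Cohort, n_top: int = 2,
                  all_codes: bool = False) -> pd.DataFrame:
    """The gold-standard positive (hospitalization, code) associations.

    By default the 'primary' truth set: the two top-ranked discharge codes
    per hospitalization.  ``all_codes=True`` widens to every discharge code.
    """
    rows = []
    for h in cohort:
        codes = h.discharge_codes if all_codes else h.primary_codes(n_top)
        for c in codes:
            rows.append({"hosp_id": h.hosp_id, "code": c, "label": 1})
    return pd.DataFrame(rows, columns=["hosp_id", "code", "label"])


def sample_negatives_preadmission(cohort: Cohort, universe: list[str],
                                  seed: int, ratio: float = 1.0,
                                  n_top: int = 2) -> pd.DataFrame:
    """Uniform negatives from the retained code universe.

    For each hospitalization, sample (ratio x number of its positives) codes
    uniformly without replacement from the universe minus every true
    discharge code of that patient.
    """
    rng = np.random.default_rng(seed)
    truth = cohort.patient_true_codes()
    uni = np.array(sorted(universe))
    rows = []
    for h in cohort:
        n_pos = len(h.primary_codes(n_top))
        want = int(round(ratio * n_pos))
        if want == 0:
            continue
        pool = uni[~np.isin(uni, sorted(truth[h.patient_id]))]
        if len(pool) < want:
            raise ValueError(
                f"code universe too small for {want} negatives of {h.hosp_id}")
        for c in rng.choice(pool, size=want, replace=False):
            rows.append({"hosp_id": h.hosp_id, "code": str(c), "label": 0})
    return pd.DataFrame(rows, columns=["hosp_id", "code", "label"])


def sample_negatives_postadmission(cohort: Cohort, seed: int,
                                   ratio: float = 1.0,
                                   n_top: int = 2) -> pd.DataFrame:
    """Negatives drawn from diagnoses plausible at admission.

    The candidate pool of a hospitalization is the union of discharge codes
    of other hospitalizations sharing at least one admission code, minus the
    patient's own true codes; hospitalizations with an empty pool are
    skipped with a warning.
    """
    if not any(h.admission_codes for h in cohort):
        raise ValueError("post-admission sampling requires admission codes")
    rng = np.random.default_rng(seed)
    truth = cohort.patient_true_codes()
    by_admission: dict[str, set[str]] = {}
    for h in cohort:
        for a in h.admission_codes:
            by_admission.setdefault(a, set()).update(h.discharge_codes)
    rows, skipped = [], 0
    for h in cohort:
        pool: set[str] = set()
        for a in h.admission_codes:
            pool |= by_admission.get(a, set())
        pool -= truth[h.patient_id]
        n_pos = len(h.primary_codes(n_top))
        want = min(int(round(ratio * n_pos)), len(pool))
        if want == 0:
            skipped += 1
            continue
        for c in rng.choice(sorted(pool), size=want, replace=False):
            rows.append({"hosp_id": h.hosp_id, "code": str(c), "label": 0})
    if skipped:
        logger.warning("post-admission sampling skipped %d hospitalizations "
                       "with empty candidate pools", skipped)
    return pd.DataFrame(rows, columns=["hosp_id", "code", "label"])


def sample_negatives(cohort: Cohort, scenario: str, universe: list[str],
                     seed: int, ratio: float = 1.0, n_top: int = 2) -> pd.DataFrame:
    if scenario == "pre":
        return sample_negatives_preadmission(cohort, universe, seed, ratio, n_top)
    if scenario == "post":
        return sample_negatives_postadmission(cohort, seed, ratio, n_top)
    raise ValueError(f"unknown negative-sampling scenario {scenario!r}")


# ---------------------------------------------------------------------------
# Classifier
# ---------------------------------------------------------------------------

@dataclass
class TrainedClassifier:
    """Unpenalized binomial/logit fit over the feature columns."""

    feature_names: list[str]
    coef: np.ndarray
    intercept: float
    _model: LogisticRegression

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        x = table[self.feature_names].to_numpy(dtype=float)
        return self._model.predict_proba(x)[:, 1]


def train_classifier(table: pd.DataFrame,
                     features: list[str] | None = None) -> TrainedClassifier:
    """Maximum-likelihood logistic regression on a labeled feature table."""
    features = features or [c for c in table.columns if "|" in c]
    y = table["label"].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("feature table must contain both labels")
    x = table[features].to_numpy(dtype=float)
    # unpenalized ML fit (binomial/logit); C=inf disables regularization
    model = LogisticRegression(C=np.inf, max_iter=2000, solver="lbfgs")
    model.fit(x, y)
    return TrainedClassifier(list(features), model.coef_[0].copy(),
                             float(model.intercept_[0]), model)


def best_f1(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Maximum F1 over a sweep of all distinct score thresholds."""
    prec, rec, _ = precision_recall_curve(y_true, scores)
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = 2 * prec * rec / np.where(prec + rec > 0, prec + rec, 1.0)
    return float(np.nanmax(f1))


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    auc_mean: float | None = None
    auc_sd: float | None = None
    f1_mean: float | None = None
    f1_sd: float | None = None
    run_aucs: list[float] = field(default_factory=list)
    topk: pd.DataFrame | None = None  # index k, columns level1/2/3
    per_code: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {"auc_mean": self.auc_mean, "auc_sd": self.auc_sd,
             "f1_mean": self.f1_mean, "f1_sd": self.f1_sd,
             "run_aucs": self.run_aucs, "meta": self.meta}
        if self.topk is not None:
            d["topk"] = {c: self.topk[c].tolist() for c in self.topk.columns}
            d["topk_k"] = self.topk.index.tolist()
        return d


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def cross_validate(cohort: Cohort, sims: SimilaritySet, scenario: str = "pre",
                   folds: int = 10, runs: int = 10, seed: int = 0,
                   negatives_ratio: float = 1.0, n_top: int = 2) -> EvalReport:
    """k-fold cross-validation over association rows, repeated ``runs`` times.

    Each run draws a fresh negative set and a fresh random partition of the
    rows; per fold, features for both partitions are computed against the
    training-fold positives only.  AUC is the rank statistic over pooled
    held-out scores; best F1 sweeps all thresholds.
    """
    universe = cohort.code_universe()
    pos = positive_rows(cohort, n_top)
    rng = np.random.default_rng(seed)
    aucs, f1s = [], []
    for run in range(runs):
        neg = sample_negatives(cohort, scenario, universe,
                               int(rng.integers(2**31 - 1)), negatives_ratio, n_top)
        rows = pd.concat([pos, neg], ignore_index=True)
        if len(rows) < folds:
            raise ValueError("fewer association rows than folds")
        kf = KFold(n_splits=folds, shuffle=True,
                   random_state=int(rng.integers(2**31 - 1)))
        y_all, s_all = [], []
        for train_idx, test_idx in kf.split(rows):
            train = rows.iloc[train_idx]
            test = rows.iloc[test_idx]
            known = [tuple(r) for r in
                     train.loc[train["label"] == 1, ["hosp_id", "code"]].itertuples(index=False)]
            train_feat = build_feature_table(cohort, sims, train, known)
            test_feat = build_feature_table(cohort, sims, test, known)
            clf = train_classifier(train_feat)
            y_all.append(test["label"].to_numpy(dtype=int))
            s_all.append(clf.predict_proba(test_feat))
        y = np.concatenate(y_all)
        s = np.concatenate(s_all)
        aucs.append(float(roc_auc_score(y, s)))
        f1s.append(best_f1(y, s))
    return EvalReport(
        auc_mean=float(np.mean(aucs)), auc_sd=float(np.std(aucs, ddof=1)) if runs > 1 else 0.0,
        f1_mean=float(np.mean(f1s)), f1_sd=float(np.std(f1s, ddof=1)) if runs > 1 else 0.0,
        run_aucs=aucs,
        meta={"scenario": scenario, "folds": folds, "runs": runs,
              "negatives_ratio": negatives_ratio, "seed": seed})


# ---------------------------------------------------------------------------
# Prospective validation
# ---------------------------------------------------------------------------

def split_by_admission(cohort: Cohort, train_fraction: float = 2 / 3,
                       date_threshold: float | None = None) -> tuple[list[str], list[str]]:
    """Chronological train/validation split on admission ordinals."""
    ordered = sorted(cohort, key=lambda h: (h.admission_ordinal, h.hosp_id))
    if date_threshold is not None:
        train = [h.hosp_id for h in ordered if h.admission_ordinal <= date_threshold]
        valid = [h.hosp_id for h in ordered if h.admission_ordinal > date_threshold]
    else:
        cut = int(round(train_fraction * len(ordered)))
        train = [h.hosp_id for h in ordered[:cut]]
        valid = [h.hosp_id for h in ordered[cut:]]
    if not valid or not train:
        raise ValueError("degenerate chronological split")
    return train, valid


def rank_candidates(cohort: Cohort, sims: SimilaritySet, hosp_ids: list[str],
                    universe: list[str], known: list[tuple[str, str]],
                    clf: TrainedClassifier) -> pd.DataFrame:
    """Score every candidate code for each hospitalization and rank them.

    Returns a frame (hosp_id, code, score, rank), rank 1 = best; score ties
    broken by lexicographic code order.
    """
    cand = pd.DataFrame(
        [(h, c) for h in hosp_ids for c in universe], columns=["hosp_id", "code"])
    feat = build_feature_table(cohort, sims, cand, known)
    feat["score"] = clf.predict_proba(feat)
    feat = feat.sort_values(["hosp_id", "score", "code"],
                            ascending=[True, False, True], kind="stable")
    feat["rank"] = feat.groupby("hosp_id").cumcount() + 1
    return feat[["hosp_id", "code", "score", "rank"]].reset_index(drop=True)


def topk_precision(ranked: pd.DataFrame, truth: dict[str, set[str]],
                   hierarchy: ICDHierarchy, k_max: int = 10) -> pd.DataFrame:
    """Fraction of hospitalizations with >=1 true code in the top k,
    at ICD levels 3 (code), 2 (block) and 1 (chapter)."""
    def anc(code, level):
        return hierarchy.ancestor_at(code, level)

    out = {f"level{lvl}": np.zeros(k_max) for lvl in (1, 2, 3)}
    hosp_ids = [h for h in ranked["hosp_id"].unique() if truth.get(h)]
    if not hosp_ids:
        raise ValueError("no hospitalization with truth codes to evaluate")
    grouped = ranked[ranked["rank"] <= k_max].groupby("hosp_id")["code"].apply(list)
    for lvl in (1, 2, 3):
        hits = np.zeros(k_max)
        for h in hosp_ids:
            true_anc = {anc(c, lvl) for c in truth[h]}
            preds = grouped.get(h, [])
            first_hit = next((i for i, c in enumerate(preds)
                              if anc(c, lvl) in true_anc), None)
            if first_hit is not None:
                hits[first_hit:] += 1
        out[f"level{lvl}"] = hits / len(hosp_ids)
    return pd.DataFrame(out, index=pd.RangeIndex(1, k_max + 1, name="k"))


def prospective_validate(cohort: Cohort, sims: SimilaritySet,
                         train_fraction: float = 2 / 3,
                         date_threshold: float | None = None,
                         k_max: int = 10, seed: int = 0,
                         scenario: str = "pre", negatives_ratio: float = 1.0,
                         n_top: int = 2, all_codes_truth: bool = False,
                         hierarchy: ICDHierarchy | None = None) -> EvalReport:
    """Date-split validation mimicking the admission of new patients.

    The classifier is trained on the earlier hospitalizations (positives
    plus sampled negatives, featurized against training positives); every
    retained code is then scored and ranked for each validation
    hospitalization, and top-k precision is reported at ICD levels 3/2/1.
    """
    train_ids, valid_ids = split_by_admission(cohort, train_fraction, date_threshold)
    train_cohort = cohort.subset(train_ids)
    universe = cohort.code_universe()
    if hierarchy is None:
        from .icd import parse_icd
        hierarchy = ICDHierarchy.default([parse_icd(c) for c in universe])

    pos = positive_rows(train_cohort, n_top)
    neg = sample_negatives(train_cohort, scenario, universe, seed,
                           negatives_ratio, n_top)
    train_rows = pd.concat([pos, neg], ignore_index=True)
    known = [tuple(r) for r in pos[["hosp_id", "code"]].itertuples(index=False)]
    train_feat = build_feature_table(cohort, sims, train_rows, known)
    clf = train_classifier(train_feat)

    ranked = rank_candidates(cohort, sims, valid_ids, universe, known, clf)
    truth = {}
    for h in cohort:
        if h.hosp_id in set(valid_ids):
            codes = h.discharge_codes if all_codes_truth else h.primary_codes(n_top)
            truth[h.hosp_id] = set(codes)
    topk = topk_precision(ranked, truth, hierarchy, k_max)
    return EvalReport(topk=topk,
                      meta={"n_train": len(train_ids), "n_valid": len(valid_ids),
                            "seed": seed, "scenario": scenario,
                            "ranked": ranked, "truth": truth})


# ---------------------------------------------------------------------------
# Per-code significance
# ---------------------------------------------------------------------------

def per_code_significance(ranked: pd.DataFrame, truth: dict[str, set[str]],
                          n_shuffles: int = 1000, fdr_q: float = 0.05,
                          seed: int = 0, k: int = 10) -> pd.DataFrame:
    """Empirical significance of per-code correct-prediction counts.

    The observed count of hospitalizations where a code is both predicted
    in the top ``k`` and true is compared against degree-preserving shuffles
    of the hospitalization-diagnosis association sets (per-hospitalization
    code counts and overall code distribution preserved).  p-values use the
    add-one rule; BH control at ``fdr_q``.
    """
    top = ranked[ranked["rank"] <= k]
    pred_sets = top.groupby("hosp_id")["code"].apply(set).to_dict()
    hosp_ids = sorted(truth)
    corpus = CooccurrenceCorpus({h: truth[h] for h in hosp_ids if truth[h]})
    codes = corpus.codes

    def counts(member):
        c = np.zeros(len(codes), dtype=int)
        for i, h in enumerate(corpus.patients):
            preds = pred_sets.get(h, set())
            for j in np.flatnonzero(member[i]):
                if codes[j] in preds:
                    c[j] += 1
        return c

    observed = counts(corpus.membership)
    rng = np.random.default_rng(seed)
    geq = np.zeros(len(codes), dtype=int)
    for _ in range(n_shuffles):
        shuf = shuffle_corpus(corpus, int(rng.integers(2**31 - 1)))
        geq += counts(shuf.membership) >= observed
    pvals = (1 + geq) / (1 + n_shuffles)
    rejected = bh_fdr(pvals, fdr_q)
    return pd.DataFrame({"code": codes, "correct": observed,
                         "pvalue": pvals, "significant": rejected})


# ---------------------------------------------------------------------------
# Extreme-lab-value enrichment sanity check
# ---------------------------------------------------------------------------

def extreme_lab_enrichment(cohort: Cohort, z_cut: float = 2.0,
                           fdr_q: float = 0.01) -> pd.DataFrame:
    """Hypergeometric enrichment of discharge codes among extreme lab values.

    For each (test, code): the overlap between hospitalizations with
    |z| > z_cut on the test and hospitalizations discharged with the code is
    tested against the hypergeometric tail over the hospitalizations in
    which the test was measured; BH control at ``fdr_q``.
    """
    if not cohort.retained_tests:
        raise ValueError("cohort must be z-scored before enrichment analysis")
    truth = [set(h.discharge_codes) for h in cohort]
    codes = cohort.code_universe()
    rows = []
    for t in cohort.retained_tests:
        measured = np.array([t in h.lab_panel for h in cohort])
        z = np.array([h.lab_panel.get(t, 0.0) for h in cohort])
        extreme = measured & (np.abs(z) > z_cut)
        m_tot = int(measured.sum())
        k_ext = int(extreme.sum())
        if k_ext == 0:
            continue
        for code in codes:
            carrier = np.array([code in s for s in truth]) & measured
            n_car = int(carrier.sum())
            if n_car == 0:
                continue
            overlap = int((extreme & carrier).sum())
            if overlap > min(k_ext, n_car):  # impossible by construction
                raise AssertionError("overlap exceeds a margin")
            p = stats.hypergeom.sf(overlap - 1, m_tot, k_ext, n_car)
            rows.append({"test": t, "code": code, "overlap": overlap,
                         "n_extreme": k_ext, "n_carrier": n_car,
                         "pvalue": float(p)})
    df = pd.DataFrame(rows, columns=["test", "code", "overlap", "n_extreme",
                                     "n_carrier", "pvalue"])
    if len(df):
        df["significant"] = bh_fdr(df["pvalue"].to_numpy(), fdr_q)
    else:
        df["significant"] = pd.Series(dtype=bool)
    return df
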
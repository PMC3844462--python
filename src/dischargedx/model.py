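"""A scikit-learn-style estimator wrapping the full inference pipeline.

``DischargeDiagnosisModel.fit`` consumes a preprocessed cohort (plus a
hierarchy and an optional co-occurrence corpus), builds the similarity
matrices, samples negatives, featurizes and fits the logistic model;
``rank`` / ``predict_top_k`` score every retained code for new-to-the-model
hospitalizations of the same cohort.  Parameters follow sklearn conventions
(get_params/set_params, trailing-underscore fitted attributes), so the
estimator composes with sklearn model-selection utilities that operate on
estimator objects.
"""

from __future__ import annotations

import pandas as pd
from sklearn.base import BaseEstimator

from .cohort import Cohort
from .evaluate import (positive_rows, rank_candidates, sample_negatives,
                       train_classifier)
from .features import build_feature_table
from .icd import (CooccurrenceCorpus, ICDHierarchy, ICDSimilarityMatrix,
                  empirical_similarity, parse_icd)
from .similarity import SimilaritySet, build_similarity_set

__all__ = ["DischargeDiagnosisModel", "icd_similarity_pair"]


def icd_similarity_pair(hierarchy: ICDHierarchy, universe: list[str],
                        corpus: CooccurrenceCorpus | None = None,
                        n_shuffles: int = 100, seed: int = 0) -> dict[str, ICDSimilarityMatrix]:
    """Build the hierarchy and empirical ICD similarity matrices.

    Without a corpus the empirical matrix degenerates to the identity
    (a code co-occurs only with itself), keeping the 16-feature layout.
    """
    hier = ICDSimilarityMatrix.from_hierarchy(hierarchy, universe)
    if corpus is None:
        emp = ICDSimilarityMatrix(hier.codes,
                                  (hier.matrix >= 1.0).astype(float), "empirical")
    else:
        emp_full = empirical_similarity(corpus, n_shuffles, seed)
        idx = [emp_full.index_of(c) if c in set(emp_full.codes) else -1
               for c in hier.codes]
        import numpy as np
        m = np.zeros((len(hier.codes), len(hier.codes)))
        for i, a in enumerate(idx):
            for j, b in enumerate(idx):
                if a >= 0 and b >= 0:
                    m[i, j] = emp_full.matrix[a, b]
            if a < 0:
                m[i, i] = 1.0
        emp = ICDSimilarityMatrix(hier.codes, m, "empirical")
    return {"hierarchy": hier, "empirical": emp}


class DischargeDiagnosisModel(BaseEstimator):
    """Patient-similarity predictor of primary discharge ICD-9 codes.

    Parameters
    ----------
    scenario : "pre" or "post" negative-sampling scheme.
    negatives_ratio : negatives per positive association.
    n_top : how many top-ranked discharge codes form the positive truth set.
    n_shuffles : shuffles behind the empirical ICD similarity.
    min_shared_tests : below this many shared tests a panel pair scores 0.
    seed : seed for every random draw inside fit.
    """

    def __init__(self, scenario: str = "pre", negatives_ratio: float = 1.0,
                 n_top: int = 2, n_shuffles: int = 100,
                 min_shared_tests: int = 3, seed: int = 0):
        self.scenario = scenario
        self.negatives_ratio = negatives_ratio
        self.n_top = n_top
        self.n_shuffles = n_shuffles
        self.min_shared_tests = min_shared_tests
        self.seed = seed

    # NB: "X" is a cohort, not an array; the estimator is container-typed.
    def fit(self, cohort: Cohort, y=None, *, hierarchy: ICDHierarchy | None = None,
            corpus: CooccurrenceCorpus | None = None,
            train_hosp_ids: list[str] | None = None,
            sims: SimilaritySet | None = None) -> "DischargeDiagnosisModel":
        if len(cohort) < 2:
            raise ValueError("need at least two hospitalizations")
        self.cohort_ = cohort
        self.universe_ = cohort.code_universe()
        if hierarchy is None:
            hierarchy = ICDHierarchy.default([parse_icd(c) for c in self.universe_])
        self.hierarchy_ = hierarchy
        if sims is None:
            icd_sims = icd_similarity_pair(hierarchy, self.universe_, corpus,
                                           self.n_shuffles, self.seed)
            sims = build_similarity_set(cohort, icd_sims, self.min_shared_tests)
        self.sims_ = sims

        train_cohort = (cohort if train_hosp_ids is None
                        else cohort.subset(train_hosp_ids))
        pos = positive_rows(train_cohort, self.n_top)
        neg = sample_negatives(train_cohort, self.scenario, self.universe_,
                               self.seed, self.negatives_ratio, self.n_top)
        rows = pd.concat([pos, neg], ignore_index=True)
        self.known_ = [tuple(r) for r in
                       pos[["hosp_id", "code"]].itertuples(index=False)]
        table = build_feature_table(cohort, self.sims_, rows, self.known_)
        self.classifier_ = train_classifier(table)
        self.feature_names_ = self.classifier_.feature_names
        return self

    def _check_fitted(self):
        if not hasattr(self, "classifier_"):
            raise RuntimeError("model is not fitted")

    def predict_proba_rows(self, rows: pd.DataFrame) -> pd.Series:
        """Probability of association for explicit (hosp_id, code) rows."""
        self._check_fitted()
        feat = build_feature_table(self.cohort_, self.sims_, rows, self.known_)
        return pd.Series(self.classifier_.predict_proba(feat), index=rows.index)

    def rank(self, hosp_ids: list[str]) -> pd.DataFrame:
        """Rank every retained code for each hospitalization (rank 1 = best)."""
        self._check_fitted()
        return rank_candidates(self.cohort_, self.sims_, list(hosp_ids),
                               self.universe_, self.known_, self.classifier_)

    def predict_top_k(self, hosp_ids: list[str], k: int = 10) -> dict[str, list[str]]:
        ranked = self.rank(hosp_ids)
        top = ranked[ranked["rank"] <= k]
        return {h: grp.sort_values("rank")["code"].tolist()
                for h, grp in top.groupby("hosp_id")}
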
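"""Max-geometric-mean link-prediction features for (hospitalization, code) pairs.

A candidate association between hospitalization H and discharge code I is
scored against a corpus of known associations (H', I'):

    Score(H, I) = max over (H', I') != (H, I) of sqrt(S(H, H') * S(I, I'))

excluding every hospitalization H' of H's own patient.  One feature column
exists for each combination of an ICD similarity (hierarchy, empirical) and
a hospitalization similarity (MH1, MH2, BT1, BT2, ECG1, ECG2, AGE, GEN),
yielding 16 columns with ECG data and 12 without.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort
from .icd import ICDSimilarityMatrix
from .similarity import SimilaritySet

__all__ = ["score_association", "build_feature_table", "feature_names"]

ICD_MEASURES = ("hierarchy", "empirical")


def feature_names(sims: SimilaritySet) -> list[str]:
    return [f"{icd}|{hm}" for icd in ICD_MEASURES for hm in sims.measure_names]


def score_association(hosp_id: str, code: str, s_h: np.ndarray,
                      s_i: ICDSimilarityMatrix, known: Sequence[tuple[str, str]],
                      sims: SimilaritySet, patient_of: dict[str, str]) -> float:
    """Score one candidate (hospitalization, code) pair against known pairs.

    ``known`` pairs belonging to the same patient, and the pair (H, I)
    itself, are excluded; the empty maximum is 0.
    """
    hi = sims.index_of(hosp_id)
    pid = patient_of[hosp_id]
    best = 0.0
    for h2, c2 in known:
        if patient_of[h2] == pid:
            continue
        if h2 == hosp_id and c2 == code:
            continue
        v = s_h[hi, sims.index_of(h2)] * s_i.value(code, c2)
        if v > best:
            best = v
    return math.sqrt(best)


def build_feature_table(cohort: Cohort, sims: SimilaritySet,
                        rows: pd.DataFrame,
                        known: Sequence[tuple[str, str]],
                        chunk: int = 512) -> pd.DataFrame:
    """Featurize candidate rows against the known-association corpus.

    ``rows`` needs columns hosp_id, code (and passes through any others,
    e.g. label); ``known`` is the list of training-positive (hosp_id, code)
    associations.  Same-patient associations and the identical pair are
    masked from every maximum.  Vectorized over row chunks.
    """
    if rows.empty:
        raise ValueError("no rows to featurize")
    unknown = set(rows["hosp_id"]) - set(sims.hosp_ids)
    if unknown:
        raise KeyError(f"rows reference unknown hosp_id(s): {sorted(unknown)[:5]}")

    patient_of = {h.hosp_id: h.patient_id for h in cohort}
    row_h = np.array([sims.index_of(h) for h in rows["hosp_id"]])
    row_pat = np.array([patient_of[h] for h in rows["hosp_id"]])

    icd_mats = {tag: sims.icd_sims[tag] for tag in ICD_MEASURES}
    for tag, m in icd_mats.items():
        missing = set(rows["code"]) - set(m.codes)
        if missing:
            raise KeyError(f"rows reference codes unknown to the {tag} "
                           f"similarity: {sorted(missing)[:5]}")
    row_c = {tag: np.array([m.index_of(c) for c in rows["code"]])
             for tag, m in icd_mats.items()}

    if known:
        known_h = np.array([sims.index_of(h) for h, _ in known])
        known_pat = np.array([patient_of[h] for h, _ in known])
        known_c = {tag: np.array([m.index_of(c) for _, c in known])
                   for tag, m in icd_mats.items()}
    else:
        known_h = np.zeros(0, dtype=int)

    out = rows.reset_index(drop=True).copy()
    names = feature_names(sims)
    feats = {name: np.zeros(len(out)) for name in names}

    if len(known_h):
        for start in range(0, len(out), chunk):
            sl = slice(start, min(start + chunk, len(out)))
            # mask: same patient, or the identical (H, I) pair
            mask = row_pat[sl, None] == known_pat[None, :]
            for tag in ICD_MEASURES:
                mask |= ((row_h[sl, None] == known_h[None, :])
                         & (row_c[tag][sl, None] == known_c[tag][None, :]))
                break  # pair identity is tag-independent; one pass suffices
            for icd_tag in ICD_MEASURES:
                s_codes = icd_mats[icd_tag].matrix[
                    np.ix_(row_c[icd_tag][sl], known_c[icd_tag])]
                for hm in sims.measure_names:
                    s_hosp = sims.matrices[hm][np.ix_(row_h[sl], known_h)]
                    prod = np.where(mask, -1.0, s_hosp * s_codes)
                    feats[f"{icd_tag}|{hm}"][sl] = np.sqrt(
                        np.maximum(prod.max(axis=1), 0.0))

    for name in names:
        out[name] = feats[name]
    return out
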
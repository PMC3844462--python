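"""The eight inter-hospitalization similarity measures.

Measure names follow the field's shorthand: MH1/MH2 (medical-history
maximal-matching similarity under the hierarchy and empirical ICD
similarities), BT1/BT2 (blood-test Euclidean and extreme-value measures),
ECG1/ECG2 (the same two measures on ECG channels), AGE and GEN.

All measures return values in [0, 1]; pairwise distance measures are turned
into similarities by the global linear transform S = 1 - D / D_max computed
per matrix over finite distances, with below-threshold pairs pinned to 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .cohort import Cohort, _panel_frame
from .icd import ICDSimilarityMatrix

__all__ = [
    "SimilaritySet",
    "history_similarity",
    "panel_similarity_euclidean",
    "panel_similarity_extremes",
    "distance_to_similarity",
    "age_similarity",
    "gender_similarity",
    "build_similarity_set",
]

HOSP_MEASURES = ("MH1", "MH2", "BT1", "BT2", "ECG1", "ECG2", "AGE", "GEN")

_SENTINEL = np.inf  # marks pairs below the shared-test threshold


def history_similarity(h1, h2, icd_sim: ICDSimilarityMatrix) -> float:
    """Maximal-matching similarity between two medical-history code sets.

    A complete bipartite graph connects the two profiles with edge weights
    given by the ICD similarity; the value of a maximum-weight one-to-one
    matching is normalized by the smaller profile size.  Empty profiles
    score 0.
    """
    a, b = sorted(set(h1)), sorted(set(h2))
    if not a or not b:
        return 0.0
    ia = [icd_sim.index_of(c) for c in a]
    ib = [icd_sim.index_of(c) for c in b]
    w = icd_sim.matrix[np.ix_(ia, ib)]
    return _matching_value(w) / min(len(a), len(b))


def _matching_value(w: np.ndarray) -> float:
    """Maximum-weight one-to-one matching value of a weight matrix."""
    if w.shape[0] == 1:
        return float(w.max())
    if w.shape[1] == 1:
        return float(w.max())
    r, c = linear_sum_assignment(w, maximize=True)
    return float(w[r, c].sum())


def _shared(z1: dict, z2: dict) -> list[str]:
    return sorted(set(z1) & set(z2))


def panel_similarity_euclidean(z1, z2, min_shared: int = 3) -> float:
    """Length-normalized Euclidean distance over the shared tests.

    Returns the raw distance D = ||z1 - z2|| / n over the n shared tests,
    or the sentinel (inf) when fewer than ``min_shared`` tests are shared;
    callers convert to a similarity with :func:`distance_to_similarity`.
    """
    common = _shared(z1, z2)
    if len(common) < min_shared:
        return _SENTINEL
    d = np.array([z1[t] - z2[t] for t in common])
    return float(np.sqrt(np.sum(d * d)) / len(common))


def panel_similarity_extremes(z1, z2, min_shared: int = 3) -> float:
    """Distance between the most extreme shared measurements.

    For each hospitalization, take the shared test with the largest |z|
    (ties broken by lexicographic test name); the distance is the average
    absolute difference of |z| magnitudes at those two tests.
    """
    common = _shared(z1, z2)
    if len(common) < min_shared:
        return _SENTINEL
    a1 = np.array([abs(z1[t]) for t in common])
    a2 = np.array([abs(z2[t]) for t in common])
    t1 = int(np.argmax(a1))  # first max = lexicographically smallest name
    t2 = int(np.argmax(a2))
    return float((abs(a1[t1] - a2[t1]) + abs(a1[t2] - a2[t2])) / 2.0)


def distance_to_similarity(d: np.ndarray) -> np.ndarray:
    """Linear map S = 1 - D / D_max over finite distances; sentinel -> 0."""
    d = np.asarray(d, dtype=float)
    finite = np.isfinite(d)
    if not finite.any():
        warnings.warn("all pairs below the shared-test threshold; similarity 0")
        return np.zeros_like(d)
    dmax = d[finite].max()
    if dmax <= 0:
        s = np.where(finite, 1.0, 0.0)
    else:
        s = np.where(finite, 1.0 - d / dmax, 0.0)
    return np.clip(s, 0.0, 1.0)


def age_similarity(a1: float, a2: float) -> float:
    """S = 1 - |a1 - a2| / max(a1, a2); identical ages (incl. 0) score 1."""
    if a1 < 0 or a2 < 0:
        raise ValueError("ages must be non-negative")
    if a1 == a2:
        return 1.0
    return 1.0 - abs(a1 - a2) / max(a1, a2)


def gender_similarity(g1: str, g2: str) -> float:
    for g in (g1, g2):
        if g not in {"F", "M"}:
            raise ValueError(f"unknown gender label {g!r}")
    return 1.0 if g1 == g2 else 0.0


@dataclass
class SimilaritySet:
    """All hospitalization-by-hospitalization similarity matrices plus the
    two ICD similarity matrices feeding them."""

    hosp_ids: list[str]
    matrices: dict[str, np.ndarray]
    icd_sims: dict[str, ICDSimilarityMatrix]

    def __post_init__(self):
        self._index = {h: i for i, h in enumerate(self.hosp_ids)}

    @property
    def measure_names(self) -> list[str]:
        return [m for m in HOSP_MEASURES if m in self.matrices]

    def index_of(self, hosp_id: str) -> int:
        return self._index[hosp_id]

    def value(self, measure: str, h1: str, h2: str) -> float:
        return float(self.matrices[measure][self._index[h1], self._index[h2]])

    def to_long_frame(self):
        """Long TSV-friendly frame (hosp_id_1, hosp_id_2, measure, value)."""
        import pandas as pd

        rows = []
        n = len(self.hosp_ids)
        for m, mat in self.matrices.items():
            iu = np.triu_indices(n, k=1)
            rows.append(pd.DataFrame({
                "hosp_id_1": np.asarray(self.hosp_ids)[iu[0]],
                "hosp_id_2": np.asarray(self.hosp_ids)[iu[1]],
                "measure": m,
                "value": mat[iu],
            }))
        return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Vectorized cohort-level construction
# ---------------------------------------------------------------------------

def _history_matrix(cohort: Cohort, icd_sim: ICDSimilarityMatrix) -> np.ndarray:
    """Pairwise history similarity, deduplicated over unique history sets."""
    known_codes = set(icd_sim.codes)
    keys = [tuple(sorted(h.history & known_codes)) for h in cohort]
    uniq = sorted(set(keys))
    uidx = {k: i for i, k in enumerate(uniq)}
    m = len(uniq)
    u = np.zeros((m, m))
    idx_sets = [[icd_sim.index_of(c) for c in k] for k in uniq]
    for i in range(m):
        if not uniq[i]:
            continue
        for j in range(i, m):
            if not uniq[j]:
                continue
            w = icd_sim.matrix[np.ix_(idx_sets[i], idx_sets[j])]
            u[i, j] = u[j, i] = _matching_value(w) / min(len(uniq[i]), len(uniq[j]))
    rows = np.array([uidx[k] for k in keys])
    return u[np.ix_(rows, rows)]


def _panel_distance_matrices(cohort: Cohort, attr: str,
                             min_shared: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Euclidean and extreme-value pairwise distances (inf = below threshold)."""
    df = _panel_frame(cohort, attr)
    z = df.to_numpy(dtype=float)
    mask = ~np.isnan(z)
    z0 = np.where(mask, z, 0.0)
    m = mask.astype(np.float64)
    n_shared = m @ m.T
    sq = (z0 * z0) @ m.T
    cross = z0 @ z0.T
    ssd = np.maximum(sq + sq.T - 2.0 * cross, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        d_euc = np.sqrt(ssd) / n_shared
    d_euc[n_shared < min_shared] = _SENTINEL

    # extremes: per (i, j), the shared test maximizing |z_i| (column order is
    # lexicographic, argmax returns the first = lexicographically smallest)
    az = np.abs(z0)
    n = z.shape[0]
    v1 = np.zeros((n, n))
    neg = np.where(mask, 0.0, -np.inf)
    for i in range(n):
        scores = az[i][None, :] + neg + neg[i][None, :]
        t1 = np.argmax(scores, axis=1)
        v1[i] = np.abs(az[i, t1] - az[np.arange(n), t1])
    d_ext = (v1 + v1.T) / 2.0
    d_ext[n_shared < min_shared] = _SENTINEL
    return d_euc, d_ext


def build_similarity_set(cohort: Cohort,
                         icd_sims: dict[str, ICDSimilarityMatrix],
                         min_shared_tests: int = 3) -> SimilaritySet:
    """Compute every applicable hospitalization similarity matrix.

    MH1 uses the hierarchy ICD similarity and MH2 the empirical one; BT/ECG
    distances pass through the global linear distance-to-similarity
    transform.  ECG matrices are omitted when the cohort carries no ECG
    panels.
    """
    if set(icd_sims) != {"hierarchy", "empirical"}:
        raise ValueError("icd_sims must provide 'hierarchy' and 'empirical'")
    mats: dict[str, np.ndarray] = {}
    mats["MH1"] = _history_matrix(cohort, icd_sims["hierarchy"])
    mats["MH2"] = _history_matrix(cohort, icd_sims["empirical"])

    d_euc, d_ext = _panel_distance_matrices(cohort, "lab_panel", min_shared_tests)
    mats["BT1"] = distance_to_similarity(d_euc)
    mats["BT2"] = distance_to_similarity(d_ext)

    if cohort.has_ecg:
        e_euc, e_ext = _panel_distance_matrices(cohort, "ecg_panel", min_shared_tests)
        mats["ECG1"] = distance_to_similarity(e_euc)
        mats["ECG2"] = distance_to_similarity(e_ext)

    ages = np.array([h.age for h in cohort], dtype=float)
    amax = np.maximum(ages[:, None], ages[None, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        age_m = 1.0 - np.abs(ages[:, None] - ages[None, :]) / np.where(amax > 0, amax, 1.0)
    np.fill_diagonal(age_m, 1.0)
    mats["AGE"] = age_m

    genders = np.array([h.gender for h in cohort])
    mats["GEN"] = (genders[:, None] == genders[None, :]).astype(float)

    for name, m in mats.items():
        mats[name] = np.clip((m + m.T) / 2.0, 0.0, 1.0)  # enforce exact symmetry
    return SimilaritySet(cohort.hosp_ids, mats, dict(icd_sims))
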
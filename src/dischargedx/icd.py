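"""ICD-9-CM code parsing, filtering and the two ICD similarity measures.

Codes live in a chapter -> block -> three-digit-code hierarchy.  Two
similarities over level-3 codes are provided:

* a hierarchy similarity, the level of the nearest common ancestor divided
  by the number of levels (three for level-3 codes), taking values in
  {0, 1/3, 2/3, 1};
* an empirical similarity calibrated on an external patient->code
  co-occurrence corpus: the Jaccard score of each pair is compared against
  degree-preserving shuffles of the patient-code bipartite graph, and the
  similarity is the fraction of shuffles the observed score strictly exceeds.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import hierarchy_data as _hd

__all__ = [
    "ICDCode",
    "ICDParseError",
    "ICDHierarchy",
    "ICDSimilarityMatrix",
    "CooccurrenceCorpus",
    "parse_icd",
    "filter_codes",
    "hierarchy_similarity",
    "jaccard_cooccurrence",
    "shuffle_corpus",
    "empirical_similarity",
]


class ICDParseError(ValueError):
    """Raised when a string is not a syntactically valid ICD-9-CM code."""


_DIAG_RE = re.compile(r"^(\d{3})(?:\.(\d{1,2}))?$")
_V_RE = re.compile(r"^(V\d{2})(?:\.(\d{1,2}))?$")
_E_RE = re.compile(r"^(E\d{3})(?:\.(\d))?$")
_PROC_RE = re.compile(r"^(\d{2})(?:\.(\d{1,2}))?$")


@dataclass(frozen=True, order=True)
class ICDCode:
    """A parsed ICD-9-CM diagnosis, procedure, V- or E-code.

    ``level`` counts hierarchy depth below the block layer: 3 for a bare
    root ("428", "V45", two-digit procedure root), 4 and 5 with one and two
    digits of decimal detail.
    """

    raw: str
    kind: str = field(compare=False)  # diagnosis | procedure | supplementary-V | external-E
    level: int = field(compare=False)

    @property
    def root(self) -> str:
        """The level-3 (three-digit / two-digit / V-root) form."""
        return self.raw.split(".", 1)[0]

    def to_level3(self) -> "ICDCode":
        if self.level == 3:
            return self
        return ICDCode(self.root, self.kind, 3)

    @property
    def root_value(self) -> int:
        """Integer value of the numeric part of the root (V45 -> 45)."""
        return int(self.root.lstrip("VE"))

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return self.raw


def parse_icd(raw: str) -> ICDCode:
    """Parse an ICD-9-CM code string.

    Three-digit numeric roots are diagnoses, two-digit roots are procedure
    codes, V/E prefixes are the supplementary and external-cause
    classifications.  Decimal digits raise the level to 4 or 5.
    """
    if not isinstance(raw, str) or not raw.strip():
        raise ICDParseError(f"empty or non-string ICD code: {raw!r}")
    token = raw.strip().upper()
    for regex, kind in (
        (_DIAG_RE, "diagnosis"),
        (_V_RE, "supplementary-V"),
        (_E_RE, "external-E"),
        (_PROC_RE, "procedure"),
    ):
        m = regex.match(token)
        if m:
            detail = m.group(2) or ""
            return ICDCode(token, kind, 3 + len(detail))
    raise ICDParseError(f"malformed ICD-9 code: {raw!r}")


def filter_codes(codes: Iterable[ICDCode]) -> set[ICDCode]:
    """Apply the study inclusion rules to a set of codes.

    External-cause E-codes are dropped; supplementary V-codes are dropped
    except V40-V49 ("persons with a condition influencing their health
    status"); diagnosis roots in 630-679 (pregnancy) and 740-999
    (congenital/perinatal/symptoms/injury) are dropped.  Procedure codes and
    all remaining diagnoses are retained.
    """
    out: set[ICDCode] = set()
    for c in codes:
        if c.kind == "external-E":
            continue
        if c.kind == "supplementary-V":
            if 40 <= c.root_value <= 49:
                out.add(c)
            continue
        if c.kind == "diagnosis":
            v = c.root_value
            if 630 <= v <= 679 or 740 <= v <= 999:
                continue
        out.add(c)
    return out


def _range_label(value: int, ranges, default=None):
    for lo, hi, *rest in ranges:
        if lo <= value <= hi:
            return rest[0] if rest else f"{lo:03d}-{hi:03d}"
    return default


class ICDHierarchy:
    """Chapter/block ancestry for level-3 ICD codes.

    Each known code maps to an ancestor chain ``(chapter, block, root)``.
    Built either from the packaged ICD-9-CM range tables
    (:meth:`default`) or from a TSV with columns
    ``code, level3, block_label, chapter_label`` (:meth:`from_table`).
    """

    def __init__(self, chains: Mapping[str, tuple[str, str, str]]):
        self._chains = dict(chains)

    # -- construction -----------------------------------------------------
    @classmethod
    def default(cls, codes: Iterable[ICDCode]) -> "ICDHierarchy":
        """Place the given codes in the standard ICD-9-CM chapter/block grid."""
        chains: dict[str, tuple[str, str, str]] = {}
        for c in codes:
            c3 = c.to_level3()
            chains[c3.raw] = cls._standard_chain(c3)
        return cls(chains)

    @staticmethod
    def _standard_chain(code: ICDCode) -> tuple[str, str, str]:
        v = code.root_value
        if code.kind == "diagnosis":
            chapter = _range_label(v, _hd.DIAGNOSIS_CHAPTERS)
            block = _range_label(v, [(lo, hi) for lo, hi in _hd.DIAGNOSIS_BLOCKS])
        elif code.kind == "supplementary-V":
            chapter = _hd.V_CHAPTER
            block = "V" + (_range_label(v, [(lo, hi) for lo, hi in _hd.V_BLOCKS]) or "")
        elif code.kind == "external-E":
            chapter = _hd.E_CHAPTER
            block = f"E{v // 10 * 10}"
        else:  # procedure: no published block layer; root is its own block
            chapter = "proc:" + (_range_label(v, _hd.PROCEDURE_CHAPTERS) or "")
            block = f"proc:{code.root}"
        if chapter is None or block is None:
            raise KeyError(f"code {code.raw} falls outside the ICD-9-CM ranges")
        return (f"{code.kind}:{chapter}", f"{code.kind}:{block}", code.root)

    @classmethod
    def from_table(cls, path: str | Path) -> "ICDHierarchy":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"code", "level3", "block_label", "chapter_label"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"hierarchy table missing columns: {sorted(missing)}")
        chains = {
            row.level3: (row.chapter_label, row.block_label, row.level3)
            for row in df.itertuples()
        }
        return cls(chains)

    def to_table(self, path: str | Path) -> None:
        rows = [
            {"code": c, "level3": c, "block_label": b, "chapter_label": ch}
            for c, (ch, b, _) in sorted(self._chains.items())
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    # -- queries -----------------------------------------------------------
    def __contains__(self, code) -> bool:
        return self._root_of(code) in self._chains

    @property
    def codes(self) -> list[str]:
        return sorted(self._chains)

    @staticmethod
    def _root_of(code) -> str:
        return code.root if isinstance(code, ICDCode) else str(code).split(".", 1)[0]

    def chain(self, code) -> tuple[str, str, str]:
        root = self._root_of(code)
        try:
            return self._chains[root]
        except KeyError:
            raise KeyError(f"code {root!r} not in hierarchy") from None

    def nca_level(self, ci, cj) -> int:
        """Level of the nearest common ancestor: 1 chapter, 2 block, 3 code; 0 none."""
        a, b = self.chain(ci), self.chain(cj)
        level = 0
        for x, y in zip(a, b):
            if x != y:
                break
            level += 1
        return level

    def ancestor_at(self, code, level: int) -> str:
        """The chapter (level 1), block (level 2) or root (level 3) of a code."""
        return self.chain(code)[level - 1]


def hierarchy_similarity(ci, cj, h: ICDHierarchy) -> float:
    """Nearest-common-ancestor similarity NCA/3 for two level-3 codes."""
    return h.nca_level(ci, cj) / 3.0


@dataclass
class ICDSimilarityMatrix:
    """Symmetric code-by-code similarity in [0, 1].

    ``tag`` is "hierarchy" or "empirical".  ``codes`` fixes row/column order.
    """

    codes: list[str]
    matrix: np.ndarray
    tag: str

    def __post_init__(self):
        self._index = {c: i for i, c in enumerate(self.codes)}

    def value(self, a, b) -> float:
        ra = ICDHierarchy._root_of(a)
        rb = ICDHierarchy._root_of(b)
        return float(self.matrix[self._index[ra], self._index[rb]])

    def index_of(self, code) -> int:
        return self._index[ICDHierarchy._root_of(code)]

    @classmethod
    def from_hierarchy(cls, h: ICDHierarchy, codes: Iterable | None = None) -> "ICDSimilarityMatrix":
        roots = sorted({ICDHierarchy._root_of(c) for c in codes}) if codes is not None else h.codes
        n = len(roots)
        chains = [h.chain(c) for c in roots]
        m = np.zeros((n, n))
        for i in range(n):
            for j in range(i, n):
                level = 0
                for x, y in zip(chains[i], chains[j]):
                    if x != y:
                        break
                    level += 1
                m[i, j] = m[j, i] = level / 3.0
        return cls(roots, m, "hierarchy")


class CooccurrenceCorpus:
    """Patient -> set of level-3 ICD codes, the empirical-similarity substrate."""

    def __init__(self, patient_codes: Mapping[str, Iterable[str]]):
        self.patients = sorted(patient_codes)
        self.codes = sorted({ICDHierarchy._root_of(c) for cs in patient_codes.values() for c in cs})
        self._code_index = {c: i for i, c in enumerate(self.codes)}
        # binary membership matrix, patients x codes
        self.membership = np.zeros((len(self.patients), len(self.codes)), dtype=bool)
        for i, p in enumerate(self.patients):
            for c in patient_codes[p]:
                self.membership[i, self._code_index[ICDHierarchy._root_of(c)]] = True

    @classmethod
    def from_table(cls, path: str | Path) -> "CooccurrenceCorpus":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if not {"patient_id", "icd_code"} <= set(df.columns):
            raise ValueError("corpus table requires columns patient_id, icd_code")
        for raw in df["icd_code"].unique():
            parse_icd(raw)  # validate
        grouped = df.groupby("patient_id")["icd_code"].apply(set)
        return cls(grouped.to_dict())

    def to_table(self, path: str | Path) -> None:
        rows = []
        for i, p in enumerate(self.patients):
            for j in np.flatnonzero(self.membership[i]):
                rows.append({"patient_id": p, "icd_code": self.codes[j]})
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @property
    def n_associations(self) -> int:
        return int(self.membership.sum())

    def per_patient_counts(self) -> np.ndarray:
        return self.membership.sum(axis=1)

    def per_code_counts(self) -> np.ndarray:
        return self.membership.sum(axis=0)

    @classmethod
    def _from_membership(cls, patients, codes, membership) -> "CooccurrenceCorpus":
        obj = cls.__new__(cls)
        obj.patients = list(patients)
        obj.codes = list(codes)
        obj._code_index = {c: i for i, c in enumerate(obj.codes)}
        obj.membership = membership
        return obj


def jaccard_cooccurrence(corpus: CooccurrenceCorpus) -> np.ndarray:
    """Pairwise Jaccard score between the patient sets of every code pair.

    J(a, b) = |patients with both| / |patients with either|; 0 on an empty
    union.  Returned in the corpus's code order.
    """
    m = corpus.membership.astype(np.float64)
    inter = m.T @ m
    counts = m.sum(axis=0)
    union = counts[:, None] + counts[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        j = np.where(union > 0, inter / np.maximum(union, 1e-300), 0.0)
    return j


def shuffle_corpus(corpus: CooccurrenceCorpus, seed: int,
                   swaps_per_edge: int = 10) -> CooccurrenceCorpus:
    """Degree-preserving shuffle of the patient-code bipartite graph.

    Repeated random edge swaps ((p1,c1),(p2,c2)) -> ((p1,c2),(p2,c1)),
    rejected when they would duplicate an existing association, preserve
    every patient's code count and every code's patient count exactly.
    """
    rng = np.random.default_rng(seed)
    pat_idx, code_idx = np.nonzero(corpus.membership)
    pat_idx = pat_idx.copy()
    code_idx = code_idx.copy()
    n_edges = len(pat_idx)
    if n_edges < 2:
        return CooccurrenceCorpus._from_membership(
            corpus.patients, corpus.codes, corpus.membership.copy())
    edge_set = set(zip(pat_idx.tolist(), code_idx.tolist()))
    n_swaps = swaps_per_edge * n_edges
    picks = rng.integers(0, n_edges, size=(n_swaps, 2))
    for e1, e2 in picks:
        if e1 == e2:
            continue
        p1, c1 = pat_idx[e1], code_idx[e1]
        p2, c2 = pat_idx[e2], code_idx[e2]
        if c1 == c2 or p1 == p2:
            continue
        if (p1, c2) in edge_set or (p2, c1) in edge_set:
            continue
        edge_set.discard((p1, c1))
        edge_set.discard((p2, c2))
        edge_set.add((p1, c2))
        edge_set.add((p2, c1))
        code_idx[e1], code_idx[e2] = c2, c1
    membership = np.zeros_like(corpus.membership)
    membership[pat_idx, code_idx] = True
    return CooccurrenceCorpus._from_membership(corpus.patients, corpus.codes, membership)


def empirical_similarity(corpus: CooccurrenceCorpus, n_shuffles: int = 100,
                         seed: int = 0) -> ICDSimilarityMatrix:
    """Shuffle-calibrated co-occurrence similarity.

    S(a, b) is the fraction of degree-preserving shuffles whose Jaccard
    score for (a, b) falls strictly below the observed one (ties count
    against).  The diagonal is fixed at 1: shuffles preserve J(a, a) = 1
    identically, and a code is maximally similar to itself.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    observed = jaccard_cooccurrence(corpus)
    wins = np.zeros_like(observed)
    seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=n_shuffles)
    for s in seeds:
        shuffled = shuffle_corpus(corpus, int(s))
        wins += observed > jaccard_cooccurrence(shuffled)
    sim = wins / n_shuffles
    np.fill_diagonal(sim, 1.0)
    return ICDSimilarityMatrix(list(corpus.codes), sim, "empirical")
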
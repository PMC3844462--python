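"""Cohort data model, tabular I/O and admission-time preprocessing.

A cohort is a set of hospitalizations, each carrying demographics, a
medical-history code set (union of past encounters, past discharge codes
and personal-history V-codes), the chronologically first lab/ECG values
from the first days of the stay, optional admission codes and a ranked
list of discharge codes.

Preprocessing mirrors admission-time information flow: keep only first
measurements inside the window, drop rare tests, keep tests whose
distribution differs between carriers and non-carriers of at least one
discharge code (rank-sum, BH-FDR), z-score against cohort statistics, and
drop hospitalizations with fewer than three available tests.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .icd import ICDCode, ICDParseError, filter_codes, parse_icd

logger = logging.getLogger(__name__)

__all__ = [
    "Hospitalization",
    "Cohort",
    "CohortStats",
    "EmptyPanelError",
    "load_cohort",
    "write_cohort",
    "select_first_measurements",
    "filter_tests",
    "zscore_panels",
    "bh_fdr",
]

VALID_GENDERS = frozenset({"F", "M"})


class EmptyPanelError(RuntimeError):
    """No lab test survived filtering."""


@dataclass(frozen=True)
class Hospitalization:
    """One admission with everything known at (or shortly after) admission."""

    hosp_id: str
    patient_id: str
    admission_ordinal: float
    age: float
    gender: str
    history: frozenset[str] = frozenset()          # level-3 code strings
    admission_codes: frozenset[str] = frozenset()  # level-3 code strings
    discharge_codes: tuple[str, ...] = ()          # ranked, best first
    lab_panel: Mapping[str, float] = field(default_factory=dict)
    ecg_panel: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.age < 0:
            raise ValueError(f"negative age for {self.hosp_id}")
        if self.gender not in VALID_GENDERS:
            raise ValueError(f"unknown gender {self.gender!r} for {self.hosp_id}")

    def primary_codes(self, n_top: int = 2) -> tuple[str, ...]:
        """The top-ranked discharge codes, the study's 'primary' truth set."""
        return self.discharge_codes[:n_top]


@dataclass
class CohortStats:
    """Per-test pooled statistics and filter decisions."""

    mean: dict[str, float]
    sd: dict[str, float]
    prevalence: dict[str, float]
    min_pvalue: dict[str, float]
    retained: list[str]


@dataclass
class Cohort:
    hospitalizations: list[Hospitalization]
    retained_tests: list[str] = field(default_factory=list)
    retained_ecg: list[str] = field(default_factory=list)
    stats: CohortStats | None = None
    ecg_stats: CohortStats | None = None

    def __post_init__(self):
        ids = [h.hosp_id for h in self.hospitalizations]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate hosp_id in cohort")

    def __len__(self) -> int:
        return len(self.hospitalizations)

    def __iter__(self):
        return iter(self.hospitalizations)

    @property
    def hosp_ids(self) -> list[str]:
        return [h.hosp_id for h in self.hospitalizations]

    @property
    def has_ecg(self) -> bool:
        return any(h.ecg_panel for h in self.hospitalizations)

    def code_universe(self) -> list[str]:
        """All retained level-3 discharge codes seen in the cohort, sorted."""
        return sorted({c for h in self for c in h.discharge_codes})

    def patient_true_codes(self) -> dict[str, set[str]]:
        """Per patient, the union of discharge codes over all admissions."""
        out: dict[str, set[str]] = {}
        for h in self:
            out.setdefault(h.patient_id, set()).update(h.discharge_codes)
        return out

    def subset(self, hosp_ids: Iterable[str]) -> "Cohort":
        keep = set(hosp_ids)
        return Cohort([h for h in self if h.hosp_id in keep],
                      self.retained_tests, self.retained_ecg,
                      self.stats, self.ecg_stats)


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

_FILES = ("hospitalizations", "history", "labs", "discharge")
_OPTIONAL_FILES = ("ecg", "admission")

_SCHEMAS = {
    "hospitalizations": {"hosp_id", "patient_id", "age", "gender"},
    "history": {"patient_id", "icd_code", "source"},
    "labs": {"hosp_id", "test_name", "day_offset", "value"},
    "ecg": {"hosp_id", "test_name", "day_offset", "value"},
    "discharge": {"hosp_id", "icd_code", "rank"},
    "admission": {"hosp_id", "icd_code"},
}


def _read(path: Path, name: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = _SCHEMAS[name] - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    return df


def _parse_codes(raw_codes: Iterable[str], where: str) -> list[ICDCode]:
    parsed, skipped = [], 0
    for raw in raw_codes:
        try:
            parsed.append(parse_icd(raw).to_level3())
        except ICDParseError:
            skipped += 1
    if skipped:
        logger.warning("%s: skipped %d unparseable ICD codes", where, skipped)
    return parsed


def select_first_measurements(events: pd.DataFrame, window_days: int = 3) -> dict[str, dict[str, float]]:
    """Per hospitalization and test, the chronologically first value within
    the first ``window_days`` days; later events are dropped.
    """
    if events.empty:
        return {}
    ev = events.copy()
    ev["day_offset"] = ev["day_offset"].astype(float)
    ev["value"] = ev["value"].astype(float)
    if (ev["day_offset"] < 0).any():
        raise ValueError("negative day_offset in measurement events")
    ev = ev[ev["day_offset"] < window_days]
    ev = ev.sort_values("day_offset", kind="stable")
    first = ev.groupby(["hosp_id", "test_name"], sort=False)["value"].first()
    panels: dict[str, dict[str, float]] = {}
    for (hid, test), val in first.items():
        panels.setdefault(hid, {})[test] = float(val)
    return panels


def load_cohort(directory: str | Path, window_days: int = 3,
                max_age: float = 120.0) -> Cohort:
    """Assemble a cohort from the TSV files in ``directory``.

    Expects hospitalizations.tsv, history.tsv, labs.tsv, discharge.tsv and
    optionally ecg.tsv and admission.tsv.  Discharge codes pass through the
    study inclusion filter; history is the union over its three sources.
    """
    d = Path(directory)
    tables = {}
    for name in _FILES:
        p = d / f"{name}.tsv"
        if not p.exists():
            raise FileNotFoundError(f"required cohort file missing: {p}")
        tables[name] = _read(p, name)
    for name in _OPTIONAL_FILES:
        p = d / f"{name}.tsv"
        tables[name] = _read(p, name) if p.exists() else None

    hosp = tables["hospitalizations"]
    if "admission_date" in hosp.columns:
        ordinals = pd.to_datetime(hosp["admission_date"]).map(pd.Timestamp.toordinal)
    elif "admission_rank" in hosp.columns:
        ordinals = hosp["admission_rank"].astype(float)
    else:
        raise ValueError("hospitalizations.tsv needs admission_date or admission_rank")

    history_by_patient: dict[str, set[str]] = {}
    for pid, grp in tables["history"].groupby("patient_id"):
        codes = filter_codes(_parse_codes(grp["icd_code"], "history"))
        history_by_patient[str(pid)] = {c.root for c in codes}

    lab_panels = select_first_measurements(tables["labs"], window_days)
    ecg_panels = (select_first_measurements(tables["ecg"], window_days)
                  if tables["ecg"] is not None else {})

    discharge_by_hosp: dict[str, tuple[str, ...]] = {}
    for hid, grp in tables["discharge"].groupby("hosp_id"):
        grp = grp.assign(rank=grp["rank"].astype(int)).sort_values("rank")
        ranked = []
        for raw in grp["icd_code"]:
            try:
                code = parse_icd(raw).to_level3()
            except ICDParseError:
                logger.warning("discharge: skipped unparseable code %r", raw)
                continue
            if filter_codes([code]) and code.root not in ranked:
                ranked.append(code.root)
        discharge_by_hosp[str(hid)] = tuple(ranked)

    admission_by_hosp: dict[str, frozenset[str]] = {}
    if tables["admission"] is not None:
        for hid, grp in tables["admission"].groupby("hosp_id"):
            codes = _parse_codes(grp["icd_code"], "admission")
            admission_by_hosp[str(hid)] = frozenset(c.root for c in codes)

    hospitalizations = []
    for row, ordv in zip(hosp.itertuples(), ordinals):
        age = float(row.age)
        if age > max_age:
            logger.warning("hosp %s: age %.0f capped to %.0f", row.hosp_id, age, max_age)
            age = max_age
        hid = str(row.hosp_id)
        hospitalizations.append(Hospitalization(
            hosp_id=hid,
            patient_id=str(row.patient_id),
            admission_ordinal=float(ordv),
            age=age,
            gender=str(row.gender),
            history=frozenset(history_by_patient.get(str(row.patient_id), set())),
            admission_codes=admission_by_hosp.get(hid, frozenset()),
            discharge_codes=discharge_by_hosp.get(hid, ()),
            lab_panel=lab_panels.get(hid, {}),
            ecg_panel=ecg_panels.get(hid, {}),
        ))
    return Cohort(hospitalizations)


def write_cohort(cohort: Cohort, directory: str | Path) -> None:
    """Write a cohort back out in the load_cohort TSV dialects."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([
        {"hosp_id": h.hosp_id, "patient_id": h.patient_id,
         "admission_rank": h.admission_ordinal, "age": h.age, "gender": h.gender}
        for h in cohort
    ]).to_csv(d / "hospitalizations.tsv", sep="\t", index=False)

    hist_rows, seen = [], set()
    for h in cohort:
        if h.patient_id in seen:
            continue
        seen.add(h.patient_id)
        for c in sorted(h.history):
            hist_rows.append({"patient_id": h.patient_id, "icd_code": c,
                              "source": "encounter"})
    pd.DataFrame(hist_rows, columns=["patient_id", "icd_code", "source"]).to_csv(
        d / "history.tsv", sep="\t", index=False)

    def _panel_rows(attr):
        rows = []
        for h in cohort:
            for test, val in sorted(getattr(h, attr).items()):
                rows.append({"hosp_id": h.hosp_id, "test_name": test,
                             "day_offset": 0, "value": val})
        return rows

    pd.DataFrame(_panel_rows("lab_panel"),
                 columns=["hosp_id", "test_name", "day_offset", "value"]).to_csv(
        d / "labs.tsv", sep="\t", index=False)
    if cohort.has_ecg:
        pd.DataFrame(_panel_rows("ecg_panel"),
                     columns=["hosp_id", "test_name", "day_offset", "value"]).to_csv(
            d / "ecg.tsv", sep="\t", index=False)

    dis_rows = []
    for h in cohort:
        for rank, c in enumerate(h.discharge_codes, start=1):
            dis_rows.append({"hosp_id": h.hosp_id, "icd_code": c, "rank": rank})
    pd.DataFrame(dis_rows, columns=["hosp_id", "icd_code", "rank"]).to_csv(
        d / "discharge.tsv", sep="\t", index=False)

    adm_rows = [{"hosp_id": h.hosp_id, "icd_code": c}
                for h in cohort for c in sorted(h.admission_codes)]
    if adm_rows:
        pd.DataFrame(adm_rows).to_csv(d / "admission.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# Test filtering and z-scoring
# ---------------------------------------------------------------------------

def bh_fdr(pvalues, q: float) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at level ``q``."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    thresh = q * (np.arange(1, m + 1) / m)
    below = p[order] <= thresh
    mask = np.zeros(m, dtype=bool)
    if below.any():
        k = np.max(np.nonzero(below)[0])
        mask[order[: k + 1]] = True
    return mask


def _panel_frame(cohort: Cohort, attr: str) -> pd.DataFrame:
    """Wide hosp x test frame (NaN = not measured), test columns sorted."""
    records = {h.hosp_id: dict(getattr(h, attr)) for h in cohort}
    df = pd.DataFrame.from_dict(records, orient="index")
    df = df.reindex(index=cohort.hosp_ids)
    return df[sorted(df.columns)] if len(df.columns) else df


def filter_tests(cohort: Cohort, min_prevalence: float = 0.05,
                 fdr_q: float = 0.01, min_group: int = 20,
                 panel: str = "lab_panel") -> tuple[list[str], CohortStats]:
    """Select informative tests and compute pooled cohort statistics.

    Tests measured in fewer than ``min_prevalence`` of hospitalizations are
    dropped.  Each surviving test is rank-sum-compared, for every discharge
    code carried by at least ``min_group`` hospitalizations, between carriers
    and non-carriers; a test is retained when at least one comparison
    survives BH-FDR control at ``fdr_q`` over all (test, code) comparisons.
    """
    df = _panel_frame(cohort, panel)
    n = len(cohort)
    if df.empty:
        raise EmptyPanelError(f"cohort has no {panel} measurements")
    prevalence = df.notna().mean(axis=0)
    candidates = [t for t in df.columns if prevalence[t] >= min_prevalence]
    if not candidates:
        raise EmptyPanelError("no test reaches the prevalence threshold")

    code_carriers: dict[str, np.ndarray] = {}
    all_codes = cohort.code_universe()
    truth = [set(h.discharge_codes) for h in cohort]
    for code in all_codes:
        mask = np.fromiter((code in t for t in truth), dtype=bool, count=n)
        if mask.sum() >= min_group and (~mask).sum() >= min_group:
            code_carriers[code] = mask

    pairs, pvals = [], []
    for t in candidates:
        vals = df[t].to_numpy(dtype=float)
        measured = ~np.isnan(vals)
        for code, carriers in code_carriers.items():
            a = vals[measured & carriers]
            b = vals[measured & ~carriers]
            if len(a) < 3 or len(b) < 3:
                continue
            try:
                p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
            except ValueError:  # all values identical
                p = 1.0
            pairs.append((t, code))
            pvals.append(p)

    retained: list[str]
    min_p: dict[str, float] = {t: 1.0 for t in candidates}
    if pairs:
        mask = bh_fdr(pvals, fdr_q)
        sig_tests = {t for (t, _), rej in zip(pairs, mask) if rej}
        for (t, _), p in zip(pairs, pvals):
            min_p[t] = min(min_p[t], p)
        retained = [t for t in candidates if t in sig_tests]
    else:
        # no code group large enough to test against: keep prevalent tests
        retained = list(candidates)
    if not retained:
        raise EmptyPanelError("no test survives the rank-sum FDR filter")

    mean, sd = {}, {}
    for t in retained:
        vals = df[t].dropna().to_numpy(dtype=float)
        s = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        if s <= 0:
            warnings.warn(f"test {t!r} has zero variance; excluded")
            continue
        mean[t] = float(vals.mean())
        sd[t] = s
    retained = [t for t in retained if t in mean]
    if not retained:
        raise EmptyPanelError("no retained test has positive variance")
    stats_obj = CohortStats(mean=mean, sd=sd,
                            prevalence={t: float(prevalence[t]) for t in retained},
                            min_pvalue={t: min_p[t] for t in retained},
                            retained=retained)
    return retained, stats_obj


def zscore_panels(cohort: Cohort, min_tests: int = 3, *,
                  lab_kwargs: dict | None = None,
                  ecg_kwargs: dict | None = None) -> Cohort:
    """Filter tests, z-score panels and drop sparse hospitalizations.

    Lab and (when present) ECG panels go through the identical pipeline:
    filter_tests -> (value - mean) / sd -> drop hospitalizations with fewer
    than ``min_tests`` available retained lab tests.
    """
    retained, st = filter_tests(cohort, **(lab_kwargs or {}))
    has_ecg = cohort.has_ecg
    if has_ecg:
        # ECG panels go through the identical filter machinery
        retained_ecg, st_ecg = filter_tests(cohort, panel="ecg_panel",
                                            **(ecg_kwargs or {}))
    else:
        retained_ecg, st_ecg = [], None

    survivors = [h for h in cohort
                 if sum(t in h.lab_panel for t in retained) >= min_tests]
    if not survivors:
        raise EmptyPanelError("no hospitalization has enough retained tests")

    # pool the normalization statistics over the hospitalizations that stay
    def _restats(hosps, names, attr, stt):
        mean, sd = {}, {}
        for t in names:
            vals = np.array([getattr(h, attr)[t] for h in hosps
                             if t in getattr(h, attr)], dtype=float)
            s = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
            if s <= 0:
                warnings.warn(f"test {t!r} has zero variance after drop; excluded")
                continue
            mean[t], sd[t] = float(vals.mean()), s
        kept_names = [t for t in names if t in mean]
        new = CohortStats(mean=mean, sd=sd,
                          prevalence={t: stt.prevalence.get(t, float("nan"))
                                      for t in kept_names},
                          min_pvalue={t: stt.min_pvalue.get(t, 1.0)
                                      for t in kept_names},
                          retained=kept_names)
        return kept_names, new

    retained, st = _restats(survivors, retained, "lab_panel", st)
    if not retained:
        raise EmptyPanelError("no retained test has positive variance")
    if has_ecg:
        retained_ecg, st_ecg = _restats(survivors, retained_ecg, "ecg_panel", st_ecg)

    def _z(panel, names, stt):
        return {t: (panel[t] - stt.mean[t]) / stt.sd[t]
                for t in names if t in panel}

    kept = [replace(h,
                    lab_panel=_z(h.lab_panel, retained, st),
                    ecg_panel=_z(h.ecg_panel, retained_ecg, st_ecg) if has_ecg else {})
            for h in survivors]
    return Cohort(kept, retained_tests=retained, retained_ecg=retained_ecg,
                  stats=st, ecg_stats=st_ecg)
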
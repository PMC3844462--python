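"""Seeded synthetic EHR cohorts and co-occurrence corpora.

The generator emulates the statistical structure the inference method
feeds on, with every association strength exposed as a dial:

* a toy ICD hierarchy (default 5 chapters x 3 blocks x 4 codes = 60 codes,
  numeric roots 100-249, all inside the study inclusion ranges) small enough
  for exhaustive oracles yet deep enough to exercise every ancestor level;
* per-code prevalence following a power law (exponent 0 = uniform null);
* diagnosis-conditional lab values: each code shifts its two informative
  tests by ``lab_shift`` baseline standard deviations;
* medical histories that echo a patient's condition codes with probability
  ``history_fidelity`` (or a block neighbor), plus random noise codes;
* admission symptom codes mapped from the primary code's block;
* an external corpus whose designated (same-block) code pairs co-occur more
  often than independence.

With ``lab_shift = 0``, ``history_fidelity = 0`` and uniform prevalence the
cohort carries no exploitable association of any kind (the null preset).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .cohort import Cohort, Hospitalization, write_cohort
from .icd import CooccurrenceCorpus, ICDHierarchy

__all__ = ["GeneratorConfig", "toy_hierarchy", "toy_codes",
           "generate_cohort", "generate_corpus", "generate_files"]

_SYMPTOM_BASE = 780  # symptom roots 780.. (one per toy block)


@dataclass(frozen=True)
class GeneratorConfig:
    """All dials of the synthetic cohort; defaults are the study conditions."""

    n_hospitalizations: int = 1000
    readmission_prob: float = 0.3          # geometric extra-admission chance
    n_chapters: int = 5
    n_blocks_per_chapter: int = 3
    n_codes_per_block: int = 4
    prevalence_exponent: float = 0.8       # Zipf over the code universe; 0 = uniform
    max_codes_per_admission: int = 3
    condition_persistence: float = 0.8     # chance a patient condition recurs
    acute_rate: float = 0.3                # chance of an extra per-admission code
    lab_shift: float = 2.0                 # sd units on informative tests
    n_tests: int = 20
    informative_tests_per_code: int = 2
    missingness: float = 0.25
    history_fidelity: float = 0.6          # condition code echoed into history
    history_block_neighbor_prob: float = 0.15
    history_noise_rate: float = 1.0        # Poisson mean of random history codes
    ecg: bool = True
    n_ecg: int = 9                         # 8 intervals + heart rate
    ecg_shift_factor: float = 0.5          # ECG shift = factor * lab_shift
    ecg_missingness: float = 0.2
    admission_codes: bool = True
    admission_confusion: float = 0.2       # chance of a random symptom code
    age_preset: str = "median63"           # or "median73" (older cohort)
    n_corpus_patients: int = 2000
    corpus_codes_mean: float = 2.0         # Poisson mean above the first code
    cooccurrence_boost: float = 0.4        # chance the next corpus code is a block partner

    @classmethod
    def null(cls, **overrides) -> "GeneratorConfig":
        """Zero-signal preset: no lab shift, no history echo, uniform
        prevalence, no co-occurrence boosts, uninformative admission codes."""
        base = cls(lab_shift=0.0, history_fidelity=0.0,
                   history_block_neighbor_prob=0.0, prevalence_exponent=0.0,
                   cooccurrence_boost=0.0, admission_confusion=1.0,
                   ecg_shift_factor=0.0)
        return replace(base, **overrides)

    @property
    def n_codes(self) -> int:
        return self.n_chapters * self.n_blocks_per_chapter * self.n_codes_per_block


def toy_codes(cfg: GeneratorConfig) -> list[str]:
    """Numeric roots 100, 101, ... laid out on the toy chapter/block grid."""
    codes = []
    for ch in range(cfg.n_chapters):
        for b in range(cfg.n_blocks_per_chapter):
            base = 100 + 10 * (ch * cfg.n_blocks_per_chapter + b)
            codes.extend(str(base + k) for k in range(cfg.n_codes_per_block))
    return codes


def toy_hierarchy(cfg: GeneratorConfig) -> ICDHierarchy:
    chains = {}
    codes = toy_codes(cfg)
    per_chapter = cfg.n_blocks_per_chapter * cfg.n_codes_per_block
    for i, c in enumerate(codes):
        ch, rest = divmod(i, per_chapter)
        b = rest // cfg.n_codes_per_block
        chains[c] = (f"toy-chapter-{ch}", f"toy-block-{ch}.{b}", c)
    return ICDHierarchy(chains)


def _prevalence(cfg: GeneratorConfig) -> np.ndarray:
    ranks = np.arange(1, cfg.n_codes + 1, dtype=float)
    w = ranks ** (-cfg.prevalence_exponent)
    return w / w.sum()


def _block_of(i: int, cfg: GeneratorConfig) -> int:
    return i // cfg.n_codes_per_block


def _block_members(cfg: GeneratorConfig) -> list[np.ndarray]:
    n_blocks = cfg.n_chapters * cfg.n_blocks_per_chapter
    return [np.arange(b * cfg.n_codes_per_block, (b + 1) * cfg.n_codes_per_block)
            for b in range(n_blocks)]


def _informative_tests(cfg: GeneratorConfig, n_channels: int, per_code: int) -> np.ndarray:
    """code x channel indicator of which channels a code shifts (round-robin)."""
    ind = np.zeros((cfg.n_codes, n_channels), dtype=bool)
    for i in range(cfg.n_codes):
        for k in range(per_code):
            ind[i, (per_code * i + k) % n_channels] = True
    return ind


def _sample_age(rng: np.random.Generator, preset: str) -> float:
    if preset == "median73":
        return float(np.clip(rng.normal(73, 12), 20, 105))
    return float(np.clip(rng.normal(63, 15), 15, 90))


def generate_cohort(cfg: GeneratorConfig, seed: int) -> Cohort:
    """Draw a complete synthetic cohort; deterministic given (cfg, seed)."""
    rng = np.random.default_rng(seed)
    codes = toy_codes(cfg)
    prev = _prevalence(cfg)
    blocks = _block_members(cfg)
    lab_info = _informative_tests(cfg, cfg.n_tests, cfg.informative_tests_per_code)
    ecg_info = _informative_tests(cfg, cfg.n_ecg, 1)
    test_names = [f"t{j:02d}" for j in range(cfg.n_tests)]
    ecg_names = [f"e{j:02d}" for j in range(cfg.n_ecg)]
    ecg_shift = cfg.ecg_shift_factor * cfg.lab_shift

    hosps: list[Hospitalization] = []
    pid = 0
    while len(hosps) < cfg.n_hospitalizations:
        pid += 1
        patient = f"P{pid:05d}"
        n_adm = 1 + rng.geometric(1 - cfg.readmission_prob) - 1 \
            if cfg.readmission_prob > 0 else 1
        n_adm = min(n_adm, 3, cfg.n_hospitalizations - len(hosps))
        if n_adm == 0:
            break
        n_cond = int(rng.integers(1, cfg.max_codes_per_admission + 1))
        conditions = rng.choice(cfg.n_codes, size=n_cond, replace=False, p=prev)
        age = _sample_age(rng, cfg.age_preset)
        gender = "F" if rng.random() < 0.5 else "M"

        # draw every admission's discharge list first, so the patient-level
        # history can echo each true discharge code with exactly
        # ``history_fidelity`` (histories include past discharge codes)
        discharges = []
        for _ in range(n_adm):
            discharge = [int(c) for c in conditions
                         if rng.random() < cfg.condition_persistence]
            if rng.random() < cfg.acute_rate:
                discharge.append(int(rng.choice(cfg.n_codes, p=prev)))
            if not discharge:
                discharge = [int(conditions[0])]
            discharge = list(dict.fromkeys(discharge))[: cfg.max_codes_per_admission]
            rng.shuffle(discharge)
            discharges.append(discharge)

        history: set[str] = set()
        for ci in sorted({c for d in discharges for c in d}):
            u = rng.random()
            if u < cfg.history_fidelity:
                history.add(codes[ci])
            elif u < cfg.history_fidelity + cfg.history_block_neighbor_prob:
                history.add(codes[int(rng.choice(blocks[_block_of(ci, cfg)]))])
        for _ in range(rng.poisson(cfg.history_noise_rate)):
            history.add(codes[int(rng.choice(cfg.n_codes, p=prev))])

        for a, discharge in enumerate(discharges):

            lab = {}
            for j in range(cfg.n_tests):
                if rng.random() < cfg.missingness:
                    continue
                shift = cfg.lab_shift * sum(lab_info[ci, j] for ci in discharge)
                lab[test_names[j]] = float(rng.normal(shift, 1.0))
            ecg = {}
            if cfg.ecg:
                for j in range(cfg.n_ecg):
                    if rng.random() < cfg.ecg_missingness:
                        continue
                    shift = ecg_shift * sum(ecg_info[ci, j] for ci in discharge)
                    ecg[ecg_names[j]] = float(rng.normal(shift, 1.0))

            admission: frozenset[str] = frozenset()
            if cfg.admission_codes:
                if rng.random() < cfg.admission_confusion:
                    block = int(rng.integers(0, len(blocks)))
                else:
                    block = _block_of(discharge[0], cfg)
                admission = frozenset({str(_SYMPTOM_BASE + block)})

            hosps.append(Hospitalization(
                hosp_id=f"H{len(hosps) + 1:05d}",
                patient_id=patient,
                admission_ordinal=float(len(hosps) + 1),
                age=round(age + a, 1),
                gender=gender,
                history=frozenset(history),
                admission_codes=admission,
                discharge_codes=tuple(codes[c] for c in discharge),
                lab_panel=lab,
                ecg_panel=ecg,
            ))
    return Cohort(hosps)


def generate_corpus(cfg: GeneratorConfig, seed: int) -> CooccurrenceCorpus:
    """External patient->code corpus with same-block co-occurrence boosts."""
    rng = np.random.default_rng(seed)
    codes = toy_codes(cfg)
    prev = _prevalence(cfg)
    patients: dict[str, set[str]] = {}
    for p in range(cfg.n_corpus_patients):
        n_extra = int(rng.poisson(cfg.corpus_codes_mean))
        chosen = [int(rng.choice(cfg.n_codes, p=prev))]
        for _ in range(n_extra):
            if chosen and rng.random() < cfg.cooccurrence_boost:
                anchor = int(rng.choice(chosen))
                block = _block_members(cfg)[_block_of(anchor, cfg)]
                chosen.append(int(rng.choice(block)))
            else:
                chosen.append(int(rng.choice(cfg.n_codes, p=prev)))
        patients[f"C{p:06d}"] = {codes[c] for c in chosen}
    return CooccurrenceCorpus(patients)


def generate_files(cfg: GeneratorConfig, seed: int, out_dir: str | Path) -> Path:
    """Write a full synthetic dataset: cohort TSVs, hierarchy.tsv, corpus.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(cfg, seed)
    write_cohort(cohort, out)
    toy_hierarchy(cfg).to_table(out / "hierarchy.tsv")
    generate_corpus(cfg, seed + 1).to_table(out / "corpus.tsv")
    return out
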
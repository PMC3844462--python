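# Methods

This note documents the models, procedures and numerical choices behind
`dischargedx`, the assumptions they rest on, and what the synthetic cohorts
do and do not establish about real EHR data.

## ICD-9-CM representation

Codes are parsed into four kinds — diagnosis (3-digit root), procedure
(2-digit root), supplementary V and external-cause E — with levels 3–5
according to decimal detail. All similarity computation operates on the
level-3 truncation. The study inclusion rules drop E-codes, V-codes other
than V40–V49, pregnancy codes (630–679) and the uninformative /
incidental ranges 740–999.

The hierarchy places each level-3 code in a chapter → block → code chain.
For diagnoses the packaged tables follow the standard ICD-9-CM tabular
list. Procedure codes use the Volume-3 body-system ranges as chapters;
Volume 3 publishes no intermediate block layer, so each 2-digit root
doubles as its own block (two distinct same-chapter roots therefore score
1/3). Codes of different kinds share no ancestor and score 0.

**Hierarchy similarity.** S = NCA/3 with chapter = 1, block = 2, code = 3.
For level-3 codes the denominator is fixed at three; the deeper 4th and
5th levels would only matter for full-detail codes, which the prediction
task never compares.

**Empirical similarity.** Jaccard scores over an external patient→code
corpus are calibrated against degree-preserving shuffles of the
patient–code bipartite graph (random edge swaps, rejected when they would
duplicate an edge; 10 swap attempts per association, a standard mixing
heuristic). The similarity is the fraction of shuffles the observed score
strictly exceeds — ties count against, making a never-co-occurring pair
exactly 0. Default 100 shuffles (configurable): the similarity is a
percentile, so its granularity is 1/n_shuffles, and 100 is enough for the
downstream maximum-based features while keeping the corpus stage linear in
corpus size. The diagonal is pinned to 1: shuffles preserve J(a,a) = 1
identically, so the strict percentile would otherwise declare every code
maximally dissimilar to itself and poison the history matching.

## Hospitalization similarities

- **History (MH1/MH2).** Profiles are matched by an exact maximum-weight
  one-to-one assignment (Jonker–Volgenant via
  `scipy.optimize.linear_sum_assignment`) on the complete bipartite graph
  with ICD-similarity weights, normalized by the smaller profile size;
  empty profiles score 0. Exact matching is cheap because history sets are
  small, and the cohort-level computation deduplicates identical history
  sets before the O(n²) pass.
- **Panels (BT1/BT2, ECG1/ECG2).** Only the chronologically first value of
  each test within the first three days of the stay is used. Tests are
  filtered (below) and z-scored; hospitalizations with fewer than three
  available retained blood tests are removed, and pairs sharing fewer than
  three tests receive similarity 0. BT1 is the Euclidean distance of the
  shared z-vectors divided by the number of shared tests n ("their
  length"; the √n alternative was evaluated and performs equivalently, so
  the more literal reading is kept). BT2 takes, for each hospitalization,
  the shared test with the largest |z| (ties broken by lexicographic test
  name, making the measure deterministic) and averages the two
  magnitude differences. Distances map to similarities by the global
  linear transform S = 1 − D/D_max with D_max the largest finite distance
  in the matrix — monotone, data-driven, and parameter-free; sub-threshold
  pairs map to 0. ECG channels flow through literally the same functions.
- **Demographics.** Age similarity 1 − |a_i−a_j|/max(a_i, a_j) (equal
  ages, including two newborns, score 1), gender an indicator.

## Blood-test filtering and normalization

Tests measured in under 5% of hospitalizations are dropped. Each surviving
test is compared (Wilcoxon rank-sum) between carriers and non-carriers of
every discharge code held by at least 20 hospitalizations on each side; a
test is retained when any comparison survives Benjamini–Hochberg control
at FDR 0.01 across all (test, code) comparisons. The grouping is
deliberately per-code with an any-significant retention rule — the most
conservative reading that still admits multi-disease markers. The BH
step-up is implemented directly (it is a first-class operation here) and
cross-checked against `statsmodels.multipletests` in the test suite.
z-statistics (mean, sd) are pooled over the hospitalizations that remain
after the fewer-than-three-tests drop, so retained tests have exactly zero
mean and unit variance in the final cohort. A cohort where no test
survives raises an explicit error rather than continuing with empty
panels.

## Features and classifier

Score(H, I) = max over known associations (H′, I′) ≠ (H, I) of
√(S(H,H′)·S(I,I′)), with all hospitalizations of H's own patient masked —
the dominant leakage channel for patients with recurrent admissions. Both
ICD measures are crossed with all eight hospitalization measures (the
history measures' internal ICD choice notwithstanding), giving 16 features
with ECG and 12 without. The known-association universe is always the
positive associations of the current training partition only: features for
held-out or validation rows are computed against training positives, and
a training positive is featurized leave-one-out (its own pair excluded).
The classifier is an unpenalized maximum-likelihood logistic regression
(binomial/logit); probabilities are used only for ranking and
threshold-sweeping, never calibrated.

## Evaluation

- **Positives.** The "primary" truth set is the two top-ranked discharge
  codes per hospitalization; an option widens truth to all discharge codes.
- **Negatives.** Pre-admission: per hospitalization, codes sampled
  uniformly from the retained universe minus every true code of that
  patient, matched 1:1 to the positives (ratio configurable).
  Post-admission: the pool is the union of discharge codes of other
  hospitalizations sharing an admission code, minus the patient's own.
- **Cross-validation.** Folds partition association rows (not patients;
  same-patient masking already removes the dominant leakage channel, and
  row-level folds keep every fold's class balance). Each run draws a fresh
  negative set and fold partition; features are recomputed per fold
  against training-fold positives. AUC is the rank statistic over pooled
  held-out scores (identical to trapezoidal ROC integration); best F1
  sweeps all distinct thresholds.
- **Prospective validation.** Chronological split (default first 2/3 by
  admission ordinal). Every retained code is scored for each validation
  hospitalization; ranking ties break lexicographically for determinism.
  Top-k precision is the fraction of hospitalizations with at least one
  true code in the top k, at ICD level 3 (code), 2 (block) and 1
  (chapter); it is non-decreasing in k and in coarsening by construction.
- **Per-code significance.** The count of hospitalizations where a code is
  both in the top-10 predictions and true is compared to degree-preserving
  shuffles of the truth association sets; p-values use the add-one rule
  (never exactly 0), BH-controlled at FDR 0.05. Tests default to a few
  hundred shuffles (the add-one floor 1/(n+1) bounds the smallest
  attainable p, so the shuffle count must exceed the number of codes
  divided by the FDR level for any rejection to be possible).
- **Enrichment sanity check.** Per (test, code), a hypergeometric tail
  test of the overlap between extreme-value hospitalizations (|z| above
  the cut, default 2) and code carriers, over the hospitalizations in
  which the test was measured; BH at FDR 0.01.

## Synthetic cohorts

The generator emulates: 60 level-3 codes on a 5-chapter × 3-block × 4-code
toy grid (small enough for exhaustive matching and ancestor-chain oracles,
deep enough to exercise every NCA level); Zipf(0.8) code prevalence;
patients with 1–3 persistent conditions, geometric readmissions, and
occasional acute codes; 20 lab tests of which each code shifts two by a
configurable number of baseline standard deviations, with 25% missingness;
nine ECG channels (one per code, at half the lab shift); histories that
echo each code of the patient's discharge-code union with exactly the
configured fidelity (default 0.6), occasionally substituting a block
neighbor, plus Poisson(1) random codes; admission symptom codes mapped
from the primary code's block with 20% confusion; and a 2,000-patient
co-occurrence corpus where same-block pairs are preferentially co-drawn.

The zero-signal preset removes *every* exploitable association: lab shift
0, history fidelity 0, no co-occurrence boosts, uninformative admission
codes — and uniform prevalence, because with skewed prevalence and uniform
negative sampling the maximum-based features legitimately learn code
frequency and the null AUC would sit above chance without any
patient-level signal. On a null cohort the rank-sum test filter correctly
rejects every test (by design it errors rather than returning an empty
panel); null-calibration runs therefore disable it (FDR threshold 1.0) to
exercise the downstream machinery.

What the synthetic experiments show: the pipeline recovers planted
diagnosis–lab and diagnosis–history associations (cross-validated
AUC ≈ 0.85 and top-10 level-3 precision ≈ 0.85 at 1,000 admissions,
2-sd shifts, fidelity 0.6), calibrates to chance on the null, and is
insensitive to the negative:positive ratio. What they do not show:
performance on real EHR data, whose lab panels are larger and collinear,
whose histories are far richer and temporally structured, and whose code
assignment carries billing bias — none of which the generator models.
Problem sizes (1,000 admissions, 60 codes, 2,000 corpus patients) were
chosen so all similarity matrices fit comfortably in memory and a full
evaluation completes in minutes; the framework itself is O(n²) in
hospitalizations and was designed for cohorts up to ~20k.

## Pipeline and reproducibility

Every random draw (generator, negative sampling, fold partitions,
shuffles) flows from explicit integer seeds; identical configuration and
seed reproduce reports bit-for-bit, and each report embeds the config
digest and seed. Similarity matrices are computed once per cohort and held
in memory across CV folds and runs — the O(n²) similarity step dominates
runtime, and reusing the in-memory matrices makes on-disk content-hash
caching of intermediates unnecessary at supported cohort sizes.

## Known limitations

- The "extremes" panel measure follows the most literal reading of an
  ambiguous construction and is isolated in one function so alternates can
  be swapped.
- Empirical ICD similarity is a percentile against a shuffle null, so rare
  code pairs with a single chance co-occurrence can score high; the
  hierarchy measure is unaffected and dominates in practice.
- CV folds partition association rows, so two rows of one hospitalization
  can fall in different folds; the self-patient mask removes the resulting
  similarity leakage but the two rows share panel noise.
- Merged multi-site cohorts, ICD-10/SNOMED, lab-value unit conversion and
  temporal history weighting are out of scope.
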
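# Methods

## Problem and data model

Post-marketing drug regulation in China assigns each drug to one of three
risk levels — prescription (Rx, label 0), over-the-counter class A (OTC-A,
label 1) and class B (OTC-B, label 2), with risk ordered Rx > OTC-A >
OTC-B.  `pharmrisk` implements a classification pipeline that predicts a
drug's risk level from its spontaneous adverse-drug-reaction (ADR) report
profile.  The unit of information is one report row: report id, region,
age, gender, drug name, ADR symptom term.  A report mentioning several
symptoms is represented as several rows; every cleaned row increments the
(drug, ADR) mention count by one.

Real spontaneous-report databases of this kind are confidential, so the
package ships a generator (`pharmrisk.simulate`) that emulates their
statistical structure and makes every downstream stage testable and seeded.

## Pipeline stages

1. **ETL** (`pharmrisk.etl`).  Rows with a missing drug name or symptom are
   dropped ("no reference value"); exact duplicates on the triple
   `(report_id, drug_name, adr_symptom)` are dropped keeping the first
   occurrence.  The triple — rather than any fuzzier key — makes
   deduplication deterministic, and two reports that agree on drug and
   symptom but not report id are deliberately both kept.  Term
   standardisation is driven by an explicit synonym map that must be
   idempotent; no fuzzy matching is attempted.  Drugs or terms with zero
   cleaned records are dropped (the signal statistic below is undefined on
   empty margins).

2. **Signal detection** (`pharmrisk.disproportionality`).  For each drug
   *i* and ADR term *j* the mention counts fold into the 2×2 table
   (A, B, C, D) and the proportional reporting ratio

       PRR = (A / (A + B)) / (C / (C + D)),

   the standard disproportionality statistic for spontaneous-report data.
   Zero handling is configurable because the classical definition leaves
   it open: A = 0 gives PRR = 0 (no mention, no signal; this preserves the
   count matrix's sparsity pattern exactly), and A > 0 with C = 0 uses the
   Haldane–Anscombe continuity correction (+0.5 on all four cells) by
   default, or a hard cap (default 100) when `zero_correction="cap"`.
   The resulting drugs × ADR-terms matrix with a per-drug label column is
   the dataset all models consume.

3. **Feature enhancement, FS-GAN** (`pharmrisk.enhancement`,
   `pharmrisk.gan`).  ADR features are ranked by total Gini impurity
   decrease accumulated over an auxiliary 100-tree random forest fit on
   the imbalanced signal matrix (selection happens *before* any
   balancing); scores are un-normalised so the total is exactly additive
   over trees, and ties break to the lower column index.  The top k = 200
   features form the training block of a small vanilla GAN; one generated
   k-vector per drug row is appended as new columns.  Nothing is ever
   deleted: dropping sparse ADR columns could silence rare but serious
   reactions, so the feature space only grows (d + k columns).

4. **SMOTE** (`pharmrisk.smote`).  Minority classes are oversampled by
   interpolating between a minority sample and one of its k = 5 nearest
   minority neighbours (Euclidean distance, ties to the lower sample
   index): `x_new = x + u (x̄ − x)`, u ~ U(0,1).  The default
   `exact_majority` mode grows each minority class to the majority count
   (887/113/47 → 887/887/887); `k_times` instead synthesises K·N⁻ samples
   with K = ⌊N⁺/N⁻⌋.  An `extrapolate` direction (`x + u (x − x̄)`) is
   provided for comparison; interpolation is the default because it is the
   canonical Chawla et al. construction and keeps every synthetic point on
   a segment between real minority samples.  The majority class is never
   resampled and no original row is ever dropped.

5. **Classification** (`pharmrisk.forest`).  A random forest: K = 100
   trees, each fit on a bootstrap of size N, best-Gini splits over
   ⌊√M⌋ randomly drawn features per node, grown to purity without pruning.
   Tree growing is delegated to scikit-learn (which implements exactly
   this); voting is done here — predicted label = majority of tree votes,
   ties to the lowest label index, scores = vote fractions.

6. **Evaluation** (`pharmrisk.metrics`).  Confusion matrix (rows = true),
   one-vs-rest precision/recall/F1 per class, accuracy, macro and
   class-size-weighted averages, one-vs-rest ROC by threshold sweep with
   trapezoidal AUC, macro AUC as the unweighted class mean.  Two macro-F1
   conventions circulate; the report's `macro.f1` is the mean of per-class
   F1 values and `macro.f1_harmonic` is the harmonic combination of
   macro-precision and macro-recall — the mean-of-F1 form is the one
   consistent with the weighted/macro tables this package reproduces in
   its tests.  Empty denominators yield 0 and a warning rather than NaN.

## Experiment designs and protocols

`pharmrisk.pipeline.run_experiment` compares three designs on one corpus:
Model 1 (PRR → RF), Model 2 (PRR → SMOTE → RF), Model 3 (PRR → FS-GAN →
SMOTE → RF).  The held-out protocol is a stratified 70/30 split with test
size ⌈0.3 n⌉ (so 1047 → 315 and 2661 → 799).  `split_mode="resample_first"`
(default) applies SMOTE/GAN to the full dataset *before* splitting — the
historical protocol, which lets synthetic neighbours of test points enter
training and therefore yields optimistic estimates; `split_mode=
"leak_free"` splits first and fits ranking, GAN and SMOTE on the training
partition only.  Both are provided deliberately: the first reproduces the
historical design, the second is the defensible measurement.

`validate_on_source` scores a trained model on all original (unaugmented,
unbalanced) drug rows.  A Model-3 forest expects d + k features while the
source matrix has d; the stored generated block from training is
re-attached row-aligned before scoring.  This padding rule is an
interpretation (no canonical answer exists for scoring un-enhanced data
with an enhanced-feature model) and is isolated in one function.

One master seed rederives every stage seed
(`ExperimentConfig.with_master_seed`), making full runs bit-reproducible.

## The synthetic-report generator

The generator emulates the structure of a provincial spontaneous-report
extract at desk scale: 1047 drugs split 887/113/47 (84.72 / 10.79 / 4.49%),
751 ADR terms, and a drug × ADR count matrix with ≈ 1.7% nonzero entries.

* Each risk class owns a pool of class-typical terms; pools of adjacent
  classes overlap 30%, so classification is learnable but not trivially
  separable.  Each drug samples a small personal vocabulary from its class
  pool.
* A drug receives Poisson(λ) reports, λ = `reports_per_drug_mean`
  (default 50).  The per-drug report-count distribution of real extracts
  is unknown to us; Poisson is an assumption, and 50 reports/drug is the
  package's desk-scale choice (real extracts are an order of magnitude
  denser; nothing downstream depends on the absolute count beyond
  coverage).
* Each report's term comes from the drug's class vocabulary with
  probability `class_profile_shift` (default 0.8) and otherwise from a
  *shared* Zipf-shaped background law.  At shift 0 the mixture collapses
  to the shared background, making per-class term distributions identical
  by construction.
* The personal-vocabulary size and the Zipf exponent are solved
  numerically (Brent's method) from the expected-coverage identity
  E[#distinct terms] = Σ_t (1 − exp(−λ p_t)) — exact under Poisson
  totals — so the realised matrix density matches
  `target_nonzero_fraction` without trial and error.  Every vocabulary
  term is additionally guaranteed at least one mention (the vocabulary is
  defined from observed reports), a negligible density perturbation.
* Duplicate rows (`dup_rate`, exact copies) and incomplete rows
  (`invalid_rate`, missing drug or symptom) are injected at
  round(rate × n_base) each, then all rows are shuffled.  All randomness
  flows from one seeded generator; identical configs give byte-identical
  CSV output.

What the generator does **not** emulate: real term vocabularies or MedDRA
coding, temporal reporting trends, regional effects, drug–drug
interactions, and the correlation structure of real co-reporting.  Tests
passing on this corpus therefore demonstrate that the pipeline recovers
planted class structure under realistic sparsity and imbalance — not that
any particular accuracy carries over to confidential real data.

## GAN: architecture and numerical choices

Generator 64-d Gaussian noise → 128 → 128 (ReLU) → k (sigmoid);
discriminator k → 128 → 128 (ReLU) → 1 (sigmoid); Adam (β₁ = 0.5) at
2e-4 for both; batch 64; one discriminator step per generator step; 2000
epochs default.  Minimal stable settings for a ≈ 1000 × 200 block — all
exposed in `GanConfig`.

Two numerical choices matter on sparse PRR data:

* **Log scaling.**  PRR values are heavy-tailed (maxima in the thousands),
  so min-max normalisation on the raw scale crushes the entire "zero
  region" into ≈ 1e-5 of the unit interval, which a sigmoid output cannot
  resolve at these step counts; the generated block then badly
  overestimates the nonzero fraction.  Training therefore runs on
  log1p(PRR) before per-feature min-max scaling (`log_scale=True`
  default).  The transform is monotone, so generated values still lie
  within each feature's training min–max range after inversion.
* **Non-saturating generator loss.**  The literal minimax generator
  objective (descend log(1 − D(G(z)))) has vanishing gradients once the
  discriminator wins, which is the normal early state on sparse blocks;
  in practice the generator then drifts, emitting mid-range values.  The
  default is the standard non-saturating surrogate (ascend log D(G(z)));
  the literal loss remains available as `generator_loss="saturating"`.

Generated-data fidelity is judged by the sparsity criterion used
throughout: the fraction of entries above ε = 0.01 on the PRR scale
(exact zeros almost never occur in generator output, so a threshold is
needed to make "nonzero" well-defined).  On the full-scale corpus the
generated block's nonzero fraction tracks the selected real block's to
within ±0.02 from ≈ 1000 epochs onward across seeds; the test suite runs
the pipeline GAN at 1000 epochs on converged training diagnostics
(D(x) and D(G(z)) plateau) and the library default stays at 2000.

Generated columns are *not* class-conditioned and the i-th generated
vector is appended to the i-th drug row in fixed drug order; no per-drug
correspondence is claimed.  Mode-collapse diagnostics beyond the sparsity
and range checks are out of scope.

## Degenerate inputs and tie-breaks (summary)

* PRR: A = 0 → 0; C = 0 → Haldane or cap; A + B = 0 impossible after ETL
  (empty drugs dropped), raises if constructed directly.
* Ranking ties → lower column index; vote ties → lower label;
  neighbour-distance ties → lower sample index.
* SMOTE requires each minority class > k neighbours, else a
  `NeighborError` signals that resampling cannot run.
* Stratified splitting requires ≥ 2 samples per class.
* Constant ROC scores → AUC 0.5 with a "degenerate" warning.

## Known limitations

* The `resample_first` split protocol leaks synthetic-neighbour information into
  training by construction; use `leak_free` for honest generalisation
  estimates.
* `exact_majority` SMOTE and the K·N⁻ rule disagree on final class sizes
  whenever N⁺/N⁻ is not an integer; both are provided, neither is claimed
  canonical.
* The GAN is a plain unconditional vanilla GAN; it reproduces marginal
  sparsity and per-feature ranges, not the joint dependence structure of
  ADR co-reporting.
* All quantitative statements in this file are computed by the test suite
  (`tests/`) or the acceptance script on the synthetic corpus; no claims
  are made about confidential real-world report data.
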
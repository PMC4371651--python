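# Methods

## Model

A compound's effect on channel x ∈ {I_Kr, I_CaL, I_Na} at test
concentration [D] is a fractional conductance scaling

* inhibitor: S_x = 1 − 1/(1 + (IC50/[D])^n)
* agonist:  S_x = 1 + Emax/(1 + (EC50/[D])^n)

Only the ratio potency/[D] enters, so potencies and concentrations must
share one unit (canonically µM, converted on load). S is continuous and
monotone in [D]; an inhibitor passes exactly S = 0.5 at [D] = IC50
regardless of the Hill coefficient, and S_inhibitor(IC50·r) +
S_inhibitor(IC50/r) = 1 for any ratio r (logistic symmetry). Both identities
are enforced as property tests.

The classifier is the single ratio

    Z = (1 + a0·S_CaL + a1·S_Na) / (1 + a2·S_Kr),   a0, a1, a2 ≥ 0.

The numerator aggregates surviving depolarising conductance, the
denominator surviving repolarising conductance. Z is non-increasing in
S_Kr and non-decreasing in S_CaL and S_Na; for all-inhibitor profiles it is
bounded by [1/(1+a2), 1+a0+a1]. With no drug effect and unit coefficients
Z = 3/2. Coefficients are constrained non-negative throughout (including
during fitting) because a negative weight would invert the
repolarisation/depolarisation semantics of the score.

Decision rules: binary endpoints predict positive iff Z ≥ t_high (boundary
inclusive — any fixed convention works, it must only be consistent);
ternary endpoints predict prolong iff Z ≥ t_high, shorten iff Z ≤ t_low
(t_low ≤ t_high enforced), no-effect otherwise, so every compound receives
exactly one label.

## Handling of incomplete potency data

* A channel with no measurement scales by exactly 1: leaving the
  conductance unscaled is the only neutral choice under
  conductance-scaling semantics.
* A missing Hill coefficient defaults to n = 1, the standard pharmacology
  convention.
* A censored potency written `>X` (no effect seen up to the top test
  concentration) carries no usable Hill parameters and is loaded as a
  missing activity, with a log note.

## Evaluation protocol

**ROC.** For each binary question the score is swept over every distinct Z
value (plus the two all-positive/all-negative extremes); tied scores
collapse to one ROC vertex. The AUC is computed twice — trapezoidal area
under the swept curve, and the Mann–Whitney rank statistic with ties
counted ½ — and the two routes must agree to 1e-12 inside `roc_curve`
itself; the test suite additionally checks against scikit-learn's
implementation. Ternary datasets pose two one-vs-rest questions:
prolongation scored by Z and shortening scored by −Z, so "higher
discriminant = more positive" holds for both. A question with zero
positives is skipped with a warning.

**Cross-validation.** Leave-one-out: each compound is predicted by a rule
fitted on the remaining n−1; folds whose training set collapses to one
class are excluded from the metrics and counted. Binary performance is
summarised by sensitivity, specificity and balanced accuracy from the
aggregated fold confusion table; ternary performance by per-direction
one-vs-rest metrics (prolongation, shortening), reported per direction and
as their mean, so users can compare against either convention.
Zero-denominator metrics return NaN (undefined), never an error.

## The coefficient optimiser

Three coefficients and one or two thresholds are few enough that a
deterministic exhaustive search is preferable to an iterative optimiser:

1. coarse per-coefficient grid {0, 0.25, 0.5, 1, 2, 4} (216 combinations);
2. for each combination, an exhaustive threshold sweep over the midpoints
   of consecutive distinct training-Z values plus the two extremes — for
   ternary rules the two directions decouple (prolongation depends only on
   t_high, shortening only on t_low), and the joint optimum over
   t_low ≤ t_high is taken on the candidate grid;
3. a local multiplicative refinement (factors 2/3, 0.8, 1, 1.25, 1.5)
   around the best coarse point; coefficients at 0 are refined against a
   small positive alternative (0.125).

The objective is balanced accuracy (ternary: mean of the per-direction
one-vs-rest balanced accuracies). Equal objectives break ties toward the
lexicographically smallest (a0, a1, a2) and the smallest threshold, making
the whole pipeline bitwise reproducible: identical data and configuration
give byte-identical reports.

Because the objective is piecewise constant with broad plateaus at small
n, distinct coefficient vectors frequently tie or nearly tie; the
tie-break prefers small vectors (including a2 = 0) on such plateaus. This
is a known identifiability limit, not a search failure — on synthetic
replicates where the fitted coefficients differ from the generating truth,
the training objective at the fit matches or exceeds the objective at the
truth.

## Synthetic-data generator

The generator emulates the structure of multi-channel HTS safety panels:

* per channel, presence with probability 1 − missing_rate (default 0.15);
* hERG activities are always inhibitory; ICaL/INa activities are agonist
  with probability agonist_rate (default 0.05, Emax ~ U[0.5, 2]);
* potencies log-uniform over potency_log10_range (default [−2, 2]) relative
  to the test concentration, which is fixed at 1 — only the potency/[D]
  ratio enters S, so the generator is unit-free;
* Hill coefficients uniform on [0.7, 1.5].

Labels are the true decision rule applied to the true Z under the
generating coefficients, then flipped with probability label_noise
(default 0.05). Noise is applied to labels rather than potencies because
the classifier consumes labels; an optional log-normal potency jitter
(off by default) supports robustness experiments and never alters labels.
Default true thresholds are anchored at the drug-free baseline
Z0 = (1 + a0 + a1)/(1 + a2): binary cut at Z0, ternary band at
(0.8·Z0, 1.2·Z0) — i.e. 1.5 and (1.2, 1.8) at unit coefficients. Anchoring
keeps "positive" meaning "net repolarisation deficit relative to no drug"
for any generating coefficients; a fixed absolute cut would skew class
balance and decouple labels from the balance semantics as soon as the
coefficients leave (1, 1, 1).

Panel structure, label noise and potency jitter draw from three
independent child streams of the seed, so changing a noise setting
perturbs only the noise and leaves the underlying compounds identical —
useful for paired experiments.

What the generator does **not** emulate: correlated potencies across
channels (real chemical series share scaffolds), assay artifacts (leak,
rundown, fit-quality differences between platforms), inter-laboratory
potency variation, and pharmacokinetics linking test concentration to
exposure. Passing tests on synthetic panels therefore demonstrate the
pipeline's statistical machinery, not clinical predictivity on real
screening data.

## Problem sizes and reproducibility

The standard synthetic evaluation uses n = 60 compounds, 20 generator
seeds, 20 label permutations for the null, and 200 random instances for
the dual-route AUC check — sizes at which the permutation null is stable
and the whole evaluation completes in well under a minute on one core.
Every stochastic step takes an explicit seed; `scripts/acceptance.py`
derives all sub-seeds from its single `--seed` argument.

## Known limitations

* Only three channels enter the score; currents such as I_K1, I_to, I_Ks
  or I_NaCa, and time-/state-dependent (kinetic) block, are out of scope.
* The score is a ranking/classification device, not a calibrated
  probability; no confidence intervals are attached to AUC or accuracy.
* Coefficients are only weakly identified from small labelled panels (see
  optimiser notes); interpret fitted ratios qualitatively.
* The balanced-accuracy objective ignores class priors and
  misclassification costs by construction.
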
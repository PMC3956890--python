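# Methods

## The dependency score

The screen asks, for an ordered pair (modulator B, target A), whether the
association between A and a binary phenotype P changes with the level of B.
Samples carrying a phenotype label are sorted ascending by B's *continuous*
expression (ties broken by stable input order); the bottom
`floor(stratum_fraction · n)` samples form the low stratum and the top ones
the high stratum (`stratum_fraction = 0.35` by default, so with n = 300
each stratum holds 105 samples). Within each stratum the plug-in mutual
information I(A; P) of the *globally* median-binarized target against P is
computed in bits, and the score is `CMI = |I_high − I_low|`.

Assumptions and consequences:

- Binarization is done once, on all labelled samples, before
  stratification. Redoing it per stratum would confound the gate with the
  stratum-specific median.
- Only the order of B matters, so the score is invariant to any strictly
  monotone transform of B (tested).
- The absolute difference is used because the relevant quantity is the
  *magnitude* of modulation; which stratum is active is kept separately in
  `CMIResult.mi_low/mi_high`. With 0/1 variables each stratum MI lies in
  [0, 1] bit, hence so does the score.
- The middle 30% of samples never enters the score. This trades power for
  contrast between clearly-low and clearly-high modulator states.

## Permutation null

The null hypothesis is "the A–P association does not depend on B". The
(A, P) pairs are therefore shuffled *jointly* across samples relative to B:
the marginal A–P association is preserved exactly while the link to B's
ordering is destroyed. Because the two strata are fixed index sets in B's
order, this is equivalent to re-drawing stratum membership, which is what
the implementation vectorizes. An alternative reading — shuffling A and P
independently — would additionally destroy the A–P marginal and test a
stronger null; we deliberately test the weaker, modulation-specific null,
which matches what the score measures.

With N permutations (default 1000) and c null scores ≥ the observed one,
`p = min(1, (1 + c)/N)`: the add-one rank convention makes the smallest
attainable p equal 1/N and never returns 0. Ties between null and observed
scores count against significance (≥, not >). Each screened direction draws
from an independent stream spawned from the base seed in lexicographic pair
order, so results are reproducible and independent of evaluation order.
Both directions of every candidate pair are screened; reciprocal edges are
legitimate outcomes.

## Network, hubs and overlap

Significant directed pairs form a `networkx.DiGraph` with the CMI as edge
weight. The "main" network is the largest weakly connected component
(direction ignored for connectivity; size ties broken toward the component
containing the lexicographically smallest gene id). Degree distributions
are fit by least squares on (log10 degree, log10 frequency) over degrees
≥ 1 — the conventional scale-free diagnostic, reported as |slope|,
|Pearson r| and R². This is a descriptive fit, not a maximum-likelihood
power-law estimate, and a constant log-frequency vector is returned as
slope 0 / R² 0 rather than NaN.

Hub selection is by out-degree cutoff: the smallest threshold
d* ≥ `min_out_degree` (default 4) whose yield does not exceed
`hub_fraction · N` (default 20%) selects every node with out-degree ≥ d*.
Selecting by cutoff rather than by rank means tied nodes are never split
arbitrarily, the budget is approached from below, and the outcome is
deterministic. Gene-set enrichment of the hubs against any annotated set is
an upper-tail hypergeometric test (`P(X ≥ overlap)`), with both sets
required to lie inside the stated universe.

## Phenotype dichotomization

With a horizon h (default 5 years): an observed metastasis at t ≤ h is
phenotype 1; follow-up beyond h is phenotype 0 regardless of a later event;
censoring event-free at t ≤ h yields no usable label and the sample is set
aside. Assigning 0 to event-free patients whose follow-up passes the
horizon is the standard reading of h-year dichotomization — the alternative
(discarding every non-metastatic patient) would leave a single phenotype
class and make the screen undefined. Boundary cases: an event exactly at h
counts as "within"; expression ties at the gene median binarize to 1 (the
rule is a strict "below the median → 0").

## Survival signature

Candidate genes are selected by stability: 400 runs (default), each fitting
a univariate Cox proportional-hazards model per gene on a 75% subsample
drawn without replacement, keeping genes with Wald p < 0.05 in ≥ 90% of
runs. Run r draws from a stream seeded by (seed, r), so any run can be
reproduced in isolation. A gene whose fit is non-estimable in a run
(constant in the subsample, or a degenerate/separated fit) counts that run
as not significant; reported β and p are averaged over the runs with an
estimable fit. Raising the stability threshold can only shrink the
selection (tested).

The univariate fits use an in-package Newton solver for the Efron-tie
partial likelihood, vectorized across genes (one iteration is a set of
suffix cumulative sums over time-sorted samples), because the resampling
stage and the random-signature null need 10⁴–10⁵ single-covariate fits.
It is cross-checked against lifelines' `CoxPHFitter` in the test suite to
~1e-3 in β, SE and p. Fits are declared degenerate when |β| reaches 50
(separation guard) and surface as NaN.

The risk score is the GGI-style unweighted contrast
`Σ x_i (β > 0) − Σ x_j (β < 0)` on raw expression values. Because each
cohort is subsequently split at its own risk-score median, the downstream
grouping is invariant to any per-cohort monotone rescaling of expression,
which makes the unweighted/raw-value choice robust to normalization
differences between cohorts.

## Evaluation

Each cohort is split into equal halves by risk (stable sort; the low-risk
group receives the extra sample at odd n; ties keep input order). Group
difference is the standard two-sample log-rank chi-square (lifelines), and
the hazard ratio with 95% Wald CI comes from a proportional-hazards fit on
the high-risk indicator. Cross-cohort discrimination is
`Dscore = Σ −log10 max(p_i, 1e-17)`; the floor caps any one cohort's
contribution at 17 and guards floating-point underflow. The base-10 log is
pinned by the packaged pseudo-signature table: the sum of −log10 of its six
independent-cohort p-values reproduces the printed total (11.4588 from
3-significant-figure p-values vs 11.4376 printed), whereas natural logs
would give ≈ 26.4.

Fisher's combined probability test uses the identity
X = −2 Σ ln p = 2 ln(10) · Dscore, referred to χ² with 2n degrees of
freedom. The empirical alternative draws same-size random signatures —
from the whole gene complement or from a candidate pool — refits each drawn
gene's coefficient sign on the designated training cohort (the natural
choice when a random gene has no precomputed sign; a gene with a
non-estimable training fit enters with a positive sign), evaluates the
Dscore on the test cohorts, and reports `#{null ≥ observed}/n_reps`
(no add-one; an observed score above every draw reports 0 at the chosen
resolution).

## Synthetic data

`generate_dependency_dataset` plants B→A gates directly on the binarized
scale: within the active stratum of B (bottom or top `stratum_fraction`),
the binary target equals P with probability `gate_strength` and is an
independent coin flip otherwise; outside the stratum target values are
filled randomly subject to an exact n/2 balance, so the written continuous
values (0s in [0, 0.5), 1s in [1, 1.5)) binarize back to the planted vector
under the strict median rule. The effect size is therefore exactly what the
CMI statistic measures: `gate_strength = 1` gives a stratum MI near 1 bit,
`gate_strength = 0` is indistinguishable from the null pairs. Because the
gate is symmetric in A and B, the reverse direction of a planted pair also
carries genuine dependency signal; calibration checks therefore use the
dedicated null pairs, not the reverse directions.

`generate_survival_family` draws i.i.d. standard-normal expression and
exponential event times with rate `baseline_hazard · exp(β Σ hazard genes)`
(baseline 0.1/year, i.e. median event ≈ 7 years against a 5-year horizon);
censoring is an independent exponential whose rate is tuned against the
mean event rate, so the realized censoring fraction matches
`censoring_rate` only approximately (tested at ±0.08). Cohorts in a family
share gene identities and true coefficients but are otherwise independent.

What the generators do *not* emulate: microarray noise models, batch or
platform effects, correlated co-expression blocks, non-proportional
hazards, or informative censoring. Passing tests therefore demonstrate
correctness and calibration of the algorithms under clean conditions, not
robustness to real-cohort artifacts.

## Problem sizes and defaults

The test suite and examples run the screen at n = 300 samples with 100
candidate pairs (both directions, 200–1000 permutations), stability
selection at 100 runs × 200 genes, and random-signature nulls at 50–100
replicates over 2–3 cohorts of 200 samples — sizes chosen so planted
effects are comfortably detectable and null calibration bands are tight
enough to be meaningful. The method defaults (35% strata, 1000
permutations, α 0.05, 400 runs, 75% subsample, 90% stability, 20% hubs
with out-degree ≥ 4, p-floor 1e-17) are the study conditions the method
was designed around and are not tuned by the tests.

## Known limitations

- The screen needs both phenotype classes present; a single-class cohort
  is rejected at dichotomization.
- Plug-in MI on ~100-sample strata is biased upward for small strata; the
  permutation test absorbs this for significance, but raw CMI values from
  different n are not directly comparable.
- Stratum size uses `floor`, so very small cohorts can make the strata
  degenerate (< 2 samples raises).
- The Wald p-values from the Cox solver are asymptotic; at very low event
  counts the resampling selection will be conservative because many runs
  are non-estimable.
- Only binary phenotypes are implemented; the stratified-MI construction
  extends to more states, but that path is untested here.
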
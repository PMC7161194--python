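# Methods

`aimpanel` designs small panels of ancestry-informative markers (AIMs) for
admixed cohorts and estimates individual admixture proportions from them.
This note records the statistical model, the design choices that were
genuinely open, the numerical conventions, and what the bundled simulator
does and does not emulate.

## The admixture model

Individual *i* carries ancestry proportions **q**<sub>i</sub> =
(q<sub>i1</sub>, …, q<sub>iK</sub>) on the K-simplex. Component *k* has
ALT-allele frequency f<sub>km</sub> at biallelic marker *m*. Conditional on
(Q, F), dosages are independent binomials:

    g_im ~ Binomial(2, a_im),    a_im = Σ_k q_ik f_km .

The log-likelihood (dropping the binomial coefficient, constant in the
parameters) is Σ<sub>im</sub> [ g ln a + (2−g) ln(1−a) ], with missing
entries skipped (missingness is assumed completely at random). Maximisation
uses the classic multiplicative EM updates for Q and F rather than
quasi-Newton block relaxation: the fixed points are identical and at panel
scale EM runs in well under a second. The supervised path (F fixed at
reference frequencies) uses a fused, numba-compiled iteration because the
matrix formulation is memory-bandwidth-bound at cohort scale
(~300 × 20,000). Monotonicity of the log-likelihood is asserted on every
iteration of every fit; a decrease beyond 1 part in 10⁹ aborts the run, and
the Q update preserves row sums exactly (to 10⁻⁸) by construction.

Numerical conventions: component frequencies are clamped to
[10⁻⁶, 1−10⁻⁶] so a homozygote never meets an impossible frequency; Q is
initialised from a seeded flat Dirichlet; in the joint fit F starts at the
pooled sample frequency plus seeded ±0.01 jitter; convergence is a relative
log-likelihood change below 10⁻⁷ (supervised default) or the caller's
tolerance. Labelled reference individuals are pinned to indicator rows of Q
and simply not updated, which keeps the coordinate-ascent monotone.

For three-component analyses of a four-reference design, the two closely
related Amerindian references are pooled into one component by a
sample-size-weighted average of their allele frequencies.

## Marker informativeness

Per-marker ancestry information is Rosenberg's informativeness for
assignment, computed in nats over the two alleles of each marker:

    I_n = Σ_j ( −p̄_j ln p̄_j + (1/K) Σ_i p_ij ln p_ij ),   0·ln 0 ≡ 0,

with p̄ the unweighted mean across the K compared populations. I_n is zero
iff the compared frequencies are equal and is bounded by ln K, attained
only at a K-way fixed difference. By default a four-population reference
set yields all six pairwise comparisons; one-vs-rest contrasts or the full
four-way statistic can be requested instead. Markers with a missing
frequency in a compared population are excluded from that comparison, not
imputed.

## Panel selection

The panel objective for a subset S of fixed size n is

    fitness(S) = Σ_c w_c (Σ_{m∈S} I_n,c(m)) / Z_c + λ · coverage(S),

where Z<sub>c</sub> is the sum of the n largest I<sub>n</sub> values for
comparison *c* over the whole candidate pool. The normalisation keeps each
comparison term in [0, 1] so that highly divergent pairs (e.g.
European–African) cannot drown the signal of the closely related pair the
panel exists to separate. Coverage is the fraction of fixed-width genome
bins (default 20 Mb) containing at least one candidate that the panel
occupies — bounded, simple, and directly rewarding genome-wide spread.
Because the informativeness part is additive over markers, every marker
carries a precomputed scalar score and evaluating a subset costs a sum plus
a bin count.

The search is a generational GA over fixed-size marker sets: tournament
selection (size 3), uniform set-union crossover with random repair to the
exact size, per-slot swap mutation (rate 0.01), elitism 1, population 200,
500 generations, mandatory seed. One initial individual is the greedy
score-ranked subset, so elitism guarantees the result never falls below the
greedy baseline. An exhaustive optimizer over all C(n, k) subsets (capped
at 10⁶) serves as the testing oracle; the GA matches it on every tested
instance. Sex chromosomes and mitochondrial markers are never eligible. An
optional LD pre-filter (greedy pruning of pairs with r² ≥ 0.2 within
500 kb) is available but off by default: a handful of linked markers does
not measurably change ancestry estimates, and keeping them preserves the
informativeness budget.

## Choosing K by masked-marker cross-validation

Markers are partitioned into five folds by a seeded shuffle. For each fold
and each candidate K, the model is fitted on the retained markers; the
held-out markers' frequencies are then estimated with Q frozen by the
q-weighted allele-frequency regression f̂<sub>km</sub> =
Σ<sub>i</sub> q<sub>ik</sub> g<sub>im</sub> / (2 Σ<sub>i</sub> q<sub>ik</sub>)
(one EM frequency pass from a pooled start), computed **leave-one-out** so
that each individual's masked dosages are predicted from frequencies
estimated on the other individuals. The error is the mean squared dosage
difference over masked entries. The leave-one-out step matters: with
in-sample frequencies the error is monotone non-increasing in K (surplus
components are free parameters), whereas out-of-sample they pay for their
estimation noise and the error curve bottoms out at the structure the data
support. The statistic is a transparent squared error on dosages, not the
deviance some admixture software reports; it ranks K the same way.

## The simulator

Allele frequencies drift along a small population tree under the
Balding–Nichols model: child ~ Beta(p(1−F)/F, (1−p)(1−F)/F) given parent
frequency p and drift F (mean p, variance F·p(1−p); a fixed allele stays
fixed). The default tree has two continental branches at drift 0.15, a
third continental branch at 0.25, and two sub-continental leaves at 0.05
from it — so one population pair is easy to separate (pairwise Hudson
Fst ≈ 0.15–0.30) and one is genuinely hard (≈ 0.05), the regime a
sub-continental AIM panel is built for. Ancestral frequencies are uniform
on [0.05, 0.95] to keep near-fixed candidates from dominating the
informativeness ranking. Admixed individuals draw q from a Dirichlet with
concentration (2.1, 0.16, 0.72, 1.0), whose mean (0.53, 0.04, 0.18, 0.25)
matches the ancestry profile of a strongly admixed South American cohort;
reference individuals are pure leaf-population members. Genotypes are
Binomial(2, q·f) with MCAR missingness at rate 0.012. Marker positions are
uniform over 22 autosomes with counts proportional to chromosome length.

What the simulator does **not** emulate: linkage disequilibrium and
haplotype structure, genotyping batch effects, allele-frequency
misspecification between reference and cohort, selection, and non-random
missingness. Passing the validation benchmark therefore shows that the
selection + estimation machinery is statistically sound under the model's
own assumptions; it does not certify performance on a real genotyping
platform.

## The validation benchmark

The end-to-end benchmark (also recomputed by `scripts/acceptance.py`)
simulates a cohort of 20,000 candidate markers, 60 reference individuals
per leaf population and 300 admixed individuals; designs a 150-marker panel
with the GA (all six pairwise comparisons, λ = 1, defaults above); and
correlates supervised ancestry estimates from the panel against estimates
from all 20,000 markers, per component, over the admixed individuals —
continental components at K = 3 (sub-continental references pooled), the
two sub-continental components at K = 4. Medians over three seeds are
reported. Supervised estimation in the benchmark uses a relative
log-likelihood tolerance of 10⁻⁵ (the correlations change by < 0.01
between 10⁻⁵ and 10⁻⁷ while the all-marker fits dominate the run time).
Problem sizes elsewhere in the test suite are chosen at "desk scale" —
hundreds to a few thousand markers — which keeps the full suite in the
minutes range while leaving every statistical property testable.

## Known limitations

* The estimator treats markers as independent; tightly linked panels
  would need LD pruning or a haplotype-aware model.
* Reference allele frequencies are treated as known in supervised mode;
  their sampling noise (reference panels of tens of individuals) biases
  small components toward zero.
* The CV error is a dosage squared error, not a deviance, so its absolute
  scale is not comparable to other software; only its argmin is meant to
  be interpreted.
* Strand-ambiguous (A/T, C/G) markers with swapped alleles between
  datasets are dropped from concordance comparisons rather than resolved
  by frequency matching.
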
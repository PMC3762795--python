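# Methods

## Scope and data model

The package analyses corpora of case-control studies of one biallelic SNP
(alleles called C and T, genotypes CC/CT/TT). A study is six non-negative
genotype counts plus two stratum labels: a broad ethnicity group
(Asian/Caucasian/African) and whether serious disease-related
complications were explicitly reported absent among cases (versus present
or unreported). Both labels are data: they are carried in the corpus file
and never re-derived at run time, because stratum membership is an
editorial judgement made when the corpus is assembled, not a computation.

The packaged corpus holds the 39 MTHFR 677C→T / type 2 diabetes studies
(4855 cases, 5242 controls) with their reported control-arm HWE p-values
kept verbatim (including printed bounds such as `<0.001`).

## Contrast coding and the zero-cell policy

Four codings map a study to a 2×2 table; the first-named group of each
label (C allele, CC, CC, TT respectively) is the exposure, so it forms
the numerator odds. The homozygote contrast discards CT individuals
entirely — "CC vs TT" compares homozygotes only, and the resulting
degrees of freedom in the reference corpus (37, not 38) confirm that
reading.

Zero cells: if a single cell of the table is zero, 0.5 is added to all
four cells (the convention of the major systematic-review software) and
the table is flagged `corrected`. If the exposed or the unexposed column
is empty in *both* arms the study is non-informative for that contrast
and is flagged `excluded` (in the reference corpus exactly one study,
with no TT carriers anywhere, is excluded from the homozygote and
recessive contrasts). Exclusion is a flagged state rather than an error
so that bookkeeping — degrees of freedom, funnel point counts — is
testable.

## Pooling

Per-study effects are Woolf log odds ratios with
`se² = 1/a + 1/b + 1/c + 1/d` on the (possibly corrected) cells.

*Fixed effect.* The default estimator is Mantel–Haenszel with the
Robins–Breslow–Greenland variance for its log; inverse-variance (Woolf)
pooling is retained as an option (`fixed_method="IV"`). The reference
corpus adjudicates the choice: on subgroups untouched by data-entry
ambiguity the MH Z statistics match the published table to two decimals.

*Heterogeneity.* Cochran's Q uses inverse-variance weights about the
inverse-variance fixed estimate (the classic form). A flag
(`q_about_mh=True`) switches the centre to the MH estimate, which some
software reports; on the reference corpus the two differ by < 0.02. I²
is the usual `max(0, 100(Q−df)/Q)`; τ² is the DerSimonian–Laird moment
estimator, never iterated (no REML or Paule–Mandel), matching the
era-standard behaviour of the tools the corpus was originally analysed
with.

*Random effects.* DerSimonian–Laird: inverse-variance weights inflated
by τ².

*Model selection.* Fixed effect iff the Q-test p-value exceeds 0.10
(strictly); the boundary p = 0.10 selects random effects. The rule is
re-applied inside every stratum and every leave-one-out iteration, since
heterogeneity is a property of the study set at hand.

*Inference.* CIs are `exp(ln OR ± 1.96 SE)` (normal multiplier, no t
quantile); the pooled effect is tested by a two-sided normal Z-test. For
k = 1 the heterogeneity statistics are defined as Q = 0, I² = 0, τ² = 0,
p = 1 (hence fixed effect).

## Hardy–Weinberg screening

Two tests on control-arm genotype counts:

- *Asymptotic:* 1-df χ² goodness of fit against expected counts
  `(n p̂², 2n p̂q̂, n q̂²)` at the observed allele frequency. A
  monomorphic arm is returned as a defined perfect fit (χ² = 0, p = 1)
  with a flag.
- *Exact:* the conditional test — enumerate every heterozygote count
  compatible with the allele-count margins, compute the
  hypergeometric-type null probabilities in log space, and sum those no
  larger than the observed configuration's (ties kept via a relative
  tolerance; plain tail sum, not mid-p).

The subgroup classifier is the **exact** test at p < 0.05 (p ≥ 0.05
counts as in-HWE). This is a deliberate choice: the asymptotic χ²
rejects two boundary studies of the reference corpus (exact p 0.062 and
0.090, asymptotic p just under 0.05), which would contradict both the
corpus's own printed per-study values — all 37 printed decimals are
reproduced by the exact test within ±0.002 — and the published subgroup
sample sizes (574/726), which only the exact classifier reproduces. Both
p-values are always computed and exported, and `classifier="asymptotic"`
or `"printed"` (reuse the corpus's reported values) are available.

## Small-study bias

Harbord's modified test: per study the efficient score of the
conditional likelihood `Z = a − (a+b)(a+c)/n` and its information
`V = (a+b)(c+d)(a+c)(b+d)/(n²(n−1))`, computed on **uncorrected** integer
tables (the score is well defined with zero cells; a continuity
correction would distort it). Double-zero studies are dropped as in
pooling; tables with V = 0 are dropped with notice. `Z/√V` is regressed
on `√V` by unweighted OLS and the intercept (the bias parameter) is
tested with a two-sided t-test on k−2 df. A residual-free fit (all
scores zero) is reported as t = 0, p = 1. Funnel-plot output is data
only — `(log OR, SE)` per included study — since visual funnel
assessment is not a statistic; no rank-correlation, Egger, or
trim-and-fill procedures are provided.

## Synthetic corpora

The generator emulates the reference corpus's structure, not any one
dataset. Per study: control T-allele frequency `q ~ Uniform(0.10, 0.55)`
(spanning the between-population frequency variation of 677C→T);
control genotypes `P(TT) = q² + fq(1−q)`, `P(CT) = 2q(1−q)(1−f)`,
`P(CC) = (1−q)² + fq(1−q)` with inbreeding coefficient `f ∈ [0,1)`
controlling HWE violation; study effect `θᵢ ~ N(θ, τ²)` applied at the
allele level by multiplying the control C-allele odds (C is the allele
contrast's exposure, so the allele-contrast estimand is `exp(θ)`); case
genotypes re-composed under HWE at the induced case frequency; counts
multinomial. Defaults: k = 39 studies, arm sizes uniform on [40, 300] —
the central range of the real corpus, which spans 7 to 1018. Randomness
is spawned per study from the master seed, so a corpus is reproducible
and extending k appends studies without disturbing earlier ones.

What the generator does *not* emulate: publication selection (funnel
asymmetry arises only through sampling noise), genotype-level effects
(dominant/recessive/homozygote ORs are emergent from the allele-level
model, not separately controlled), covariates, or linkage with other
loci. Passing simulation checks therefore validate the estimators'
calibration under a clean generative model, not robustness to those
real-data features.

`operating_characteristics` runs simulate → meta-analyse repeatedly and
reports CI coverage of the true OR, the Z-test rejection rate, and the
estimator means. With the default acceptance settings (k = 20, ~500 per
arm, 1000 replicates) the Z-test size under the null falls in
[0.03, 0.07] and DL coverage under τ = 0.3 in [0.92, 0.97]; 2000
HWE-true control arms of n = 200 at MAF 0.3 keep the exact test's size
≤ 0.06. These problem sizes keep the full suite comfortably within a few
minutes while leaving Monte-Carlo error well inside the asserted bands.

## Numerical and degenerate-input conventions

- Exact-test enumeration is done in log space (gammaln) and normalised
  before summation, so arms of tens of thousands are exact to double
  precision.
- Monomorphic arms: asymptotic (0, 1) with flag; exact p = 1 (single
  attainable configuration).
- `select_model` boundary: p = 0.10 → random (strict inequality for
  "no heterogeneity").
- Empty strata are omitted from stratified reports with a notice, not an
  error; an all-excluded contrast raises.
- Report rendering rounds ORs/CIs and Q to 2 decimals and I² to whole
  percent; JSON exports carry full precision. Reruns with identical
  inputs are byte-identical (no hidden randomness in the analysis path).

## Known divergences from previously reported values

Recomputing the reference corpus reproduces the published corpus totals,
all subgroup sample sizes, every printed per-study HWE decimal, the
African and Caucasian subgroup heterogeneity statistics to two printed
decimals, and the overall pooled ORs at two decimals for the allele,
dominant and recessive contrasts. Four published quantities are **not**
reproducible from the published genotype counts under any convention we
tested (alternative Q centrings and weightings, Breslow–Day,
continuity-correction and inclusion variants, and exhaustive per-study
recount searches): the overall/Asian-subgroup Q statistics (e.g. allele
Q prints 76.62 where the counts give 81.76 — a value confirmed
independently by a second implementation), the overall homozygote OR
(prints 0.82 [0.71, 0.95]; the counts give 0.83 [0.72, 0.96] by both MH
and IV), the Asian allele OR (prints 0.86; the counts give 0.88,
downstream of the same τ² difference), and the Harbord p-value (prints
0.939; the counts give 0.378). The pattern — exact agreement on the
African/Caucasian subgroups, disagreement wherever certain other studies
enter — indicates the original analysis was run on per-study inputs that
differ from the published count table in ways that cannot be recovered.
The package computes from the counts as published; the affected
acceptance tests assert the printed values and fail honestly rather than
being loosened to pass.

## Limitations

Unadjusted ORs only (no covariate adjustment, no genotype trend tests);
no meta-regression, cumulative meta-analysis, Hartung–Knapp adjustment
or prediction intervals; no Egger/trim-and-fill/selection models; no
X-linked or multi-allelic HWE extensions; literature search and
screening machinery is out of scope — the corpus file is the interface.
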
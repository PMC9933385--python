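# Methods

This note documents the statistical procedures `bfretest` implements, the
defaults it ships, the numerical choices behind them, and what the synthetic
literature generator does and does not emulate.

## The retest procedure

Every record is one published t test reduced to its printed summaries. The
pipeline treats the article's numbers as the data and recomputes everything
downstream of them.

**Verification.** The printed *P* is compared with the recomputed one before
any analysis, because a transcription or computation error upstream would
contaminate every downstream quantity. A "*P* = x" claim is congruent when the
recomputed *P* rounds (half-even) to x at the precision the article printed
(at most `tolerance_dp` decimals, default 3) *and* the two agree about
significance at α. The significance comparison is made at the printed
precision: the printed number is all a reader ever had, so a recomputed
0.0496 against a printed "0.05" is congruent — both say "not significant at
0.05" once rounded. Inequality claims ("*P* < x", "≤ x") are congruent when
the recomputed value satisfies the bound and sits on the same side of α as
the bound itself. Incongruent rows are excluded by default (`policy =
"exclude"`); `"flag_only"` retains them with a flag for audit use.

**t reconstruction.** One-sample and paired tests use t = m̄/(s/√n) with
df = n − 1, where m̄ and s are the mean and SD of the (paired) differences —
the schema deliberately stores difference summaries for dependent tests, not
group summaries, because group summaries alone cannot recover the
within-pair correlation. For two independent groups, an F test of variance
equality decides the formula: the statistic is the larger sample variance
over the smaller (so the test is invariant to group order), its *P* is twice
the upper F tail capped at 1, and `equal_variances = (p > alpha_f)` with
`alpha_f = 0.05` by default. The gate must be explicit and configurable
because it flips between the pooled-SD t (df = n₁+n₂−2) and the Welch t,
whose Welch–Satterthwaite df is kept as a real number throughout — rounding
it to an integer moves *P* in the third decimal, which matters at the
verification stage. When a record carries a printed t but not the summaries,
the t is passed through unchanged (`reported_passthrough`) with the df
implied by its kind and sample size; this mirrors how a reader retests a
published result from the test statistic alone.

**P recomputation.** Two-sided throughout: P = 2·P(T_ν > |t|), via scipy's
Student-t survival function. The source articles report two-sided tests
against α = 0.05, and the agreement analysis inherits that convention.

## The JZS Bayes factor

Under the null the standardized effect δ is 0; under the alternative
δ ~ Cauchy(0, r) with r = 0.707, the conventional "medium" default. The
Cauchy prior is expanded as a normal scale mixture — δ | g ~ N(0, g),
g ~ InverseGamma(1/2, r²/2) — which gives the marginal-likelihood ratio as a
one-dimensional integral over g (see the package README for the formula).
ν and the effective sample size N are (n−1, n) for one-sample/paired tests
and (n₁+n₂−2, n₁n₂/(n₁+n₂)) for independent groups. The package reports
BF₀₁ = 1/BF₁₀.

Numerics: the improper integral is mapped onto (0, 1) by g = u/(1−u) and
evaluated with adaptive Gauss–Kronrod quadrature (`scipy.integrate.quad`,
relative tolerance 1e−8, at most 200 subintervals). The integrand is formed
in log space with the central-t denominator folded in, so only the bounded
ratio is ever exponentiated; this keeps the result finite without overflow
for |t| at least up to 50 (BF₀₁ ≈ 6e−27 at t = 50, n = 30). The integrand has
a finite nonzero limit at u → 1 (the g^(−3/2) prior tail, the (Ng)^(−1/2)
shrinkage factor and the (1−u)^(−2) Jacobian cancel to a constant), which the
integrand function returns explicitly. A quadrature whose error estimate
exceeds 100× the relative target raises a `NumericError` rather than
returning silently.

Correctness is established two independent ways in the test suite: against
pingouin's implementation of the same Rouder formula (agreement to ~1e−6
relative), and against a Monte-Carlo oracle that shares no code with the
quadrature — BF₁₀ = E_{δ~Cauchy(0,r)}[f_nct(t; ν, δ√N)] / f_t(t; ν),
estimated from 10⁷ Cauchy draws of δ taken by inverse-CDF over a scrambled
Sobol sequence, with the noncentral-t density evaluated through its exact
normal/chi-square mixture representation
f_nct(t; ν, μ) = E_{V~χ²_ν}[√(V/ν)·φ(t√(V/ν) − μ)] (V drawn as the second
low-discrepancy coordinate). The low-discrepancy draws put the oracle's error
near 1e−5, so a three-decimal agreement check is meaningful even where BF₁₀
is order 100; the mixture identity itself is verified separately against
scipy's noncentral-t density.

## Evidence scales and agreement

Three categorical scales label each retest: *P* bands at 0.001 / 0.01 / 0.05;
|d| bands at 0.2 / 0.5 / 0.8; and the modified Jeffreys ladder for BF₀₁ at
1/100, 1/30, 1/10, 1/3, 1, 3, 10, 30, 100. The printed ladders leave boundary
membership unspecified, so a fixed closure rule makes labels deterministic:
a BF₀₁ on a boundary joins the band further toward the null (≥ closure), *P*
bands are closed on the left edge, and BF₀₁ exactly 1 is its own
"no evidence" category. All cutoffs are configurable for sensitivity
variants.

The agreement analysis dichotomizes at *P* < 0.05 and BF₀₁ < 1. Percent
agreement is 100 × concordant / total. Cohen's κ = (p_o − p_e)/(1 − p_e) is
computed on the 2×2 significance-by-direction table; BF₀₁ exactly 1 cannot
arise from the continuous computation but can after rounding a stored
results file, so such records are excluded from the 2×2 and counted
separately. With degenerate marginals (p_e = 1, all mass in one
row-column pair) κ is defined as 1 for perfect agreement and 0 otherwise;
this matters in strong-signal simulations where every test is significant and
null-rejecting, which should read as perfect agreement rather than 0/0. The
anecdotal cross-tab stratifies by test kind × (1/3 < BF₀₁ < 3 vs outside) ×
significance; the two discordant decisive cells (BF₀₁ ≥ 3 with significant
*P*, BF₀₁ ≤ 1/3 with nonsignificant *P*) are kept as explicit columns so the
cells always sum to the total. Percentages print at two decimals, half-even.

Effect sizes are standard Cohen's d: mean difference over pooled SD
(independent) or mean of differences over their SD (dependent/one-sample),
sign preserved, magnitude used for banding. Published retest audits sometimes
print effect sizes several-fold larger than d computed from the same
summaries; this package makes no attempt to reproduce any nonstandard
variant.

## The synthetic literature generator

The generator stands in for a pooled extraction sheet. Defaults, chosen once:

| parameter | default | rationale |
|---|---|---|
| `kind_mix` | independent : dependent = 438 : 355, no one-sample | the split observed in a pooled orthodontic-journal audit |
| `n_dist` | per-group n uniform on [10, 60] | small-to-moderate clinical study sizes |
| `null_prop` | 0.5 | mixed literature; fully configurable |
| `effect_dist` | Cauchy(0, 0.707) truncated at \|δ\| ≤ 5 | equals the analysis prior, so the BF is well-calibrated by construction; `fixed` and `normal` variants exist for mis-specification tests |
| `sigma` | 1 | pure scale parameter |
| `report_rounding_dp` | 3 | journals print ~3 decimals; values rounding to 0 become "< 0.001" |

Sample means are drawn from N(true mean, σ/√n) and sample SDs from the exact
scaled-χ sampling distribution σ√(χ²_{n−1}/(n−1)) — not fixed at σ — so the
F-test gate sees realistic variance heterogeneity and both pooled and Welch
branches are exercised. Dependent tests are generated directly as difference
summaries, matching the schema. The reported *P* is produced by running the
package's own reconstruction on the emitted summaries and rounding, which
makes every generated row verify congruent by construction — the generator
validates the rounding rule, not the reconstruction. One `numpy` Generator is
seeded once per table, so tables are bit-reproducible.

What the generator does **not** emulate: article-level clustering (several
dependent tests extracted from one article), publication bias, and
transcription errors. Passing calibration on synthetic data therefore shows
the machinery is correct under clean reporting; it does not estimate how
often real articles misreport.

## Problem sizes and expected behaviour

The acceptance script and test suite use: 20 000 all-null tests for the
type-I calibration (rejection rate 0.05 ± 0.004, a 3-standard-error band);
2 000 tests at fixed δ = 2 with 30 per group for the strong-signal limit
(agreement ≥ 99%, κ ≥ 0.95 — in practice both hit their maxima); 2 000
mixed-regime tests for the anecdotal-zone structure; and a 16-point (t, ν, N)
grid at 10⁷ draws for the Monte-Carlo cross-check. Under the null the
recomputed *P* is uniform on (0, 1) up to the Welch approximation in the ~5%
of equal-variance pairs the F gate sends down the Welch branch; a
Kolmogorov–Smirnov check at n = 20 000 does not detect the deviation.

## Known limitations

- Reconstructing t from a printed *P* and df alone (inverse-CDF recovery) is
  out of scope; records must carry summaries or a printed t.
- One-sided tests, nonparametric retests, informed/shifted priors, one-sided
  Bayes factors and ROPE-style interval tests are not implemented.
- Dependent-test records must store difference summaries; group-wise
  summaries with an assumed correlation are not accepted.
- κ is reported without a confidence interval; bootstrap CIs are a rendering
  of uncertainty this package leaves to its callers.
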
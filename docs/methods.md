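# Methods

## The problem

A family of `n` simultaneous hypothesis tests produces `n` p-values
`p_1..p_n`. Uncorrected testing at a per-comparison level `α_PC`
inflates the family-wise error rate (FWER), the probability of at least
one false rejection, to `1 − (1 − α_PC)^n` under independence; the
expected number of false positives among `m` true nulls is `α·m`
regardless of dependence. The package implements the two classical
remedies — shrink the per-test level so the FWER stays below `α`, or
control the expected false fraction among the calls (the FDR) — plus the
estimation machinery (π₀, pFDR, q-values) that makes FDR control
adaptive.

## Adjusted values and stop rules

The sequential procedures are defined by stop rules (Holm: step down
from the smallest p-value, stop at the first failure; Hochberg: step up
from the largest, the first success rejects everything smaller). We
report *adjusted p-values* that are made self-consistent with those stop
rules by monotonisation: Holm takes a running maximum down the ranks of
`(n − k + 1)·p_(k)`, Hochberg (and BH/BY) a running minimum from the
largest rank. With that choice, "reject iff adjusted ≤ α" reproduces the
sequential procedure exactly, tied raw p-values receive identical
adjusted values (stable sort), and all adjusted values are capped at 1
because they are probabilities.

Boundary conventions, deliberately asymmetric and tested:

* adjusted-value rejection is closed (`adjusted ≤ α`);
* the Bonferroni *threshold* formulation is open (`p < α/n`);
* the BH critical-value scan is strict (`p_(k) < (k/n)·level`, searching
  for the highest qualifying rank). At interior boundary points the BH
  rejection flags can therefore differ from `adjusted ≤ level`; the
  flags follow the critical-value scan.

All comparisons are done on the computed floating-point values without
tolerance; the formulas are elementary arithmetic, and the test suite
allows 1e-12 relative tolerance against independently coded oracles.
The Šidák adjustment is evaluated as `-expm1(n·log1p(-p))` for accuracy
at small p.

## The step-up variant

`hochberg-variant` multiplies the k-th *smallest* p-value by `k` (so the
largest is multiplied by `n`), scanning from the largest down. This is
not Hochberg's 1988 procedure — the standard step-up multiplier for the
largest p-value is 1, not `n` — but the variant circulates in tutorial
walkthroughs, so it is implemented separately rather than silently
replacing the standard method, and its output is flagged
`standard=False`. It is far more conservative than standard Hochberg
(for the largest p-value it coincides with Bonferroni) and should not be
used for analysis.

## FDR estimation choices

* **Storey's FDR(t) = π₀·m·t / S(t)**: `m` is the *total* number of
  tests and `S(t) = #{p_i ≤ t}`; the estimate is capped at 1, and
  `S(t) = 0` is an error because the positive FDR conditions on at least
  one rejection.
* **π₀ estimators**: `(2/n)·#{p_i > 0.5}` (default) and `2·mean(p)`,
  both clamped into `[1/n, 1]` — the floor avoids division blow-ups, the
  cap stops the twice-mean estimator from exceeding 1. Both assume
  alternatives are stochastically small so that the upper half of [0,1]
  is null-dominated; heavy-tailed or conservative p-values bias them
  upward (which is the safe direction for FDR control).
* **q-values**: `q(p_i) = min over thresholds t ≥ p_i of FDR(t)` with
  `t` ranging over the observed p-values only — the minimum over
  continuous `t` is always attained at an observed p-value, so no finer
  grid is needed. Computed as the π₀-scaled BH values with a running
  minimum; with π₀ = 1 the q-values equal BH-adjusted p-values exactly
  (bit-identical, by matching the multiplication order).
* **PFP** estimates `E(V)/E(R)` with `V̂ = π₀·m·t` and `R̂ = S(t)` —
  the only estimators constructible from the quantities above — and
  therefore coincides numerically with Storey's pFDR here, though the
  two are conceptually different (ratio of expectations vs expected
  ratio) and PFP is defined independently of the dependence structure.
* **BY**: under `dependence="positive"` the factor is `c(n) = 1` and the
  procedure is exactly BH; under `"arbitrary"` critical values are
  divided by the harmonic number `c(n) = Σ_{i≤n} 1/i` (equivalently
  adjusted values are multiplied by it and capped).

## Synthetic-data generator

`generate` draws one-sided z-test p-values: statistic
`z_i = √ρ·Z_common + √(1−ρ)·Z_i + effect·1[alternative]`, p-value
`Φ̄(z_i)`. This is the simplest generative model with an exact uniform
null, a single tunable effect size, and single-parameter positive
dependence (every pair of tests has correlation ρ while null marginals
stay uniform). `round(m·π₀)` tests are nulls; identical seeds give
bit-identical output.

Defaults model a mid-sized expression screen and are fixed once: m = 1000
tests, π₀ = 0.8, effect = 3 (clearly detectable individually, not
trivially so after correction), ρ = 0, 100 replicates. The error-control
studies use the sizes stated with their results: all-null FWER at
m = 100 with 2000 replicates; BH FDR at m = 200, π₀ = 0.8, effect = 3
with 1000 replicates, at ρ = 0 and ρ = 0.2 ("weak positive
correlation"); π₀ recovery at m = 5000 with 50 replicates. These sizes
give Monte-Carlo standard errors a few thousandths wide — small enough
that a real violation of the guarantees would show — while the whole
suite runs in seconds.

What the generator does **not** emulate: two-sided or discrete test
statistics, heteroskedastic effect sizes, block or negative dependence,
and composite nulls. Passing tests show the procedures implement their
definitions and hold their guarantees under this mixture model; they do
not certify behaviour under, e.g., strong or negative correlation
(where BH is not guaranteed and BY is the appropriate choice).

Evaluation conventions: the false-discovery proportion `V/R` is defined
as 0 when `R = 0` (FDR semantics); the conditional mean of `V/R` given
`R > 0` is reported separately as the empirical pFDR. Power is the mean
fraction of true alternatives rejected; the FWER indicator is `V ≥ 1`.
Monte-Carlo standard errors are sample SDs over replicates divided by
√reps.

## Method recommender

The decision table (an explicit interpretation, versioned here): if no
false positives can be tolerated → FWER family, concretely Holm (valid
under arbitrary dependence, dominates Bonferroni); else a confirmatory
analysis with at most `small_n` tests (default 300, configurable —
"a couple of dozens to a couple of hundreds") → Holm; else dependent
tests → Benjamini–Yekutieli; else → Benjamini–Hochberg with q-values
alongside. The recommender is total — every answer combination yields
exactly one implemented method — and returns the traversed
question/answer path.

## Known limitations

* Local FDR (per-test posterior null probability) is out of scope: it
  needs a density estimate under the alternative and is hard to estimate
  precisely.
* Covariate-aware FDR methods (weighting, IHW-style, adaptive
  shrinkage) are out of scope.
* The π₀ estimators are the two simple moment/counting forms above, not
  the spline-smoothed λ-grid estimator.
* p-values are assumed continuous; with heavily discrete p-values the
  uniform-null premise of every procedure here is conservative at best.
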
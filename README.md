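# mtcorrect

Multiple-testing correction for families of p-values: family-wise error
rate (FWER) control, false-discovery rate (FDR) control, Storey q-values,
a study-design method recommender, and a Monte-Carlo harness that verifies
each method's error-control guarantee on synthetic data.

## Who this is for

Anyone who runs many hypothesis tests at once — differential expression
screens, GWAS, proteomics, ecology, psychology — and needs the per-test
p-values corrected before calling discoveries. Testing *C* hypotheses
each at level α inflates the family-wise error rate to

    α_FW = 1 − (1 − α_PC)^C

so 20 tests at α = 0.05 already carry a 64% chance of at least one false
positive, and a 20,000-gene screen expects α·m = 1000 of them.

## Methods

| method | guarantee | form |
|---|---|---|
| Bonferroni | FWER ≤ α | p′ᵢ = min(1, n·pᵢ) |
| Šidák | FWER ≤ α (independence) | p′ᵢ = 1 − (1 − pᵢ)ⁿ |
| Holm (step-down) | FWER ≤ α, any dependence | rank k multiplier n − k + 1, running max |
| Hochberg (step-up) | FWER ≤ α (independence / positive dep.) | same multipliers, running min from the top |
| Benjamini–Hochberg | FDR = E[V/R] ≤ level | p₍ₖ₎ vs critical value (k/n)·level |
| Benjamini–Yekutieli | FDR ≤ level, arbitrary dependence | BH with critical values / c(n), c(n) = Σ 1/i |
| Storey pFDR / q-values | FDR among called set | FDR(t) = π₀·m·t / S(t); q(pᵢ) = min_{t ≥ pᵢ} FDR(t) |
| PFP | E(V)/E(R) | V̂ = π₀·m·t, R̂ = S(t) |

π₀ (the proportion of true nulls) is estimated either as (2/n)·#{pᵢ > 0.5}
or as 2·mean(p), clamped into [1/n, 1]. A deliberately non-standard
step-up variant (`hochberg-variant`, rank-k multiplier k) is included for
comparison with tutorial walkthroughs; its output is flagged
`standard=False`.

Every correction is an sklearn-style estimator (`fit` / `transform` /
`get_params`), so they drop into pipelines; module-level functions
(`holm_adjust`, `bh_reject`, `qvalues`, ...) wrap them for one-liners.

## Worked example

```python
from mtcorrect import holm_adjust, bh_reject

p = [0.00001, 0.00008, 0.00012, 0.021, 0.049, 0.052, 0.43, 0.88]
res = holm_adjust(p, alpha=0.05)
for raw, adj, rej in zip(p, res.adjusted, res.rejected):
    print(f"p={raw:<8g} holm={adj:<10.5g} rejected={rej}")
```

```
p=1e-05    holm=8e-05      rejected=True
p=8e-05    holm=0.00056    rejected=True
p=0.00012  holm=0.00072    rejected=True
p=0.021    holm=0.105      rejected=False
p=0.049    holm=0.196      rejected=False
p=0.052    holm=0.196      rejected=False
p=0.43     holm=0.86       rejected=False
p=0.88     holm=0.88       rejected=False
```

Holm keeps the three clearly significant tests and drops the borderline
ones. BH at a 5% FDR additionally rejects p = 0.021 (BH-adjusted 0.042),
trading a few expected false discoveries for power — the same data through
`bh_reject(p, fdr_level=0.05)` gives adjusted values
`[8e-05, 0.00032, 0.00032, 0.042, 0.0693, 0.0693, 0.491, 0.88]`.

The same operations from the shell:

```sh
mtcorrect adjust --method holm --input pvalues.csv --output holm.csv
mtcorrect adjust --method qvalue --pi0-estimator twice_mean_p \
    --input pvalues.csv --output q.csv
mtcorrect recommend --exploratory --n-tests 20000 --independent \
    --tolerate-false-positives        # prints: bh
mtcorrect simulate --m 200 --pi0 0.8 --effect 3 --reps 500 --seed 42 \
    --methods bonferroni,holm,hochberg,bh --output perf.csv
```

The simulate call above measures, on 500 synthetic replicates of 200
tests (80% true nulls, alternatives shifted by 3 SD):

```
    method  empirical_fwer  empirical_fdr  power
bonferroni           0.046         0.0037 0.3106
      holm           0.050         0.0040 0.3179
  hochberg           0.050         0.0040 0.3180
        bh           0.706         0.0413 0.7157
```

FWER methods hold the 5% family-wise rate but find only ~31% of the true
effects; BH gives up the FWER guarantee (it is 71% likely to make at
least one false call) yet keeps the false fraction among its calls at
~4% while more than doubling power.

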
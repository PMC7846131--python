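# funcfdr — functional false discovery rates

`funcfdr` estimates false discovery rates that **vary with an informative
variable**. In many genomics screens each hypothesis test carries a covariate
that says something about how likely the null is, or how powerful the test is
— the basepair distance between a gene and a SNP in an eQTL scan, or the
per-gene read depth in an RNA-seq differential-expression analysis — while
leaving the null distribution of the p-value untouched. Covariate-free
q-values ignore this information; `funcfdr` uses it to re-rank tests and
reject more hypotheses at the same target FDR.

## Model and statistic

Each test i yields a p-value `P_i` and a covariate, quantile-normalized to
`Z_i ~ Uniform(0,1)`. The two-group model is

```
H | Z = z   ~  Bernoulli(1 - pi0(z))         # functional null proportion
P | H = 0   ~  Uniform(0,1)                  # null p-values stay uniform
P | H = 1,z ~  f1(p | z)                     # alternatives pile up near 0
```

so the joint density is `f(p,z) = pi0(z) + (1 - pi0(z)) f1(p|z)`. The optimal
test statistic is the posterior null probability (functional local FDR)

```
r(p,z) = pi0(z) / f(p,z)
```

and the functional q-value of test i averages r over all tests at least as
extreme: `q_i = mean{ r_j : r_j <= r_i }`. Rejecting `q_i <= alpha` targets
positive FDR level alpha, and thresholding r is Bayes optimal among all rules
with the same rejection probability.

The package provides:

* **`pi0_functional`** — three conservative estimators of `pi0(z)` built on
  the thresholding identity `E[1{P > lambda} | z]/(1 - lambda) >= pi0(z)`:
  a scaled-logit GLM (monotone), a B-spline GAM (GCV-selected flexibility),
  and a kernel factorization (Storey's scalar estimate times a
  probit-transform KDE of z among tests with `p > lambda`), plus a bootstrap
  MISE surrogate for choosing lambda.
* **`joint_density`** — a probit-transform adaptive nearest-neighbour KDE of
  `f(p,z)` on the unit square, with an optional pool-adjacent-violators
  projection making every z-profile non-increasing in p.
* **`core`** — local FDRs, functional q-values, significance calls, and the
  covariate-free Storey q-value baseline.
* **`simulate`** — the generative model with known truth and closed-form
  oracles for r, pFDR/pFNR and the Bayes error, plus a replication harness
  comparing the functional rule to the baseline.

## Worked example

```python
import funcfdr as F

cfg = F.SimulationConfig(m=5000, pi0_spec="linear:c0=0.6,c1=0.3",
                         alt_spec="beta:a=0.25", seed=42)
dataset = F.generate_dataset(cfg)
result  = F.ffdr_pipeline(dataset, alpha=0.05, pi0_method="glm",
                          lam=0.5, seed=42)
```

Running `python examples/run_analysis.py` (which adds the TSV round-trip and
the baseline comparison) prints:

```
tests analysed:            5000
fFDR discoveries (5% FDR): 357
standard q-value calls:    351
fFDR true positives:       345   realised FDP: 0.034
```

357 tests are called at a 5% FDR target versus 351 for covariate-free
q-values; because the truth is known here, we can see the realised false
discovery proportion (0.034) stays below the target while the extra
discoveries are real. The other scripts in `examples/` demonstrate the three
`pi0(z)` estimators, the replication study, and the closed-form oracles.

A thin CLI wraps the same pipeline for shell use:

```
funcfdr simulate --m 5000 --seed 42 --output tests.tsv
funcfdr run --input tests.tsv --alpha 0.05 --pi0-method gam --output results.tsv
funcfdr study --m 3000 --replicates 50 --output summary.tsv
```

## Documentation

`docs/methods.md` describes the estimators, their tuning parameters and
defaults, the numerical choices, and what the simulation harness does and
does not establish about real data.
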
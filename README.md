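# pebri

Personalized reference intervals and reference change values for clinical
laboratory tests, via parametric empirical Bayes (PEB).

## The problem

Laboratories interpret a result against a *population* reference interval
(RI_pop), the central 95% of a healthy reference population. But each person
regulates most biomarkers around an individual homeostatic set point whose
spread (within-subject variation, CV_I) is usually much smaller than the
spread between people (CV_G). A result can be grossly abnormal *for that
patient* while sitting comfortably inside RI_pop — and vice versa.

Two personalized tools exist: the *reference change value* (RCV), which asks
whether the change between two consecutive results exceeds what analytical
plus within-subject variation can explain, and the *personalized reference
interval* (RI_per), centered on the patient's own mean. Neither corrects for
regression toward the mean: a patient whose baseline happens to sit far from
the population mean will, on average, drift back toward it on retesting, and
thresholds centered on the raw baseline misread that drift as change.

## The model

After a normalizing transformation (natural log, or Box-Cox with exponent
λ), results of healthy subject *i* are modeled hierarchically:

    X_n | μ_I ~ N(μ_I, σ_I²)        μ_I ~ N(μ_pop, σ_G²)

With `σ_pop² = σ_G² + σ_I²` and the intraclass correlation
`B₁ = σ_G² / σ_pop²`, the posterior set point after n prior results with
mean x̄_n is the shrinkage estimate

    Ŷ = μ_pop + (x̄_n − μ_pop) · B_n ,   B_n = B₁n / (B₁n + (1 − B₁))

and the next result is flagged when

    |X_{n+1} − Ŷ| > Z · √(1 − B₁·B_n) · σ_pop        (Z = 1.96 two-sided 95%)

This one formula unifies the three tools: at n = 0 it *is* RI_pop; at n = 1
it is a regression-corrected RCV, strictly narrower than the classical
lognormal RCV (`√(1 − B₁²)·σ_pop < √2·σ_I` whenever σ_G > 0); as n grows it
converges to the fully personal interval `Ŷ ± Z·σ_I`.

The three parameters (μ_pop, σ_pop, B₁) come from either of two pathways:

- **Routine laboratory (LIS) data** — a Box-Cox-normal "central peak" fit to
  first-per-patient results gives λ, μ_pop, σ_pop; results outside the
  central 99% are dropped; sequential result pairs more than 24 h apart are
  robust-regressed (x_next on x_prev) and the slope is B₁.
- **A biological-variation (BV) study** — nested ANOVA with a four-level
  outlier cascade (analytical, Reed participant-mean, time-trend, variance
  homogeneity) yields CV_I and CV_G; with the analytical CV_A from quality
  control, `σ_I² = ln(1 + (CV_I² + CV_A²)/10⁴)`, `σ_G² = ln(1 + CV_G²/10⁴)`
  on the log scale.

## Worked example

```python
from pebri import BVEstimates, bv_to_peb, peb_threshold

# albumin-like biological variation (CVs in percent; mean in g/dL)
bv = BVEstimates(cv_i_pct=2.3, cv_g_pct=6.0, cv_a_pct=1.8, mu_pop_original=4.522)
params = bv_to_peb(bv)
print(f"B1 = {params.b1:.3f}")

for history in ([], [4.0], [4.0, 4.1, 4.0]):
    d = peb_threshold(history, params, n_use=len(history))
    print(f"n={d.n_prior}: [{d.lower:.3f}, {d.upper:.3f}] g/dL")
```

```
B1 = 0.808
n=0: [3.968, 5.153] g/dL
n=1: [3.792, 4.423] g/dL
n=3: [3.809, 4.342] g/dL
```

At n = 0 everyone shares the population interval (width 1.19 g/dL). One
prior result of 4.0 g/dL already narrows the interval to 0.63 g/dL and
recenters it — not on 4.0, but partway back toward the population mean
(shrinkage). Three prior results tighten it to 0.53 g/dL. A new result
outside the printed limits would be a statistically significant deviation
from this patient's own baseline at the 95% level.

The same works from the command line:

```bash
pebri simulate --subjects 700 --visits 3 --out cohort.csv
pebri fit-lis cohort.csv --out params.yaml
pebri evaluate cohort.csv params.yaml --out report.csv
pebri thresholds params.yaml --history 4.0,4.1,4.0
```

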
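# trajmix

Clustering of longitudinal trajectories with simultaneous variable selection,
via finite mixtures of lasso-penalized random-intercept linear mixed-effects
models.

## The problem

Longitudinal cohort studies — the motivating example is daily
moderate-to-vigorous physical activity (MVPA, minutes/day) of adolescent
girls measured at three waves (ages 14, 17, 23) together with ~31 candidate
individual, social and neighborhood covariates — often hide distinct
subgroups: some participants maintain a flat activity level, some decline,
a few increase. Two-step pipelines (cluster the outcome trajectories, then
select covariates on the pooled sample) rest on contradictory assumptions.
`trajmix` implements the one-step alternative: a finite mixture in which
each latent cluster g carries its own sparse linear mixed-effects model, so
clustering and per-cluster variable selection happen in a single fit.

## The model

For subject i with stacked outcome vector `y_i` (n_i records), fixed-effects
design `X_i` (intercept, wave indicator, candidate covariates) and a subject
random intercept (`Z_i = 1`):

    y_i | cluster g  =  X_i beta_g + Z_i b_i + eps_i,
    b_i ~ N(0, sigma_g^2 d_g),     eps_i ~ N(0, sigma_g^2 I),

so marginally `y_i ~ N(X_i beta_g, sigma_g^2 (d_g J + I))`. The observed-data
likelihood is the mixture `sum_g pi_g phi_g(y_i)`, and the fit maximizes the
penalized objective

    sum_i log sum_g pi_g phi_g(y_i)  -  lambda1 sum_g ||beta_g||_1

(the intercept is never penalized) by alternating an exact E-step
(responsibilities `w_ig` and mixing weights `pi_g`) with a per-cluster
penalized M-step: coordinate descent with soft-thresholding on `beta_g`
under the whitened weighted least-squares objective, then a profile update
of `(d_g, sigma_g^2)`. The number of clusters G and the penalty `lambda1`
are chosen by BIC over a grid, with `-2 loglik + df log N` and df counting
nonzero fixed effects, 2G variance parameters, and G-1 mixing weights.

## Worked example

```python
import trajmix as tm

# a cohort with clearly separated trajectory clusters: 568 subjects,
# 3 waves with monotone dropout, 31 candidate covariates
cohort, truth = tm.simulate_cohort(tm.inflated_separation_spec(), seed=0)

res = tm.MixtureLMM.from_dataset(
    cohort, G=3, config=tm.FitConfig(seed=0, n_starts=3)
).select(G_grid=[2, 3, 4])
print(res.summary())
print("ARI vs truth:", round(tm.adjusted_rand_index(res.labels, truth["cluster"]), 3))
```

prints (selection table abridged):

```
Mixture of penalized linear mixed-effects models
====================================================
subjects: 568   observations: 1577   candidates: 32
G = 3   lambda1 = 3.813   converged: True (26 iterations)
loglik = -6132.767   BIC = 12545.338

Components
----------------------------------------------------
[0] increaser    n=47   pi=0.086  intercept=  30.265  wave=  19.783  sigma=10.723  d= 0.598  nonzero=2
[1] decreaser    n=304  pi=0.539  intercept=   4.725  wave= -22.799  sigma= 8.018  d= 0.547  nonzero=9
[2] maintainer   n=217  pi=0.375  intercept=  13.082  wave=  -0.357  sigma= 6.120  d= 0.433  nonzero=16

Selected coefficients (original covariate scale)
----------------------------------------------------
                   cluster_0 cluster_1 cluster_2
intercept              7.399    30.939    13.435
wave                  24.830   -28.615    -0.448
self_management                  0.093
belief                          -0.535    -0.237
social_support                  -1.684
distance_to_school     0.268               0.142
number_of_parks                 -0.025     0.448
...
ARI vs truth: 0.935
```

BIC picked G = 3 and a mid-path penalty; the three components recover the
generative increaser/decreaser/maintainer structure (generative wave slopes
+30, −30, −1.1 on the raw scale) and the adjusted Rand index against the
true partition is 0.935. The component coefficients inside the header block
are on the standardized-covariate scale; the selection table back-transforms
them to original units. Weak spurious covariates can survive at the
BIC-optimal penalty (see `docs/methods.md` on the penalty's scale coupling);
the strong true effects (e.g. `social_support` −1.75 in the decreaser
cluster) are recovered with the right sign and magnitude.

The same pipeline is scriptable from the shell:

```bash
trajmix simulate --seed 1 --out cohort.csv --truth-out truth.csv
trajmix select --data cohort.csv --g-grid 2,3,4 --out search.json --grid-csv grid.csv
trajmix fit --data cohort.csv -G 3 --lambda1 3.6 --out model.json
trajmix report --data cohort.csv --model model.json --out-dir reports/
```

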
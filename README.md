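# conseed — consecutive seeding of metastases

`conseed` models a metastasis that is **seeded repeatedly** by cells
migrating from another tumor, rather than founded exactly once.  The model
is a multitype continuous-time branching process with immigration: cells of
clone *i* (of *N* clones in the source tumor) arrive at the metastatic site
at a constant rate λᵢ (cells/day) and then divide at rate *b* and die at
rate *d* (*b* > *d*).  Everything depends on the rates only through

* the **seeding influx** kᵢ = λᵢ/b — mean number of clone-*i* cells arriving
  per cell generation (total k = Σkᵢ),
* the **lineage survival probability** ρ = 1 − d/b,
* the **net growth rate** r = b − d,

and the **detection size** Y at which the metastasis is examined.

The package provides three layers:

1. **Closed forms** (`conseed.analytic`): the clone sizes at detection
   follow a Dirichlet-multinomial (Pólya-urn) law and the clone *frequencies*
   a Dirichlet(k₁,…,k_N) law, giving the mean clone number
   n̄ = N − Σᵢ C(Y+k−kᵢ−1, Y)/C(Y+k−1, Y), the polyclonality probability
   P(n>1) = 1 − Σᵢ C(Y+kᵢ−1, Y)/C(Y+k−1, Y), the transferred diversity
   D̄₂/D₁ = k/(1+k) (Simpson index), the fixation index
   F_ST = (1 − 1/M)/(1+k) across M metastases, and the expected number of
   surviving seeded cells X̄ = k[ln(ρY) − ψ(k)].  All binomial-coefficient
   ratios are evaluated in log-gamma space, so Y up to 10⁹ and non-integer
   kᵢ are handled exactly.
2. **Stochastic simulation** (`conseed.simulate`): an exact Gillespie
   engine with per-seed lineage tagging, plus a fast hybrid mode that
   promotes large lineages to their limiting growth law (validated against
   the exact engine in the test suite).
3. **Inference** (`conseed.inference`): maximum-likelihood estimation of the
   per-tumor seeding influx k̂ⱼ (and, jointly, the source-tumor clone
   composition γ̄) from a clones × samples frequency matrix, with
   multiplicative 95% confidence intervals k̂ⱼ·e^(±1.96σⱼ), σⱼ² = α/(N−1),
   α ∈ [1,2], the fast approximation k̂ⱼ ≈ (N−1)/(α·D_KL(γ̄‖γⱼ)), and
   per-sample diagnostics.

It is aimed at cancer-genomics researchers who have clone frequencies from
multi-region/multi-tumor sequencing (after upstream clonal deconvolution)
and want to quantify how many cells seeded each lesion, and at modellers who
need a validated simulator and the exact composition laws.

## Worked example

Fit seeding influxes for three metastases with a known source composition:

```python
import conseed as cs

gamma_bar = [0.25, 0.40, 0.35]                      # source clone mix
cohort = cs.generate_cohort(gamma_bar, [1.5, 4.0, 8.0], seed=7,
                            clone_labels=["c1", "c2", "c3"],
                            sample_labels=["met1", "met2", "met3"])
res = cs.estimate_influx_known_primary(gamma_bar, cohort)
print(res.summary())
```

```
Consecutive-seeding influx estimates (Dirichlet MLE)
================================================================
samples: 3   clones: 3   log-likelihood: 4.9640
primary composition known; converged in 1 iteration(s)
max stationarity residuals: sample 8.78e-16  (clone conditions apply to joint fits only)
----------------------------------------------------------------
      k_hat  ci_low  ci_high  sigma2  alpha  kl_divergence  degenerate
met1  3.342   0.622    17.95  0.7358  1.472         0.3567       False
met2  1.199  0.2635    5.452  0.5973  1.195          1.182       False
met3  11.02   1.736    70.02  0.8897  1.779        0.09639       False
----------------------------------------------------------------
gamma_bar: c1=0.25, c2=0.4, c3=0.35
```

`met3`'s composition is closest to the source (KL divergence 0.096), so it
must have received the largest influx (k̂ ≈ 11 cells per generation);
`met2` diverged most and was seeded least.  With N = 3 clones the CIs span
roughly a factor five either side.  Converting influxes to seeded cells at a
typical survival probability ρ = 5% and detection size Y = 10⁸:

```python
x = res.seeded_cells(rho=0.05, detect_size=1e8)   # X = k[ln(rho Y) - psi(k)]
# met1 48.0, met2 18.8, met3 144.1 surviving seeded cells
```

Forward predictions for a tumor with total influx k = 2.7 (the CLI
equivalent is `conseed predict --config model.yaml --out out/`):

```python
m = cs.SeedingModel.from_scaled([0.6, 1.2, 0.9], survival_prob=0.05,
                                net_growth=0.0125)
cs.predict_table(m, [1e7, 1e8, 1e9], n_mets=4)
```

```
         Y  k_total  mean_n_clones  p_polyclonal  diversity_transfer      fst  expected_seeded_cells  mean_detection_time_days
  10000000      2.7       2.999906           1.0             0.72973 0.202703              33.279067                986.046417
 100000000      2.7       2.999977           1.0             0.72973 0.202703              39.496046               1170.253224
1000000000      2.7       2.999994           1.0             0.72973 0.202703              45.713026               1354.460032
```

At this influx nearly every metastasis is polyclonal, 73% of the source's
clonal diversity is transferred on average, and a lesion detected at 10⁸
cells was built from about 40 surviving seeded cells over ~3 years.

A command-line surface (`conseed predict|simulate|infer|robustness`) wraps
the same functions; every run writes TSV tables plus a JSON manifest with
the settings and RNG seed.

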
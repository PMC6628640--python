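# Methods

## Model

A metastasis grows as a multitype linear birth–death process with
immigration.  Clone *i* ∈ {1,…,N} cells arrive from the source tumor as a
Poisson stream of rate λᵢ (cells/day, constant: the source is assumed
mature, its clone mix stable); each cell in the lesion divides at rate *b*
and dies at rate *d*, independently.  The neutral regime is assumed
throughout: one (b, d) pair is shared by all clones within a tumor (rates
may differ between tumors).  Growth is evaluated at the detection time T,
the first time the total size reaches Y cells.

Working parameters: influx kᵢ = λᵢ/b (dimensionless, per-generation),
survival probability ρ = 1 − d/b, net growth rate r = b − d.  In scaled
time (b = 1), kᵢ = λᵢ and ρ = r.  `SeedingModel` stores rates per day and
computes scaled views on demand; conversions are bijective and round-trip
to 1e-12 relative as long as d/b is not within ~1e-3 of criticality (the
subtraction 1 − d/b then loses precision in double arithmetic — a property
of the parameterization, not the implementation).

Key consequences implemented in `analytic`:

* mean clone size ȳᵢ(t) = (kᵢ/ρ)(e^{rt} − 1), the solution of
  ȳ′ = rȳ + λᵢ;
* clone size at fixed t: negative binomial with (possibly non-integer)
  shape kᵢ and q = kᵢ/(ȳᵢ + kᵢ);
* clone cell counts at detection: Dirichlet-multinomial with weights kᵢ
  (equivalently, a Pólya urn with double replacement); clone frequencies:
  Dirichlet(k₁,…,k_N), hence Beta marginals with variance
  γ̄ᵢ(1−γ̄ᵢ)/(1+k);
* mean clone number n̄, polyclonality probability P(n>1), the small-k
  approximation P(n>1) ≈ 1 − κ!·Y^{−κ} with κ = k(1−1/N), transferred
  Simpson diversity k/(1+k), fixation index (1−1/M)/(1+k), surviving seeded
  cells X̄ = k[ln(ρY) − ψ(k)] and mean detection time T̄ = X̄/(ρλ).

Numerics: every binomial-coefficient ratio is a difference of `gammaln`
values — no factorial is ever formed — so Y ≤ 10⁹ and real-valued shapes
are exact to double precision.  The Dirichlet log-density returns an
explicit +∞ (with a warning) at a boundary frequency whose concentration is
below one.

Two definitional points that were genuinely open:

* The Simpson index is the probability that two random cells are of
  different clones, D = 1 − Σγᵢ²; presentations that plot "twice" this
  probability are treated as a display rescale, since the transfer and
  fixation identities (k/(1+k), (1−1/M)/(1+k)) hold for D itself.
* X̄ counts seeding events whose lineage **survives long-run**, not merely
  lineages extant at detection.  The identity X̄ = ρλT̄ forces this
  reading: doomed lineages linger (standing crop ≈ λ(1−ρ)/r cells), so the
  extant-lineage count exceeds X̄ by a Y-independent offset.  The simulator
  reports both (`n_surviving_seeds`, `n_extant_lineages`).
* P(n>1) is monotone in Y and under uniform scaling of all influxes, but
  **not** in a single kᵢ: one dominant clone suppresses detected
  polyclonality.  The property tests assert the correct monotonicities.

## Self-seeding first event

When a metastasis (rather than the primary) is the seeding source, the
surviving-seed stream is an inhomogeneous Poisson process whose rate is
proportional to the source's exponentially growing size, normalized so that
at the source's mature size the surviving influx is k per generation.  In
units of the source's size fraction f of mature size, the integrated rate
is k·f, so the first-event fraction is exponential with rate k and its
geometric mean is e^{−γ_EM}/k ≈ 0.5615/k (γ_EM the Euler–Mascheroni
constant), capped at 1 when quoted as a fraction of mature size.  The
geometric-mean (mean-log) reading is adopted because it reproduces the
published 56% figure at k = 1; the closed form is validated against an
event-level thinning simulation (`simulate_first_seeding_fraction`), which
deliberately simulates candidate events window by window rather than
inverting the CDF.

## Simulator

`exact` mode is a plain Gillespie simulation: event rates are immigration
λᵢ, birth b·y and death d·y; each immigration opens a tagged lineage;
detection is the first event after which the total size is ≥ Y (so the
final size may overshoot by the last event's single cell).  Ties cannot
occur under continuous exponential clocks.  A configurable event budget
(default 10⁸) turns runaway runs into an explicit `EventBudgetError`.
Established seeds are counted at detection by giving each extant lineage of
s cells its exact future-survival probability 1 − (d/b)^s.

`hybrid` mode accelerates large detection sizes by a per-lineage promotion:
when a lineage reaches `promote_size` cells (default 64), the martingale
limit of a linear birth–death process is sampled — each of the n current
cells contributes weight 0 with probability 1 − ρ, else Exp(1/ρ), so the
lineage's future is B ~ Binomial(n, ρ) surviving roots and a deterministic
Gamma(B, 1/ρ)·e^{rt} trajectory.  B = 0 occurs with exactly the true
extinction probability (d/b)^n; such a lineage stays in the stochastic pool
conditioned on extinction (birth and death rates swapped — the exact
conditional law), so doomed cells still linger and presence calls are
unbiased.  Immigration and all small lineages remain fully stochastic.
What the promotion discards is the finite-time fluctuation of an
already-large lineage around its growth asymptote, an error that vanishes
as Y/promote_size grows; the crossover test compares exact and hybrid runs
at the same Y and the reduced-size acceptance test runs hybrid against the
closed forms.  Replicate seeds derive from one master seed via
`SeedSequence`; runs are bit-reproducible for fixed seed and budget.

Problem sizes used by the test suite: the analytic-versus-simulation check
runs 10⁵ hybrid replicates at Y = 10⁴ (≈ 40 s); the exact/hybrid crossover
uses Y = 2000; fixed-time negative-binomial checks use ~2×10⁴ exact
replicates.  These sizes keep Monte-Carlo error small relative to the
3-standard-error acceptance bands while the full suite stays in minutes;
the composition laws are scale-free in Y, so nothing but Monte-Carlo width
depends on this choice.

## Inference

Given frequencies γᵢⱼ (clones × samples, each column a tumor), the model
likelihood is Dirichlet with concentrations kⱼ·γ̄ᵢ per sample.  The MLE
satisfies Σᵢγ̄ᵢβᵢⱼ = 0 per sample and Σⱼkⱼβᵢⱼ = 0 per clone, with
βᵢⱼ = ln γᵢⱼ − [ψ(kᵢⱼ) − ψ(kⱼ)].

* **Known primary:** the per-sample score in ln kⱼ decreases monotonically
  from +∞ to −D_KL(γ̄‖γⱼ), so a bracketed Brent solve is exact and the
  estimate diverges iff the divergence is ~0.  Diverging estimates are
  capped (default 10³) and flagged `degenerate` — near-identical
  compositions genuinely carry no upper information about the influx.
* **Joint:** block-coordinate ascent alternates exact per-sample root
  solves with an exact concave maximization over γ̄ on the simplex (nested
  root search on the KKT multiplier), so the objective is provably
  nondecreasing; after the objective plateaus (relative change < 1e-10, at
  most 500 rounds, else an explicit `ConvergenceError`) a Newton solve of
  the full stationarity system polishes both families of residuals to
  ~1e-13.  Capped samples stay pinned, in which case the stationarity
  system cannot be satisfied exactly and the residuals report that honestly.
  With few samples the joint likelihood can be genuinely unbounded (a
  feedback between one sample and γ̄); the cap keeps arithmetic finite and
  the flag marks the affected samples.
* **Zero frequencies** break ln γᵢⱼ; policy `floor` (default) sets zeros to
  half the smallest nonzero frequency in that sample and renormalizes (the
  least-informative completion preserving normalization), `drop` removes
  clones absent from every sample, `error` refuses.  Substitutions are
  logged.
* **Uncertainty:** Var(ln k̂ⱼ) = σⱼ² = α/(N−1) with α ∈ [1,2].  The
  default α is the observed-curvature interpolation
  α = (N−1)/(k̂²·I(k̂)), I(k) = Σγ̄ᵢ²ψ′(kγ̄ᵢ) − ψ′(k), which equals 1
  exactly in the high-divergence (k→0) limit and 2 in the low-divergence
  (k→∞) limit and is clipped to [1,2] between.  This choice is what makes
  the 95% multiplicative interval k̂·e^{±1.96σ} calibrate at nominal
  coverage in the recovery experiment; the KL-based fast approximation
  (N−1)/(α·D_KL) exposes both regime endpoints as a bracket plus a
  log-linear heuristic interpolation for use when no MLE is available.

## Synthetic cohorts and robustness

`generate_cohort` draws each sample from Dirichlet(kⱼ·γ̄) — exactly the
law the inference assumes — so estimator calibration can be measured with
known truth.  What it does *not* emulate: finite detection size (columns
are the large-Y frequency limit), sequencing depth and clone-deconvolution
error structure, or within-patient correlation between samples.  Passing
calibration here therefore validates the estimator under its own model, not
robustness to model misspecification; the noise experiment probes the
simplest violation.

The robustness experiment, per sample: draw a true influx from a lognormal
law (median 3, log-sd 0.5 — inside the range inferred from published
patient cohorts), draw frequencies for N = 10 clones from the composition
law with a uniform primary mix, estimate k̂ (known-primary), multiply every
frequency by an independent unit-median lognormal factor with 50%
linear-scale coefficient of variation, renormalize, re-estimate, and record
|k̂_ξ − k̂|/k̂.  Mean, median, 90th percentile and maximum are reported
(degenerate estimates excluded with a logged count), because which summary
the published "<6.3%" bound refers to is not stated; under these conditions
the mean is dominated by the low-divergence tail and sits above the median.
`scripts/acceptance.py` reports the mean, as the most conservative common
reading.

## Known limitations

* Neutral diversity only: no per-clone (bᵢ, dᵢ) fitness differences.
* Seeding rates are constant in time; a still-growing source tumor is not
  modelled (its effect enters only through the self-seeding first-event
  result).
* No cluster (multi-cell) seeding events, no spatial structure, no new
  mutations arising inside the metastasis, no metastasis-to-metastasis
  seeding networks.
* The inference treats samples as independent given (γ̄, kⱼ) and takes
  clone frequencies as measured; calling clones from reads is upstream of
  this package.
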
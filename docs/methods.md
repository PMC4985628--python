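# Methods

## The model

`neutralsad` fits and tests Hubbell's neutral model of biodiversity on
per-sample species abundance distributions (SADs) from microbiome OTU
tables. A local community of `J` individuals turns over one individual at a
time; the replacement is an immigrant from the metacommunity with
probability `m`, otherwise the offspring of a random local individual. The
metacommunity itself is governed by the fundamental biodiversity number
`θ`. Two exact sampling formulas give the probability of an observed
abundance configuration `D = {n_1..n_S}`:

* **Ewens** (no dispersal limitation, `m = 1`):
  `P(D|θ) = J!/(Π n_i Π φ_a!) · θ^S/(θ)_J`,
  with `(θ)_J` the rising factorial and `φ_a` the number of species seen
  exactly `a` times.
* **Etienne** (dispersal limitation through `I = m(J−1)/(1−m)`):
  `P(D|θ,m) = J!/(Π n_i Π φ_a!) · θ^S/(I)_J · Σ_{A=S}^{J} K(D,A) I^A/(θ)_A`,
  where `A` counts ancestral immigrant lineages and `K(D,A)` is a sum over
  allocations `{a_i}` of products of unsigned Stirling numbers of the first
  kind, `Π_i s̄(n_i,a_i) s̄(a_i,1)/s̄(n_i,1)`.

Raw OTU read counts are treated as individuals; zero-count OTUs are dropped
per sample (the formulas are defined over present species). No rarefaction
or normalization is applied by default; an opt-in rarefaction exists for
very deep samples because the `K(D,A)` computation costs `O(J·Σ n_i)`.

## Numerics

Everything is carried in log space end to end; no probability is ever
exponentiated outside tests on tiny `J`.

* Stirling numbers follow the recurrence `s̄(n+1,a) = s̄(n,a−1) + n·s̄(n,a)`
  via `logaddexp`. A dense triangular table is available up to `n = 8192`
  (memory guard); above that a single sweep materializes only the rows
  actually needed (one row per distinct abundance), which is how samples
  with `J` in the tens of thousands stay in memory.
* `K(D,A)` is a log-space polynomial convolution: species `i` contributes
  the coefficient vector `c_i(a) = s̄(n_i,a)(a−1)!/(n_i−1)!`, `a = 1..n_i`.
  Singletons contribute `[1]` and reduce to an index shift, so
  singleton-rich neutral samples are cheap. Vectors are convolved smallest
  first to keep intermediates short.
* Rising factorials `(x)_y` are exact `O(J)` sums of `log(x+k)` (cumulative
  sums give `(θ)_A` for all `A` in one pass). The gammaln-difference form
  was rejected: at `I ≈ 2·10¹¹` (i.e. `m = 1−10⁻⁹`) it loses ~10⁻³ absolute
  through cancellation, which would swamp the Etienne→Ewens limit.
* Ewens MLE: the score equation `S = Σ_{k<J} θ/(θ+k)` has a strictly
  increasing left side, so Brent bracketing on `[10⁻⁸, 10⁸]` (relative
  tolerance 10⁻¹⁰) is exact. `S = 1` and `S = J` push the maximum to the
  boundary; such fits return the cap with `converged=False`.
* Etienne MLE: Nelder–Mead over `(log θ, logit m)` from a 3×4 multi-start
  grid (θ at {½, 1, 2}× the Ewens estimate; m at {0.1, 0.5, 0.9, 0.999}),
  K-series computed once per sample, convergence at `fatol = 10⁻⁶`. `m` is
  capped to `[10⁻⁹, 1−10⁻⁹]`: the likelihood is flat in `m` near 1 whenever
  dispersal limitation is absent, and an open interval is required by the
  formula. The cap is tight enough that the Etienne maximum never falls
  below the Ewens maximum by more than 10⁻⁶ at the sample sizes used here
  (the residual scales like `J²(1−m)`), which a looser cap would violate.
* **Ridge tie-break.** The Etienne surface has a near-flat ridge connecting
  `(θ, m→1)` to `(θ→∞, I ≈ θ_Ewens)`: both ends reproduce the Ewens
  formula, one by construction, the other because at `θ→∞` every ancestor
  is a new species and `I` plays θ's role. Among starts tied within 10⁻⁴
  log-likelihood units, the fit with the largest `m̂` is reported — the
  nested-model end — which keeps no-dispersal-limitation fits reproducible
  and matches the field's convention of reporting `m ≈ 1` there.

## Tests of neutrality

* **Likelihood-ratio test** (Ewens null vs Etienne alternative):
  `D = 2(logL₁ − logL₀)` referred to χ²(1); `p > α` is recorded as "no
  significant difference" (NSD). The models are nested, so `D ≥ 0` up to
  optimizer noise (tiny negatives floored at 0).
* **Exact neutrality test**: fit by MLE, simulate `n_sim = 100` artificial
  communities at the fitted `(θ, m, J)` with the sequential-construction
  urn (individual `j` immigrates with probability `I/(I+j−1)`; lineage `k`
  founds a new species with probability `θ/(θ+k−1)`), score everything at
  the fitted parameters, and compare. Two p-values are reported:
  `chisq` refers `q = 2|logL_obs − mean(logL_sim)|` to χ²(1) (the
  convention of the published survey tables this package reproduces;
  absolute value because the observed likelihood can fall on either side of
  the simulated mean), and `empirical`, the rank
  `(1+#{logL_sim ≤ logL_obs})/(n_sim+1)`. The default variant is `chisq`
  for table compatibility, but only the empirical variant is calibrated:
  on true neutral data the chisq variant rejects far above its nominal
  level because the observed log-likelihood is maximized while the
  simulated ones are not. Calibration claims in the test suite therefore
  use the empirical variant. An optional refit mode scores each artificial
  dataset at its own MLE instead; it is off by default.
* One root seed per test/survey is split into per-replicate substreams by
  index, so every result is bit-reproducible and independent of evaluation
  order.

## Synthetic data

The generator emulates 16S survey tables (depths `J ~ 10²–10⁴`, richness
`S ~ 10–500`, the 18-site/5-location metadata vocabulary) from three SAD
models: neutral draws at known `(θ, m, J)` via the simulator; a geometric
(niche pre-emption) series with dominance `k` — expected share
`k(1−k)^(i−1)` renormalized over `S` species; and a lognormal. Niche counts
are one multinomial of size `J` per sample. Defaults are the calibration
conditions used throughout the tests: neutral `(θ=40, m=0.9, J=1000)`,
geometric `(k=0.5, S=11, J=2000)`, lognormal `(σ=1.5, S=100, J=2000)`.
OTU identity is not matched across samples — every statistic here is a
per-sample SAD function. No sequencing-error or compositional artifacts
are emulated, so passing tests say nothing about read-level noise in real
data.

## Known limitations

* **No power against geometric SADs.** The ranked-share profile of a
  geometric series with ratio `1−k` coincides with the expected ranked
  profile of the neutral (Poisson–Dirichlet) family at the θ solving
  `θ/(1+θ) = 1−k`, so a geometric sample sits squarely in the typical set
  of its own fitted neutral model. Measured rejection rates of the exact
  test against geometric fixtures are ≈0% at any dominance `k` (0.2–0.8),
  under the empirical, chisq and refit variants alike. This is a property
  of single-sample SAD-likelihood tests, not of this implementation: the
  same machinery rejects a perfectly even SAD 100% of the time at the
  empirical floor `1/(n_sim+1)` and lognormal-share fixtures at ~60%.
  Conclusions from this test about niche structure are correspondingly
  weak whenever the alternative mimics a neutral rank profile.
* The chisq exact-test variant is anti-conservative on true neutral data
  (~40% false rejection measured at `θ=40, m=0.9, J=1000`); it is kept
  because it is what the published per-sample tables print.
* θ and `I` are poorly identified from a single sample when dispersal
  limitation is weak (the ridge above); `m̂` near the cap should be read as
  "no evidence of dispersal limitation", not as an estimate of 1.
* Problem sizes in the test-suite calibrations (50 replicates, `n_sim=100`,
  `J ≤ 2000`) were chosen to make the Monte-Carlo assertions stable at
  desk scale; the library itself handles `J` up to the configurable guard
  of 30 000.
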
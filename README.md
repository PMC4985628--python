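# neutralsad

Neutral-theory testing for microbiome species abundance distributions.

`neutralsad` asks, for each sample of a 16S OTU count table: *is this
community's abundance pattern consistent with neutral assembly?* It is
aimed at microbial ecologists who want the two classical sampling-formula
likelihoods, their maximum-likelihood fits, and the standard neutrality
tests in one place, at survey scale (thousands of samples), with exact
log-space numerics.

## What it computes

For a sample with abundances `n_1..n_S` (`J = Σ n_i` reads, `φ_a` species
seen `a` times):

* **Ewens sampling formula** — the neutral likelihood without dispersal
  limitation (`m = 1`):
  `P(D|θ) = J!/(Π n_i Π φ_a!) · θ^S/(θ)_J`,
  with MLE of the fundamental biodiversity number θ from the score
  equation `S = Σ_{k<J} θ/(θ+k)`.
* **Etienne sampling formula** — adds an immigration probability `m`
  through `I = m(J−1)/(1−m)`:
  `P(D|θ,m) = J!/(Π n_i Π φ_a!) · θ^S/(I)_J · Σ_{A=S}^{J} K(D,A) I^A/(θ)_A`,
  with the dispersal kernel `K(D,A)` built from unsigned Stirling numbers
  of the first kind and joint MLE of `(θ, m)`.
* **Likelihood-ratio test** between the two (χ², 1 df): is dispersal
  limitation detectable, or do the formulas make *no significant
  difference* (NSD)?
* **Exact neutrality test**: simulate 100 artificial communities at the
  fitted `(θ, m, J)` with the sequential-construction urn and compare the
  observed sample's likelihood against the ensemble — no alternative model
  required.
* **Synthetic OTU tables** with known ground truth (neutral, geometric
  niche, lognormal) for calibration and power studies, plus batch survey
  reporting (per-sample tables, per-site NSD/neutral summaries,
  rank-abundance exports).

See `docs/methods.md` for the model, numerics, and known limitations.

## Worked example

```python
import numpy as np
from neutralsad import (
    SyntheticSpec, generate_table, sample_to_sad,
    lrt_ewens_vs_etienne, exact_neutrality_test,
)

# 20 neutral communities at known truth: theta=40, m=0.9, J=1000 reads
spec = SyntheticSpec(n_samples=20, generator="neutral",
                     theta=40.0, m=0.9, J=1000, seed=7)
table, truth = generate_table(spec)

sad = sample_to_sad(table, table.sample_ids[0])
lrt = lrt_ewens_vs_etienne(sad)
exact = exact_neutrality_test(sad, n_sim=100, seed=1, variant="empirical")
print(f"J={sad.J} S={sad.S}")
print(f"theta={exact.fit.theta:.2f} m={exact.fit.m:.3f}")
print(f"LRT: D={lrt.deviance:.3f} p={lrt.p_value:.4f} nsd={lrt.nsd}")
print(f"exact test: q={exact.q:.3f} p_emp={exact.p_empirical:.3f} "
      f"neutral={exact.neutral}")
```

Output:

```
J=1000 S=131
theta=45.85 m=0.569
LRT: D=1.421 p=0.2332 nsd=True
exact test: q=0.273 p_emp=0.436 neutral=True
```

Read: the fitted biodiversity number (45.9) brackets the generating truth
(40); the LRT deviance (1.42, p = 0.23) means dispersal limitation is not
detectable in this sample (NSD, as expected at m = 0.9 and this depth —
m̂ is then only weakly identified); and the observed log-likelihood sits at
the 44th percentile of the 100-community null ensemble, so neutrality is
not rejected.

The same pipeline runs from the shell:

```
neutralsad synth --generator neutral --n-samples 20 --theta 40 --m 0.9 \
    -J 1000 --seed 7 --out-dir fixtures/
neutralsad survey --otu-table fixtures/otu_table.wide.tsv \
    --metadata fixtures/otu_table.metadata.tsv --n-sim 100 --seed 1 \
    --out-dir results/
```

which writes `per_sample.tsv` (one row per community: J, S, θ, m,
log-likelihoods, q, p, NSD and neutral flags), `site_summary.tsv`
(per-site counts and NSD percentages) and `run_config.yaml`.

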
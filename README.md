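# isofoodweb

Stable-isotope food-web analysis for two-site community comparisons — built
for studies that contrast a reference site with a perturbed one (the
motivating case is a seagrass bed at a shallow CO₂ vent versus a control
bed) using replicated quadrat sampling and δ¹³C/δ¹⁵N measurements of basal
sources and consumers.

The package provides, as a tested and reusable pipeline:

* **Community structure** — Sorensen similarity `S = 2a/(2a+b+c)` between
  site taxon sets, Shannon diversity `H′ = −Σ pᵢ log₂ pᵢ`, Pielou evenness
  `J′ = H′/H′max`, densities per m², trophic-group composition, Student/Welch
  t-tests between sites, and Kruskal–Wallis with a Dunn/Bonferroni post-hoc.
* **Isotopic niche** — the five Layman community metrics (NR, CR, CD, NND,
  SDNND), the standard ellipse area `SEA = π√det Σ̂` with small-sample
  correction `SEAc = SEA·(n−1)/(n−2)`, Bayesian SEA posteriors under a
  conjugate normal–inverse-Wishart model, and the overlap area of two SEAc
  ellipses.
* **Trophic position** — `TL_c = (δ¹⁵N_c − δ¹⁵N_b)/Δₙ + λ` against a
  designated primary-consumer baseline (defaults Δₙ = 2.5‰, λ = 2).
* **Bayesian mixing model** — diet proportions `p` of each consumer species
  over 2–4 aggregated basal sources (seagrasses, algae, epiphytes, SOM) with

  `x_ij ~ Normal( Σₖ pₖ(μₖⱼ + μ_TEF,ⱼ), Σₖ pₖ²(σₖⱼ² + σ_TEF,ⱼ²) + τⱼ² )`,

  `p ~ Dirichlet(1)`, half-normal residual SDs, Metropolis-within-Gibbs
  sampling, and posterior mean / KDE mode / 95% highest-density region per
  source with split-chain R-hat diagnostics. Default trophic enrichment
  factors are the herbivore values 2.5 ± 2.5‰ (δ¹⁵N) and 0.47 ± 1.23‰ (δ¹³C).
* **Synthetic studies** — a generator that emulates the two-site replicated
  design (4 quadrats of 30 × 30 cm per site, negative-binomial counts,
  vent-ward isotopic depletion, consumers drawn from known diets) with a
  ground-truth ledger, so every stage is testable in a closed loop.

## Worked example

```python
import numpy as np
from isofoodweb import (MixingModel, SourceGroup, TEF,
                        sorensen_index, layman_metrics)

# similarity of the two sites' taxon lists (11 shared, 32 vs 23 taxa)
control = {f"t{i}" for i in range(32)}
vent = {f"t{i}" for i in range(21, 44)}
print(round(sorensen_index(control, vent), 2))       # 0.4

# diet of one consumer species from two isotopically distinct sources
sources = [SourceGroup("plant", -20.0, 0.5, 0.0, 0.5, 10),
           SourceGroup("detritus", -10.0, 0.5, 10.0, 0.5, 10)]
rng = np.random.default_rng(1)
p = np.array([0.7, 0.3])                             # true diet
mu = np.array([[-20.0, 0.0], [-10.0, 10.0]]) + [0.47, 2.5]
sd = np.sqrt((p**2) @ (0.25 + np.array([1.23, 2.5])**2))
consumers = rng.normal(p @ mu, sd, size=(30, 2))     # 30 specimens

result = MixingModel(consumers, sources, tef=TEF()).fit(seed=3)
print(result.summary().round(3))
```

```
           mean   mode  ci_low  ci_high  q_low  q_high   rhat
source
plant     0.697  0.697   0.659    0.729  0.662   0.732  1.001
detritus  0.303  0.303   0.271    0.341  0.268   0.338  1.001
```

The posterior mean diet (≈70% plant, ≈30% detritus) recovers the proportions
the specimens were generated from; `ci_low`/`ci_high` is the 95%
highest-density region, `q_low`/`q_high` the central interval, and `rhat`
the split-chain convergence diagnostic (values ≤ 1.1 indicate convergence).

The full pipeline (community → niche → trophic levels → mixing) runs from
the command line:

```sh
isofoodweb run --seed 7 --out-dir results      # paper-like synthetic preset
isofoodweb simulate --seed 7 --out-dir data    # just the synthetic inputs
```

and writes a reproducibility manifest before any results, then CSV tables
(diversity, densities, niche summary, trophic levels, mixing posteriors) and
a JSON run report.

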
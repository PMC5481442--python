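# Methods

This note documents the models and numerical choices behind `isofoodweb`,
what the synthetic generator does and does not emulate, and the known
limitations.

## Community metrics

Shannon diversity uses log base 2 (bits per individual) by default, with the
base configurable for cross-package comparison; Pielou evenness uses the
same base, which cancels in the ratio `J′ = H′/log(richness)`. Diversity is
computed **per replicate quadrat** and site contrasts are tested with a
two-sample t-test on the replicate values (a t-test on site means requires
replicate-level indices; computing one index on pooled counts would leave
nothing to test). Taxa recorded at a site but absent from a particular
replicate contribute zero counts to that replicate — no pseudo-counts.

The Student t-test pools variance (two-sided); a Welch variant is offered
because group variances in field data often differ visibly. Both groups
being exactly constant raises a degenerate-input error rather than
returning an arbitrary statistic.

The Kruskal–Wallis test (tie-corrected, via `scipy.stats.kruskal`) drives
source aggregation. When the global test is significant, Dunn-type pairwise
rank comparisons with a **Bonferroni** correction decide which pairs remain
mergeable — a deliberately conservative default, since the post-hoc
procedure is rarely reported in field studies. All observations identical is
handled explicitly (H = 0, p = 1) because the tie correction would otherwise
divide by zero.

Trophic-group composition is reported over individuals (not taxa), and taxa
lacking a group assignment appear under an explicit `unassigned` key rather
than being dropped.

## Trophic position

`TL_c = (δ¹⁵N_c − δ¹⁵N_b)/Δₙ + λ` with defaults Δₙ = 2.5‰ (herbivore
fractionation) and λ = 2 (primary-consumer baseline). The baseline is chosen
among **user-designated** primary consumers as the entity with the lowest
mean δ¹⁵N at the site (ties: larger n, then lexicographic label); designation
is metadata, never inferred from the data. TL_sd is the SD of per-specimen TL
values computed against the baseline *mean*; baseline variance is not
propagated — a documented limitation, matching how ± SD is usually reported.
Values below λ are reported as-is (they are informative about baseline
choice), never clamped.

## Isotopic niche

Layman metrics are computed on species mean signatures (one point per
species) — "distance to centroid" and "nearest neighbour" are species-level
concepts — while ellipse areas are computed on specimen-level points per
site, matching how the two families of metrics are conventionally drawn in
two-site comparisons. Both choices are only conventions of the calling code:
the functions accept any point set. SDNND uses the sample SD (ddof = 1).

SEA is `π√det Σ̂` with the n−1 sample covariance; SEAc multiplies by
`(n−1)/(n−2)`. The SEAc ellipse used for overlap is the Mahalanobis ellipse
of squared radius `(n−1)/(n−2)`, whose area is exactly SEAc.

**Bayesian SEA** uses the conjugate normal–inverse-Wishart model in the
vague-prior limit: posterior `Σ | data ~ IW(ν₀ + n, Ψ₀ + S)` with ν₀ = 3
(minimal proper for 2-D), Ψ₀ = 10⁻³ I, S the centred scatter matrix, and a
flat limit on the mean's prior. The conjugate form was chosen over a generic
MCMC because it is exact, fast, and testable against the analytic
concentration `π√det Σ` at large n. The small-sample correction is applied
per draw. Draws are deterministic given the seed and strictly positive.

**Ellipse overlap** is grid rasterisation over the union bounding box
(default 1000 cells per axis; 2000 gives ≲1% error on a unit-circle lens
with area ≈1.23). Exact conic intersection was rejected as fragile for
near-degenerate ellipses; the grid estimate is symmetric by construction and
converges as the resolution grows.

## Bayesian mixing model

The likelihood is the canonical source + TEF variance form: specimen means
are `Σₖ pₖ(μₖⱼ + μ_TEF,ⱼ)` and variances `Σₖ pₖ²(σₖⱼ² + σ_TEF,ⱼ²) + τⱼ²`,
with a single TEF application (consumers one trophic step above sources) and
no concentration dependence. Priors: symmetric Dirichlet(1) on the simplex;
half-normal (scale 5‰, configurable) on each residual SD τⱼ. The residual
term can be disabled, which also makes the likelihood identical to the
simplex-grid quadrature oracle used in the tests.

Sampling is Metropolis-within-Gibbs on additive-log-ratio transformed
proportions (and log τ), vectorised across chains. The ALR Jacobian `Πₖ pₖ`
combines with the Dirichlet density to give `α Σₖ log pₖ` in z-space.
Per-coordinate step sizes adapt toward ~44% acceptance in windows of 50
iterations **during burn-in only**, so the post-burn-in chain is a fixed
Markov kernel. Defaults: 4 chains × 20 000 iterations, 10 000 burn-in,
thin 10 (4 000 kept draws); a fit takes a few seconds. Convergence is
split-chain R-hat (via arviz) per source proportion with a 1.1 threshold —
non-convergence warns, it does not abort.

Internally sources are sorted by name before sampling and draws mapped back
to the caller's order, so reordering the source list permutes the results
exactly at a fixed seed.

Summaries per source: arithmetic posterior mean; mode as the argmax of a
Gaussian KDE (Silverman bandwidth) with boundary reflection at 0 and 1; the
95% interval as the **highest-density region** — the narrowest window of
sorted draws holding ⌈0.95 n⌉ of them, exact width ties broken by the most
central window (relevant only for near-uniform marginals, where all windows
tie). Central quantiles are also reported for comparison. Degenerate
(constant) draw vectors short-circuit the KDE.

Source aggregation pools species within a named ecological group only when
the Kruskal–Wallis/Dunn procedure finds no significant difference on *both*
isotopes; otherwise the group is split per species with a warning, and the
model simply receives more sources.

## Synthetic studies

The generator emulates the study design the analysis stages expect: two
sites × 4 replicate 30 × 30 cm quadrats (0.09 m²); counts per taxon from a
negative binomial with dispersion 5 (overdispersion is typical of quadrat
counts; `dispersion=None` gives the Poisson limit); Gaussian source
signatures with a **uniform** (Δδ¹³C, Δδ¹⁵N) shift applied to every basal
source at the vent site; and consumer specimens drawn from the mixing
likelihood itself at known diet proportions — so fitting the mixing model to
generated consumers is a closed-loop parameter-recovery test. Abundance and
isotope streams use independent child seeds of the config seed; two runs
with the same config are identical.

The packaged `paper-like` preset mirrors the published study's structure:
32 control / 23 vent taxa with 11 shared (expected Sorensen 0.40 when all
taxa are detected); trophic-group percentages 58.4/24.7/14.6/1.5/0.8
(control) and 72.9/25.5/1.1/0.4/0.1 (vent) with pooled totals of 384 and
879 individuals; four source groups (two seagrass and two algal species,
epiphytes, SOM) spanning δ¹³C −21…−8.5‰ and δ¹⁵N 0.3…3.6‰ at the control
site; a vent shift of (−2.5, −1.5)‰; herbivore TEFs 2.5 ± 2.5‰ and
0.47 ± 1.23‰; and eight consumer species with fixed diets over the four
groups. The two designated primary-consumer candidates are given strongly
contrasting diets (SOM-heavy vs algae-heavy, true δ¹⁵N means ≈1.2‰ apart)
and 20 specimens each, so baseline selection is reliable despite the ±2.5‰
TEF variability the likelihood puts on every specimen.

What the generator does **not** emulate: spatial autocorrelation among
quadrats, temporal dynamics, source-specific (non-uniform) vent shifts,
detection/size bias in airlift sampling, or carbonate-chemistry mechanisms.
Because the vent shift is uniform, the generated vent δ¹⁵N span is wider
than the narrow range observed in the field, where different sources shifted
by different amounts. Consequently, passing the closed-loop tests shows the
pipeline's stages are mutually consistent and estimable at realistic sample
sizes — not that field data of this type will yield posteriors this tight;
with four sources and real TEF uncertainty, marginal diet posteriors are
wide and their lower 95% bounds often reach 0, as the HDR summaries show.

## Numerical choices and degenerate inputs

* Covariances with a smallest eigenvalue ≤ 10⁻¹² of the largest are treated
  as singular (degenerate-geometry error) rather than producing a
  near-zero-area ellipse.
* |δ| > 100‰ triggers a units warning, not an error.
* Empty taxon sets, all-zero count vectors, single-taxon evenness,
  < 2 points (Layman), < 3 points (SEA), < 4 points (Bayesian SEA) and
  < 3 consumer specimens (mixing) raise typed errors from
  `isofoodweb.exceptions`.
* Pipeline problem sizes: the end-to-end run fits one mixing model per
  consumer species per site (16 fits for the preset) at the default MCMC
  settings, and the niche stage draws 10 000 SEA posterior samples per site;
  test-suite closed-loop runs use these same defaults, while unit tests use
  shorter chains chosen for statistical adequacy of the property under test.

## Known limitations

* TL uncertainty ignores baseline variance (see above).
* The mixing model has no covariates, no hierarchical pooling across
  species, no isotope routing, and no elemental-concentration weighting.
* Ellipse overlap is computed on maximum-likelihood SEAc ellipses, not on
  posterior draws; a posterior overlap distribution would require pairing
  draws across sites and is out of scope.
* The Dunn post-hoc uses the normal approximation; exact small-sample rank
  enumeration is used only as a test oracle.
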
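# Methods

This note documents the statistical models implemented in `isospec`, the
assumptions they carry, the defaults and why they were chosen, and what the
synthetic-data generator does and does not emulate.

## Problem setting

A population of a generalist predator may consist of individuals that each
use only a narrow subset of the population's diet ("individual
specialization"). Stable isotope ratios (δ13C for carbon/energy source,
δ15N for trophic level, both in ‰) integrate diet over the turnover time of
the sampled tissue, so measuring two tissues with different turnover rates
(muscle, ~months; caudal fin, different window) per individual gives
repeated diet-proxy observations per individual. `isospec` quantifies
specialization from such data at three levels: variance decomposition of
the raw isotope values, model-based diet estimation, and regression of a
specialization index on covariates.

## Niche variance decomposition (WIC/TNW)

With `x_ij` the j-th observation (tissue) of individual `i`, `n_i` its
count and `N = Σ n_i`:

    TNW = (1/N) Σ_ij (x_ij − x̄)²          total niche width
    WIC = Σ_i (n_i/N) Var_i                within-individual component
    BIC = Σ_i (n_i/N) (x̄_i − x̄)²          between-individual component

All variances use the population (1/n) convention; it is the only
convention under which `TNW = WIC + BIC` holds exactly (law of total
variance), and the package asserts this additivity on every result.
Individuals observed once contribute `Var_i = 0` to WIC but full weight to
BIC; this handles unbalanced tissue replication (lost fin samples) without
dropping individuals. `WIC/TNW` near 1 indicates generalist individuals,
near 0 specialists. The two isotopes are decomposed independently, and
muscle/fin values enter uncorrected for their systematic offset by default
(the offset is genuine within-individual variation on the diet-proxy scale;
a `center_tissues` flag removes per-tissue means for sensitivity analysis).

**Null test.** The generalist null holds that every individual samples the
same pooled distribution. Each of `n_reps` (default 1000) bootstrap
replicates redraws, for every individual, `n_i` values with replacement
from the site's pooled sample and recomputes the ratio. The p-value is
one-tailed toward specialization with add-one smoothing,
`p = (1 + #{null ratio ≤ observed}) / (n_reps + 1)`; ties count against
rejection. Resampling pools within site only — each site is an independent
population. Degenerate inputs (all observations identical) raise an error
rather than returning an undefined ratio.

## Hierarchical Bayesian mixing model

Consumers' isotope values are convex combinations of `J` prey-source
signatures. Diet proportions are parameterised in isometric log-ratio (ILR)
space with a fixed Helmert-type sequential-binary-partition basis, giving
an unconstrained `(J−1)`-dimensional Gaussian scale:

    p_i = ILR⁻¹(α + ε_i),   α_d ~ N(0, 1),   ε_i ~ N(0, σ_RE² I)
    x_ik ~ N( Σ_j p_ij (μ_jk + Δ_k),  Σ_j p_ij² (σ_jk² + σ_Δk²) + σ_res,k² )

where `μ_jk, σ_jk` are source means/SDs, `Δ_k, σ_Δk` the trophic
discrimination factors, and `σ_res,k` a per-isotope residual ("process +
residual" error: source and discrimination uncertainty propagate through
the weights, the residual absorbs the rest). Priors on `σ_RE` and
`σ_res,k` are half-Normal(1) — weakly informative on the ‰ scale. With
`σ_RE = 0` the model collapses to a single shared diet; with one source the
diet is identically 1.

**Sampling.** Adaptive random-walk Metropolis-within-Gibbs with blocks for
α, all ε_i in parallel, log σ_RE, and each log σ_res,k, plus two
reparameterization moves that de-correlate the hierarchy: a translation
move (shift α, counter-shift every ε_i; likelihood-invariant) and a funnel
scale move (rescale all ε_i and σ_RE jointly; the ε prior cancels exactly
against the Jacobian). Without these moves σ_RE mixes an order of magnitude
more slowly. Proposal scales adapt toward ~30% acceptance during burn-in
with diminishing adjustments, then freeze. Defaults: 3 chains × 30 000
iterations, 50% burn-in, thinning 10. Convergence is gated on split-R̂ ≤
1.1 and bulk ESS ≥ 200 for every sampled parameter (ArviZ); failing fits
are returned flagged rather than raised, and summarisation then requires an
explicit `force`.

**Identifiability.** With 4 sources and 2 isotopes the mixing polytope is
underdetermined; the posterior is partly prior-informed and the package
warns accordingly. Individual-level proportions are strongly shrunk toward
the population diet when each individual contributes a single tissue
observation — posterior point estimates of `σ_RE` are biased low in this
regime, which is inherent to the design, not the sampler.

## Specialization indices (PSi / IS)

For individual diet `p_i` and population diet `q` (column mean of the diet
matrix), `PS_i = 1 − 0.5 Σ_j |p_ij − q_j|`; `IS = mean(PS_i)`. Individual
diets are posterior means by default (posterior medians, renormalised, as
an option). The null test draws, per replicate and individual, a
`Multinomial(resolution, q)/resolution` diet and recomputes IS from scratch
(including the replicate's own population mean). The discretization
`resolution` (default 100) is the one genuinely arbitrary constant — a
continuous-proportion analogue of item-count resampling — and is exposed
prominently in every interface. Sources with zero population share are
dropped from resampling with a warning. The p-value convention matches the
niche module (one-tailed toward small IS, add-one smoothed).

## Trophic position and classical tests

    TP = λ + (δ15N_consumer − δ15N_baseline) / enrichment

with λ = 1 (phytoplankton baseline: suspended particulate organic matter)
and enrichment 3.04‰ per trophic level by default. TP uses muscle δ15N
only (balanced replication across sites); per-site baselines are the
arithmetic mean of replicate SPOM filter values. Between-site TP is
compared with a classical one-way ANOVA; variance homogeneity of unbalanced
fin samples with a two-sided F ratio test (`s_a²/s_b²`, n−1 variances,
`p = 2·min(tail, 1−tail)`). Prey trophic-group composition is the
percentage of species per functional group (carnivores, detritivores,
herbivores, omnivores) per site, full precision retained with 1-decimal
display values.

## Beta regression of PSi

`PS_i ∈ (0,1)` is modelled as Beta(μφ, (1−μ)φ) with `logit(μ) = Xβ` and
constant precision φ (log link internally). Estimation is ML via
statsmodels' `BetaModel` followed by a damped-Newton polish using the
package's own analytic score: quasi-Newton line searches stall near the
machine precision of the objective, while the score remains informative, so
the polish drives the gradient max-norm to ~1e−9 and the convergence flag
is defined by first-order conditions (max-norm < 1e−5), not by the
optimizer's internal stopping rule. SEs come from the inverse observed
information at the polished optimum; Wald `z = β̂/SE` with two-sided normal
p-values. Covariates enter raw (unstandardized) so coefficients are
directly interpretable; categorical terms expand with the first sorted
level as reference. Boundary responses are a hard error unless the standard
compression `y' = (y(n−1)+0.5)/n` is explicitly enabled — silent
compression would change the estimand.

## Synthetic-data generator

`generate_study` emulates the sampling design of a two-river field study:
two sites with 27 and 21 individuals, muscle + fin per individual with a
fin-dropout fraction of 8/21 at the second site (13 fins retained), four
prey functional groups with Gaussian signatures, and Gaussian measurement
noise. Defaults and rationale:

- **Source signatures** sit in the δ13C ∈ [−38, −32.5]‰, δ15N ∈ [8.5, 12]‰
  window with SDs of 0.7–1.1‰ — plausible for muscle tissue of blackwater
  river prey fish and wide enough that the 4-source/2-isotope problem is
  informative but not trivial.
- **TDF** (0.4, 3.04)‰ for (δ13C, δ15N) with 0.5‰ SDs: conventional
  muscle values; the δ15N value matches the enrichment constant used for
  trophic position.
- **Tissue offset** fin − muscle = (+5.0, −0.3)‰: reproduces the ~5‰
  δ13C muscle-vs-fin gap seen in such data as a simple additive constant.
- **Diets**: population concentration (1.7, 2.6, 1.9, 3.8) (mean diet ≈
  0.17/0.26/0.19/0.38); individual diets by default are Gaussian in ILR
  space around the population mean (`re_sd = 0.5`), mirroring the fitting
  model so parameter recovery is exact-model; a Dirichlet mode exists for
  misspecification checks.
- **Measurement noise** 0.12‰, the stated analytical precision of the
  mass-spectrometry setup being emulated.
- **Baselines** (5.31, 3.06)‰ place the sites' consumers near trophic
  levels 4 and 4.4 respectively.

What the generator does *not* emulate: seasonal/hydrological variation in
source signatures, prey-assemblage turnover, tissue-specific discrimination,
within-individual temporal diet change (the two tissues differ only by the
fixed offset plus noise), and non-Gaussian measurement error. A green test
against this generator therefore establishes correctness of the estimators
under the stated model, not robustness to ecological misspecification.

`generate_generalist_null` resamples an existing dataset so every
individual draws i.i.d. from the pooled per-(site, tissue, isotope)
empirical distribution — the exact world in which the bootstrap null tests
should produce uniform p-values, which the test suite verifies with a
Kolmogorov–Smirnov check over 200 replicate experiments (null tests run at
1 000 replicates each there to keep the suite fast; the index defaults of
1 000/10 000 are unchanged).

## Numerical choices and degenerate inputs

- C:N ≥ 3.5 flags lipid bias (threshold inclusive — fail safe); flagged
  samples abort or warn per configuration since no lipid model is in scope.
- Ethanol-preservation correction is affine per isotope with user-supplied
  coefficients; requesting a correction without coefficients is an error,
  and the default (no correction, logged) assumes deposited values were
  corrected upstream.
- Isotope plausibility windows: δ13C ∈ [−60, 0]‰, δ15N ∈ [−10, 30]‰.
- TNW = 0, zero-variance ANOVA/F denominators, single individuals, and
  boundary beta responses all raise typed errors instead of returning
  NaN.
- All Monte Carlo routines take explicit integer seeds; the pipeline
  derives per-stage seeds from one master seed via SHA-256 and records them
  in the run manifest, so identical config + inputs give byte-identical
  output bundles.

## Known limitations

- The mixing model fits each tissue separately and offers no
  concentration-dependence or informative diet priors.
- The IS null's discretization resolution has no canonical value; p-values
  depend mildly on it (hence its prominence in the configuration).
- Reproduction of the original field study's published tables requires its
  deposited individual-level data, which are not redistributable here; the
  acceptance checks that recompute published values fail with an
  explanatory message until those CSVs are supplied (see
  `tests/test_acceptance.py` for the expected schemas).
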
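# Methods

This note documents the models, parameter choices and numerical decisions
behind the package, and what the synthetic-data tests do and do not
demonstrate about real museum material.

## δ13C corrections

**Lipid normalization.** δ13C_normalized = δ13C_raw − 3.32 + 0.99 × C:N.
The correction is the standard protein/lipid mass-balance normalization for
aquatic tissue; the constants reproduce the reference dataset's only fully
worked correction (raw −23.70 ‰ at C:N 4.3 → −22.76 ‰) exactly. It is
applied to *all* specimens, not only those flagged lipid-suspect
(C:N > 3.3): flagged records are classified and retained, never dropped,
because the bias is correctable arithmetically. At C:N = 3.32/0.99 ≈ 3.354
the correction vanishes.

**Oceanic Suess correction.** The correction factor is
*a*·exp((*y* − 1850) × 0.027), where *a* ≤ 0 ‰ is the regional per-year
surface-water δ13C decline and *y* the resolved collection year. The
(negative) factor is *subtracted* from the normalized value — the sign
convention is fixed by the requirement that corrected historical values move
toward the pre-industrial baseline (toward zero), which every published
corrected pair in the packaged reference table satisfies. Regional *a*-values
derive from accumulated surface-water Suess effects by division by the
140-year 1850–1990 span, rounded half-away-from-zero to 4 decimals; all five
packaged (CSE, a) pairs reproduce under this rule, and the pairing is
enforced as a type invariant.

Years before 1850 clamp the correction to zero; at exactly 1850 the formula
value *a*·e⁰ = *a* is used. The ~0.005–0.007 ‰ discontinuity is below the
0.01 ‰ reporting precision. Collection-date specifiers resolve as: exact
date → its year; closed range → floor of the midpoint; "before Y" → Y.
Report output rounds half-away-from-zero to 2 decimals; all internal values
are kept at full precision, so corrected-then-rounded values may differ by
±0.01 from tables that were rounded from different intermediates.

**Era correction of modern prey sources.** Prey-source δ13C means measured in
the modern ocean are corrected *back* to a specimen's collection era by
subtracting the accumulated factor difference between the source reference
year (default 2005, configurable) and the specimen year, shifting modern
means up by roughly 0.3–0.4 ‰. Source s.d.s are left unchanged.

## Trophic position

TP = 2 + (δ15N − δ15N_POM)/TEF, or with the marine-mammal bone-collagen
offset, TP = 2 + (δ15N − δ15N_POM − TEF_mmt)/TEF. Packaged parameters:

- POM baselines (‰): Ross Sea 0.6, South Shetlands 1.7, South Atlantic
  sector 1.5, South Georgia 3.6 (range 2–5.4), Strait of Magellan 8.1
  (range 5.6–12.2), Falkland Islands 9.4, Patagonian west coast 9.4. POM is
  keyed on the *location label*, separately from the Suess-region alias map
  (the Patagonian west coast shares the Strait-of-Magellan *a*-value but has
  its own 9.4 ‰ baseline). Point values are the default; the ranges are
  exposed for sensitivity sweeps via per-location overrides.
- TEF schemes: `post` = 3.4 ‰ (the conventional marine value, upper end of
  the plausible 2–3.4 band; values outside that band warn); `mmt` layers
  TEF_mmt = 2.03 ± 0.71 ‰ on top of it. A fin-whale-specific scheme has no
  packaged default because no defensible constant is published for it — it
  must be configured explicitly.
- Group summaries use sample (n−1) standard deviations; single-member groups
  report their value with s.d. unavailable. Outlier flags compare TP to
  configurable guild bands (whales 3.2–3.4, seals 3.8–4.1) and annotate,
  never remove.

## Mixing model

Tracer j of consumer i is modelled as
N(Σ_k p_k(μ_jk + λ_j), √(Σ_k p_k²(σ_jk² + τ_j²) + ξ_j²)): source summary
statistics (μ, σ) are fixed known values (the prey table publishes only
summary statistics, not raw data), λ/τ are the per-tracer trophic
discrimination mean/s.d., and ξ_j is a residual scale present under the
default `process+residual` error model. The default discrimination is
λ_δ15N = 2.03 ‰, τ_δ15N = 0.71 ‰ (the bone-collagen value) and zero for
δ13C; because this substitutes for an unpublished choice, the CLI requires
explicit acknowledgment when the default is used, and the pipeline manifest
logs it with provenance "assumed". The Humboldt-krill source publishes no
s.d.; it is stored as 0 and the residual term supplies variance.

Priors: Dirichlet(1,…,1) on p (equal prior diet weightings); half-Normal on
each ξ_j with scale set to the consumers' tracer s.d. (1 ‰ fallback for
single-consumer fits, configurable). The residual term is what makes
fitting each specimen as its own n = 1 consumer group well-posed; with one
observation ξ is weakly identified, so per-specimen posteriors are
deliberately conservative — dominance calls ("dominant source" = posterior
mean above a configurable 0.5 threshold, else "mixed") sharpen as the
residual prior tightens.

**Sampler.** Adaptive random-walk Metropolis on the stick-breaking transform
of the simplex (z = 0 maps to the uniform point; the log-Jacobian is applied
so the flat Dirichlet prior is exact) plus log ξ. Proposal covariance is
re-estimated per chain during burn-in from the chain history (scaled
2.38²/d) with Robbins–Monro scale tuning toward a 0.23–0.30 acceptance rate,
and frozen at the end of burn-in so the retained draws come from a fixed
Markov kernel. Defaults: 3 chains × 100 000 iterations, burn-in 50 000,
thinning 50 → 3 000 retained draws. Convergence is summarized by the classic
between/within Gelman–Rubin R̂ (warn > 1.05; hard non-convergence flag
> 1.2, always reported, never silent) and per-chain Geweke z-scores with
autocorrelation-corrected standard errors. All randomness flows from one
integer seed through `numpy.random.default_rng`; per-specimen fits derive
distinct sub-seeds deterministically.

K = 1 problems short-circuit to the exact degenerate posterior (p = 1,
s.d. 0). Process-only error with zero total variance in a tracer raises an
error advising the residual model.

## Permutation statistics

PERMANOVA uses the distance-matrix pseudo-F
((SS_T − SS_W)/(g−1)) / (SS_W/(N−g)) with SS from pairwise squared
distances. The default metric is unstandardized Euclidean on
(δ13C_SE, δ15N): with one variable this makes the statistic coincide exactly
with the classical one-way ANOVA F, the most defensible reading of
univariate permutation comparisons. Significance uses unrestricted label
shuffles with the +1/+1 rule (observed statistic included) at a default
9 999 seeded permutations; small designs can enumerate all distinct label
arrangements exactly. Zero total sum of squares defines F = 0, p = 1;
zero within-group sum of squares gives F = ∞, which permutations handle by
counting ties.

SIMPER is fixed to Bray–Curtis. Two-group mode averages over between-group
pairs; single-set mode (used for the within-group dissimilarity of one
collection of consumers' diet-proportion vectors) averages over all pairs.
Per-variable contributions |x_ik − x_jk| / Σ_m(x_im + x_jm) are averaged
over pairs and normalized to percentages summing to 100.

## Synthetic data

The generator draws specimen tracer values as group mean + Gaussian group
scatter + Gaussian analytical noise (±0.188 ‰ δ13C, ±0.204 ‰ δ15N),
truncated only by the physical sanity windows ([−40, 0] and [−5, 30] ‰)
with resampling; collection dates cycle through exact/range/"before" forms
to exercise date resolution. Mixture consumers follow the mixing-model
generative form exactly. The packaged historical-like scenario uses the
published per-species group means and s.d.s for both collection periods as
its parameters.

What passing synthetic tests show: the pipeline recovers known group means
within analytical tolerance, the sampler recovers known diet proportions
(posterior means within ±0.10, ≥ 85% empirical coverage of 95% intervals
over 50 replicates), and the permutation statistics agree with independent
oracles. What they do not show: robustness to diagenesis, preservation
artefacts, mislabelled provenance, non-Gaussian measurement error, or
discrimination factors that differ from the assumed bone-collagen value —
all real concerns for museum material that no simulation at these settings
addresses.

## Problem sizes and known limitations

Validation simulations use 30 consumers over 3 well-separated sources, with
replicate fits at 3 × 8 000–12 000 iterations (the retained-draw count stays
well above the diagnostics' needs); headline fits and the analysis scripts
use the full 3 × 100 000 study configuration, which completes in seconds to
a few minutes per fit on one CPU.

Known limitations: per-specimen (n = 1) posteriors are prior-influenced and
should be read as fingerprints, not diet estimates; published PERMANOVA F
values and mixing-model posterior percentages that depend on unpublished
per-specimen supplements are validated by statistical contract (oracles,
recovery, coverage) rather than by numeric reproduction; TP for specimens
whose true foraging region differs from the collection label inherits the
wrong POM baseline — that mismatch is exactly what the outlier flags and
fingerprinting are for.
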
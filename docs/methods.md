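# Methods

`camotype` asks a concrete question about background-matching camouflage:
when a background varies continuously in colour and texture, which single
sample of it is the best camouflage?  The package implements the full chain
of reasoning — a small probability calculus, a measurement pipeline from
camera pixels to perceptual features, a typicality ranking, experiment
design, and the mixed-model statistics that would analyse the resulting
field and laboratory data — together with a synthetic-background generator
that supplies ground truth for every stage.

## The match-probability calculus (`theory`)

For a background with discrete variants at probabilities `p_1..p_K`, a prey
item whose colour is itself a random draw from the background matches its
local patch with probability `sum(p_i^2)`, while a specialist on variant
`k` matches with probability `p_k`.  Because `max(p) >= sum(p^2)` (with
equality only for a uniform distribution), matching the most common
variant weakly dominates random sampling; `dominance_gap` returns the
margin.  For continuous backgrounds the analogue of "most common" is the
point minimizing expected deviation cost over the sample distribution:
the arithmetic mean (centroid) under squared-Euclidean cost, the
coordinate-wise median under absolute cost (`optimal_point`; even sample
counts use the mid-point of the central pair, the usual convention).
These identities are exact; tests check them against Monte-Carlo and
grid-minimization oracles rather than against themselves.

## Synthetic backgrounds (`synth`)

The generator emulates a photographed population of tree-bark backgrounds:

* **Tree-level colour** — a 3-vector of linear reflectances drawn from a
  population Gaussian.  Defaults: mean `(0.30, 0.25, 0.18)` (a brownish
  bark tone), between-tree SD 0.05 per channel with inter-channel
  correlation 0.8.  A smooth within-tree colour field (SD 0.03, correlation
  length ~256 px) adds patch-to-patch colour variation; its realized
  patch-mean covariance is of the order of, but below, the nominal
  within-tree covariance because of spatial averaging.
* **Texture** — an achromatic field synthesized in the frequency domain.
  White Gaussian noise is shaped so that the fraction of total spectral
  power in each of six octave bands (coarse to fine) equals the tree's
  band-weight vector, with a `1/f` falloff inside each band.  Per-tree
  weights are log-normal around `(0.26, 0.22, 0.18, 0.14, 0.11, 0.09)`
  with log-scale SD 0.3.  The field modulates the colour field
  multiplicatively at 35% RMS contrast.
* **Camera encoding** — the linear image is gamma-encoded (default 2.2)
  to produce "camera" pixels; the linear truth is retained.
* **Determinism** — one master seed; each tree uses a stream keyed by
  `(seed, tree_id)`, so populations are extensible without reshuffling.

Default image size is 1500 x 1200 px so that five non-overlapping
591 x 296 px patches always fit.  The generator is *not* a photorealistic
bark model: it has no cracks, lichen, anisotropy or specularity, and its
feature distribution is unimodal by construction.  Tests passing on it
show that the pipeline recovers known parameters under its own model
assumptions, not that real bark satisfies them.

A rendered colour standard (six-step achromatic series from 0.03 to 0.90
linear reflectance plus four chromatic patches) accompanies each
population for calibration testing.

## Calibration (`calibrate`)

A per-channel power law is fitted to the achromatic series in log-log
space, using values relative to the brightest grey patch so that a global
gain imbalance in a channel (an off-white illuminant, say) lands in the
white-point factor rather than distorting the fitted exponent.  White-point
factors equate the brightest grey patch across channels.  Mapping to a
non-human receptor space (e.g. avian cone catches) is a user-supplied
linear matrix applied after balancing, defaulting to the identity: the
downstream mathematics is agnostic to the colour space, and no specific
receptor sensitivities are assumed.  Values brighter than the top chart
patch extrapolate along the fitted curve (logged, not clipped).  A
non-monotone measured grey series raises a calibration error, as it
indicates saturation or a corrupt chart.

## Features (`features`)

The unit of analysis is a patch the size of the printed prey item:
591 x 296 px, i.e. a 5 cm base (round-half-up of 5/2.54 x 300 dpi) by
2.5 cm height (ceiling of 2.5/2.54 x 300) at 300 dpi.  Patches are placed
sequentially, each offset drawn uniformly over the exact set still
compatible with previously placed patches, restarting on dead ends; this
keeps the five-patch packing feasible even though two patch widths nearly
fill the default image.

* **Colour descriptor** — the per-channel mean of the patch, the minimal
  summary consistent with ranking each sample by a single colour position.
* **Texture descriptor** — the granularity spectrum: fractions of
  spectral power in six octave-spaced radial frequency bands of the
  mean-subtracted, Hann-windowed achromatic channel.  Orientation is
  pooled radially.  The descriptor is invariant to intensity shifts and,
  after normalization, to uniform intensity scaling.  A constant patch
  has no texture; it maps to the uniform vector `1/n_bands` with a
  warning so that downstream distances stay finite.

Coarse-band fractions are intrinsically noisy when the analysed area
spans only a few coarse-scale cycles; recovery tests at reduced image
sizes therefore use fewer octaves, while the full-scale configuration is
validated at 101 trees x 5 patches.

## Typicality and stimulus selection (`typicality`)

Features are standardized per dimension (mean 0, SD 1).  Under a
multivariate Gaussian model the ML location is the sample mean, so the
"most probable background sample" is operationalized as the centroid, and
each sample is ranked by the Euclidean distance of its standardized
colour (resp. texture) part from the colour (resp. texture) centroid —
two separate rankings, ties broken by provenance id.  Standardizing
before the distance computation makes the ranking invariant to affine
rescaling of raw features; whether the original analysis standardized is
unknown, so this is a declared choice.

A non-parametric cross-check ranks samples by leave-one-out Gaussian
product-kernel density (normal-reference bandwidth per block).  On the
synthetic populations the two rankings agree closely overall (Spearman
0.93-0.98), and the densest sample always lies far inside the typical
half of the distance ranking.  They do *not* agree sample-for-sample at
the very centre of the distribution: KDE estimation noise near the mode
exceeds the tiny density differences between near-central samples, so the
exact membership of a "most typical 12" set is estimator-dependent.  This
is a known limitation of the KDE cross-check, and it is why selection is
defined on the ML distances with the KDE ranks as a diagnostic only.

Selection dichotomizes each ranking at its median (common vs rare) and
takes, within each of the four colour x texture cells, the
`n_per_treatment` samples extremal for that cell: smallest
`d_colour^2 + d_texture^2` for common/common, largest for rare/rare, and
the signed difference of squared distances for the mixed cells.  A single
scalar score per cell makes the selection deterministic and testable.

## Experiment design (`design`)

The field schedule places all 48 selected targets once per block
(default 10 blocks), assigning targets to tree slots by random
permutation and pin coordinates uniformly in a configurable placement
rectangle.

The search schedule pairs participant `p` with target `i` on background
`(i + p) mod n`, covering all `n^2` stimuli exactly once while giving
every participant each target and each background once.  Trial order
follows a Williams balanced Latin square, so each target occupies each
serial position exactly once across participants and first-order
carryover is balanced.  The construction needs an even `n`; `n = 48` is
the design size of interest.  Ten flagged practice trials precede the
test trials.  `compose_stimulus` alpha-blends the apex-up triangular
target onto a background, refusing placements that intersect the target's
own extraction region.

## Outcome simulation (`simulate`)

Field: each placement draws a latent bird-predation time from an
exponential whose log-hazard is
`baseline + b_c*d_c + b_t*d_t + b_i*d_c*d_t + block RE + target RE`,
plus an independent exponential censoring process for non-bird outcomes.
Outcomes are recorded at the first inspection of the 7/24/31/48/55/72 h
schedule after the earlier latent event, survivors censored at 72 h —
the event-at-check-time coding a coarsely inspected field trial actually
yields.  Defaults: baseline log-hazard -5.0 per hour (~62% predation by
72 h), `b_c = b_t = 0.5` per standardized distance unit, random-effect
SDs 0.25, censor rate 0.003/h.  The interaction default `b_i = -0.14` is
sized so the texture slope `b_t + b_i*d_c` vanishes at the colour
distance typical of colour-rare stimuli selected from the default
population (`d_c ~ 3.5`): texture matching only matters when colour
already matches, which is the structure the statistics are meant to
recover.

Search: log10 reaction time is normal with mean
`0.75 + (-0.058)*z_c + (-0.039)*z_t` plus target/background random
intercepts (SD 0.05) and residual SD 0.25, truncated at the 30 s timeout;
the slopes apply to z-scored distances, the scale on which such slopes
are conventionally reported.  Hits follow an independent logistic model
(baseline logit 1.2, slopes 0.404 and 0.280 per z-unit) with an
asymptotic miss floor of 0.02; timeouts are always misses.

## Statistics (`stats`)

Field records are analysed by mixed-effects Cox regression: Breslow
partial likelihood with the 2 x 2 commonness factors (or continuous
distances) as fixed effects and normal random intercepts for target
pattern and block on the log-hazard.  No installed Python survival
package offers frailty terms, so the model is implemented directly
(`_coxfrailty`), following the penalized-partial-likelihood / Laplace
approach of Ripatti & Palmgren and the R `coxme`/`survival` frailty
machinery: an inner Newton solve of the penalized likelihood for fixed
variances, an outer Nelder-Mead maximization of the Laplace-approximate
integrated likelihood over the log-variances (searched within
`[1e-4, 9]`).  Factors are tested by the change in deviance
(-2 x integrated log-likelihood) between nested fits against a
chi-squared distribution; a significant colour x texture interaction
triggers the stratified follow-up (texture tested within each colour
stratum).  The fixed-effects-only path agrees with lifelines'
`CoxPHFitter` to 5 decimal places in the test suite, and the deviance
test's null rejection rate measures ~5% over 800 simulated null
experiments.  Deviance changes can be fractionally negative from
variance-optimization noise; they are clamped at zero with a warning.

Search records: a linear mixed model for log10 RT (practice, miss and
timeout trials excluded) and a variational-Bayes binomial mixed model
for hits (timeouts as misses), both with z-scored distances as fixed
effects and crossed target/background random intercepts, via
statsmodels.  Per-effect chi-squared values are Wald statistics
(`(estimate/SE)^2` on 1 d.f.); at these sample sizes they are
essentially the likelihood-ratio values, and the variational posterior
SDs for the binomial model are treated as standard errors.

Alpha is 0.05 throughout and no multiplicity correction is applied.

## Problem sizes and numerical choices

Replicated studies use the design scale (48 targets x 10 blocks = 480
field records; 48 x 48 = 2304 search trials).  The acceptance script
runs 100 effect replicates and 400 null replicates of the field chain
and 5 replicates of the search chain; the test suite uses smaller
replicate counts for the same checks.  Unit tests run the image stages
on reduced geometries (e.g. 640 x 520 images, 64 x 128 patches), since
every count and contract is size-invariant; full-scale behaviour is
covered by the acceptance tests.  Full-size populations are streamed
one image at a time through feature extraction rather than held in
memory.

Known limitations: the generator's unimodal, isotropic, crack-free
texture model; the identity default receptor mapping; the KDE
cross-check noise at the distribution centre; Wald rather than LR
chi-squared values for the search mixed models; and the single-exponent
response-curve family in calibration (adequate for power-law encodings,
approximate for cameras with tone-curve shoulders).
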
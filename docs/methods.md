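# Methods

`reefmetab` reconstructs, as a tested pipeline, a benthic primary-production
analysis for a Caribbean fringing reef under seasonal coastal upwelling.
Two sites — wave/current-exposed (EXP) and sheltered (SHE) — are compared
between a non-upwelling (NoUp) and an upwelling (Up) period for five
functional groups of primary producers: scleractinian corals (genera
*Montastraea* and *Diploria*, pooled at the analysis level), frondose
macroalgae (*Dictyota*), algal turfs, crustose coralline algae (CCA) and
sand hosting microphytobenthos.

## Flux model

A specimen incubated in a closed chamber changes the dissolved O₂
concentration at rate ΔC/Δt. The specimen flux, per m² of its
three-dimensional surface per hour, is

    p = ((ΔC/Δt − blank rate) · V) / (A₂D · s)

with V the chamber volume (L), A₂D the planar specimen area (cm², converted
to m²), and s the group's 2D→3D surface-area conversion factor.
Concentrations read in mg L⁻¹ are converted to mmol L⁻¹ with the O₂ molar
mass 31.998 g mol⁻¹; a configuration switch accepts µmol L⁻¹ readings
directly, and the two unit paths agree to 1 × 10⁻¹² relative (tested).
The blank rate is the mean drift of seawater-only controls matched on
(site, season, light/dark phase); several matching blanks are averaged, and
a *missing* blank is an error, never a silent zero.

Light-phase flux is net production P_n; the negated dark-phase flux is
respiration R (stored as a positive magnitude; an apparently positive dark
flux is degenerate input — logged and clamped to R = 0); gross production
is P_g = P_n + R, an exact identity in every output row.

Fluxes are normalized to the **3D** specimen area (A₂D · s). This keeps the
upscaling chain dimensionally consistent: the contribution equation below
multiplies by s again to convert planar covered seafloor into organism
surface.

Illuminance loggers (lx) are converted to photosynthetically active
radiation with the linear daylight approximation PAR = k·lx; the default
k = 0.0185 µmol m⁻² s⁻¹ lx⁻¹ is the common daylight constant and is
exposed in configuration.

## Survey geometry and upscaling

Benthic cover b comes from 50 m line-point-intercept transects read at
0.5 m intervals (101 points including both ends); the per-transect
proportion is count/101 and the site/season estimate is the mean over
transects. Rugosity r is the chain-method ratio of contour to linear
length over 10 m sub-transects (r ≥ 1; a chain shorter than the tape is
clamped to 1 with a warning). Conversion factors s are means of
per-specimen 3D/2D area ratios.

A group's contribution to reef metabolism per m² of *planar seafloor* is

    c_i = p_i · s_i · b_i · r

Turf and sand use s = 1 (their areas are measured planarly); r is applied
to every group, including sand, because the equation applies it without
exception. The "other" cover category (3–9 % of the seafloor) is carried
through coverage estimates but excluded from upscaling.

Daily ecosystem production extrapolates to a 12 h light / 12 h dark cycle.
The default convention (`net_24h`) debits dark-phase respiration from the
daily net budget:

    P_g(d) = 12 · Σ c_g        P_n(d) = 12 · Σ c_n − 12 · Σ c_resp

so P_g(d) − P_n(d) = 24 · Σ c_resp exactly. Because the exact diel formula
is a genuine modelling choice, `net_light_only` (P_n(d) = 12 · Σ c_n) is
available as a switch; daily totals are convention-dependent and are
reported with their convention tag.

For inference on daily totals, ecosystem-level pseudo-replicates are formed
by dealing specimens round-robin into n = min(group count) slots within a
site × season and summing group means within each slot; the mean over
pseudo-replicates equals the point estimate whenever group counts are
multiples of n.

## Bayesian inference engine

The mean–variance relationship of the response is stabilized by a power
transform: Taylor's law (log cell variance regressed on log |cell mean|)
gives slope b and exponent λ = 1 − b/2; the signed power sign(y)·|y|^λ is
applied, or the sign-preserving sign(y)·log1p(|y|) when |λ| < 0.05 (a power
transform cannot stabilize var ∝ mean², only a log can). Signed forms keep
negative fluxes (heterotrophic sediment in the dark) in the analysis.

Candidate models are all *hierarchical* (marginality-closed) term sets over
the factors group, site and season: an interaction is admitted only with
all its lower-order margins, and the intercept-only model is included.
Three factors give exactly 19 such models (2, 5 and 167 for one, two and
four factors — the antichain counts of nonempty factor subsets).

Each model is a Gaussian linear model in treatment coding, fitted by a
conjugate Gibbs sampler alternating

    β | σ² ~ Normal,   σ² | β ~ InverseGamma(a + n/2, b + RSS/2)

under weakly informative priors β ~ N(0, 10⁸·I), σ² ~ InvGamma(0.001,
0.001). Two chain profiles are configured: `paper` (650 000 iterations,
50 000 burn-in, thinning 5 → 120 000 retained), matching the original
field-campaign analysis, and `fast` (6 500 / 500 / 5 → 1 200 retained).
The pipeline defaults to `fast` so an end-to-end run finishes in seconds;
for a conjugate Gaussian sampler on these problem sizes the fast profile is
well past convergence, and the `paper` profile is a flag away when
posterior tail precision matters.

Model fit is ranked by the deviance information criterion
DIC = D̄ + pD with pD = D̄ − D(θ̄) evaluated at the posterior means; a
negative pD is logged, never hidden. All models within ΔDIC < 2 of the
best form the candidate set; their coefficients are averaged with DIC
weights w ∝ exp(−ΔDIC/2) on the union coefficient space (a coefficient
absent from a model counts as 0). For posterior contrasts under
model-selection uncertainty the candidates' retained draws are *stacked*
in proportion to their weights (flagged experimental: averaging posterior
means and stacking draws answer subtly different questions).

Uncertainty statements use shortest-interval 95 % highest-posterior-density
(HPD) intervals: the narrowest window of ⌈0.95·n⌉ consecutive sorted
samples, ties resolved toward the smallest lower endpoint. Pairwise cell
comparisons report the posterior of the cell-mean difference on the
transformed scale with pMCMC = 2·min(frac > 0, frac < 0), floored at the
Monte-Carlo resolution 2/n and capped at 1, starred at 0.05/0.01/0.001.
No back-transform of effect sizes is attempted; comparisons are ordinal
statements on the transformed scale.

Classical cover statistics are retained for the survey stage: two-way
site × season ANOVA with type-II sums of squares, preceded by a
Kolmogorov–Smirnov normality check on residuals (against a fitted normal,
without the Lilliefors correction — a deliberate simplification) and a
Brown–Forsythe (median-centred Levene) homogeneity check; when the
interaction is significant at 0.05, all pairwise cell t-tests are reported
with Bonferroni-multiplied p-values capped at 1. Cover proportions are
analysed untransformed.

## Synthetic-data generator

No public raw dataset accompanies the analysis, so the generator emulates
every input table with the campaign's reported statistical structure; its
defaults are the study conditions, not tuning knobs:

- **Fluxes.** Per (group, site, season) cell, a target light flux
  ~ N(P_n, sd) and dark flux ~ −N(R, sd) are drawn per specimen and the end
  O₂ concentration is *back-computed* through the flux equation (including
  the realized mean blank drift), so the analysis pipeline recovers every
  drawn flux exactly — an algebraic inversion tested to < 10⁻⁹.
  Anchor means: coral P_n/P_g 16/19 (NoUp) and 12 (Up), turf 19 (Up) and
  roughly half that during NoUp, CCA higher at EXP during NoUp and at SHE
  during Up, weakly autotrophic sand; SDs ~25–30 % of the mean, typical of
  short-term bottle incubations. Ten replicates per cell by default
  (configurable); negative draws are permitted (sediment can be net
  heterotrophic), though draws that would deplete the chamber below
  0.2 mg L⁻¹ are jointly redrawn (a hypoxia guard mirroring the field
  practice of keeping incubations short).
- **Cover.** 101 i.i.d. multinomial draws per transect with per-site/season
  probabilities anchored at coral 41/39 % (EXP), the 24/26/25 % coral/turf/
  sand split (SHE, NoUp) and 47 % macroalgae (SHE, Up); the five target
  groups cover ~91 % (EXP) and ~97 % (SHE) of the seafloor and "other"
  absorbs the remainder.
- **Rugosity and conversion factors.** Normal draws truncated at 1 with the
  location calibrated so the *post-truncation* mean equals the nominal
  value (EXP 1.32, SHE 1.53; Diploria 2.28, Montastraea 1.34, macroalgae
  4.29, CCA 2.10). The nominal SD serves as the underlying scale; when the
  mean sits close to the bound the realized SD is necessarily smaller than
  nominal (a ≥1-truncated normal cannot match both moments when
  sd/(mean−1) > 1), a known limitation.
- **Loggers.** I.i.d. normal temperature/illuminance series at 2-minute
  spacing, calibrated so converted PAR reproduces 146 ± 47 (NoUp) and
  230 ± 58 (Up) µmol m⁻² s⁻¹.
- Start concentration is fixed at 6.5 mg L⁻¹ (mid-range warm seawater);
  only the end concentration varies — fluxes are invariant to the baseline
  (tested). Blank drift defaults to ±0.01 ± 0.005 mg L⁻¹ h⁻¹
  (light/dark), small against specimen signals.

The generator does **not** emulate instrument-level autocorrelation,
tide/cloud dynamics, or spatial autocorrelation along transects; cover
SDs across synthetic transects therefore reflect multinomial sampling only
and are smaller than the patchiness-driven field SDs (±12 %). Passing
tests demonstrate the correctness of the arithmetic, the calibration of
the inference engine, and order-of-magnitude realism of the upscaled
totals — not agreement with any particular field dataset.

All generators are deterministic under the scenario seed, with independent
child streams per table; pipeline reruns with the same configuration
reproduce byte-identical artifacts (SHA-256 manifest, tested).

## Numerical choices and problem sizes

- O₂ molar mass 31.998 g mol⁻¹; areas cm² → m² via 10⁻⁴.
- Gibbs chains initialize σ² at the sample variance; Cholesky solves of the
  posterior precision; retained-draw bookkeeping (iterations − burn-in)/thin
  is validated.
- The HPD tie-break (smallest lower endpoint) makes the interval unique on
  ties; pMCMC never reports 0 (floor 2/n).
- Routine test and acceptance runs use the `fast` chain profile, 10–200
  replicates per cell, 50-replicate model-recovery and 200-replicate HPD
  calibration studies — sizes chosen so the whole suite completes in a few
  minutes while leaving Monte-Carlo error well inside the asserted
  tolerances.
- Degenerate inputs: zero/negative durations, volumes, areas, probabilities
  not summing to 1, unknown factor levels and rank-deficient designs all
  raise informative errors rather than propagating silently.

## Known limitations

- The diel-extrapolation convention and the power-transform exponent of the
  original analysis are not fully determined by the published summary; both
  are explicit, configurable choices here, and daily totals should be read
  as convention-dependent order-of-magnitude estimates (the default
  scenario lands in the low hundreds of mmol O₂ m⁻² d⁻¹).
- Closed, unstirred chambers bias fluxes low relative to in-situ flow;
  upscaled values are conservative by construction.
- Model-averaged comparisons mix posteriors across models by draw
  stacking; alternatives (single-best-model inference) are available by
  fitting with the best model's term set directly.
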
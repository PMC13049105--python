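# Methods

## Carbonate system from the (A_T, pH_T) pair

With [H⁺] known from total-scale pH, the system is algebraic: carbonate
alkalinity is total alkalinity minus the borate, water, and minor acid–base
contributions,

    CA = A_T − [B(OH)₄⁻] − [OH⁻] + [H⁺]_free + [HSO₄⁻] + [HF],

and the three carbon species follow from K1/K2. pCO2 is CO2*/K0 without the
fugacity correction (≈0.3% at 1 atm, far below the uncertainty of the
inputs). Saturation states use calcium proportional to salinity
(Riley & Tongudai), Ω = [Ca²⁺][CO₃²⁻]/Ksp.

Constants (all evaluated at in-situ T, S; surface pressure): Lueker et
al. (2000) K1/K2 (total scale), Dickson (1990) boric acid and bisulfate,
Perez & Fraga (1987) HF, Millero (1995) water, Weiss (1974) K0, Uppström
(1974) total boron, Mucci (1983) solubility products. Each implementation is
pinned by a unit test to the formulation's published check value at
T = 25 °C, S = 35. This default set is the standard choice for
Mediterranean surface work; the `constant_choice` argument exists so
alternative families can be registered.

Design choices:

* **Salinity default 38** when a record carries none (Mediterranean surface
  value at the study reefs); flagged in `salinity_defaulted` metadata.
* **Pressure fixed at 0 dbar** — the tiles sit at 0.5–3 m, where pressure
  corrections are far below measurement uncertainty.
* **Total pH scale everywhere**; no scale conversions are exposed.
* **Verification oracle**: `ph_from_at_ct` recovers pH from (A_T, C_T) by
  bisection on [3, 9.5] (tolerance 1e-8, ≤200 iterations); the alkalinity
  residual is monotone in pH so bisection cannot fail. A property test
  round-trips 1,000 random states to 1e-6 pH units.

Known gap: derived values in published field tables are means over
thousands of per-sample computations with co-varying pH and temperature and
unpublished per-sample salinity. A single solver call at the printed mean
inputs reproduces pCO2 and both saturation states within a few percent, but
dissolved inorganic carbon can sit ~2% from such a tabulated mean; this is a
property of averaging a nonlinear map, not of the solver (which matches
standard check cases exactly).

## Chamber fluxes

Oxygen rates are the OLS slope of the per-minute concentration series
(µmol L⁻¹ min⁻¹) × 60 × chamber volume (3.7 L); an endpoints-only mode
exists for analytes with only start/end samples. Gross photosynthesis is
GP = NP − R with respiration negative when O2 is consumed. Calcification
uses the alkalinity anomaly at 2:1 stoichiometry with seawater density
fixed at 1.025 kg L⁻¹ (the protocol's stated correction, deliberately not
recomputed from T/S). Nutrient uptake is the control-corrected start−end
difference × volume / duration; concentrations below the flow-analyser
detection limits (0.05 mmol m⁻³ NH4+; 0.01 mmol m⁻³ NO3⁻, PO4³⁻) are
floored at the limit and flagged. Saturation QC uses the Garcia & Gordon
(1992) Benson–Krause O2 solubility fit: light incubations are flagged above
150% saturation, dark ones below 80%. Duplicate alkalinity bottles are
averaged before differencing. Sign conventions (consumption and net
dissolution negative, nutrient removal positive) are stated on the types.

## PI curves

The saturating exponential y = α(1 − β·e^{γx}) is fitted by bounded
nonlinear least squares with γ constrained negative — with γ > 0 the
expression diverges and α could not be the maximum rate. Multi-start over
γ₀ ∈ {−0.001, −0.01, −0.1} with α₀ = max(y), β₀ = 1; best final SSE wins,
ties broken toward the smallest |γ|. Flat input data short-circuit to
(α = constant, β = 0). Irradiance adjustment is multiplicative by default —
measured NP × ŷ(600)/ŷ(PAR_incubation) — which preserves zeros and scales
with per-tile activity; a `substitute` mode returning ŷ(600) directly is
available since the original analysis does not state its adjustment form.
Dawn/dusk incubations where ŷ(PAR) ≈ 0 are rejected with an explicit error
rather than producing unstable ratios.

## Community structure

Grid counts (25 squares of 5 × 5 cm per tile side) become percent covers;
when layering pushes a side's raw total above 100%, covers are rescaled
proportionally (relative percentages), otherwise left unscaled. Biomass
applies species-specific dry weights (g DW per 25 cm² patch) to covers,
summed over **both** tile sides — back-side fauna carry mass. Communities
are classified from front-side algal covers: calcifying if the calcifier
share of algal cover is ≥ 0.6, fleshy if the fleshy share is ≥ 0.6, mixed
otherwise (threshold configurable; zero algal cover yields `mixed` +
`no_algae` flag). Richness uses presence = any occupied square; colonisation
(present later but not at T0) warns rather than errs, since the study system
showed loss-only dynamics. Bray–Curtis runs on untransformed relative covers
(scipy); a pair of all-zero rows is defined as distance 0 and flagged.

PERMANOVA: pseudo-F from among/within sums of squared dissimilarities,
p = (1 + #{F_perm ≥ F_obs}) / (1 + n_permutations), with an exhaustive mode
enumerating all distinct label orderings for exact p on small designs.
Default 9,999 permutations with an explicit seed. Type-I error is verified
by simulation (null rejection rate at α = 0.05 within [0.03, 0.07]); the
statistic is cross-checked against scikit-bio's implementation in the test
suite.

## Hierarchical response model

Standardised biomass (strictly positive ratios to the initial measurement)
uses a Weibull likelihood with shape σ_B and log-linked mean; standardised
process rates (which may be negative) use a Gaussian with identity link.
The linear predictor is µ_i = β + ζ[g(i),1] + ζ[g(i),2]·t_i over the s = 9
(community × pH) cells, time in days. Cell effects factor as
ζ = δ_s · diag(σ_ζ) · L′ with L the Cholesky factor of the 2×2
intercept–slope correlation. Priors: β flat (implemented as Normal(0, 10³));
σ and σ_ζ ~ Gamma(0.01, 0.01) shape–rate; δ_s ~ Student-t(3, 0, 2.5);
correlation ~ LKJ(1), i.e. uniform on the 2×2 correlation. Standardisation
to T0 is by ratio (results are naturally read as fold-changes); a difference
mode exists for zero baselines.

**Sampler.** No gradient-based PPL is used; the posterior is sampled with an
ensemble MCMC (80% differential-evolution moves, 20% snooker moves; ≥48
walkers). "Chains" are independent ensembles; after discarding warm-up
steps the flattened walker draws are thinned deterministically to exactly
chains × (iterations − warmup) retained draws, so the reference plan of
4 chains × 10,000 iterations with 2,000 warm-up retains 32,000 draws.
Convergence is checked with split-R̂ (< 1.05) per parameter via arviz.

**Geometry.** The sampler walks the *centred* variables — ζ itself plus
(β, log σ_ζ, atanh ρ, log σ) — with the Student-t prior on δ_s applied
through the exact change of variables (including the |det(diag(σ_ζ)L′)|⁻ˢ
Jacobian), and δ_s derived from the draws afterwards. In this design the
data strongly identify the cell effects, and a non-centred walk puts the
ensemble in a funnel it cannot traverse (pilot runs: R̂ ≈ 2 and σ_ζ
unrecoverable); the centred walk attains pooled 95%-CI coverage ≈ 0.97 for
β, the cell slopes and σ_ζ at the reduced settings used in testing
(2 chains × 2,000 iterations, 400 warm-up). Walkers initialise in a small
ball around per-cell OLS lines. Seeds are mandatory; chains spawn
independent substreams from the master seed.

**Decision rule.** An effect between two conditions is "meaningful" iff
their equal-tailed 75% credible intervals are disjoint; intervals sharing an
endpoint count as overlapping. Bayes R² is the posterior-draw average of
var(fitted) / (var(fitted) + expected residual variance) (for the Weibull
family the residual variance is λ²(Γ(1+2/k) − Γ(1+1/k)²) per observation).

**Scale note on σ_ζ.** With the literal factorisation ζ = δ·diag(σ_ζ)·L′,
the marginal SD of the slope column is √(ρ²σ_ζ₁² + (1−ρ²)σ_ζ₂²) rather than
σ_ζ₂ alone; the factorisation identity ζ = rebuild(δ, σ_ζ, ρ) is preserved
exactly on every retained draw.

## Synthetic-data generator

The generator encodes the study conditions and is the test bed for every
stage:

* **pH mixtures**: per zone, a quiet background plus a venting component
  (weights/locations solved so mean and quartiles land on the zone targets:
  ambient 8.02 (7.99, 8.05); low 7.70 (7.72, 8.00); extreme low 6.43
  (6.43, 6.68)); default per-zone sample counts 6,342 / 5,587 / 5,546 at
  15-min cadence.
* **Species pool**: 61 taxa — 25 algae (8 calcifying), 1 turf group, 35
  invertebrates (10 calcifying) — with roles and log-normal dry weights in
  ~[0.05, 2] g per 25 cm² (calcifiers heavy, turf light; real dry weights
  are not published, so these are calibration choices).
* **Cover trajectories**: per-species extinction draws whose probability
  matches the per-(community, zone) mean-loss targets (fleshy 7/7/18,
  mixed 4/6.5/17, calcifying 4/7/14 for ambient/low/extreme); calcifiers
  forced extinct under extreme low pH by day 100; survivor covers shrink
  toward per-zone endpoint factors (1.0 / 0.65 / 0.1) with turf growing
  under venting. Realised biomass ratios land near −9% / −23% / −95% at the
  final time point.
* **Incubations**: linear O2 trends, alkalinity and nutrient bottle pairs
  consistent with planted rates; noise defaults (O2 0.5 µmol/L per minute,
  A_T 2 µmol/kg per bottle, nutrients 0.01 mmol m⁻³) chosen at instrument
  precision. Noise-free runs invert the flux arithmetic exactly.
* **Function trends**: all zones share a common T0 baseline — tiles
  recolonise in the ambient zone and are transplanted at T0, so divergence
  develops afterwards — with endpoints at day 120 planting calcification
  decline into net dissolution under extreme low pH and rising
  photosynthesis and NH4+ uptake as pH falls.
* **PI observations**: nine 1-h incubations per day (06:00–22:00), three
  days, diel PAR peaking at 600 µmol m⁻² s⁻¹; noise calibrated per tile
  from its own signal variance so fitted R² lands in the 0.52–0.73 band.

What the generator does **not** emulate: temporal autocorrelation in sensor
series, hydrodynamics of vent plumes, seasonal temperature cycles, within-
incubation carbonate feedbacks, spatial correlation between neighbouring
tiles, and observation error in species identification. Passing tests
therefore demonstrate that the estimators invert the assumed measurement
model at realistic noise, not that they are robust to every field artefact.

## Problem sizes in the default test run

The suite fits the hierarchical model at 2 chains × 2,000 iterations
(400 warm-up) for the 50-replicate coverage study, 2 × 800 for the
directional end-to-end checks (10 replicates × 3 functions), 200 simulated
tiles for the PI-curve band, and 500 null simulations × 199 permutations for
PERMANOVA calibration; these sizes give stable Monte-Carlo verdicts while
keeping a full run to a few minutes.

## Known limitations

* Only the (A_T, pH_T) input pair is supported; no pressure-corrected deep
  chemistry, no alternative pairs.
* The Weibull location is mean-parameterised via the log link; other
  conventions (scale-parameterised) would shift β's interpretation.
* The ensemble sampler mixes more slowly than gradient-based NUTS for the
  hyperparameters (σ_ζ, ρ); their R̂ can sit above 1.05 at the reduced test
  settings even when data-identified quantities (cell slopes, σ) are well
  converged. Interval coverage — verified by simulation — is the quantity
  the analysis relies on.
* PERMANOVA assumes exchangeability under the null; no strata/blocking.
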
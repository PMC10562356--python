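# Methods

This note documents the models, sampling laws, numerical choices and design
decisions behind `forcarb_uq`, and what the synthetic test conditions do and
do not demonstrate about real inventories.

## Scope and intent

The package is an uncertainty-propagation *pipeline*, not a calibrated
ecosystem model. The stand/soil process model is a deliberately simple
surrogate that preserves the input/output contract of full process-based
stand simulators (daily weather in, annual stocks, fluxes and
harvest-driven management out) so that every stage of the Monte Carlo
machinery — sampling, fixing draws per simulation, accounting, attribution,
risk — can be built, tested and exercised end to end on synthetic data.
Quantitative national numbers are out of reach by construction; qualitative
structure (scenario orderings, the time evolution of uncertainty sources,
area-dependence of range widths) is the target.

## Surrogate stand model

**Photosynthesis.** Annual gross primary production per pixel is

GPP = LUE · fAPAR(BA) · Σ_d R_d · f_T(T_d) · f_D(D_d) · f_W(P) · f_C(CO₂),

with radiation R in MJ m⁻² d⁻¹ and all daily modifiers in [0, 1]:
a temperature ramp f_T = clip((T − T_min)/(T_opt − T_min), 0, 1)
(T_min = 0 °C, T_opt = 18 °C), an exponential vapour-pressure-deficit
decline f_D = exp(−κD) (κ = 0.4 kPa⁻¹), a soft water modifier
f_W = clip(P₃₀/W_ref, 0, 1) from the trailing 30-day precipitation sum
(W_ref = 30 mm), and a saturating CO₂ response f_C = C/(C + C½)
(C½ = 300 ppm). Light capture fAPAR = max(0.05, 1 − e^(−0.09·BA)); the
floor lets clearcut pixels regrow. LUE = 1.45 gC MJ⁻¹ puts annual GPP near
900–1100 gC m⁻² for a closed southern-boreal canopy, the right magnitude
for the system being emulated. GPP is linear in LUE and monotone in CO₂ by
construction.

**Allocation and turnover.** Autotrophic respiration is a fixed fraction of
GPP (0.50), NPP = GPP − Ra. Ground vegetation receives up to 15 % of NPP,
enough to track its equilibrium biomass B(site, light) =
B_site · (0.2 + 0.8 · light), with B_site = 2000…800 kgC ha⁻¹ from the most
fertile to the poorest site type and light = e^(−0.06·BA); the remainder
goes to trees. Tree litter is a single turnover flux (0.04 yr⁻¹ of total
tree carbon), ground-vegetation turnover is 0.30 yr⁻¹.

**Mortality.** Crowding mortality removes the stem excess above a
Reineke-type maximum density N_max = 2200 · (dbh/25)^(−1.605) stems ha⁻¹;
below the threshold it is exactly zero. Random mortality defaults to an
expected-value fractional loss (0.005 yr⁻¹), which keeps pixel trajectories
smooth at small sample sizes while preserving the flux; a Bernoulli mode is
available (`stochastic_mortality`).

**Carbon conservation.** The update order is harvest → mortality → turnover
→ allocation, each flux computed from the stock it acts on, so

Δ(tree C + ground-vegetation C) = NPP − litter − mortality litter − harvest

holds to machine precision on every step (property-tested over 10⁴ random
states). Collected harvest leaves the ecosystem; uncollected residues enter
the litter flux.

**Structure.** Stem volume is kept proportional to tree carbon
(V = C_stem/(ρ·c_f), stem carbon = total/BEF with BEF = 1.55, ρ the
species-weighted wood density 400/385/485 kg m⁻³ for pine/spruce/birch,
c_f = 0.5). Diameter follows from volume and surviving stem count through
V = f·N·π(d/200)²·h with the allometric height h = 2.2·d^0.68, so
structural variables increase monotonically with allocated stemwood carbon.
Initialization instead computes volume as BA · height · form factor, with
the form factor reduced as the live crown shortens
(f = 0.45·(1 − 0.25·(1 − crown ratio))); crown height is a linear
height/diameter/species expression multiplied by the per-simulation crown
factor. The small inconsistency between the measured height used at
initialization and the allometric height used afterwards is a known,
harmless seam of the surrogate. Clearcuts reset age and structure;
replanting installs 2000 stems ha⁻¹ of negligible carbon.

## Soil and organic-soil emissions

Mineral soil carries three pools (fast/slow/humus) with first-order decay
rates 0.48 / 0.045 / 0.004 yr⁻¹ spanning two orders of magnitude, transfer
fractions 0.30 (fast→slow) and 0.15 (slow→humus), optional Q₁₀ = 1.8
temperature modification around 4 °C mean annual temperature. Litter enters
the fast pool; mass balance Δtotal = litter − respiration is exact.

**Spin-up.** Initial pools come from iterating 7-year blocks of historical
forcing (random year order, historical harvest targets) until the relative
change of total soil carbon between successive cycles is < 10⁻⁴ (maximum
300 cycles; non-convergence sets a flag rather than raising). The stand is
restarted from its sampled initial state for the litter block, making the
forcing periodic, so the linear soil model converges geometrically to its
periodic steady state; for constant forcing this is the analytic fixed
point L/k, which the tests verify. The spun-up state depends on the
simulation's sampled pixels, ages, site types and parameters, and is shared
by all scenarios of that simulation.

**Drained organic soils.** No dynamic pools: a per-simulation sampled
emission-coefficient table (means and standard deviations as in the README)
supplies constant CO₂/CH₄/N₂O fluxes by fertility class (site types 1–3
nutrient-rich, >3 nutrient-poor), and the soil stock is a per-simulation
constant peat carbon draw. Litter falling on organic soil is treated as
decomposing without accumulation (the stock is held constant), so the
pixel's heterotrophic term is litter + the CO₂ coefficient converted to
carbon. Negative sampled CO₂ coefficients (possible for the nutrient-poor
class, mean −70 g m⁻² yr⁻¹) are meaningful uptake and kept; strictly
positive gases (CH₄, N₂O) are truncated at zero.

## Management

Default triggers (per species pine/spruce/birch): clearcut at diameter
≥ 26/25/24 cm OR dominant height ≥ 24/23/22 m OR age ≥ 80/70/60 y
(combinator configurable), thinning at basal area ≥ 26/28/24 m² ha⁻¹
removing 35 % of the stock. These are representative managed-boreal
guideline numbers shipped as a configurable rule set — the exact national
guideline tables are external to this package. Protected and poorly
productive land is never harvested. Clearcut stemwood becomes round wood;
half of the residues (configurable) are collected as energy wood, the rest
falls as litter. Round and energy wood are tracked jointly against the
combined regional target. Eligible pixels form a single pooled random
order (no preference between thinning- and clearcut-eligible stands); the
marginal pixel's action is executed in full, so overshoot is bounded by one
pixel's yield — harvest actions are discrete silvicultural events, not
continuously divisible.

Country targets in Mm³ yr⁻¹ are scaled to the synthetic landscape by the
ratio of landscape forest area to a reference national forest area
(2 × 10⁷ ha), then allocated to regions by historical shares. Historical
years (2015–2021) follow the realized statistics in all scenarios;
projection years use multiplier × historical mean. The 2 % target deviates
are drawn per projection year by default (once per simulation is available
as a switch) — the yearly-statistical-noise reading of the sampling law.

## Uncertainty engine

Seeding is hierarchical: master seed → per-simulation stream → per-region
substream, all via `numpy` `SeedSequence`, so ensembles are bitwise
reproducible and independent of execution order. Harvest-scenario and RCP
labels never enter the seed path; consequently 2015–2021 trajectories are
identical across harvest scenarios for matched seeds, and scenario
differences are purely causal. Weather series depend only on
(region, GCM, RCP) and the master seed — they are scenario *data*, not
per-simulation noise; the GCM label drawn per simulation selects among
them. All uncertainty components are sampled independently (correlations
between sources are deliberately ignored, matching the study design being
emulated).

Site-type resampling uses a row-stochastic confusion matrix (default: 70 %
retention, the remainder on adjacent classes) optionally tilted by stand
structure: pixels taller than expected for their age shift probability
toward fertile classes. Site types are locked after the initial draw;
re-drawing mid-simulation raises a contract error.

Pixel sample sizes scale with region area (the largest region receives
`n_pixels`, others proportionally, floor 25). This emulates the fact that
small regions carry fewer computational units and therefore noisier
regional means — the mechanism behind the area-dependence of uncertainty
ranges that the risk stage measures.

## Attribution and risk

The redundancy index is the Stewart–Love statistic: with canonical
correlations ρ_k between the feature block and the output block, and output
loadings (correlations of outputs with their own canonical variates),
Rd = Σ_k ρ_k² · mean_j(loading_jk²), clamped to [0, 1]. Canonical
correlations are computed from rank-revealing QR decompositions of the
centred blocks and an SVD of Q_xᵀQ_y — numerically stable and exact for the
univariate case, where Rd reduces to the squared (multiple) correlation.
The default analysis scores each feature column separately against the
scalar output (the r² special case) and reports per-set maxima for the
multi-column sources (pCrob/pPrel/pYas/pECorg/pHarv); a joint-CCA mode per
feature set is available. Per-set maxima over many near-null columns are
upward-biased in small ensembles — the per-year harvest deviates (72
columns) show this most clearly; indices are interpreted only relative to
one another. Categorical drivers (RCP, harvest scenario, GCM) are one-hot
encoded with the first level dropped; constant columns are flagged and
removed; NoHarv is excluded by default because it would swamp the harvest
signal.

Risk summaries are purely empirical: P̂(X ≤ t) = #{x ≤ t}/n and central
interquantile widths using linear interpolation of order statistics
(`numpy.quantile`, method "linear") — chosen for determinism across
implementations.

## Synthetic study conditions

Defaults emulate the source statistics: regional mean basal area within
11–18 m² ha⁻¹ and mean age within 44–91 y; segment areas log-normal
(median 0.8 ha, σ = 1 on the log scale) truncated to [0.026, 540] ha;
species mixtures Dirichlet around the regional composition (sums to 1 by
construction); organic-soil fractions 8–20 %; country round wood uniform in
[68, 78] and energy wood in [7.2, 10.2] Mm³ yr⁻¹. The default landscape has
four regions of 300–6000 segments with a south–north-like gradient
(spruce-rich/younger to pine-rich/older); an 18-region layout is a config
away. Parameter pools are correlated multivariate draws (one shared latent
factor per pool, relative spread 4 %) truncated to physical supports; the
spread was set once so that parametric uncertainty is a leading but not
overwhelming variance source alongside initial-state sampling, GCM choice
and the harvest scenario, mirroring the attribution structure of the class
of study emulated.

The test-scale study used by the test suite and the acceptance script is
4 regions × ≤500 pixels × 50 simulations × (RCP4.5 × four harvest
scenarios), 2015–2050 — sizes chosen so a full grid runs in about a minute
on one CPU; full-scale values (20 000 pixels, 300 simulations, 3 RCPs)
remain configuration options.

What passing tests show: the pipeline's identities (conservation, NBE
recomputability, target/shortfall accounting) are exact; its sampling laws
match their specifications; and the ensemble reproduces the expected
qualitative structure (NoHarv accumulates the largest carbon stock and the
most negative NBE; small regions show the widest NoHarv ranges at the start
of the period; harvest choice becomes a leading uncertainty source by
mid-century in ensembles where it varies). What they do not show: real
inventories have spatial correlation between segments, non-exchangeable
within-region structure, disturbance regimes (wind, fire, insects),
nitrogen limitation, and model-structural error — all outside the surrogate
by design, and the first-order reasons real-data uncertainty would be
larger than the synthetic ensemble suggests.

## Known limitations

- The surrogate's absolute flux levels (NEP ≈ 200–300 gC m⁻² yr⁻¹ on the
  default landscape) sit at the productive end of the boreal range; the
  package's claims are about orderings and uncertainty structure, not
  levels.
- Static organic-soil coefficients likely understate future emissions under
  warming; no dynamic peat model is provided.
- Thinning removes carbon proportionally across the stand rather than from
  below, and volume is strictly proportional to stem carbon after
  initialization.
- Out-of-calibration weather is logged, not clamped: extreme trend settings
  can push the surrogate outside the range its defaults were chosen for.
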
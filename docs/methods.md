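# Methods

## Model structure and assumptions

The kinetic model describes a well-mixed batch reactor in which all
levan chemistry happens extracellularly. Growth is Monod on reactor
sucrose with first-order death; no other substrate supports growth (the
cultures the model emulates are run in rich broth, so every nutrient
except sucrose is assumed non-limiting). Secreted levansucrase is a
growth-associated product: its accumulation rate is `alpha * mu * X`,
with yield `alpha` (mg enzyme per gDW biomass) the key regime-dependent
parameter. The three enzymatic activities — hydrolysis,
transfructosylation, levan degradation — are specific rates
(mmol per mg enzyme per hour) multiplied by the enzyme pool.

Two deliberate bookkeeping choices follow the source formulation rather
than strict elemental balance:

* **Enzyme pool.** Volumetric enzymatic rates use `E_pool = alpha * X`,
  not the integrated enzyme state `E`. With a nonzero death constant the
  two diverge by `integral(alpha * k_d * X dt)`; `E` is carried and
  reported but does not feed back into the rates. A config flag
  `equations="as_printed"` additionally reproduces the literal published
  balances in which the hydrolysis term enters the glucose, fructose and
  sucrose equations without the enzyme-pool factor; the default applies
  the pool uniformly, since the hydrolysis rate carries per-mg units and
  the glucose balance requires it.
* **Fructosyl non-conservation.** Each transfructosylation event
  consumes one sucrose plus one free fructose but adds only one levan
  unit. This is a property of the printed model and is reproduced, not
  corrected. Its practical consequence is that the free-fructose pool
  can be driven to zero during active polymerisation; at that boundary
  the integrator floors the derivative of any exhausted pool at zero
  (an empty pool cannot be drawn down) while leaving interior dynamics
  untouched.

The degradation switch is a Heaviside gate at `t_levdeg_onset`. The
integrator (`scipy.solve_ivp`, LSODA, rtol 1e-8/atol 1e-10 by default)
splits the horizon at the onset so no adaptive step straddles the
discontinuity; a smooth `tanh` gate of configurable sharpness is
available for gradient-based work. Only 33% of the levan pool resists
degradation in the rate law (`0.67 * L` in the saturation term); no hard
stop at a residual level is imposed beyond what the rate law gives.

Units: the state is in mM (levan as fructosyl-monomer equivalents,
162.14 g/mol) because the Michaelis constants are in mM; measurement
I/O converts to g/L with sucrose 342.30 and glucose/fructose
180.16 g/mol. The cumulative growth-sucrose state is tracked as a
positive integral of the growth-uptake rate for interpretability.

## Parameters

Fitted, regime-specific values (growth/expression side): `mu_max`
0.2454 h⁻¹ (low and transition) vs 0.1 h⁻¹ (high); `alpha` 18.19 mg/gDW
(low) vs 45 (transition and high); transition `Y_X/S` ≈ 0.015 gDW/mmol.
The transfructosylation capacity 6.42 mmol·mg⁻¹·h⁻¹ is shared by both
rate-law terms and held constant across regimes, as are all other
enzymatic constants (levansucrase activity does not change with the
medium; only its expression does).

The remaining constants are **non-authoritative placeholders** chosen
once to give realistic batch behaviour at the published scale (levan
maxima of tens of g/L peaking at ~18 h in the low regime and ~36 h in
the high regime, biomass of order 1–2 gDW/L, sucrose depletion driving
a post-peak levan decline with a fructose rebound):

| parameter | value | unit | role |
|---|---|---|---|
| K_s | 20 | mM | Monod half-saturation |
| k_d | 0.01 / 0.005 | 1/h | death (low+transition / high) |
| Y_X/S | 0.040 / 0.015 / 0.010 | gDW/mmol | low / transition / high |
| v_max,hyd | 1.2 | mmol/(mg h) | hydrolysis capacity |
| K_M,hyd | 60 | mM | hydrolysis half-saturation |
| K_M,trans1 | 5000 | mM | sucrose-only route (weak) |
| K_M,trans2 | 8000 | mM² | fructose-acceptor route (dominant) |
| v_max,deg | 0.15 | mmol/(mg h) | levan degradation capacity |
| K_M,deg | 50 | mM | degradation half-saturation |
| t_levdeg_onset | 18 / 24 / 36 | h | degradation onset per regime |

The acceptor-dominant transfructosylation parameterisation
(K_M,trans1 ≫ effective acceptor K) is what produces the observed
hydrolysis-first dynamics: early hydrolysis builds the free-fructose
pool, transfructosylation then overtakes it, and the
hydrolysis-to-transfructosylation (H/T) balance falls with sucrose
abundance. Note that the *cumulative* H/T ratio (total hydrolysis over
total transfructosylation) is structurally ≥ 1 minus the
degradation-recycled share, because every acceptor-route event consumes
a hydrolysis-derived fructose; transfructosylation dominance shows in
the instantaneous rates during mid-production, not in the cumulative
ledger.

## Calibration and sensitivity

The objective is the SSE between simulation and observation in
measurement units over all species on the sampling grid. The default
optimiser is bounded trust-region-reflective least squares on
log-transformed parameters (strictly positive, spanning decades); a
plain unbounded Levenberg–Marquardt mode is provided. Multi-start
(default 10 starts: the supplied initial set plus log-uniform draws
inside the bounds, all seeded from one master seed) guards against local
minima; the best start by SSE wins. Goodness of fit is the
range-normalised RMSE per species in percent — the normaliser
(max − min of the observed series) is a package choice; mean- and
max-normalised variants are selectable. The condition-level figure is
the unweighted mean over the five measured species. The default free
set is the growth/expression side (`mu_max`, `K_s`, `k_d`, `Y_X/S`,
`alpha`, `t_levdeg_onset`); the enzymatic capacities and Michaelis
constants are held fixed, consistent with constant enzyme chemistry
across regimes.

The sensitivity scan perturbs one parameter at a time by ±50%, holding
the rest, and scores each perturbed trajectory against the baseline by
per-species range-normalised RMSE; failed simulations are recorded
per-cell without aborting the scan. No profile-likelihood or
Fisher-information identifiability analysis is attempted.

## Snapshot coupling and flux analysis

Coupling is snapshot-based, not a time-stepping dynamic-FBA loop: at
9 h (configurable) the kinetic model supplies mu, the uptake mu/Y_X/S
and alpha, imposed as fixed bounds (lb = ub; a relaxed ≤ mode exists
for feasibility diagnosis). The levansucrase yield constraint needs a
protein molecular weight to become a flux; the default 53,000 mg/mmol
is a SacB-class value and config-overridable. The minimal-total-flux LP
splits every reversible reaction into an irreversible pair and minimises
the summed split flux with scipy's HiGHS solver; steady state is
verified to 10⁻⁹. Individual fluxes at the optimum can be non-unique;
flux-sums are reported from the returned vertex. Flux-sums are
Φ_i = ½ Σ_j |S_ij v_j|, normalised by the sucrose uptake so the uptake
metabolite anchors at exactly 1. Activity classification uses the 10⁻⁶
mmol·gDW⁻¹·h⁻¹ threshold and the four named patterns (active
everywhere, low-only, transition+high, inactive everywhere); anything
else is labelled "other".

The supplementation scenario replaces the growth equality with a floor
at 50% of the coupled growth rate (configurable) — a hard equality
would leave no degree of freedom for the levansucrase-maximising
objective — and compares closed versus opened precursor exchange.
The knockdown scenario caps one reaction and re-solves the
minimal-total-flux problem; branch-point reactions are flagged
increased/decreased/unchanged at the activity threshold.

## Synthetic data and the toy network

The generator simulates each condition with its regime preset, samples
at the experimental grid (6, 12, 18, 24, 30, 36, 48, 60, 72, 96,
120 h), and applies mean-one multiplicative lognormal noise (default
CV 3%, the scale suggested by the replicate scatter of the published
summary table) with an optional detection floor; additive Gaussian
noise is selectable. It emulates magnitudes and sampling structure, not
instrument artefacts (no retention drift, co-elution or
replicate-specific batch effects), so passing calibration tests shows
the estimator works under the assumed noise model — not that the noise
model matches a real HPLC campaign.

The toy stoichiometric network (17 reactions, 11 metabolites) is
mass-balanced and deliberately minimal: sucrose uptake and cleavage to
hexose phosphate, the PGI vs G6PDH branch at glucose-6-phosphate with a
non-oxidative return route, a lumped glycolysis/respiration energy
spine with overflow and maintenance sinks, amino-acid synthesis (the
only NADPH consumer), biomass, and a levansucrase-protein
pseudo-reaction draining amino acids and ATP with a secretion exchange.
The amino-acid supplement exchange ships closed. The levansucrase
composition (10 amino-acid units + 20 ATP per mmol protein) is a
uniform placeholder, not a measured composition — scenario results on
the toy network are structural, not quantitative; in particular the
published 1.342-fold supplementation response of the genome-scale model
is not a target for the toy fixture. Internal amino-acid synthesis is
costly but possible, so the coupled baseline is always feasible and
supplementation strictly increases the maximised enzyme flux.

## Numerical choices and limitations

* Report-grid quadrature: time-integrated rate diagnostics (the
  flux-weighted H/T average) are computed on a grid refined to 0.5 h,
  since coarse sampling under-resolves fast conversions at high enzyme
  yields.
* The fitted growth/expression values with the placeholder enzymatic
  constants under-predict peak biomass in the high regime (≈0.8 vs
  ≈2.6 gDW/L) and reach roughly half the published high-regime levan
  titre; the low-regime magnitudes and all timing structure (18 h vs
  36 h peaks) are reproduced. Supplying the measured kinetic constants
  would remove this gap without code changes.
* Parameter recovery tests free only (`mu_max`, `alpha`); with all ten+
  constants free the problem is structurally unidentifiable from five
  noisy species at eleven time points.
* Analysis problem sizes (three replicates, 10–20 recovery datasets,
  the 17-reaction network) are the package's default study conditions;
  all scale up by argument.
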
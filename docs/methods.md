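# Methods

## Scope and conventions

The package quantifies benthic sulfide cycling from three measurement
types — voltammetric microprofiles, porewater depth profiles and benthic
chamber incubations — and upscales station fluxes to a two-stratum basin
budget. One depth convention is used everywhere: depth in mm, positive
downward, 0 at the sediment–water interface; overlying-water points carry
negative depths. Fluxes are in mmol m⁻² day⁻¹ and are positive when
directed out of the sediment, so a sulfide pool increasing with depth
yields a positive (efflux) value and an oxygen profile decreasing into the
sediment a negative (uptake) value. Every CSV written by the package stamps
this convention, the seed and a configuration hash in its header.

## Diffusive fluxes

Fluxes follow Fick's first law under a steady-state assumption,
*J* = φ(0)·*D*ₛ·d*C*/d*z*, with the sediment diffusivity from the modified
Weissberg tortuosity relation *D*ₛ = *D*/(1 − 2 ln φ(0)). The gradient is
an ordinary least-squares fit over a closed depth window (default the top
0–5 mm; endpoints inclusive; deeper windows configurable per station and
analyte). Censored (below-detection) points are excluded from the fit
rather than substituted at DL/2 — substitution biases the slope badly in
three-point windows — and each exclusion is logged. The uncertainty is
reported as exactly ±2 standard errors of the slope (a 95% interval by the
normal approximation, not a t-quantile), propagated linearly through the
constant factor φ·*D*ₛ.

Free-solution diffusion coefficients use a Boudreau-style formulation:

- seawater dynamic viscosity μ(S, t, P) from the Kukulka et al. polynomial
  (centipoise; valid −2 to 40 °C, S 0–45);
- O₂ from the dedicated fit D = (0.2604 + 0.006383·T_K/μ)×10⁻⁵ cm² s⁻¹;
- H₂S from the Hayduk–Laudie correlation
  D = 13.26×10⁻⁵/(μ^1.14·V_b^0.589) with the LeBas molal volume
  V_b = 32.9 cm³ mol⁻¹;
- the ions HS⁻, Fe²⁺ and Mn²⁺ from linear pure-water temperature fits
  (m₀ + m₁·t)×10⁻⁶ cm² s⁻¹ with (10.4, 0.273), (3.31, 0.150) and
  (3.18, 0.155) respectively;
- a Stokes–Einstein factor μ(0,t)/μ(S,t,P) converts to in-situ salinity
  and pressure. Following the convention of the standard aquatic-science
  toolbox for these relations, the two viscosity-based gas correlations are
  evaluated at the in-situ viscosity before this factor is applied.

At the brackish study conditions (S = 12, 10 °C, 1 atm) this yields
1.362×10⁻⁴ (O₂), 1.028×10⁻⁴ (H₂S) and 0.406×10⁻⁴ (Fe²⁺) m² day⁻¹.
The "H2S" coefficient is used for total dissolved sulfide throughout.

Surface porosity is a required physical input with no universal value; when
a station does not provide one the package assumes φ(0) = 0.9, typical of
organic-rich mud, and logs the assumption at INFO level. Because measured
porosities are rarely reported alongside microprofiles, absolute flux
values inherit this assumption linearly.

## Voltammetric signal processing

A cyclic scan runs −0.1 → −1.8 V and back at 1000 mV s⁻¹. Peaks are
quantified on the forward sweep as local maxima above a **linear baseline
drawn between the endpoints of the analyte's potential window** — the
simplest model consistent with sharp peaks on slowly varying backgrounds,
and one with a trivial oracle. Default windows: sulfide −0.95 to −0.60 V
(the free-sulfide peak sits near −0.7 V and drifts toward −0.9 V at high
concentration), FeS(aq) −1.20 to −1.05 V (reported as signal intensity
only; no calibration standard exists), Fe²⁺ −1.49 to −1.35 V, Mn²⁺ −1.65
to −1.50 V, O₂ −0.50 to −0.20 V. Within the sulfide window up to two peaks
are reported; two maxima closer than 0.05 V are treated as one peak with a
shoulder (grid-scale robustness), which defines when a double peak counts
as a polysulfide candidate.

The backward sweep carries a wave proportional to total dissolved sulfide
(ΣH₂S: HS⁻, H₂S, polysulfides, labile metal sulfides) over 2–1200 μM. How
the original instrument software measured this wave is not standardised;
the package uses **plateau minus baseline** (median current at potentials
more positive than −0.4 V minus median at potentials more negative than
−1.3 V), a choice that is exact for sigmoid waves and robust to noise.

Calibration is by standard additions (OLS slope with intercept; at least
three additions; a non-positive slope is an error), with Mn²⁺ as the pilot
ion: a fresh pilot calibration rescales every stored sensitivity by the
ratio new/reference. Four scans are taken per depth; the first is discarded
(electrode conditioning) and the remaining replicates averaged. Detection
limits default to 20 μM (O₂), 10 μM (Mn²⁺, Fe²⁺) and 0.2 μM (H₂S);
replicate means below the DL are reported *at* the DL with a `below_dl`
flag, so no uncensored value ever lies below its DL. A replicate relative
spread above 5% sets a QC flag but does not reject the value. The forward
sulfide peak saturates near 250 μM; replicate means from 1% below that
ceiling upward are flagged `saturated` and re-quantified from the backward
wave (a forward reading within noise of the ceiling cannot be trusted;
no hysteresis is applied).

Polysulfide speciation assumes a mean chain length x = 5 (appropriate for
porewater pH 7–8) and that polysulfide sulfur shares the free-sulfide
calibration slope. The more negative peak of the double peak carries the
(x−1) zerovalent atoms per molecule, so [Sₓ²⁻] = h₋/slope/(x−1); the other
peak is free sulfide plus the terminal S(−II), so
[HS⁻] = h₊/slope − [Sₓ²⁻], floored at zero. The polysulfide fraction is
referenced to the backward-wave ΣH₂S; a fraction above 1 is reported as an
error rather than clipped, since it indicates inconsistent signals.

## Chamber fluxes

flux = OLS slope of concentration vs time (converted to mmol m⁻³ day⁻¹) ×
enclosed water height (sediment-free volume / 651.4 cm² chamber area). The
height is an input: volumes are measured per deployment and rarely
published; synthetic defaults are 0.1–0.2 m. A deployment is "bdl" when
all samples are censored, or when four or more quantified samples give a
slope with a two-sided t-test p ≥ 0.05 — a statistical reading of "below
detection" chosen because published tables report bdl without a stated
rule. Dilution by syringe-sample replacement water is ignored (replacement
protocols are unreported); for six ~50 ml syringes against tens of litres
of enclosed water the bias is well under the fit uncertainty.

## Regional budget

Two strata: the HTZ (default 47 320 km², flux = mean of the mat-station
surface fluxes, whose upward sulfide is consumed at the mats = "retained")
and the permanently anoxic basin (default 18 954 km², flux = deep-station
efflux = "to water"). Loads are flux × area × 365 days × 32 g mol⁻¹,
expressed in kton S yr⁻¹; with 32.065 g mol⁻¹ the HTZ load shifts by
~0.2%, and both constants are configurable. Comparison against printed
values rounds half away from zero to the printed digits. The 82 m station
(a weak-flux HTZ margin site) is excluded from the HTZ mean, which is the
mean of the three mat stations. No uncertainty is attached to the areas;
flux uncertainty can be carried through linearly but is not reported by
default.

## Synthetic-data generator

Profiles come from the steady-state two-point boundary-value problem
φ*D*ₛ·C″ − k(z)·C + R(z) = 0 with piecewise-constant rates, a Dirichlet
top boundary (bottom-water concentration) and a zero-gradient bottom
boundary, discretised by second-order central differences (mirror node at
the bottom) on a 0.025 mm internal grid and solved as a tridiagonal
system. The scheme is exact for the piecewise-linear/quadratic analytic
steady states used as oracles. Scenario elements:

- **production zone** (top, bottom, rate in μM day⁻¹ per bulk volume):
  sulfate reduction at depth; in a reaction-free zone above it the profile
  is linear and the surface flux equals the depth-integrated production.
- **mat layer**: "total consumption" is modelled as a first-order sink at
  5×10³ day⁻¹, strong enough that the concentration at the mat top stays
  below 0.1 μM (penetration depth ~0.12 mm) while avoiding a free-boundary
  problem. The discrete budget (flux in minus flux out vs integrated
  consumption) closes to machine precision; the flux delivered to the mat
  base is recorded in the truth record alongside the ~0 interface flux.
- **Fe source** (depth, flux): dissolved iron released over a 2 mm band
  (reductive dissolution at the contact with older, iron-rich deposits),
  with a first-order Fe sink (50 day⁻¹) wherever sulfide exceeds 1 μM and
  a corresponding sulfide sink (30 day⁻¹, FeS precipitation) below the
  production zone. Sulfide is solved first and its field gates the iron
  sink, which keeps the two fields essentially non-overlapping, as in
  deep-basin cores with shallow lacustrine clay.

Sampling adds Gaussian noise truncated at zero (concentrations are
non-negative), applies detection-limit censoring, and includes two
overlying-water points. Scan step defaults to 0.5 mm with the 0.25 mm
instrument minimum enforced. Synthetic voltammograms place Gaussian peaks
(σ = 15 mV) at the characteristic potentials with the saturation and
centre-drift behaviour described above, and a logistic backward wave;
chamber series rise linearly at flux/height with truncated Gaussian noise.
Identical seeds reproduce identical outputs everywhere.

Parameter-recovery scenarios draw the target flux log-uniformly over
0.1–10 mmol m⁻² day⁻¹ and size the reaction-free transport zone so the
concentration at its base reaches ~240 μM (capped at 6–100 mm), matching
the hundreds-of-μM pools observed in organic-rich basin sediments; the
fit window spans that zone. Under these conditions (noise 2 μM) refitted
fluxes recover truth within 5%, dominated by regression noise.

What the generator does **not** emulate — and hence what passing recovery
tests do not establish for field data: transient diagenesis and
non-steady-state boundary layers, bioturbation/bioirrigation, multi-species
redox kinetics, pH/carbonate chemistry, electrode drift and fouling,
lateral heterogeneity (the factor-of-three gap between point microprofiles
and large-footprint chamber fluxes), and real porosity depth structure.

## Numerical choices and degenerate inputs

OLS fits use `scipy.stats.linregress`; the closed-form textbook formulas
serve as an independent oracle in the tests (agreement to 10⁻¹⁰ relative).
Gradient windows are closed intervals on the profile grid. Degenerate
inputs raise rather than guess: fewer than three uncensored points or zero
depth variance in a window, fewer than two usable replicates, non-positive
calibration slopes, porosity outside (0, 1], windows outside the scanned
potential range, negative concentrations in a noiseless solver field.
Peak detection requires a 1 nA minimum height by default; the
double-peak/shoulder tie-break is the 0.05 V separation rule.

## Known limitations

Absolute diffusive fluxes scale linearly with the assumed surface porosity.
The diffusion-coefficient formulation reproduces the standard toolbox
values to ~1% but is a reconstruction, not a shared code path. FeS(aq) is
semi-quantitative by nature of the method. The bdl rule for chambers is a
modelling choice, as is the plateau definition of the backward wave. The
budget treats each stratum as homogeneous; no hypsometric weighting is
attempted.
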
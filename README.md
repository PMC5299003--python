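# benthifilter

Quantification of the **benthic sulfide filter**: the near-complete
consumption of the upward porewater sulfide flux at the sediment–water
interface by mats of sulfide-oxidising bacteria (*Beggiatoa*), as observed
along hypoxic-to-euxinic basin transects such as the Eastern Gotland Basin
(Baltic Sea).

The package is written for sediment biogeochemists working with solid-state
Au/Hg voltammetric microelectrodes and benthic lander incubations. It covers
the full quantitative chain:

1. **Voltammetry** — cyclic-voltammogram processing: baseline-corrected peak
   detection in per-analyte potential windows, backward-wave total-sulfide
   (ΣH₂S) measurement, standard-addition calibration with Mn²⁺ pilot-ion
   rescaling, replicate averaging with detection-limit censoring, and
   polysulfide (Sₓ²⁻) speciation from the forward double peak.
2. **Diffusive fluxes** — Fick's first law with tortuosity correction:

   *J* = φ(0) · *D*ₛ · d*C*/d*z*,  *D*ₛ = *D* / (1 − 2 ln φ(0)),

   with *D* the free-solution diffusion coefficient at in-situ
   salinity/temperature/pressure (Boudreau-style relations with a
   Stokes–Einstein viscosity correction), the gradient d*C*/d*z* an OLS fit
   over a stated depth window (typically the top 0–5 mm), and 95%
   uncertainty reported as ±2 standard errors. Positive fluxes are directed
   out of the sediment.
3. **Chamber fluxes** — benthic chamber incubations: flux = slope of the
   concentration–time series × enclosed water height, with a "bdl" verdict
   when the slope is indistinguishable from zero or all samples are censored.
4. **Budget** — two-stratum upscaling: areal sulfur loads (kton S yr⁻¹) for
   the hypoxic transition zone (HTZ, 80–120 m) and the permanently anoxic
   deep basin, and the fraction of the basin-wide sulfide flux retained by
   the benthic filter.
5. **Synthetic data** — a steady-state 1-D reaction–diffusion generator
   producing porewater profiles (with analytic truth fluxes), matching
   voltammograms and chamber series, so every stage is testable by
   parameter recovery.

## Worked example

Simulate an HTZ mat station, refit its sulfide flux, and upscale:

```python
from benthifilter import *

scenario = Scenario(
    station_label="htz-95m",
    water_depth=95.0,
    production_zone=(5.0, 25.0, 150.0),   # sulfate reduction, 150 uM/day
    mat_layer=(0.0, 1.0),                 # Beggiatoa mat at the interface
    max_depth_mm=25.0,
    depth_step=0.25,
    noise_sd=2.0,
    seed=7,
)
profile, truth = generate_profile(scenario)
slope, se = fit_gradient(profile, "H2S", depth_window=(1.0, 5.0))
flux = diffusive_flux(slope, se, scenario.porosity, truth.Ds["H2S"])
print(f"gradient  : {slope:.1f} uM/mm")
print(f"flux      : {flux.value:.2f} +/- {flux.two_se:.2f} mmol m-2 day-1")
print(f"truth     : {truth.true_flux_to_mat['H2S']:.2f} mmol m-2 day-1")

budget = filter_budget(flux_htz=2.87, flux_anoxic=3.14)
print(budget.rounded())
```

prints

```
gradient  : 38.4 uM/mm
flux      : 2.93 +/- 0.04 mmol m-2 day-1
truth     : 3.00 mmol m-2 day-1
{'load_retained_kton_yr': 1586.0, 'load_to_water_kton_yr': 695.0,
 'load_total_kton_yr': 2281.0, 'fraction_retained_pct': 70.0}
```

The 150 μM/day source over 20 mm sustains a 3.0 mmol m⁻² day⁻¹ upward flux;
fitting the noisy sampled profile below the mat recovers it within its 95%
interval plus the ~2% discretisation/noise error. With the HTZ mean flux
(2.87 mmol m⁻² day⁻¹ over 47 320 km²) and the deep-basin efflux
(3.14 mmol m⁻² day⁻¹ over 18 954 km²), 1586 of 2281 kton S yr⁻¹ — 70% —
is retained at the mats and 695 kton S yr⁻¹ escapes to the anoxic water
column.

## Command line

```bash
benthifilter simulate     --scenario scenario.yaml --seed 1 --out profile.csv
benthifilter voltammetry  --scans scans.csv --calib calib.yaml --out profile.csv
benthifilter profile-flux --profiles profiles/ --config run.yaml --out table2.csv
benthifilter chamber-flux --series series.csv --out table3.csv
benthifilter budget       --config run.yaml --out budget.json
benthifilter run          --config run.yaml          # chain all stages
```

All tabular I/O is CSV with documented headers; the depth convention
(positive downward, 0 at the sediment–water interface) plus the seed and a
configuration hash are stamped in a `#` comment header of every output.

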
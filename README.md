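# sizespectra

Trait-resolved community size spectrum modelling for marine food webs.

## The problem

Size-structured ecosystem models usually assume every predator eats prey a
fixed factor smaller than itself — a constant predator–prey mass ratio
(PPMR), typically around 100 for fish.  Real feeding relationships are far
more diverse: some taxa (fast, visually hunting squid) take prey close to
their own size throughout life, while others (low-activity cephalopods,
filter feeders, baleen whales) keep eating tiny prey even as they grow
enormous, so their PPMR *rises* with body size.  `sizespectra` is a
community size spectrum model built to quantify what this diversity of
size-based feeding does to emergent ecosystem structure and function:
biomass, production, stability, energy turnover, spectrum shape, trophic
position.

The community comprises a static phytoplankton spectrum plus four dynamic
functional groups — zooplankton, low-activity cephalopods, high-activity
cephalopods and fish.  The abundance density `N_i(w, t)` (ind m⁻³ g⁻¹) of
each group evolves by a McKendrick–von Foerster equation with a
growth-diffusion term:

    ∂N_i/∂t = −∂(g_i N_i)/∂w − μ_i N_i + ½ ∂²(f_i N_i)/∂w²

with

* growth `g_i = K_i V_i(w) D_i(w, t)` — net growth efficiency × search rate
  (`V_i = y_i w^α`) × suitable prey mass density
  `D_i = Σ_j θ_ij ∫ w′ φ_i(w, w′) N_j(w′) dw′`;
* mortality `μ_i = μ_p + μ_O` — predation (the same double integral seen
  from the prey side) plus a size-dependent background closure;
* diffusion `f_i = y_i w^α Σ_j K_ij² ∫ w′² φ_i N_j dw′` — the second moment
  of mass intake, representing growth variability among individuals.

Feeding preference is lognormal in the log mass ratio,
`φ = exp(−[ln(w/(β(w) w′))]²/2σ²)`, where the preferred PPMR `β(w)` is
constant for fish (100), zooplankton (1000) and high-activity cephalopods
(25), and a rising power law for low-activity cephalopods (10⁴ at their
minimum size to 3×10⁶ at their maximum).  Recruitment is fixed at each
group's smallest size class (zooplankton from phytoplankton; fish equal to,
and each cephalopod group half of, the local zooplankton abundance).

The headline experiment contrasts a **control** set (3 runs; cephalopods
parameterized exactly as fish apart from their size ranges) with a
**feeding + growth (F+G)** set (27 runs; distinct cephalopod PPMR, diet
width and growth-efficiency traits over a 3×3×3 factorial of recruitment
scaling, high-activity PPMR and low-activity PPMR-curve scaling), and
reports percent changes of set medians in community biomass, production,
biomass stability (1/CV) and energy-turnover rate (P/B).

## Worked example

```python
import sizespectra as ss

cfg = ss.default_config(years=300, averaging_years=100)
sim = ss.Simulation(cfg)
result = ss.run_simulation(cfg, sim=sim)
m = ss.evaluate_run(result, sim=sim)
print(f"community biomass : {m.total_biomass:.4f} g m^-3")
print(f"production        : {m.production:.4f} g m^-3 yr^-1")
print(f"turnover time     : {m.turnover_time:.2f} yr")
print(f"stability (1/CV)  : {m.inv_cv:.2f}")
print(f"spectrum slope    : {m.spectrum_slope:.2f}")
```

prints

```
community biomass : 0.0530 g m^-3
production        : 0.0889 g m^-3 yr^-1
turnover time     : 0.60 yr
stability (1/CV)  : 3.31
spectrum slope    : -2.37
```

i.e. the trait-resolved community holds ~0.05 g of consumer biomass per m³,
turns it over in about seven months, fluctuates with an annual-biomass CV
of ~0.30 (1/CV ≈ 3.3), and its abundance spectrum falls slightly steeper
than the canonical −2.  `m.rtp` and `m.realised_ppmr` carry the per-group
trophic-position and diet-realised PPMR curves: with the default traits the
high-activity cephalopods feed at trophic positions ≈3.5–4.3 with realised
PPMR near their preferred 25, while the low-activity group realises a PPMR
near 10⁶, feeding far down the spectrum for its size.

The same operations are available from a CLI:

```bash
sizespectra run --years 300 --outdir run_out        # one simulation
sizespectra sweep --set feeding_growth --outdir fg  # one experiment set
sizespectra experiment --outdir exp                 # control vs F+G contrasts
sizespectra synth --seed 1 --outdir inputs          # synthetic inputs
sizespectra metrics run_out --outdir metrics_out    # post-process stored runs
```

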
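# Methods

## Model

The community is a set of abundance density fields `N_i(w, t)`
(ind m⁻³ g⁻¹) over body mass `w` (g), one per dynamic functional group
(zooplankton, low-activity cephalopods, high-activity cephalopods, fish),
driven by a static phytoplankton spectrum.  Each group obeys a
McKendrick–von Foerster equation with a second-order growth-diffusion term:

    ∂N/∂t = −∂(gN)/∂w − μN + ½ ∂²(fN)/∂w².

Growth is fully prey-driven, `g_i = K_i V_i D_i`, with a linear (non-
saturating) functional response: `V_i(w) = y_i w^{α_i}` is the volume
searched per year and `D_i(w) = Σ_j θ_ij ∫ w′ φ_i(w, w′) N_j(w′) dw′` the
mass density of suitable prey, summed over all pools including
phytoplankton.  Mortality is predation (the same encounter integral seen
from the prey side) plus a background/senescence closure
`μ_O(w) = k_s (w/w_s)^{p_s}` for `w ≥ w_s`, zero below.  The diffusion
coefficient `f_i = y_i w^{α_i} Σ_j K_ij² ∫ w′² φ_i N_j dw′` is the second
moment of mass intake; `K_ij = K_i θ_ij` reconciles the per-group growth
efficiency with the pairwise interaction coefficients (all θ default to 1).

Size selection is lognormal in the log predator:prey mass ratio with
preferred ratio β and width σ (in ln prey-mass units).  β is constant for
three groups and allometric, `β(w) = β₀ (w/w_min)^γ`, for the low-activity
cephalopods; β₀ and γ are solved from the two anchors β(w_min) = 10⁴ and
β(w_max) = 3×10⁶, so the implemented curve reproduces that range exactly
for any size range.

Reproduction is not resolved: after every update the smallest size class of
each group is overwritten with a fixed recruitment — zooplankton with the
phytoplankton density at that class, fish with the zooplankton density at
their smallest class, each cephalopod group with half of it, further scaled
by the sweep factor p.  Phytoplankton is pure forcing: it is never depleted
and has no dynamics, so the community is an open, energy-forced system.

## Numerics

The equation is solved on a uniform grid in `x = log10 w` with 0.1-wide
bins spanning log10 w ∈ [−13, 5] (180 bins); derivatives transform as
`∂/∂w = (w ln10)⁻¹ ∂/∂x`.  Group size limits snap to the nearest bin edge
(ties downward).  The update per substep is:

* first-order upwind differencing of the advective flux `gN` (growth is
  non-negative, so upwind = backward in mass); the flux leaving the last
  bin of a group's range is lost (death by outgrowing the range);
* central second difference of `fN` in mass coordinates, with zero-value
  ghost cells at the range ends;
* mortality applied as an exact factor `exp(−μ h)` per substep, so
  mortality-only dynamics are exact to machine precision;
* recruitment boundary re-imposed after every substep.

The nominal step is weekly (dt = 1/52 yr), but each step is sub-cycled
automatically so that both the advective CFL number `g·h/(w ln10 Δx)` and
the diffusion number `f·h/(w ln10 Δx)²` stay below 0.9: the transient
waves these communities generate transiently exceed the weekly stability
limit, and sub-cycling (recomputing rates each substep) preserves the
scheme while keeping it stable.  A step that would need more than 64
subdivisions aborts with a CFL diagnostic.  Negative densities produced by
the central diffusion stencil are clipped to zero and the clipped mass is
accumulated as a QC diagnostic; accepted runs keep it below 0.1% of
standing biomass.  Integrals use the midpoint rule on the shared grid
(`dw = w ln10 Δx` per bin).  The solver is fully deterministic: identical
configurations reproduce trajectories bit for bit.

Runs last 1000 simulated years by default; per-group biomass `∫ w N dw` is
recorded at the last weekly step of each year, and the mean abundance
spectrum is accumulated over the final 500 annual snapshots (both
configurable).  No convergence test is applied; the community settles into
its attractor (a fixed point or a limit cycle) well before year 400 under
the default parameterization.

## Parameters

Printed, substance-level values: high-activity cephalopod PPMR 25 (swept
12.5/25/50); low-activity PPMR rising from 10⁴ to 3×10⁶ (curve scaling
swept 0.5×/1×/2×); net growth efficiencies 0.3 (high-activity), 0.4
(low-activity), 0.2 (fish and zooplankton); recruitment sensitivity scalars
p ∈ {0.5, 1, 2}; weekly steps, 0.1-log10 bins, 1000-year runs averaged
over the final 500 years; control cephalopods parameterized as fish except
for their size ranges.

Everything else is a package convention, chosen once for a realistic,
persistent, quasi-steady community and then frozen:

| parameter | value | rationale |
|---|---|---|
| size ranges (log10 g) | zoo [−7, −1], cephs [−2, 4], fish [−3, 5], phyto [−13, −5] | schematic roles of the groups; phyto overlaps the zoo recruitment class |
| fish / zooplankton PPMR | 100 / 1000, constant | conventional fish value; zooplankton feed far down-spectrum |
| kernel widths σ | 1.0 (fish, high-activity), 1.5 (zoo, low-activity) | broader diets for the high-PPMR groups |
| search rate | y = 1000 m³ yr⁻¹ g⁻⁰·⁸ (zoo 400), α = 0.8 | standard volume-search allometry; magnitudes give realistic specific growth (order 1–10 yr⁻¹ at small sizes) within the weekly-step stability envelope |
| background mortality | flat (p_s = 0, w_s = w_min): 2.0 (zoo), 0.5 (cephs), 0.3 (fish) yr⁻¹ | natural-mortality magnitudes; a flat closure removes the zero-mortality stagnation of starved juvenile cohorts and lets the system reach the quasi-steady regime the metrics assume |
| phytoplankton | N_P = 10⁻³ w⁻² ind m⁻³ g⁻¹ | Sheldon-like slope −2; intercept gives ~0.02 g m⁻³ standing phytoplankton biomass |

## Metrics

Per run, over the averaging era: mean total annual biomass; CV of the
annual totals (sample sd, n−1) and its inverse as the stability metric;
community somatic production `P = Σ_i ∫ g_i N_i dw` recomputed on the
era-mean state (a flux-based time-averaged alternative was considered and
not implemented; the era-mean convention is simple and deterministic);
turnover time B/P and its reciprocal P/B as the energy-turnover rate; OLS
slope/intercept of log10 total density vs log10 mass over occupied bins.
Trophic positions solve the fixed point `TP(w) = 1 + Σ shares·TP(prey)`
with biomass-weighted diet shares `θ w′ φ N dw′` (phytoplankton ≡ 1),
iterated to 1e-10; prey classes whose own TP is undefined (empty diet in a
crafted state) are excluded from the average rather than propagating NaN.
Realised PPMR is `w / exp⟨ln w′⟩` under the same shares.  Sets are
summarized by medians, and contrasts are percent changes of treatment
medians vs control.

## What the synthetic data emulate — and what they do not

The generator stands in for a voyage-derived phytoplankton size spectrum
and for empirical cephalopod trophic-position tables.  It produces a
truncated power law with optional multiplicative lognormal bin noise, and
observation points around two generative trophic-allometry lines (steep
and high for the high-activity group, shallow and low for the
low-activity group).  It does not emulate station structure, taxonomy,
seasonality or measurement-specific biases; passing tests demonstrate
correct mechanics and recovery of generative parameters, not fidelity to
any particular ocean transect.

## Design choices and limitations

* **Sub-cycled explicit scheme** rather than a strict single weekly step:
  see Numerics; the reporting cadence is still weekly.
* **Linear functional response** (no feeding saturation) per the growth
  closure above; combined with fixed recruitment this promotes predator–
  prey limit cycles.  Under the default parameterization both experiment
  sets live on moderate limit cycles (annual-biomass CV ≈ 0.3), which is
  what gives the stability metric a meaningful, finite value.
* **Trait-table sensitivity.**  The contrast experiment's *signs* depend on
  the full trait table.  With the conventions above, the trait-resolved
  set is dominated by the low-activity cephalopods — their rising PPMR
  gives them access to the richest part of the spectrum at every size,
  their high efficiency (0.4) converts it well, and no predator reaches
  their large sizes — so community biomass and production are *higher*
  and P/B *lower* than control, while community stability (1/CV) is
  higher.  A different (e.g. empirically fitted) trait table can reverse
  the biomass/production signs; treat the shipped defaults as a
  demonstration parameterization, not an estimate for any real system.
* **No fishing, temperature forcing, reproduction dynamics or space.**
* The phytoplankton pool is non-depletable, so energy input is effectively
  unlimited at the base; absolute biomass levels scale with the (arbitrary)
  phytoplankton intercept and search-rate magnitudes.
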
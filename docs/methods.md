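# Methods

`porehr` computes soil heterotrophic respiration (HR) — the microbial
CO2 efflux from decomposing soil organic matter — mechanistically, from
the geometry of water in pore space up to climate-driven global trends.
This note records the model chain, the numerical choices, the defaults
and their rationale, and the limits of what the synthetic tests
establish.

## 1. Pore-scale stage

**Media** (`porehr.media`). 2D granular media are built by random
sequential addition of non-overlapping circular grains of uniform
diameter λc until the rasterized porosity first reaches the target
(default 0.5; 2D disc RSA jams at ~0.547 solid fraction, so 0.5 is
reachable with a bounded attempt budget). Grains are clipped at the
domain edges (finite chip, no periodicity). A pixel is solid if its
center falls in a grain; default resolution 20 px per λc. Pore pockets
not 4-connected to the largest top-connected pore body are converted to
solid (typically < 1% of porosity, recorded in provenance): isolated
porosity can neither drain nor exchange gas, and sealing it makes the
fully saturated state exactly one water cluster. An overlapping-grain
(boolean model) variant is available via `overlap=True`.

**Drainage** (`porehr.percolation`). Image-based invasion percolation:
air enters at the top boundary and repeatedly invades the accessible
water pixel with the lowest capillary entry pressure, proxied by the
largest local aperture (Euclidean distance to solid); ties break in
row-major order, making runs bit-reproducible. The air front uses
8-connectivity, water patches 4-connectivity (prevents checkerboard
leakage). Trapping (water 4-disconnected from the bottom outlet becomes
non-invadable) is implemented but **off by default**: with it, drainage
of the 3 cm × 2.25 cm reference chip stalls at residual saturation
≈ 0.42, whereas the drainage experiments this emulates reach
saturations below 0.1. With trapping on, the trapped mask is refreshed
every `n_pore/500` steps (exact for media under 5000 pore pixels);
trapping is monotone, so a stale "trapped" flag can never be wrong —
refreshing only delays the discovery of newly trapped clusters.

**Patch statistics.** Water patches are 4-connected components; the
patch touching the bottom row is flagged as the spanning (draining)
cluster. The size-distribution ansatz n(s) = s^−τ exp(−s/ξ) is fitted
per saturation with the Fisher exponent fixed (187/91 in 2D) on finite
clusters only, in units of λc² cells — the natural percolation "site"
here, and the only unit in which cutoffs of order γ(1−θ̃) with γ ~ 100
are measurable at all. Two estimators are provided:

* `method="moment"` (default): the characteristic cluster size
  ⟨s²⟩/⟨s⟩, the standard model-free cutoff-scale statistic. Always
  finite; robust to the dust of one/two-pixel fragments.
* `method="mle"`: maximum likelihood for the truncated density on the
  tail above 0.25 cells. On simulated drainage ensembles this is
  usually *unidentified* (the finite-cluster spectrum decays more
  slowly than the Fisher power law, so the optimum sits at infinite
  cutoff); such levels are excluded with a warning. The MLE is kept
  because it is exact on data actually drawn from the stated density
  (verified by parameter recovery in the tests).

γ is the through-origin least-squares slope of ξ̂ on (1−θ̃). On our
ensembles the moment-based γ̂ is of order 20–70 depending on the
saturation range and trapping rule — the same order as, but below, the
literature value 100; the fit diagnostics (R² near or below zero)
honestly reflect that ξ̂(θ̃) on these simulations is not proportional
to (1−θ̃). See the repository's acceptance discussion.

**Two-phase reactive transport** (`porehr.pore_rt`). Steady diffusion
(no advection) of O2, DOC and CO2 on the phase raster, finite-volume
5-point with harmonic-mean face transmissibilities. Henry partitioning
is imposed by working in an aqueous-equivalent potential per species,
continuous across interfaces, with effective air-side diffusivity
D_air·H (dimensionless H: O2 32, CO2 1.2 at 25 °C; DOC non-volatile).
Boundary conditions: fixed atmospheric O2 above the top row; all other
edges no-flux; DOC held at C0_DOC on water pixels with a solid
4-neighbour (organic-matter dissolution at the grain perimeter). Those
same perimeter pixels carry the Michaelis–Menten respiration sink
R_surf = Vm·Cs/(Cs+Km,s)·C/(C+Km,O2) with interface length h per solid
neighbour. Because the DOC Dirichlet sites coincide with the reaction
sites, the DOC factor is constant there and only O2 needs Picard
iteration (relative tolerance 1e-8; the diffusion stencil is assembled
once and only the linearized sink diagonal changes). CO2 is produced
1:1 with O2 consumed (unit respiratory quotient; the model does not
state otherwise). Verification: an analytic 1D slab solution (2%), the
global O2 balance (influx = consumption to well under 1%), and a
fixed-geometry refinement test (< 3% on doubling resolution).

The domain respiration R̃h = Σ (R_surf/Vm)·Δℓ over the solid–liquid
interface. The scaling experiment regresses log(R̃h/Nc) on log(Sc)
across drainage states and realizations; the slope is reported with a
bootstrap CI. At very low saturation (θ̃ ≈ 0.2) the remaining water
fragments into thousands of near-pixel patches; these states are part
of the stated protocol and are included.

## 2. Single-patch model (`porehr.patch_dre`)

A water patch is a sphere of radius r0 with surface-held oxygen
u(1) = 1 and symmetry u'(0) = 0:

    u'' + (2/χ) u' = β u/(u + α),
    α = Km,O2/C0,
    β = 3 Vm φ Cs r0² / (Dm λc C0 (Cs + Km,s)).

α measures microbial oxygen affinity against supply (aerobic range
0.01–0.5); β is a Thiele-modulus-like ratio of surface reaction
capacity to diffusive supply. Discretization: second-order finite
differences on 400 nodes, the center singularity closed by symmetry
(6(u₁−u₀)/h² = βu₀/(u₀+α)); damped Newton with a positivity-preserving
line search, convergence on the residual scaled to concentration units
(tolerance 1e-10); continuation in β above 100; quadratic mesh grading
toward χ=1 for β > 2000 (depletion-layer width ~ sqrt((1+α)/β)). When
depletion is expected (β > 6) the first-order analytic profile seeds
the iteration. Total patch respiration is reported as R̃ = 3u'(1)
(surface-flux form; the volume integral is computed too and must agree
to 0.1% — the divergence-theorem check). The printed closed forms for
the limiting regimes (zeroth-order parabola for α ≪ u, valid only for
β ≤ 6; the sinh profile for α ≫ u) are implemented with the removable
χ→0 singularity evaluated analytically; note both limits overestimate
consumption, so the numerical solution is validated against the
envelope they span (upper line β, lower line the α=10 profile), which
is how the full model is conventionally displayed.

## 3. Patch-count theory (`porehr.patch_theory`)

Nc(θ̃) = N0·(1/ξ)^(τ−1)·Γ(1−τ) − E_τ(1/ξ), with ξ = γ(1−θ̃),
N0 = (L/λc)^(d(1−θ̃)), and Sc = θ̃/Nc by mass conservation. The
incomplete-gamma pieces are evaluated by analytic continuation
(recurrence Γ(a,x) = (Γ(a+1,x) − x^a e^−x)/a until the argument is
positive, asymptotic expansion beyond x = 700), verified against an
independent multiprecision oracle to 1e-6. Two conventions deserve
note:

* The zeroth-moment integral ∫₀¹ n(s̃)ds̃ diverges at s̃→0 for τ > 1;
  its analytically continued value (exposed as `bracket_continuation`)
  is *negative* over most saturations and is therefore not usable as a
  patch count. The formula above — with N0 multiplying the first term
  only — is positive, O(1–10⁶), and decreasing in θ̃ over (0, ~0.9),
  and is what the package uses. A lower-cutoff quadrature diagnostic
  (`nc_integral_cutoff`) makes the regularization auditable.
* The formula does not tend to 1 at θ̃→1; the single-cluster limit is
  imposed as a convention (Nc(1) = 1 exactly; Nc clamped to ≥ 1
  elsewhere, flagged). Near-saturation (θ̃ ≳ 0.9) the formula rises
  spuriously — a known failure of the percolation ansatz away from the
  threshold, shared with the microfluidic-validation literature.

Defaults: τ = 187/91 and d = 2 at the pore scale; τ = 2.19 and d = 3
for field-scale upscaling; γ = 100.

## 4. Climate-to-cell upscaling (`porehr.environment`)

Per cell, from (T, θ̃, texture, altitude, DOC):
O2 partial pressure by the barometric law; dissolved O2 by Henry's law
with van 't Hoff temperature dependence (C0 ≈ 0.276 mol m⁻³ at sea
level, 25 °C; decreasing in T); Dm(T) by Stokes–Einstein T/μ(T) scaling
with the Vogel viscosity correlation (increasing in T); λc and φ from a
shipped texture table (clay 2 µm … sand 1 mm; editable CSV);
Vm(T) = Vm_ref·Q10^((T−25)/10) with Q10 = 2 and Vm = 0 at or below
0 °C (frozen). The upscaling itself: patch statistics at d = 3 in a
representative volume L² × depth (both 0.1 m); the water volume per
patch Sc·φ·V defines the sphere radius r0; (α, β) from the cell state;
per-patch oxygen flux Φ = 4π r0 Dm C0 u'(1); and

    HR = (Nc/L²) · Φ · 12.011 gC/mol · 3.156e7 s/yr   [gC m⁻² yr⁻¹].

No published closed form exists for this last step; the construction
above (spherical equivalent patch + divergence-theorem flux) is this
package's documented choice. `Vm_ref = 2.2e-9 mol m⁻² s⁻¹` is the one
calibrated constant: fixed once so the reference cell (15 °C, θ̃ = 0.5,
loam, sea level) emits 250 gC m⁻² yr⁻¹, the magnitude of reported
global-mean topsoil HR; it was not adjusted afterwards. Absolute HR
magnitudes therefore carry this single degree of freedom — shapes,
monotonicities and trends do not. With the areal-rate convention,
fine-clay textures reach HR ~ 1e4-plus; the magnitude-envelope test is
documented over the sand–silt texture box. The emergent moisture
response is bell-shaped with its optimum near θ̃ ≈ 0.65 at 25 °C:
reaction-limited (β ∝ r0² small) on the dry branch, oxygen-limited
(boundary-layer β ≫ 1) on the wet branch.

## 5. Gridded pipeline (`porehr.pipeline`, `porehr.synth_forcing`)

Monthly HR per cell; annual HR is the mean of monthly rates (already
per-year units). Zonal series use cos-latitude area weights over the
latitude bands tropical (0–23.5°), subtropical (23.5–40°), temperate
(40–65°), arctic (65–90°), both hemispheres; zones with no cells or a
zero baseline (fully frozen) are skipped. Trends: normalization by the
baseline-window mean, OLS slope in % yr⁻¹ with HC3 robust 95% CI (HC0
undercovers on 20–70-point series; measured 88% vs 92% coverage at the
nominal 95%), and the Mann–Kendall test (S = Σ sign pairs, tie-corrected
variance, continuity-corrected normal p; exact against pair enumeration
in tests). Monte-Carlo input-sensitivity draws one random day per month
per cell from a daily companion dataset and recomputes annual HR. DOC
scenarios scale the DOC field linearly in time (bounds +20%/−5% by the
end of the horizon); because soil DOC (default 4 mol m⁻³ ≈ 50 mg C/L)
far exceeds Km,s = 0.1 mol m⁻³, HR responds only a few percent — the
substrate factor is near saturation.

The synthetic forcing generator supplies the statistical skeleton the
pipeline needs — latitudinal mean gradients (equator 27 °C, pole drop
45 °C), hemisphere-phased seasonal cycles (amplitude 2→15 °C equator to
pole), stationary AR(1) monthly anomalies (T: sd 1.5 °C, ρ = 0.5;
saturation: sd 0.05), optional linear trends, a wet-tropics/dry-
subtropics moisture profile, and a daily companion whose within-month
means equal the monthly fields exactly. It does **not** emulate real
spatial covariance, orography, land masks or humidity–temperature
coupling; green pipeline tests therefore establish the statistical
machinery (weighting, normalization, CI coverage, MK exactness) and the
cell model's response — not fidelity to any reanalysis product.

## 6. Known limitations

* The pore-scale patch-size spectra of this drainage algorithm are
  shallower than the 2D Fisher power law, so the fixed-τ cutoff fit is
  fragile; the cutoff coefficient γ comes out of order tens, not 100.
* The near-saturation branch of the patch-count formula is a
  convention, not a prediction.
* Upscaling treats every patch as the characteristic sphere; the patch
  size *distribution* enters only through Nc and Sc.
* 2D pore-scale physics stands in for 3D; d = 3 enters only through
  the patch-count exponents.
* DOC is quasi-static; no autotrophic respiration; topsoil (0–10 cm)
  only; no land-use effects.
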
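# Methods

## The EO framework

An environment–organism (EO) model couples S species to F environmental
factors (chemical concentrations, arbitrary units consistent within a
model). Dynamics are

    dr/dt  = Σβ sβ fβ(r) + σ(r)          (environment)
    dsα/dt = sα gα(r)                     (species)

with per-capita impact functions fβ (concentration·time⁻¹·biomass⁻¹),
per-capita sensitivity functions gα (time⁻¹), and an allogenic term σ for
external forcing (zero in a closed model; a chemostat uses
σ(r) = d·(r_in − r) plus dilution −d on every species).

The instantaneous interaction a′αβ(r) = ∇gα(r)·fβ(r) (time⁻¹·biomass⁻¹)
measures the momentary effect of β's environmental impact on α's growth
rate; its per-factor terms are the elementary mechanisms (enrichment,
depletion, pollution, detoxification). For closed systems, integrating
a′αβ(r(τ))·sβ(τ) along the realized trajectory decomposes the growth-rate
change of every species exactly into per-effector cumulative interactions.
This identity is the package's core correctness oracle: `ceo_residual`
evaluates both sides along a stored trajectory and reports the largest
relative gap (≈1e-8 at the default tolerances; the acceptance suite
requires <1e-5).

Impact/sensitivity functions are assembled from a registry of parametric
forms (constant, linear, Monod, sums, products) that carry analytic
gradients and serialize to YAML/JSON, so models round-trip through config
files without code execution. Arbitrary callables are accepted in library
use; their gradients fall back to central finite differences with step
h = max(1e-6, 1e-6·|r_ρ|), one-sided at the r_ρ = 0 boundary so model
functions are never evaluated at negative concentrations.

## Built-in models and calibration

**Toxin–nutrient detoxifier.** One species A over (n, q):

    g_A = mu_max·n/(K_n+n) − delta_max·q/(K_q+q)
    f_A = ( −(mu_max/Y)·n/(K_n+n),  −d_max·q/(K_d+q) )

Nutrient uptake is tied to the growth term through the yield Y — toxin
death does not recycle nutrient. Detoxification is per-capita Monod
removal independent of growth state, as appropriate for secreted-enzyme
degradation that continues in non-growing cells. The toxin enters as an
additive death term rather than multiplicative growth inhibition so the
two elementary mechanisms contribute separably to the interaction.

Defaults (time in hours, concentrations in model units): mu_max = 0.8,
K_n = 0.5, delta_max = 0.45, K_q = 0.3, Y = 1, d_max = 0.8, K_d = 0.1.
These were calibrated once so that the model's qualitative signature holds
from the reference starting state (n0, q0) = (1, 0.4): the self-interaction
is positive there (detoxification dominating), the batch cumulative
interaction crosses zero exactly once, every condition of the synthetic
plate design (below) grows out of its toxin lag within the 120 h assay
window, and the growth-curve estimator's switch time tracks the true
cumulative switch time. The scientific claims carried by the model are
sign and ordering patterns, not the parameter values themselves.

**Degrader–crossfeeder.** Species D and C over polymer p and metabolite m:

    f_D = ( −u_p·p/(K_p+p),  phi·u_p·p/(K_p+p) − u_m·m/(K_m+m) )
    g_D = e_p·u_p·p/(K_p+p) + e_m·u_m·m/(K_m+m)
    f_C = ( 0,  −u_c·m/(K_c+m) )
    g_C = e_c·u_c·m/(K_c+m)

D's metabolite impact is a flux balance — net production while polymer is
abundant, net consumption once it runs out — so the production→consumption
switch emerges without an explicit switch function. phi ≤ 1 caps metabolite
yield stoichiometrically; with phi = 1 total p + m never increases in a
closed run. Defaults: u_p = 3, K_p = 0.5, phi = 1, u_m = 0.5, K_m = 0.5,
e_p = e_m = 0.3, u_c = 1, K_c = 0.5, e_c = 0.45. The degradation rate and
the crossfeeder's efficiency were chosen so that, in the flow-channel
setting, one channel transit converts a substantial fraction of the
polymer and the crossfeeder outcompetes the degrader in the
metabolite-rich downstream region — without this the channel shows no
spatial structure at realistic washout rates.

## Batch integration and cumulative interactions

`integrate` uses LSODA (stiff-capable, adaptive) at rtol 1e-8 / atol 1e-10
by default, with dense output on 2001 uniform samples. Concentrations and
abundances are clipped to zero inside the RHS and after sampling; a run in
which clipping removes more than 0.1% of any field's scale is rejected
(Monod fluxes vanish at zero, so genuine solutions only graze the
boundary — observed clipped fractions are ~1e-12).

Cumulative interactions integrate a′αβ(r(τ))·sβ(τ) with a cumulative
Simpson rule on the sample grid. Simpson rather than trapezoid matters
here: at 2001 samples the trapezoid bias (~1e-4 relative) would dominate
the decomposition residual that the tests use as an oracle. Open
(chemostat) trajectories are refused by default, because the decomposition
assumes σ = 0; `allow_open=True` accepts the approximation explicitly.

## Flowcell

Intermediates obey ∂r/∂t = D ∂²r/∂x² − vx ∂r/∂x + Σβ sβ(x) fβ(r(x)) with
Dirichlet inlet (injected media composition) and zero-diffusive-gradient,
advective outflow at x = L. Cells are sessile: at each location
dsα/dt = sα[gα(r(x))·(1 − Σγ sγ/λ) − θ], with washout mortality
θ = 0.005·vx and a shared occupancy cap λ (default 1; the cap scales the
abundance units). The cap multiplies growth only; mortality always acts.

Discretisation: first-order upwind advection, second-order central
diffusion in flux form (so the inert-tracer mass balance closes to
rounding, ~1e-17 per step), explicit Euler with
dt ≤ cfl / (vx/dx + 2D/dx²). The combined bound is required: satisfying
the advective and diffusive limits separately is not sufficient for the
summed operator. Defaults: L = 10, N = 200, D = 0.5, cfl = 0.8. D is
large enough to stabilize the low-order scheme yet keeps the Péclet number
L·vx/D ≫ 1 at the flow rates of interest (Pe = 100–400 for vx = 5–20).

Steadiness is declared when the per-field relative change rate falls below
`steady_tol` (default 1e-7) over a 5-time-unit window. Each field is
scaled by its own maximum, with an abundance floor of 1e-6·λ: a species
washed out below the floor no longer blocks the declaration, while a
species invading from microscopic abundance does. One caveat is inherent
to the biology: where the degrader/crossfeeder fitness gap crosses zero,
the exclusion front stalls only algebraically, so the Figure-style
scenarios declare quasi-steady at steady_tol = 1e-4 on an N = 100 (library
scenario default) or N = 60 (acceptance runs) grid. The media profile is
steady one to two orders tighter than that by declaration time, and the
reported quantities (niche coordinate, biomass ordering across flow rates)
are insensitive to the residual front creep at well below grid resolution.

The space–time correspondence metric normalizes each factor by its range
along the batch trajectory and reports the mean distance from every
profile point r(x) to the nearest trajectory point r(t). It is
one-directional by design: the steady channel may realize only the early
part of the batch path (flow refreshes the environment before exhaustion).
At Pe = 200 and θ → 0 the mismatch is ≈0.014; the acceptance bound is
0.05. At Pe < 1 the underlying assumption fails by construction and no
bound is claimed.

The niche-opening coordinate x* is the smallest x at which
g_target(inlet) + C_target←effector(x) exceeds θ, where C(x) is the
along-channel cumulative interaction with transit parameterization
dτ = dx/vx. It is a prediction from the interaction calculus alone; the
occupancy competition decides how much biomass actually accumulates
downstream of it.

## Plate estimator and synthetic experiments

The measured interaction compares matched subpopulations: the low-density
wells act as a monoculture-like reference of size equal to 1/R of the
high-density inoculum. After background correction
(κ = R/(R−1)·(⟨OD_h0⟩−⟨OD_l0⟩) from plate-wide class means of the first
three readings; each well zeroed by its own first-three mean and shifted
back by κ or κ/R), replicates are averaged per class and the curve
high/R − low is reported. The abundance *difference* is the default
statistic — it tracks the shape of the underlying cumulative interaction
and is robust to read noise; ratio and log-ratio variants are available
behind an option. Optional LOESS smoothing (span 0.2 of the time range)
never extrapolates and is kept separate from the raw curve.

The synthetic generator emulates the 96-well two-density design: a 4×4
grid of initial toxin × nutrient conditions (linear maps of a
0–30 µg/mL antibiotic range at 0.4/30 units per µg/mL and a 0.5–5 mM
nutrient range at 1 unit per mM), three replicates per class at OD-like
inocula 0.004/0.001 (R = 4), readings every 0.5 h for 120 h. Noise is a
per-well constant background (mean 0.09, SD 0.002) plus i.i.d. Gaussian
read noise (SD 0.003) — typical plate-reader magnitudes, all configurable.
The truth object stores the exact trajectories and cumulative series and
can re-emit plates with fresh noise cheaply, which is how the
noise-robustness checks run 200 replicate plates in seconds.

What the generator does **not** emulate: lag phases and physiological
adaptation, evolution of resistance, OD nonlinearity at high density,
evaporation and edge effects, well-to-well cross-contamination. Passing
tests therefore certify the estimator chain and its consistency with the
modeled dynamics, not robustness to every artifact of real plates.

Estimator consistency is asserted as: on noise-free synthetic plates, the
measured curve's positive→negative switch time matches the true cumulative
self-interaction switch time of the high-density culture within 5% of the
120 h assay (observed worst gap ≈4 h, in the slowest, lowest-nutrient /
highest-toxin corner where the estimator's finite-density lag is largest).

## Numerical and design notes

- Interaction decomposition closure (per-factor terms vs. total) is exact
  by construction; tests assert it to 1e-12 together with agreement
  against an independently computed ∇g·f.
- Analytic registry gradients agree with central differences to better
  than 1e-9 relative on random interior points.
- Zero-contour locations of interaction fields are left to the caller
  (plotting); fields report raw values.
- Problem sizes: acceptance-grade flowcell runs use N = 60–100 grid points
  and the batch runs 2001 samples; grid-refinement checks double N = 100
  to 200 at vx = 20 and see <0.1% change in the steady media profile.
- Chemostat mode exists for exploring open-system equilibria; no
  equilibrium-perturbation interaction estimation is implemented.

## Known limitations

- 1D geometry only; no biofilm mechanics, motility, or
  attachment/detachment beyond the washout term.
- The occupancy cap is a single shared ceiling; per-species or
  height-structured capacity is out of scope.
- The estimator assumes the two density classes share kinetics (no
  density-dependent physiology beyond the modeled feedback).
- Cumulative-interaction theory requires closed systems; the chemostat
  override integrates the same formula but the decomposition is then only
  approximate.
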
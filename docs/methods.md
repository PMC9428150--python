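# Methods

This note records the modeling choices behind `bonepkpd`: the equations it
integrates, where its constants come from, what the synthetic data do and
do not emulate, and the numerical decisions a user re-parameterizing the
model should know about.

## Pharmacokinetic layer

Alendronate disposition is modeled as a linear, time-invariant compartment
system between dose events. Amounts are in mg, time in days, serum in
ng/mL (mg/L × 1000), molar conversions use 249.1 g/mol (alendronic acid;
configurable). Five topologies share one state layout (gut, central CC,
non-calcified tissues NCT, bone BC, inactive bone IC, urine); constants a
topology does not use must simply be absent.

Oral doses enter the gut in full; only the bioavailable fraction F crosses
to plasma as the gut empties at k_CC, the remainder being implicit fecal
loss (no feces state). IV infusions enter CC at a constant rate over their
duration; the absorption term is replaced accordingly. Simultaneous events
merge by summing amounts.

The default solver is LSODA with rtol 1e-8 / atol 1e-10 mg, restarted at
every dose event so boluses are exact jumps rather than stiff spikes. An
exact piecewise matrix-exponential propagator (`method="expm"`) exists for
fitting loops, where thousands of forward solves are needed; the test
suite checks the adaptive solver against an *independently written*
matrix-exponential oracle, so the two paths never certify each other.

## Bone cell population model

Cell concentrations (pM) of pre-osteoblasts, active osteoblasts,
pre-osteoclasts and active osteoclasts evolve under differentiation,
proliferation and apoptosis fluxes gated by first-order Hill
activator/repressor functions; osteocytes track the matrix fraction
(dOt = η·df_bm, so Ot − η·f_bm is a first integral the integrator
preserves exactly). Signaling is quasi-steady-state:

- TGF-β ∝ matrix resorption rate (plus a basal term); it recruits
  osteoblast progenitors, holds pre-osteoblasts, and gates osteoclast
  apoptosis.
- RANKL balances production on pre-osteoblasts (disuse-promoted) plus the
  disease term against turnover and competitive capture by OPG (from
  active osteoblasts, PTH-repressed) and RANK (on pre-osteoclasts). PTH is
  constant in all scenarios, so its gates fold into one production
  constant, kept explicit (`pth0`, `K_pth_opg`) for structure.
- Sclerostin from the osteocyte network is disuse-promoted and suppresses
  Wnt, which drives pre-osteoblast proliferation. Because Ot/f_bm is
  conserved, sclerostin responds to loading, not to osteocyte number.
- Mechanotransduction is one factor pair about a strain-energy setpoint
  ψ_ref: catabolic = 2/(1 + (ψ/ψ_ref)^n) (applied to RANKL and sclerostin
  production), anabolic = 2 − catabolic. Both are 1 at the setpoint,
  bounded by [0, 2]; zero load gives the maximal catabolic factor. This
  single pair also stands in for the nitric-oxide branch of the loading
  response. Stiffness is a power law in matrix fraction and ash fraction
  (84370·(f_bm/100)^2.58·ᾱ^2.74 MPa), ψ = σ²/2E for a per-site uniaxial
  stress σ (defaults: 1 MPa at the f_bm = 15% site, 2 MPa at 25%); ψ_ref
  is evaluated at the baseline state, so the reference is homeostatic at
  each site by construction.

**Steady state and k_form.** The healthy baseline solves the four cell
equations with disease off and mechanical factors pinned to 1. The
formation rate constant defaults to the balancing value
k_form = k_res,nom·Oc_a/Ob_a at that state — formation and resorption
cancel at homeostasis by construction (a 10-year drug-free run moves f_bm
by < 0.1%). Supplying `k_form` explicitly overrides this.

**Disease.** Postmenopausal osteoporosis is a sigmoidal extra RANKL
production, P_max·Δt^γ/(Δt^γ + τ^γ), with onset at t = 0, half time τ and
steepness γ; treatment begins 19 years after onset. One symbol serves as
the half time (the source literature uses two symbols inconsistently for
the time constant and the exponent; here: `half_time`, `gamma`).

**Mineralization and density.** Matrix carries a tissue-age histogram of
(mass, ash) cohorts: new osteoid enters at the primary ash fraction
(0.45), every cohort relaxes exponentially toward the maximum (0.70) at
κ = 8e-4/day, resorption removes average composition, and cohorts are
merged at the old end past 200 bins (their ash has converged, so merging
is lossless in practice). Tissue density is affine in ash
(1.41 + 1.29·ᾱ g/cm³); apparent density is ρ = (f_bm/100)·ρ_tissue(ᾱ)
(marrow mass neglected — BDG is a ratio, so a constant offset would only
damp it uniformly). The histogram advances in daily substeps from the
dense ODE output with trapezoidal formed/resorbed increments, and the ODE
matrix fraction (and osteocytes, preserving the first integral) is
resynchronized to the histogram mass at each chunk boundary.

**Damage.** A first-order accumulation/repair ODE is carried in the state
but off by default; enabling it changes no interface. It is a stub: the
simulated scenarios do not exercise it.

## Parameter provenance and the unit bridge

The published coupled-model constants (the per-topology PK fits and the
six variant columns, including Π_act, Π_rep and the saturation constant f)
ship verbatim in `reference.py` as named inputs. The underlying cell-model
constants of the source lineage are not published alongside them, so
`data/bcpm_default.yaml` is this package's own set: Hill constants placed
so the gates sit mid-range at baseline, cell pools and rates at the
lineage's order of magnitude, and the handful of genuinely free scales
(k_res,nom, the disease amplitude P_RANKL_max, the TGF-β apoptosis gate)
calibrated once so that, with the published PK-PD1 constants, the coupled
model reproduces the reported clinical regime — ≈18% apparent-density loss
over the 19-year disease phase and ≈7%/≈4% two-year BDG at the
f_bm = 15%/25% sites. The file is versioned and every constant is
overridable.

One genuine unit gap remains: the printed Π constants (day/mM), combined
with the printed bioavailability, dose, and skeletal volume, give
drug-effect products orders of magnitude too small to move the cell model
for any turnover consistent with the fitted bone elimination rate. The
cell-concentration convention that closes this gap lives in the
unpublished part of the source model. `PDParams.effect_scale`
(dimensionless, default 1.25e3, i.e. the Π products effectively read the
drug concentration near µM scale) is that bridge, calibrated together with
the BCPM defaults; setting it to 1 recovers the raw printed units.

With the printed saturation constant the active-subcompartment cap binds
only marginally within a 2-year course (a single 70 mg weekly regimen
cannot raise [Ale_BC] to 0.077 mM); the saturation *mechanism* is
therefore exercised in tests with a deliberately tight cap, which is also
where its signature (late-time linear cumulative excretion under
variant 6) is sharpest.

## Coupling

The active/inactive split is algebraic in the total bone-compartment
content: g(f_bm) = (S_v/f_bm)·(f_bm0/S_v0), clamped to [0, 1], g ≡ 1 below
f_bm0 = 5% and 0 at f_bm = 100%. The quintic specific-surface polynomial
is kept exactly as printed, including its 0.2 mm²/mm³ residual at full
porosity — flagged, not corrected. Under saturation the active
concentration is capped at f·g and further inflow accrues to the inactive
part (the split being algebraic, the cap simply re-routes it). Release is
k_el,BC = k_res,eff·Oc_a with the *drug-reduced* k_res (the self-consistent
closed form and the release feedback use the same rate), and the BC→CC
return flux is k_el,BC·[Ale_act]·V_Bone/(f̄_bm/100), the local per-volume
release scaled to the skeleton through the average matrix fraction
f̄_bm = 43.7% — recomputed as the harmonic volume-weighted mean of cortical
(93%, 80% of tissue volume) and trabecular (14%, 20%) matrix fractions,
not hard-coded. Variant 6's total-BC cap gates the CC→BC inflow through a
narrow smooth ramp (2% of the cap) so the ODE right-hand side stays
integrable; the ramp width is far below every quantity reported.

Sites are addressed by their matrix fraction value (15 or 25), never by
anatomical name: the source material assigns the names to the two values
inconsistently between text and figures, and nothing in the model depends
on the name.

## Calibration machinery

Curve errors are mean-normalized RMSEs (coefficients of variation), so
curves in different units can be averaged: three terms (×100/3) for the
PK-only error, eight (×100/8) for the coupled error — four curve kinds ×
two sites, with BDG compared per site. Model curves are evaluated at the
data's time points from dense output.

The fitter is a real-coded GA — tournament selection (k = 3), SBX
crossover (η = 10), bounded polynomial mutation (rate 1/n, η = 20),
elitism, log₁₀-scaled bounds, fully seeded — with defaults of population
100 × 300 generations (the source reports no GA settings; these are
conventional for a bounded ~10-parameter global fit). Candidate failures
score a large penalty and are never raised. Two refinements follow, both
the package's own choices:

1. a Nelder–Mead polish of the best candidate in the scaled space, and
2. for PK fits, a bounded trust-region least-squares pass on the stacked
   normalized residuals, started from the GA's best candidate *and* from
   its images under the model's two near-symmetries — flip-flop kinetics
   (absorption rate ↔ total central exit rate, V_c rescaled, exit branch
   ratios preserved) and the label exchange of the two parallel peripheral
   compartments. Both symmetries are only approximate for these topologies
   (the slow return flows break them), so the basins differ in residual
   and the data select the right one; multi-starting merely guarantees the
   optimizer visits both. On noise-free synthetic curves this recovers
   every constant of the 3C-parallel model to machine precision across
   seeds; with multiplicative noise the recovery error grows, as the tests
   assert.

One-at-a-time sensitivity re-evaluates the full error breakdown at ±10%
of each fitted constant (two rows per constant plus a baseline, mirroring
the published table layout); a failing perturbed simulation is recorded
as a missing row with its reason.

## Synthetic data

The clinical curves the original model was fitted to (single-dose serum
and short-term urine, long-term urine after 4×7.5 mg 12-h IV infusions,
and 2-year BDG at two sites) are digitized from figures and not deposited,
so all closed-loop testing runs on synthetic curves. Grids mimic the
cited designs (13 serum points over 2 days, 7 short-urine points, 14
long-urine points to day 540, monthly BDG to day 730); noise is
mean-preserving multiplicative lognormal, per-curve σ, fully seeded
(byte-identical files for a fixed seed). The generator's PK truth is the
published 3C-parallel fit; the coupled truth is the PK-PD1 column plus the
default BCPM file.

What passing tests therefore show: the machinery — simulation, error
assembly, GA, sensitivity — closes the loop on data *from the model
family itself*. What they do not show: recovery from real digitized
curves, with their correlated digitization error, inter-study
heterogeneity and model misspecification; and the absolute BCPM constants
remain a calibrated stand-in for the unpublished set.

## Problem sizes and tolerances

Treatment simulations integrate the 13-dimensional coupled system with
LSODA (rtol 1e-7, atol 1e-12) between dose events (intervals capped at 30
days), daily histogram substeps, and a 19-year pre-phase in 30-day chunks;
a 2-year weekly course takes ~10 s on one CPU and a daily course ~45 s.
The recovery experiments use a reduced GA budget (population 40, 80
generations) that the refinement step makes sufficient. The variant-6
saturation check runs 6 treatment years so the slow tissue compartment
(τ ≈ 480 days) equilibrates before late-window slopes are compared.

## Known limitations

- Continuous remodeling: no discrete BMU events, so the two antiresorptive
  mechanisms (capacity loss vs apoptosis) are more interchangeable than
  they would be in an intermittent model.
- Systemic PK coupled to a single-site PD: the skeleton-average scaling of
  the return flux assumes the site tracks the skeleton.
- The default BCPM constants are calibrated, not measured; conclusions
  about absolute cell concentrations should not be drawn from them.
- No spatial resolution, no renal-impairment or food-effect absorption
  submodels, no other bisphosphonates' parameterizations.
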
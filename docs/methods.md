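# Methods

## Model

A receptor populates up to three conformational states S ∈ {BC, EC, EO}
(bent-closed, extended-closed, extended-open). Each state binds ligand with
intrinsic rates kon_S (1/(M·s)) and koff_S (1/s); the two closed states
share one intrinsic affinity, and the open state binds r-fold tighter
(affinity ratio r = Ka_EO/Ka_closed, Ka_S = kon_S/koff_S). Free states
exchange with first-order rates k(X→Y); ligand-bound states exchange as
well, with equilibria fixed by thermodynamic cycle closure:

    K'(X⇌Y) = K(X⇌Y) · Ka_Y / Ka_X.

Around the three-state cycle BC→EC→EO→BC the product of forward/reverse
rate ratios must be 1 (detailed balance); `build_scheme` either derives
exchange rates from target free-state populations (k(X→Y) = scale·f_Y,
which closes every cycle exactly) or validates user-supplied rates to
within 1e-6 on the log-cycle product.

**Fast-exchange assumption.** When conformational exchange is much faster
than binding and unbinding, the ensemble binds as a single effective 1:1
species with population-weighted apparent rates:

    kon_app  = Σ_S f_S · kon_S     (f_S: free fractions — binding flux
                                    leaves the unbound pool)
    koff_app = Σ_S g_S · koff_S    (g_S: saturably-bound fractions —
                                    release flux leaves the bound pool)

with g_S ∝ f_S·Ka_S renormalized over the states present. The simulator
validates this numerically: with exchange ≥ 50× all binding-related rates,
global 1:1 fits of full-scheme traces recover the weighted rates within 2%
(noiseless) and the complete fit→deconvolve pipeline recovers all six state
rates within 10% at 1% noise. With exchange ≤ 0.01× binding rates the
dissociation becomes visibly multi-exponential and the 1:1 fit residuals
exceed 5× the noise floor — the detectable failure mode.

## Fitting

**Global 1:1 fit** (`LangmuirGlobal`). The piecewise
association/dissociation curve (association to Req·(1−e^−kobs·t), then
pure exponential decay after the competitor-chase time t_D; rebinding
suppressed by competitor excess) is fitted to all analyte concentrations
jointly: kon_app and koff_app shared, one Rmax per trace. Rates are
optimized as log10 values (positivity without constraints, scale-free
steps) by trust-region least squares from a fixed 3×3 start grid
(kon ∈ {1e4, 1e5, 1e6} 1/(M·s) × koff ∈ {1e-4, 1e-2, 1} 1/s); the best
residual wins, ties by grid order, so the fit is deterministic. SEs come
from the Gauss–Newton covariance (JᵀJ)⁻¹·s² at the optimum, transformed
off the log scale by the delta method; 95% CI = estimate ± 2·SE. Fits are
unweighted by default; per-trace inverse-variance weights are accepted.
Coverage under 2% Gaussian noise is 91–96/100 seeded replicates for the
joint (kon, koff) ± 2·SE check.

**Equilibrium cross-check.** Req at each concentration is reconstructed
from the fitted parameters at t = 1000/(kon[A]) (a thousand binding
times), i.e. Req = Rmax·kon[A]/(koff+kon[A])·(1−e^−(koff+kon[A])t), and
the Req-vs-[A] points are fitted to a hyperbola with baseline fixed at 0;
the half-max concentration is the equilibrium K_d and should match
koff_app/kon_app (they agree within 2% on synthetic round trips). koff = 0
makes Req ≡ Rmax and the K_d degenerate; this is flagged, not fitted
around.

**Closure trap** (`TrapDissociation`). Dissociation traces at a titration
of closure-stabilizing Fab are fitted as single exponentials: flow mode
shares the initial amplitude MFI0 and the background across Fab
concentrations (all traces start from the same pre-equilibrated bound
level) with one koff_app per concentration; BLI mode fits (R0, koff_app)
per trace with zero background (reference-subtracted). koff_app vs [Fab]
is then fitted to a Hill-slope-1 dose–response with free baseline anchored
by the no-Fab point (the no-Fab ensemble off-rate is itself apparent, so
fixing it at 0 would be wrong; a baseline-fixed variant is exposed).
Plateau = koffmax, half-max = EC50.

Two saturation scales govern the titration: Fab capture of the bound
closed pool versus the plateau rate (half-max ≈ koff_C/(g_C·kon_Fab)) and
Fab capture versus reopening of the bound closed state (≈ reopen/kon_Fab,
up to ~50× larger at fast conversion). The default titration grids span
both scales; a titration that stops short of the second scale leaves the
plateau extrapolated rather than data-anchored and can over- or under-shoot
by a few percent. Known limitation: at very deep saturation the flow-mode
shared-amplitude fit acquires a small (~1%) upward bias in the individual
koff_app values from residual model mismatch; the per-trace estimator does
not, and is used for the bound-property checks. On simulator data the
fitted koffmax never exceeded the closed-state koff_C (worst ratio 0.9995
over a conversion sweep) and is within 5% of koff_C once the EO·L→C·L
conversion is ≥ 20× koff_C — operationally, koffmax is a lower limit on
koff_C, approaching it when conversion is not rate-limiting (the plateau
tends to the harmonic combination conv·koff_C/(conv+koff_C)).

**Deconvolution** (`deconvolve_state_rates`). The weighted sums are
inverted in the measurement order: EC rates from the extended (EC+EO)
ensemble given directly measured EO rates,

    kon_EC  = (kon_app(ext)  − f_EO·kon_EO) / f_EC
    koff_EC = (koff_app(ext) − g_EO·koff_EO) / g_EC,

then BC rates from the basal ensemble given EC and EO. Populations are
per-ensemble inputs (Fab stabilization redistributes states, so extended
fractions are not renormalized basal ones). The forward∘inverse map is the
identity to 1e-10 relative over 1000 random feasible parameter draws.
Negative deconvolved rates are returned with an `infeasible` flag rather
than clipped. koff = K_d·kon (relative errors in quadrature) provides the
equilibrium-route cross-check of each deconvolved off-rate.

**Error propagation.** First-order (delta-method) propagation with
central-difference gradients, treating inputs as independent. By default
only rate SEs propagate; population SDs and the affinity-ratio SD can be
included. A seeded Monte-Carlo propagation (default 10,000 draws)
cross-checks every delta-method SE and reports the worst relative
deviation. Caveat: for near-saturated bound fractions with a large
relative SD on r (e.g. r = 729 ± 211), the first-order SD underestimates
the Monte-Carlo spread substantially because the fraction is strongly
nonlinear in r over that range; the Monte-Carlo option is the honest
number there.

## Synthetic data generator

`synth_bundle` emulates the structure of deposited assay datasets: per
ensemble (basal / extended / open), association + competitor-chase traces
at three analyte concentrations; EDTA-background traces per concentration
(flow) or drifting reference-sensor traces (BLI); a closure-Fab titration
dissociation series; and a truth record of all generating parameters with
the implied apparent rates. Output is byte-identical for a fixed seed, and
noisy output requires an explicit seed.

Observation model: observable = Rmax · (total ligand-bound fraction,
including Fab-trapped bound species) + background + linear drift (BLI) +
i.i.d. Gaussian noise. Free ligand and Fab are held constant within each
protocol segment (pseudo-first-order: cells and sensor tips consume
negligible analyte); the competitor chase zeroes the labeled-ligand
association rate rather than adding an explicit competitor species.

Canonical parameter regimes (all rates in SI units):

- `alpha4_flow` (cell-surface regime): closed-state kon 4e5 1/(M·s) — the
  typical protein–protein range — with the open state 20-fold slower;
  closed koff 0.12 1/s (the cell-surface closure-trap plateau); affinity
  ratio r = 729, which together with detailed balance fixes
  koff_EO ≈ 8.2e-6 1/s (~4 orders slower). Basal free populations
  {BC 0.900, EC 0.093, EO 0.007} (BC-dominant basal cell-surface
  ensemble), extended {EC 0.70, EO 0.30}. Ligand at 5/10/20 nM, 600 s
  association + 600 s chase, Rmax 1000 MFI, background 120 MFI, noise sd
  10 MFI (1% of Rmax).
- `alpha5_bli` (soluble-ectodomain regime): closed kon 5e5, open 5-fold
  slower; closed koff 1.6 1/s (the ectodomain closure-trap plateau);
  r = 3106 ⇒ koff_EO ≈ 1.0e-4 1/s. EO-enriched basal populations
  {BC 0.40, EC 0.35, EO 0.25} (ectodomain truncation raises the open
  population), extended {EC 0.45, EO 0.55}. Analyte at 25/50/100 nM,
  300 s association + 600 s chase, Rmax 1 nm, sensor drift 2e-4 nm/s,
  noise sd 0.005 nm.

Conformational-exchange rates are not experimentally known; the defaults
place the ensembles firmly in the fast-exchange regime (scale 50 1/s and
400 1/s respectively) and are labeled as regime choices in the truth
record. The split of the bound-state exchange equilibrium into rates is
likewise undetermined; the default scales the opening (toward-EO) leg by
the affinity ratio and keeps the closing leg at its free-state value,
making the EO·L→C·L conversion rate an explicit, controllable quantity
(a symmetric `sqrt` split is available). Ensemble stabilization by Fabs is
modeled by restricting the state set, except for the closure-trap Fab,
which is explicit (pseudo-first-order binding to closed states; Fab-bound
closed states keep closed-state ligand kinetics and closed⇌closed
exchange but cannot reopen).

What the generator does **not** emulate — hence what passing tests do not
show about real data: ligand depletion and mass-transport limitation,
instrument artifacts beyond linear drift and Gaussian noise (no
autofluorescence drift, gating loss, sensor decay), heterogeneous receptor
glycoforms or aggregates, incomplete Fab saturation of the target states,
and force-dependent rate modulation.

## Numerics

Each protocol segment is a linear constant-coefficient ODE system; the
default propagator is the matrix exponential of the segment rate matrix on
the uniform sample grid (exact to machine precision; species conservation
holds to ~1e-14). A BDF stiff integrator at rtol 1e-10/atol 1e-14 is
available (`method="ode"`) and agrees with the analytic single-state curve
to ~7e-10 relative; it serves as the cross-check route in tests.
Degenerate inputs follow fixed conventions: kobs = 0 yields an all-zero
trace; a flat dose–response is flagged `degenerate` with NaN half-max; a
non-increasing trap titration is flagged `non_saturating`; reference-trace
extrapolation is refused. Dissociation-phase fits re-zero time at
competitor addition and ignore the pre-chase portion.

## Problem sizes

The test suite and the acceptance script use 200-point traces at three
(occasionally four) analyte concentrations, 100-replicate coverage runs,
1000 random draws for the deconvolution identity, and 9-point Fab
titrations over 4–5 conversion-rate regimes; the full suite runs in well
under a minute of simulation time plus fitting.
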
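# Methods

This note documents the models, numerical schemes and design choices behind
`debyesim`, in the spirit of a package methods appendix: what is computed,
under which assumptions, and where the numerical contracts come from.

## Dispersion model

The medium is linear, isotropic, homogeneous and non-magnetic, in the
quasi-static (electric-currents) regime: magnetic induction is neglected,
valid for centimetre-scale samples below tens of MHz.  Its dielectric
response is

ε*_r(ω) = σ_s/(jωε0) + ε_∞ + Σ_k Δε_k / (1 + (jωτ_k)^(1−λ_k)),

with ε0 = 8.8541878128e-12 F/m (CODATA 2018) shared package-wide.  λ_k = 0
gives the first-order Debye pole used everywhere downstream; λ_k ∈ (0, 1)
(Cole–Cole broadening) is supported for frequency-domain evaluation only,
because it has no finite-order time-domain ODE representation.  Frequencies
are accepted in Hz; ω = 2πf is formed internally.

Poles are stored sorted by τ descending.  Pole labelling is a gauge
freedom — any permutation describes the same medium — and a canonical order
makes models comparable and, during fitting, makes crossover meaningful
(see below).

Per pole, σ(ω) = −ωε0 Im ε*_r is non-decreasing and ε_r(ω) = Re ε*_r
non-increasing in ω; both properties are inherited by any positive sum of
poles and are asserted as property tests on log-spaced grids.  Conjugate
symmetry ε*(−ω) = conj ε*(ω) holds analytically for real parameters but the
public API accepts only f > 0, so there is no signed-frequency path to
test; it is not asserted.

## Terminal quantities and spectra

A plate-electrode sample of electrode area S and gap l maps bulk to
terminal quantities through the cell constant S/l:

Y(ω) = G + jB = (S/l)(σ(ω) + jωε0 ε_r(ω)),

inverted as σ = G·l/S and ε_r = B/(ωε0)·l/S.  These conversions are
frequency-local and exactly invertible; round-trip identity to 1e-12
relative is a test invariant.  Spectra are CSV with a header; a
`column_map` names the frequency column and any of (G, B), (Re Y, Im Y) or
(|Z|, impedance phase) layouts, so third-party deposits load without code
changes.  Replicated files are stacked on a leading replicate axis and
averaged before fitting.

## Genetic-algorithm fit

Parameters span many decades, so the genome is the log10 vector
(σ_s, ε_∞, {Δε_k, τ_k}) inside the boxes log10 Δε ∈ (−3, 8),
log10 τ ∈ (−12, 1), log10 σ_s ∈ (−4, 0), log10 ε_∞ ∈ [0, 8] (the ε_∞ upper
bound closes the box at the same magnitude ceiling as Δε).  The cost is the
log-space squared misfit of the complex permittivity summed over the
measured grid.  The imaginary parts of ε*_r are negative for a passive
medium, so their absolute values are compared — |Im ε*_r| = σ/(ωε0) is the
physically meaningful magnitude and the only way the logarithm is defined.

The optimiser is a generational GA: tournament selection (size 20, lowest
cost wins, earliest index on ties for determinism), uniform per-gene
crossover within a couple with probability 0.9, per-gene mutation with
probability 0.10, one-individual elitism, and a stagnation stop (no
improvement beyond 1e-12 for 200 generations).  Defaults: population 1000,
up to 2000 generations.  Elitism makes the best-cost history monotone,
which is asserted on every run; a fixed seed gives bit-identical results.

Two design choices were settled empirically on 4-pole synthetic-recovery
experiments and are worth recording:

* **Canonical pole order during evolution.**  Without it, uniform crossover
  between parents whose poles are stored in different orders mates Δε of a
  slow pole with τ of a fast one and scrambles otherwise good solutions.
  Genomes are therefore re-sorted by τ descending after initialisation and
  after every variation step.
* **Mixed mutation.**  Mutation replaces a gene either by a uniform redraw
  inside its bounds (probability ½, global exploration) or by a Gaussian
  perturbation whose standard deviation anneals geometrically from 0.3 to
  0.05 decades over the run (local refinement).  Redraw-only mutation
  locates the right basin but stalls around 1% cost; with the mixed
  operator five of six seeds reach the noise floor of a noisy 4-pole
  recovery problem, and `best_of_seeds` over three seeds is used where a
  single run's basin luck should not matter.

Pole count selection follows the usual nested-model logic via
`multi_start_fit`: cost decreases with N and plateaus once N reaches the
number of relaxation processes resolvable in the band; pick the smallest N
meeting the user's tolerance, since each extra pole costs ODEs in the time
domain.

Identifiability caveat: poles with nearby τ trade off against each other,
so parameter-space agreement is only meaningful for well-separated truths;
recovery on realistic noisy data is judged in function space (the σ(f) and
ε_r(f) curves), which is robust to that degeneracy.

## Time domain: the ADE system

Substituting one Debye pole into the quasi-static Ampère law and inverse
transforming yields, per pole, the auxiliary field e_k (a first-order
low-pass copy of E):

τ_k de_k/dt = E − e_k,  J_ek = (ε0Δε_k/τ_k)(E − e_k),

and the total current density
J = σ_s E + ε0ε_∞ dE/dt + Σ_k J_ek.  Initial fields are zero.

**Lumped solver.**  Under uniform-field conditions E = V(t)/l and
I = S·J.  The auxiliary ODEs are integrated with SciPy's BDF (the τ_k of
the tissue fixtures span 1.7e-7–3.8e-3 s, so the system is stiff), with an
analytic diagonal Jacobian, rtol 1e-10, and the source's max-step policy:
one hundredth of the period for sines; 0.1 µs inside pulse edges and 1 µs
elsewhere for trapezoidal bursts.  The solver restarts at waveform
breakpoints so derivative discontinuities are never stepped across.
Sources must provide an analytic dV/dt — the ε_∞ displacement term would
otherwise amplify differentiation noise — which is why custom sources
without a derivative are rejected.

**Amplitude/phase extraction.**  A least-squares fit of
a·cos(ωt) + b·sin(ωt) + c over the final period(s) of both current and
voltage; the constant term makes the fit immune to DC offsets, and the
reported phase is the current's lead over the voltage (positive for a
capacitive sample).

**Static comparator.**  `simulate_static_conductivity` is the
constant-conductivity null model, I = S σ_s V/l, with no displacement term:
at these bandwidths the vacuum-level displacement of a non-dispersive
comparator is negligible, and the contrast of interest — flat plateaus
versus the intra-pulse droop of a dispersive sample — is purely conductive.

## Axisymmetric finite elements

The cylinder is solved on its (r, z) half-section [0, R]×[0, h] with a
structured mesh of linear triangles (2·nr·nz elements) and the
axisymmetric measure 2πr.  Centroid quadrature is exact here: basis
gradients are element-wise constant and the weight r is linear, so the
assembled stiffness is exact, and homogeneous solutions (linear potential)
are reproduced at any resolution.  Boundaries: z = h terminal and z = 0
ground are Dirichlet; r = 0 (axis) and r = R (insulation) are natural.

Frequency domain solves ∇·(σ*∇V) = 0 with σ*(ω) = jωε0 ε*_r(ω), per
element, so layered media are a per-element array away.  The terminal
current is the sum of weak-form reaction forces over terminal nodes —
superconvergent and exactly conservative: terminal and ground currents
balance to machine precision because the stiffness matrix has zero row
sums.

Time domain steps the potential with backward Euler (the ε_∞ term
implicit) while each per-element auxiliary field (components e_r, e_z)
advances by the exact exponential solution of its relaxation ODE assuming
E varies **linearly** across the step: with α = exp(−Δt/τ) and
β = (τ/Δt)(1 − α),

E_new − e_new = α(E_prev − e_old) + β(E_new − E_prev).

The first-order hold matters.  Holding E constant at the new level instead
drives J_ek of any pole with τ ≪ Δt to zero — the fast poles' capacitive
contribution ε0Δε·dE/dt vanishes — which was measured as a 2.8° phase error
and ~5% sup-norm discrepancy against the lumped oracle at Δt = T/500.  With
the linear-in-E update the scheme recovers that limit exactly and lands
within 0.2% sup-norm of the lumped solver at the standard T/100 policy.
Eliminating e_k per element leaves one real sparse solve per step, with the
factorisation cached per distinct Δt.  The update is unconditionally
stable; accuracy is governed by the max-step policy.

## Synthetic measurements

The generator emulates the study conditions: a 40 Hz–10 MHz sweep at 20
points per decade (f_i = 40·10^(i/20) for f_i < 10 MHz, 108 points, plus
the 10 MHz endpoint: 109 points), ten replicate samples of the ⌀18.50 mm ×
5 mm cylinder, and multiplicative lognormal noise of unit mean applied
independently to every G and B sample with coefficient of variation 0.02 —
a scale-free noise model matched to log-space fitting and to the
few-percent replicate spread typical of plate-electrode tissue
measurements.  It does **not** emulate electrode polarisation, parasitic
lead inductance/capacitance (the overshoot real rigs show at pulse edges),
temperature drift, or frequency-correlated instrument error; passing
recovery tests therefore demonstrate correctness of the fitting and
simulation machinery under the stated noise model, not robustness to every
artefact of real spectroscopy.

## Numerical contracts exercised by the tests

* dispersion evaluation vs a term-by-term oracle: 1e-12 relative;
* terminal/bulk conversions: exact inverses to 1e-12; CSV round trip
  lossless (shortest-round-trip floats on write, round-trip parsing on read);
* lumped steady state vs frequency domain: 0.5% amplitude, 0.2° phase;
* FEM vs lumped, homogeneous: 0.2% (frequency), 0.5% sup-norm (time);
* FEM charge balance: 1e-10 relative (frequency domain);
* GA: monotone history, in-bounds genomes, bit-identical under a seed.

Problem sizes used in the test suite (8–16 divisions per mesh edge, five
simulated periods, GA populations of 60–1000) are chosen so the whole suite
runs in a couple of minutes while every contract above is still binding.

## Known limitations

* Cole–Cole (λ ≠ 0) models evaluate in the frequency domain but cannot be
  fitted or simulated in time; the multipole Debye surrogate is the
  supported route.
* Nonlinear electroporation dynamics (field-dependent conductivity) are out
  of scope; the model is linear time-invariant.
* The structured mesh handles the cylinder geometry only; no adaptive or
  unstructured meshing, and the full 3-component Cartesian ODE block is
  exercised only in its 2-component axisymmetric restriction.
* Phase extraction at low frequency is sensitive to the length of the
  settling transient relative to the window; with five periods and a
  one-period window the residual transient of the slowest tissue pole
  (τ ≈ 3.8 ms) biases 1 kHz phases at the 0.1° level, which is why
  cross-domain phase agreement is stated as a bound rather than a point
  value.
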
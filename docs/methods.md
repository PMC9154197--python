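# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `pingctc`, in the order the pipeline runs.

## Mean-field model

The core object is the exact firing-rate reduction of two all-to-all
coupled QIF populations with Lorentzian-distributed bias currents
(half-width Δ, center η).  State order throughout is
`(r_e, V_e, S_ee, S_ei, r_i, V_i, S_ie, S_ii)`.  Units: time in ms, rates
in spikes/ms, voltages dimensionless; with the default membrane constant
τ = 8 ms the reference oscillator has period T* ≈ 24.23 ms, and the mean
per-cell rate R_e ≈ 1/T* (about one spike per cell per gamma cycle), which
fixes the rate unit unambiguously.

Default parameters (the reference set used everywhere unless overridden):
τ_e = τ_i = 8 ms, Δ_e = Δ_i = 1, η_e = η_i = −5, τ_se = 1 ms (AMPA-like),
τ_si = 5 ms (GABA_A-like), J_ee = J_ii = 0, J_ei = J_ie = 13, tonic drives
Ī_e = 10, Ī_i = 0.  The second reference point Ī_e = 8.4 sits close to the
Hopf curve (located at Ī_e ≈ 8.13 by eigenvalue bisection) and oscillates
at ≈ 32.8 Hz with broad, low volleys.

**Forcing convention.**  The external current is Ī + τ·g(t), so g(t) adds
directly to dV/dt after the division by τ.  This makes the phase equation
below exact as written, with no stray τ factors.  The von Mises drive
p(t) = exp(κ cos(2π(t−μ)/T))/I₀(κ) has period-average exactly 1 for every
κ; it is evaluated in log-space with the scaled Bessel function `i0e`, so
coherences up to κ = 200 and beyond never overflow.  The κ → ∞ limit (a
delta-pulse train carrying the same mean drive) is kept symbolic and only
used by closed-form map expressions.

**Integration.**  All 8-D integrations use scipy's explicit RK45 with
rtol = 1e-10, atol = 1e-12 by default (sweep-internal relaxations use
1e-9/1e-11).  Tightening to 1e-12 moves the measured period by < 1e-4 ms.
The time span is split at square-pulse edges so the discontinuity never
meets the error estimator.

**Limit cycles.**  V_e maxima are located by event detection on dV_e/dt;
because V_e carries a lower secondary maximum within each cycle, events are
filtered to within 25% of the full V_e swing of the global maximum.  A
transient of 50 putative periods is discarded; an oscillation is declared
when the V_e peak-to-trough over the last five periods exceeds 1e-4
(robust near the Hopf point, where amplitudes are small), otherwise a
typed "no cycle" result (None) is returned so parameter sweeps stay
scan-friendly.  Period and anchor point are then polished by a Newton
shooting step with the section condition dV_e/dt = 0 at phase 0 (the V_e
maximum — the phase origin of every downstream quantity).  The orbit is
stored as 1024 uniform samples plus periodic cubic splines; Floquet
multipliers come from the monodromy matrix of the variational equations
with the analytic Jacobian.

**Equilibria.**  At an equilibrium the synapses and voltages eliminate
analytically, leaving two equations in (r_e, r_i); roots are found from a
5×5 seed grid and classified by the eigenvalues of the full 8-D Jacobian.
Hopf points along a one-parameter sweep are located by bisection on the
real part of the leading complex pair to 1e-6 in the parameter; normal-form
coefficients (super/sub-critical classification) are out of scope.

## Phase reduction

The iPRC is the T*-periodic solution of the adjoint equation
Ż = −DF(γ(t))ᵀZ with normalisation Z·γ̇ = 1.  It is computed by backward
integration: backward in time the periodic solution is attracting (the
contracting Floquet modes contract again), so the solution is integrated
period by period (at rtol 1e-11) until successive periods differ by less
than 1e-8 — typically well under the 80-period cap given multipliers of
order 0.07 — then rescaled to satisfy the normalisation at phase 0.  The
residual max|Z·γ̇ − 1| over all 1024 grid phases is stored and is < 1e-6
in the tested regimes.  The defining property is verified independently:
explicit ε = 1e-4 voltage kicks reproduce Z_Ve to within 2% of its
amplitude.

The phase equation is θ̇ = 1 + g(t)(Z_Ve(θ) + Z_Vi(θ)) (E-only forcing
uses Z_Ve alone).  Inside scans it is integrated by a fixed-step RK4 on
jit-compiled kernels — 1500 steps per forcing period, 6000 when κ > 30 to
resolve sharp volleys — with the iPRC evaluated through periodic
cubic-spline coefficients; the scheme was cross-checked against RK45 at
tolerance 1e-10.  Derivatives of the iPRC (needed by the variational
equation of the stroboscopic map) are spectral: FFT differentiation of the
periodic samples.

## Locking analysis

The stroboscopic map P advances the phase by one forcing period T; its
lift is accumulated from the continuous monotone solution, never
reconstructed from wrapped values.  Rotation numbers use a weighted
Birkhoff average of the lift increments (exponential bump weights
exp(−1/(x(1−x)))) over N = 750 iterates, which reaches ~1e-6 accuracy —
far beyond the O(1/N) plain average — and is exact to machine precision at
A = 0.  Normalisation: ρ̂ is in units of T* per forcing period, so p:q
plateaus read p/q.  A plateau is the maximal contiguous set with
|ρ̂ − p/q| < 1e-4; its edges are refined by bisection between grid points
(the rotation number leaves a saddle-node plateau like a square root, so
the 1e-4 threshold displaces the measured edge negligibly).

Arnold-tongue boundaries solve the saddle-node system
{P^q(θ) = θ + pT*, ∂P^q/∂θ = 1} by pseudo-arclength continuation in the
scaled variables (θ/T*, T/T*, A): SVD tangent, bordered (minimum-norm)
Newton corrector to ‖G‖ < 1e-9, steps 2e-3 adaptive up to 1e-2 with
halving on failure, stopping at the A-range ends (the tip at A = 0 is a
degenerate limit of both curves and is approached, not solved).  Seeds
come from one coarse staircase scan at A = 0.02.  ∂P^q/∂θ is integrated
from the variational equation with the FFT-differentiated iPRC.  In the
pulsatile limit the boundaries are the closed-form lines
T*/T = (q/p)(1 + A·Z_max) and (q/p)(1 + A·Z_min); they agree with the
κ = 200 continuation to within 5% in T/T* for A ≤ 0.1.

**Full-model locked orbits.**  A p:q locked state of the forced 8-D system
is a qT-periodic orbit, found by Newton shooting on x − Φ_qT(x) with the
monodromy matrix from the variational equations (looser tolerance 1e-8 —
it only steers Newton; the residual itself is measured at 1e-10).  Because
the volleys are sharp, Newton's basin is narrow: the guess is first
relaxed *along the attracting orbit* by forward integration over whole
forcing periods (60 cold from the phase-reduction phase, 5 on warm starts
in sweeps) before the Newton loop; convergence is declared at residual
1e-9 and stability at max |Floquet multiplier| < 1 + 1e-6.  Locking
intervals are swept outward from a ratio inside the plateau in steps of
0.004 in T/T* with warm starts, and each edge is refined by bisection to
0.001 — well inside the 0.01 comparison tolerance used in the tests.

## CTC factors

On a locked qT-periodic orbit (1024 samples), volley peaks are located
with sub-sample quadratic interpolation; minor wiggles below 20% of the
rate range are not volleys.  Δτ = (t_inh − t_p)/T wrapped to [0, 1), with
t_p the input peak preceding the I-volley (per volley in 2:1 orbits, where
both Δτ₁, Δτ₂ and per-volley Δα are reported; the tallest volley defines
the headline value).  Δᾱ is the ratio of period-averaged E-rates
(forced/unforced), Δα the ratio of refined peak heights (the reference
peak is refined identically, so A = 0 gives exactly 1), and Δσ the ratio
of half-widths at the (max+min)/2 level, each normalised by its own
period; the crossings used are the ones flanking the tallest peak.
Tongue-section sweeps sample 10 points per amplitude, inset 5% of the
plateau width from each edge, and record unlocked points as missing rather
than interpolating.

## Competition and switching

With two inputs the distractor peak is placed midway between consecutive
peaks of the faster input (μ₂ = T₁/2 if T₂ ≥ T₁, else T₂/2; antiphase at
equal periods).  Equal-period competition keeps a T-periodic system and is
judged by the rotation number (locked iff |ρ̂ − 1| < 1e-4); unequal
periods use the time-T₁ map of the continuously integrated phase equation
and the vector strength r of the angles 2πθ/T*, locked iff r > 0.8.
Robustness scans discard a 100-iterate burn-in before computing r; the
three reference synchronisation-index runs use the first 1000 recorded
phases from θ₀ = 0 with no burn-in, matching how those indices are
defined.  The reported index is transient-sensitive at the percent level
(the converging case yields r ≈ 0.98), which is why comparisons carry a
±0.02 band.

Pulse switching starts from the stable orbit entrained by two identical
antiphase streams (κ = 2, T = 0.84 T*, A = 0.1).  The "primary" is the
input whose volley most closely precedes the E-volley, and pulse phases
t/T are measured within the primary's cycle — without this convention the
switching window lands half a cycle off.  A square pulse (amplitude 1.5,
duration 2 ms, E-cells only) is applied at each phase; the PRC is
(T₀ − T₁)/T₀ with T₁ the E-volley interval containing the pulse (positive
= advance), and the attended stream is read from the sign of
d = (t_e − t_p1) − (t_e − t_p2) (preceding peaks), measured one cycle
before the pulse and again after 30 base periods of relaxation; a sign
flip marks a switch.  At the defaults the switching phases form one
contiguous window ≈ [0.40, 0.85] and |PRC| ≈ 0 where the pulse lands on
the I-volley.

## QIF network simulator

The microscopic ground truth is an Euler simulation (default Δt = 1e-4 ms)
of N_e + N_i QIF neurons, threshold/reset ±500, refractory hold of
T_ref = 2τ/V_th = 0.032 ms after each crossing (Euler overshoot at
threshold is accepted — no interpolation).  All neurons of a population
share the common input; synapses are population-level variables driven by
delta rates: a spike at step k increments S_ab by J_ab/(N_b τ_sb) at step
k+1.  Bias currents come from the Lorentzian either as symmetric
deterministic quantiles η_j = η + Δ tan(π/2·(2j−n−1)/(n+1)) (noise-free,
the test default) or by seeded inverse-CDF draws; seeded runs are
byte-for-byte reproducible.

What the simulator emulates: the infinite-N population dynamics whose
averages the mean-field describes exactly, including step-drive and
forcing-onset protocols.  What it does not: sparse or structured
connectivity, conduction delays, conductance synapses, intrinsic noise
beyond quenched heterogeneity — so agreement here validates the reduction,
not the biological realism of the network.  At N = 5000 + 5000 the binned
E-rate (window 0.08 ms) tracks the mean-field trace with RMSE ≈ 4% of the
peak rate on the forced segment, and the error decreases monotonically
over N ∈ {500, 2000, 5000}.

## Problem sizes and determinism

The test suite and the acceptance script use: 1024-sample cycles and
iPRCs; staircase grids of step 0.002 in T/T* (plateau edges then bisected
to 5e-5); rotation numbers with 750 iterates; 1000 iterates for
synchronisation indices; full-model edge sweeps at 0.004/0.001 resolution;
a 4-amplitude × 10-point tongue-section sweep for the communication-factor
bound; N = 5000 + 5000 neurons at Δt = 1e-4 ms for the spiking validation;
a 20-point phase grid for the switching window.  Every reported quantity
is deterministic given the configuration; the only randomness in the
package (Lorentzian draws, raster subsampling) is seeded.

## Known limitations

* Weak-coupling regime: phase-reduction predictions are trusted for
  A ≲ 0.1–0.2; the full-model shooting is the arbiter beyond that.
* The sweep logic tracks one attractor; bistable regions of the forced
  system (and basins of the unforced bistable strip near oscillation
  onset, Ī_e ≈ 8) are not mapped.
* Tongues with |p| or |q| > 2 are reachable through the same API but have
  no dedicated seeds or tests.
* Fold-of-limit-cycle continuation, codimension-2 points and
  information-theoretic communication measures are out of scope.
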
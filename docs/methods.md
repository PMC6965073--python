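# Methods

## The model

`mtp06` implements the mid-myocardial (M-cell) version of the ten
Tusscher–Panfilov 2006 (TP06) human ventricular myocyte model: 19 first-order
ODEs for the membrane potential V_m, twelve Hodgkin–Huxley-type gating
variables, the fraction R̄ of closed sarcoplasmic-reticulum (SR) release
channels, and the ion concentrations Na_i, K_i, Ca_i (bulk), Ca_ss (dyadic
subspace) and Ca_SR. The sarcolemmal currents are I_Na, I_CaL, I_Kr, I_Ks,
I_to, I_K1, I_NCX, I_NaK, I_pCa, I_pK, I_bNa and I_bCa;

  dV_m/dt = I_stim − ΣI,

with the 1-ms, 60 pA/pF stimulus entering depolarizing-positive (and its
charge booked in the K_i balance, as in the original model). Units are ms,
mV, mM, pA/pF. External concentrations are fixed (K_o 5.4, Na_o 140,
Ca_o 2.0 mM). The M cell uses g_Ks = 0.098 nS/pF, g_to = 0.294 nS/pF with
the epicardial s-gate kinetics; all remaining constants are the published
TP06 values (`constants.py`).

The model algebra exists exactly once, in a jitted kernel (`_kernel._eval`);
the public RHS, the current accessor, the time stepper, and every reduced
(slow-fast, voltage-clamped) system are views on that kernel through a
frozen-state mask. This guarantees, by construction, that a "fast subsystem"
is the full system with slow variables held constant — the property the
decomposition analyses rely on (and which a test asserts directly).

### Long-QT variants

Two modified parameterizations reproduce LQT-related afterdepolarization
phenomenology; both are multiplicative scalings of the original constants:

| variant | scalings (relative to original TP06) |
|---|---|
| `mTP06a` | g_Ks ×0.4, g_Kr ×1.5, P_up ×0.6 |
| `mTP06b` | mTP06a plus τ_fL ×0.5 and g_CaL ×2.0 |

The τ_fL halving is applied to **both** voltage-dependent I_CaL inactivation
gates (f and f2); per-gate override fields exist because the alternative
(f only) is a live convention in the literature. The both-gates choice was
fixed by reproducing the known critical g_Kr for EAD onset in the paced
mTP06b cell at 0.2 Hz (0.775 here vs 0.772 reference; the f-only variant
gives 0.745 and was rejected).

All scaling factors exposed by analysis functions are *normalized*: ratios
to the active variant's control values. `build_parameters("mTP06b",
{"scale_gKr": 0.721})` therefore means 0.721 × (1.5 × original g_Kr).

## Numerics

**Integration.** The workhorse is a fixed-step hybrid Rush–Larsen scheme
(gates advanced exactly on their linear relaxation equations, V_m and
concentrations by forward Euler) at dt = 0.01 ms, the field-standard
approach for this model family. An adaptive LSODA path (rtol 1e-8,
per-variable atol) serves as reference: over a paced beat the two agree to
< 1 mV outside the upstroke, and halving dt changes a converged APD₉₀ by
< 0.05 ms. Step-size studies of the marginal pause-induced-EAD protocol
were run down to dt = 0.005 ms; results quoted as dt-converged are stable
across 0.02/0.01/0.005. Unit tests run at dt = 0.02 ms where the checked
property is step-robust.

**AP features.** APD₉₀ is measured from the dV/dt-maximum of the
stimulus-evoked upstroke to 90 % repolarization of the amplitude
(peak − preceding phase-4 minimum, per beat). The AP peak is the maximum
within 50 ms of stimulus onset; V_max (the phase-2 dome) is the maximum in
[peak+25 ms, peak+200 ms].

**EAD detection.** EADs are plateau V_m oscillations at least 200 ms after
the AP peak and before repolarization below −75 mV; local extrema are found
with a prominence floor of 1 mV (suppresses integrator ripple; the
phenomena of interest are ~5–30 mV). Both thresholds are configurable;
detected counts are insensitive to halving the output step.

**Behavior classes.** `no_EAD`; `fR` (EAD-bearing APs that are genuinely
short: APD₉₀ ≤ 5 s *and* repolarized to rest before the next stimulus —
an AP terminated only by the next stimulus is repolarization failure);
`RF` (repolarization failure; at the boundary the discrimination follows
the extra-stimulus protocol: one stimulus after the last test stimulus,
and failure to return below −75 mV within 5 s means RF); and
`local_response` (arrest at the depolarized stable equilibrium:
inter-stimulus V_m never below −40 mV and, outside a 500-ms post-stimulus
settling window, confined to a 2-mV band — a quiet level, as opposed to
the oscillating RF state). The overshoot-based local-response criterion
sometimes used elsewhere is unusable with a 60 pA/pF stimulus, whose
deflection from a depolarized baseline always exceeds 0 mV; the quiet-band
form captures the intended distinction (convergence to the stable
equilibrium) directly.

**Convergence criterion.** Paced runs stop when the beat-to-beat relative
changes of V_min, V_max and APD₉₀ all fall below 1e-3 (hard cap
30 simulated minutes). Steady states "for a first parameter set" are taken
after 30 min of pacing; every subsequent parameter value is warm-started
from its predecessor's final state. This continuation convention matters:
scan results are direction-dependent near bistable regions, so critical-
point bisection inherits state from the bracket-start side (the scan
direction), and the phase-diagram sweeper records its traversal order and
can flag hysteresis by scanning both ways.

**Initial conditions.** The packaged default initial state is the original
model's published 1-Hz state; `default_initial_state` relaxes it for 120 s
without stimulation, which is the operational "steady state at resting
V_m". Exact resting concentrations are not printed in the sources for the
modified variants, so relaxation defines them reproducibly.

## Bifurcation machinery

Autonomous analyses fix K_i at 140 mM (removing the conservation
degeneracy); Na_i stays free unless a protocol fixes it at 6 mM
(slow-fast and voltage-clamp analyses).

**Equilibria.** A ladder of V_m seeds (−90…+20 mV, gates at steady state,
remaining variables relaxed under a V_m clamp) feeds a Newton solve
(`scipy.optimize.root`, hybr). Conditioning is essential: gate equations
are posed in fixed-point form (y − y_inf = 0) and balances are scaled by
characteristic rates; without this the 1/τ spread (~10⁸) stalls the
solver. Because Na_i equilibrates far more slowly than everything else, a
fallback solves the Na_i-fixed fast equilibrium inside a secant iteration
on the Na_i balance. Accepted equilibria have scaled residual < 1e-10 and
are classified by the eigenvalues of a central finite-difference Jacobian
(per-variable relative steps; the leading eigenvalue is stable to step
halving at ~1e-4 relative). Up to three equilibria (V_E1 < V_E2 < V_E3)
are tracked; "spiral" annotation means the leading eigenvalue (largest
real part) belongs to a complex pair — the convention used wherever
"spiral sink/source" is reported.

**Continuation.** Natural-parameter stepping with warm starts; Hopf points
refined by bisection on the sign of the leading pair's real part (axis
tolerance 1e-4 by default), saddle-nodes flagged at real-eigenvalue zero
crossings or branch folds. Pseudo-arclength continuation is deliberately
out of scope: the study's branches are scanned on fine grids and folds are
handled by bidirectional scanning.

**Limit cycles.** Single shooting with the period as unknown and a
Poincaré anchor (the state component of largest scaled time-derivative is
pinned). Floquet multipliers come from the variational equations
propagated along the shot orbit (midpoint-Magnus, Φ ← expm(J·h)·Φ with
h = 0.05 ms): finite-difference monodromy fails on relaxation-type Ca²⁺
cycles because the release timing responds nonlinearly to any finite
perturbation of the initial state. A converged orbit must carry its
trivial multiplier within 1e-3 of 1.
Period-doubling (multiplier through −1), Neimark–Sacker (complex pair
through |μ| = 1) and saddle-node-of-cycles (+1) are flagged along
continuations; "homoclinic" is a heuristic label for period blow-up beyond
20 s toward a saddle, matching the descriptive use in the source analyses.

**Spontaneous oscillations (SO).** Classified from a long unstimulated run
(default 300 s, last 60 s window): sustained V_m oscillation ≥ 1 mV → SO;
quiescence below −75 mV → rest; otherwise arrest at a depolarized stable
equilibrium. Two-parameter diagrams assemble Hopf loci (eigenvalue
bisection) and SO onset/offset loci (bisection on the long-run class,
started near V_E3).

## Slow-fast decompositions

*xs²-parameterized*: frozen {xs, Na_i = 6 mM, Ca_SR, K_i}; the I_Ks open
probability xs² is the axis (internally xs = √axis). Quasi-equilibrium
branches qV_E1–3 with stability and spiral character, Hopf refinement, and
the steady-state xs²(V) curve for overlays. The trapping report measures
dwell time of a full-system trajectory (computed with the same frozen
slow variables) within 2 mV of the stable qV_E3 segment; "trapped" means
dwell ≥ 100 ms (both configurable; conclusions are robust to 2× changes).

*Ca_SR-parameterized, voltage-clamped*: free variables {fCass, R̄, Ca_ss,
Ca_i} with V_m clamped and voltage gates at their clamped-V steady state;
Ca_SR is the axis. The Hopf value of Ca_SR is the release threshold: a
clamped full-system trajectory crossing it predicts spontaneous SR release.

## Voltage clamp

Pulse trains (default 1-s steps −85 → −10 mV at 0.5 Hz, 10 min) with Na_i
fixed at 6 mM and K_i at 140 mM. Spontaneous SR release events are Ca_SR
falls ≥ 5 % within 100 ms with a concurrent Ca_i rise; events starting
within 50 ms of a pulse onset are flagged pulse-triggered and excluded
from spontaneous counts. The clamped-subsystem bifurcation diagram vs V_m
keeps the voltage gates as (equilibrated) states rather than eliminating
them analytically — identical at equilibria and it preserves the
single-transcription invariant. Initial Ca_SR for fixed-V_m runs is the
holding-potential steady state (affects transients, not attractors).

## Problem sizes

Desk-scale defaults replace the sources' exhaustive 0.001-step scans:
coarse grids (e.g. 21×21 or smaller) with warm-started traversal and
bisection-refined boundaries reproduce critical values to the same
resolution at a small fraction of the cost. The test suite further
shortens pre-pacing (hundreds of beats) and SO windows where the asserted
property is insensitive to the cut; the acceptance script runs the full
30-minute pre-pacing protocol.

## What the simulations do and do not show

All inputs are generated by the package (protocols, grids, scaling sets);
there is no external data and no randomness anywhere — identical configs
give identical outputs. The synthetic signals used in unit tests
(idealized APs with injected plateau oscillations, Ca_SR traces with
injected drops) exercise the detectors against closed-form expectations;
they do not emulate channel noise, cell-to-cell variability, or
multicellular electrotonic loading, so passing tests validate the
deterministic single-cell pipeline, not tissue-level EAD behavior.

## Known divergences found during validation

- The stable limit-cycle strip of the clamped Ca²⁺ subsystem between its
  Hopf and Neimark–Sacker points is unresolvably thin at control P_up
  near H₁; the attracting Ca²⁺ oscillation just inside H₁ is already a
  slow, weakly modulated relaxation cycle (no closed period-1 orbit to
  shoot). Clean stable cycles exist at moderately raised P_up (e.g.
  ×1.41 at −35 mV), where shooting and simulation agree to 0.2%.
- The paced local-response onset does **not** coincide with the V_E3
  Hopf point here: the paced trajectory remains on the coexisting
  spontaneous-oscillation attractor well after V_E3 has been stabilized
  and is captured only once that attractor collapses (~0.3 lower in
  normalized g_Kr). The structural relations — local responses occur
  only on the stable-V_E3 side, the cell is arrested at the equilibrium
  there, and both boundaries shift in parallel with g_Ks — do hold.

## Known limitations

- The critical-value reproductions carry a ~0.5 % parameter-scale bias and
  a +2–3 ms APD₉₀ bias relative to the published reference values;
  marginal phenomena at the edge of the EAD region — most
  visibly the CL-3 s pause-induced EAD onset — can flip between "just
  inside" and "just outside" within that fidelity margin. The package
  reports what it computes.
- The published β-adrenergic-stimulation condition includes scalings
  beyond the printed g_CaL/g_Ks/P_up folds; `beta_as_scalings` accepts
  extras, but the packaged defaults cover only the printed values.
- Homoclinic points are heuristic labels, not continued orbits; no
  codimension-2 classification.
- Negative-conductance branch segments (e.g. g_Kr < 0) are mathematical
  continuations, not physiology; they are computed only when a scan
  explicitly requests them.
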
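# Methods

## Model

The transmission chain is a one-dimensional serial arrangement of six
rigid masses (impactor, load cell, impactor tip, femoral head, stem taper
replica, responding tissue), hanging vertically, with a single positive
coordinate per node along the impaction axis. Displacements are measured
from the static equilibrium configuration; every element force law is
evaluated at its *total* deformation (gravitational preload plus relative
displacement), so the reported PoM forces — deviations from preload —
start at exactly zero.

Element laws:

* **Spring–damper** (impactor–load cell, load cell–tip, stem–tissue,
  tissue–ground): `F = k·(c0 + Δu) + b·Δv`, compression positive.
* **One-sided hard stop** (tip–head): zero for an open gap; in contact the
  stiffness ramps linearly over the transition region δ,
  `F = min(x/δ, 1)·(k·x + b·Δv)`, clamped non-negative. The damping term
  shares the stiffness ramp so the contact force is continuous at onset
  (only the stiffness ramp is physically constrained; ramping the damping
  likewise is our choice, made for continuity).
* **Taper friction** (head–stem): transmitted axial force limited by the
  static cone `µs·N(d)` while sticking, `µk·N(d)` while sliding, with
  `N(d) = N0 + β·d²` driven by the insertion depth
  `d = max(0, d0 + u_head − u_stem)`. Insertion is treated as *reversible*
  (d can decrease during rebound; a fully separated junction, d = 0,
  transmits nothing). A ratcheting variant would be equally defensible;
  the reversible reading is the simpler mechanism and is used throughout.

Static initialization solves the chain bottom-up: each spring is
compressed by the weight it carries, the hard stop closes far enough to
carry the three masses above it (`k·x²/δ = W` inside the ramp), and the
initial insertion depth is the smallest d whose static friction capacity
holds the supported weight, `µs·(N0 + β·d0²) = W`; d0 ≈ 5.87 µm for the
reference chain. With gravity disabled all preloads vanish.

## Integration

The equations of motion are integrated with a fixed-substep semi-implicit
(symplectic) Euler scheme: 16 substeps per 800 kHz output sample
(dt = 78.125 ns), velocities updated before positions. At the friction
element each substep first computes the stick force that would cancel the
relative head–stem velocity by the end of the substep
(`F = v_rel_predicted / (dt·(1/m_head + 1/m_stem))`); if that force lies
inside the static cone it is applied (exact sticking, no creep), otherwise
kinetic sliding friction opposes the impending motion. This discrete
Karnopp variant is chatter-free and unconditionally consistent with the
friction cone.

We first implemented the integration with adaptive implicit stiff solvers
(LSODA, Radau, BDF with the output spacing as maximum step). LSODA and
Radau fail outright on the discontinuous friction law; BDF silently takes
bad steps across the stick–slip switch, injecting energy (head/stem
velocities of tens of m/s appear within the first output interval and the
tip–head contact opens permanently). The fixed-substep scheme has no such
failure mode: the stiffest mode of the chain (load-cell spring,
ω ≈ 2.1·10⁵ rad/s) satisfies ω·dt ≈ 0.016, the overdamped tip contact
satisfies b·dt/m ≈ 0.3, and halving or quartering the substep changes the
reference impactor peak by < 10⁻⁴ relative. The standalone
`taper_friction_force` API retains the classical velocity-threshold
Karnopp form (stick band v_eps = 10⁻⁴ m/s) for direct evaluation of the
friction law outside the integrator.

## Inputs and signal conditioning

The mallet is not a modeled mass; its measured or synthesized force pulse
acts directly on the impactor node. The canonical synthetic blow is a
half-sine with the measured blow statistics (peak 9247 N, first-peak width
0.140 ms); `extract_first_peak` isolates the first lobe of a recorded
waveform between 0.5 %-of-maximum threshold crossings and zero-pads it
(how the bench processing tapered the segment is not documented;
zero-padding is assumed). Random blows draw peak and width from normal
distributions truncated at zero.

Simulated PoM traces are passed through the same conditioning as the bench
recordings before features are extracted: 4th-order Butterworth low-pass
applied forward and backward (zero phase; the "4th-order zero-phase"
description is read as a 4th-order design applied twice, the common
laboratory convention), cutoffs 20/10/15 kHz for mallet/impactor/stem, and
normalization to the mallet peak. Features are the first and second
positive local maxima in time order (prominence threshold 1 % of the
global maximum to ignore ripple), their spacing (period), and the delay of
the first peak after the mallet peak. The windowed RMSE runs from the zero
crossing before the first to the zero crossing after the second peak of
the *measured* trace; when a trace rides an offset and never recrosses
zero after the second peak, the local minimum after it substitutes for the
missing crossing (the strict variant raises instead).

## Parameter estimation

Ten parameters are uncertain; Monte-Carlo screening (uniform sampling over
broad ranges, |Spearman| rank correlation of normalized peaks and windowed
RMSEs against the nominal run) ranks their influence. Rank correlation is
used because the response surfaces are strongly nonlinear; uniform
sampling because no prior distribution is available. Three weakly
influential parameters keep broadly estimated values (transition depth
50 µm, normal-force constant 5 N, tissue damping 10 % of the tissue spring
stiffness); the remaining seven are identified by minimizing the summed
squared error of both PoM traces over their RMSE windows across all
datasets. Optimization works on the logarithms of the (all-positive)
parameters and proceeds in two stages: a bounded trust-region
least-squares pass from the nominal values, then an adaptive Nelder–Mead
simplex descent. The two stages address a structural near-degeneracy:
scaling (µs, µk) down and β up by a common factor leaves the junction
force `µ·(N0 + β·d²)` unchanged except through the small constant term
µ·N0 (5 N against kilonewton-scale clamping forces), so the SSE has a
long, extremely ill-conditioned valley — straight in log coordinates —
whose floor gradient is below finite-difference noise (stick–slip switch
times are quantized to the integration substep). The gradient-based pass
lands in the valley quickly; the simplex, which elongates along the
valley and needs no derivatives, descends it. On noise-free
pseudo-measurements from three blows this recovers all seven free
parameters to ≈ 0.1 % relative; a pure bounded Nelder–Mead multi-start is
available as a fallback. Sampled or iterated points with
µ_kinetic > µ_static are regularized by clamping µ_kinetic.

The degeneracy sets a hard limit under sensor noise: with 2 % additive
noise (≈ 0.3 % of the mallet peak after the PoM filters) only the tiny
µ·N0 ≈ 2.5 N term separates the friction coefficients from β, and the
errors of the degenerate group (µs, µk, β, and especially the tip-contact
parameters) reach tens of percent regardless of optimizer effort or
dataset count — sharply identified parameters such as the impactor and
stem stiffness stay at or below a few percent. This is an identifiability
property of the model, not an estimator defect, and recovery results
under noise should be read accordingly.

Standard problem sizes used by the checks in this repository: recovery
experiments use three half-sine blows of different amplitude and width
(noise-free and 2 %-noise variants); the sensitivity screen defaults to
200 Monte-Carlo samples; the sweeps use their full 130- and 64-cell
grids.

Pseudo-measurements (the synthetic stand-in for the bench recordings)
simulate a chain with known parameters, add white Gaussian sensor noise
scaled to the mallet peak, and apply the per-PoM filters; the optional
outlier screen drops datasets whose impactor dominant frequency deviates
more than 25 % from the group median (the bench study excluded three
datasets for distinctly different oscillatory behavior without stating its
threshold).

## Sweeps

The impactor sweep covers 5 linearly spaced masses (0.1–2 kg) × 26
log-spaced stiffnesses (100 N/mm–10⁶ N/mm; the stiffness axis spans four
decades, hence logarithmic); the tissue sweep 8 × 8 log-spaced masses
(0.1–20 kg) and stiffnesses (0.1–50 N/mm) with the 10 % damping rule
applied per cell. Cells whose impactor trace shows no peak of ≥ 1 %
prominence within 0.8 ms are flagged, not dropped. Only ranges and counts
of the grids are prescribed by the bench study; the spacings are our
choice.

## What the synthetic data do and do not show

The half-sine pulse matches the measured blows' peak, duration and
single-lobe shape but not their asymmetry or superimposed mallet ringing;
pseudo-measurements inherit the model's own dynamics and hence cannot
expose structural model error. Accordingly, the impactor-side quantities
(peak attenuation ≈ 29 % of the mallet peak, ≈ 3.2–3.5 kHz ringing,
≈ 0.07 ms delay) reproduce the bench observations, while the simulated
stem-side response with the synthetic pulse overshoots the measured
attenuation (second stem peak ≈ 0.55 of the mallet peak versus 21.2 %
measured; delay 0.22 ms versus 0.46 ms): the stem PoM is the farthest
position from the input and accumulates every modeling simplification —
the hard-stop law variant, the reversible insertion reading, and the
idealized pulse shape. Passing tests on synthetic data therefore validate
the mechanics, conditioning and fitting machinery, not the stem-side
predictive accuracy against real recordings.

## Numerical choices and limitations

* Output grid: exactly `duration·sample_rate + 1` samples; default 641
  samples at 1.25 µs.
* Stick tolerance: the static cone test uses a 10⁻⁹ relative margin so the
  marginally preloaded initial state stays on the stick branch.
* Tip damping is taken as printed (240 Ns/mm ≈ 100× critical for the tip
  mass); the contact is therefore effectively a rigid viscous coupling
  while closed, and the contact stiffness is correspondingly hard to
  identify.
* One axis only: no off-axis blows, no misalignment, no taper-strength or
  pull-off prediction; the junction is purely an axial force-transmission
  element.
* The energy-accounting helper is exact only for the bilateral-contact
  diagnostic variant of the chain (the one-sided stop stores no tracked
  elastic energy).
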
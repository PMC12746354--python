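# Methods

## Signal model

A voxel of a PVP/water phantom is modeled as two magnetization pools:
an on-resonant water pool (T1, T2, ADC from the tube catalog) and one
off-resonant polymer pool at offset Δν representing the upfield PVP
proton band. Each pool is propagated independently through the AFI
pulse train by a 1-D extended phase graph (EPG) simulation, and the
acquired signals are combined coherently,

    S_i = S_i,res + w · S_i,off · exp(i(2π·Δν·TE + φ)),   i = 1, 2,

with the weight w and the TE-independent phase offset φ as free
parameters. Only a two-frequency model is implemented: the spectra
show two polymer bands (≈2.1 and ≈3.3 ppm), but one effective band
keeps the degrees of freedom identifiable; an n-component extension
would be a straightforward sum of further terms but is untested.

The flip angle is estimated from the combined steady-state signals by
the dual-TR relation α = arccos((r·n−1)/(n−r)) with r = |S2|/|S1| and
n = TR2/TR1. Arguments of the arccos outside [−1, 1] are a physical
failure mode of the estimator (the interference can push |S2| above
|S1|); such estimates are carried as NaN, first-class values that
statistics skip but report.

## EPG engine

State: complex amplitudes F(k), conj(F(−k)) and Z(k) over integer
dephasing orders k (one order = 2π across the voxel), stored as three
growing arrays with the conjugate hand-off at k = 0. Operators:

* **RF rotation** — one 3×3 complex matrix applied at every order.
  The matrix is the Cartesian hard-pulse rotation conjugated into the
  (F+, F−, Z) basis. Off resonance it is the matrix exponential of
  the rotating-frame Bloch generator for a rectangular pulse of
  duration τ: a rotation by √(ω1²+Δω²)·τ about an axis tilted out of
  the transverse plane by arctan(Δω/ω1). On resonance this reduces to
  the standard EPG rotation matrix. Relaxation and diffusion are
  suspended during the 0.5 ms pulse (τ ≪ T2 for all tubes).
* **Relaxation** — E2 on transverse orders, E1 on longitudinal ones,
  recovery of Z(0) toward m0.
* **Gradient shift** — integer order shift with the conjugate
  hand-off through k = 0. Amplitude shifted past the order cap
  (k_max, default 4096) is accumulated in a truncation-loss counter;
  the simulation aborts if the loss exceeds 1e−6 of m0.
* **Diffusion damping** — for a linear gradient ramp producing an
  order change Δk over an interval τ, a transverse state at signed
  order k is attenuated by exp(−ADC·κ²·(k²+kΔk+Δk²/3)·τ) with
  κ = 2π/voxel (the b-factor of a constant-gradient interval);
  longitudinal states by exp(−ADC·κ²·k²·τ).
* **Free precession** — F(k) gains exp(−i·2π·Δν·t) per the engine's
  internal phase convention.

Gradient moments are quantized to integer multiples of the 2π quantum
2π/(γ·voxel) — 11.74 mT·ms/m for the 2.0 mm voxel, matching the
11.75 mT·ms/m step of the acquisition protocol — using
γ/2π = 42.577478 MHz/T. Unquantized moments are rejected with the
nearest valid value named.

### Phase conventions

The internal engine convention is F+ ∝ e^{−i·2π·Δν·t}; the *recorded*
demodulated signal is reported in the receiver convention in which a
positive frequency offset advances phase by +2π·Δν·t, i.e. the
conjugate coherence. Entering the upfield polymer band with a
positive Δν then makes its pulse-to-echo phase advance by exactly the
+2π·Δν·TE term of the combination formula. This pairing is the unique
handedness choice among the four possible sign combinations that
reproduces both published grid minima (Φ0 = 60° at 3 T with
w/φ = 0.136/−0.18π, and Φ0 = 120° at 7 T, TE = 3.0 ms, with
0.078/−0.59π) together with asymmetries of the right sign and
magnitude; the mirrored choices shift the curve minima to the
opposite side of 90°.

To avoid double counting the pulse-to-echo phase, the off-component
signal is recorded immediately after the pulse and scaled by its
analytic T2 decay exp(−TE/T2,off); the explicit factor in the
combination formula then supplies the entire pulse-to-echo precession
phase, while phase accumulated across TR intervals remains in the EPG
state. The on-resonant component is recorded at the echo time.

## AFI sequence simulation

Each TR interval: pulse with its scheduled phase → relaxation and
precession to TE → record the demodulated signal → relaxation and
precession for the rest of the interval → diffusion damping and
gradient shift. The quadratic RF phase schedule Φ_j = Φ0·j(j+1)/2 is
evaluated in exact integer arithmetic for integer Φ0 so it cannot
drift over thousands of pulses.

**Spoiler timing.** The spoiler ramp is modeled as spanning the whole
TR, so the diffusion weighting is independent of where the echo sits
inside the interval. This keeps the single-pool steady state — and
hence the one-pool flip-angle estimate — exactly TE-invariant, which
is both the physical expectation for a single resonance and a useful
structural test. Concentrating the ramp into a shorter window would
change the cross-term diffusion weighting by a few percent at most at
these moments; the fitted w absorbs scale factors of that size.

**Pseudo-steady state.** RF-spoiled trains settle slowly, so the
simulation runs 200 TR pairs of settling (30 s of sequence time,
far beyond the 2 s of dummy scans of the acquisition protocol) and
then averages the demodulated complex signals over two consecutive
windows, each an integer number of RF-phase-cycle periods (the
smallest multiple of the pulse-pair period ≥ 32 pairs). The second
window is returned; the window-to-window change is the settle
residual and must stay below 1e−6 (relative), otherwise the
simulation raises with its settle report. For speed the state arrays
are pruned of trailing orders below 1e−14·m0; with the catalog's
relaxation and diffusion parameters the active window stays a few
hundred orders.

**Isochromat oracle.** A brute-force Bloch simulation over n equally
spaced isochromats across one voxel (spoiler phase 2π·Δk·x per spin,
identical pulse phases, relaxation and averaging) provides an
independent route to the same signals; with equal spacing the
discrete mean aliases only orders that are multiples of n, so
n = 2000 reproduces the voxel integral essentially exactly. The
oracle has no diffusion model — diffusion damping is
configuration-order physics with no per-isochromat analogue — so
EPG-vs-isochromat comparisons run with ADC = 0. Agreement is at the
1e−6 level, well inside the 1e−3 contract.

## Interference-parameter fitting

(w, φ) are fitted per curve by minimizing the RMS deviation between
measured and simulated flip angles over the mutually successful grid
points. Since the component signals do not depend on (w, φ), they are
simulated once per Φ0 and cached; the objective is then a closed-form
recombination. Optimization is a deterministic 21×24 grid over
w ∈ [0, 1] × φ ∈ (−π, π] followed by Nelder-Mead refinement from the
best three grid starts, with φ treated on the circle and w kept in
its physical box by a quadratic penalty. Simulator failures at
candidate parameters contribute a fixed 180° penalty per point rather
than aborting the fit. w is bounded to [0, 1] as a minority-component
weight. Fitting T1/T2 of the off pool or Δν is out of scope (held
fixed, matching how the published fits were run).

## Default parameters

| parameter | default | rationale |
|---|---|---|
| TR1/TR2 | 25/125 ms | acquisition protocol (n = 5) |
| TE | 1.9 ms | spoiling-curve protocol at 3 T |
| flip angle | 60° | nominal acquisition angle |
| pulse duration | 0.5 ms | rectangular non-selective pulse |
| voxel (spoil direction) | 2.0 mm | acquisition resolution |
| moment sets I–IV | 117.5/587.5 … 705/3525 mT·ms/m | the four acquired spoiler settings |
| Δν | 320 Hz (3 T), 747 Hz (7 T) | upfield PVP band scaled to field |
| T1,off / T2,off | 100 ms / 5.7 ms (≤25 wt% PVP); 70 ms / 1.6 ms (50 wt%) | inversion-recovery T1 of the polymer resonances and spectral T2* of the upfield band; not separately published for each tube, so configurable and always logged in outputs |
| Φ0 grid | 0–180° step 20° | acquisition grid |
| TE grid | 1.5–6.1 ms step 0.2 ms | acquisition grid |
| k_max | 4096 | far above the pruned active window; truncation monitored |

## Synthetic measurements

The generator emulates ROI statistics of flip-angle maps: for each
grid point the noiseless two-component (S1, S2) are computed, each of
n_voxels voxels receives independent complex Gaussian noise (sd as a
fraction of m0), magnitudes are formed — hence Rician voxel noise —
and the ROI statistic is taken over voxel-wise flip-angle estimates
(default) or over ROI-mean magnitudes (option). All randomness flows
from one explicit seed. Defaults: sd = 0.002·m0 (signal-to-noise of
roughly 50 on |S1|, typical for a 3-D acquisition at this voxel
size) and 100 voxels (a circular ROI of radius ≈11 mm in a 4 cm tube
at 2 mm resolution); the true values were not published, so both are
order-of-magnitude choices and remain configurable.

What the generator does *not* emulate: true intra-tube B1+ variation
(ROI standard deviations in real maps mix noise and field
inhomogeneity; here they are pure noise), spatial structure, partial
volume at tube walls, scanner drift, and any deviation of the real
PVP spectrum from a single effective off-resonant band. Tests passing
on synthetic data therefore validate the pipeline's self-consistency
and identifiability, not the fidelity of the two-frequency model to
any particular phantom.

## Numerical choices and degenerate inputs

* Angles are degrees and times ms in every public interface; SI
  internally.
* Flip-angle arguments within 1e−12 outside [−1, 1] are clipped
  (floating-point overshoot); genuine violations return NaN. A signal
  ratio exactly equal to n (zero denominator) raises.
* Curve minima are grid-restricted (no interpolation) with ties
  broken toward smaller Φ0; all published statements about minima are
  grid statements.
* The asymmetry Δα requires both 60° and 120° present and successful;
  otherwise it is NaN.
* CSV outputs carry an explicit `failed` column so NaN estimates
  survive round trips; sidecar JSON carries protocol, provenance,
  config hash and package version.

## Known limitations

* One effective off-resonant band; no chemical exchange, J-coupling,
  or lineshape structure of the polymer spectrum.
* Non-selective hard pulses only; no slice profile, no imaging
  gradients (their moments are an order of magnitude below the
  smallest spoiler).
* Isotropic diffusion with a single ADC shared by both pools.
* The isochromat oracle cannot check the diffusion operator (checked
  instead against its scalar closed form).
* Fitted (w, φ) absorb the unpublished off-pool relaxation times; w
  is not interpretable as a pure proton-density fraction.
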
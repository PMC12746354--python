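# afisim

EPG simulation and analysis of **actual flip angle imaging (AFI)** with
off-resonant signal interference in PVP/water phantoms.

## The problem

AFI is a dual-TR steady-state gradient-echo method for mapping the
transmit (B1+) field: two interleaved repetition times TR1 < TR2 with
identical RF pulses give signals S1, S2 from which the local flip
angle follows as

    α = arccos((r·n − 1) / (n − r)),    r = |S2|/|S1|,   n = TR2/TR1.

The accuracy of AFI depends on how well transverse coherence is
destroyed between pulses — by spoiler gradients and by a quadratic RF
phase schedule Φ_j = Φ_{j−1} + j·Φ0. In water, the flip-angle estimate
as a function of the phase increment Φ0 (the *spoiling curve*) is
symmetric about Φ0 = 90°. In polyvinylpyrrolidone (PVP)/water
phantoms — the standard tissue-mimicking filling for coil validation
and B1+ mapping — spoiling curves become strongly asymmetric and the
estimate depends on the echo time, errors that spoiling alone cannot
explain. The cause is interference between the water resonance and
off-resonant PVP proton bands: the polymer pool is barely saturated
(short T1) and adds a TE- and Φ0-dependent complex offset to both AFI
signals.

`afisim` implements the full simulation-and-analysis pipeline for this
effect:

* an **extended phase graph (EPG) engine** (`afisim.epg`) with RF
  rotation (including an off-resonant tilted-axis excitation matrix
  for hard pulses), relaxation, integer-order gradient dephasing, and
  isotropic diffusion damping of configuration states;
* a **dual-TR AFI sequence simulator** (`afisim.sequence`) iterated to
  pseudo-steady state, plus a brute-force isochromat Bloch simulator
  used as an independent cross-check;
* the **two-frequency interference model** (`afisim.interference`):
  S_i = S_i,res + w·S_i,off·exp(i(2π·Δν·TE + φ)), i = 1, 2;
* **spoiling-curve / TE-sweep analyses** (`afisim.analysis`) with the
  asymmetry statistic Δα = α(Φ0=120°) − α(Φ0=60°), curve minima and
  percent deviations;
* **RMSE fitting** of (w, φ) to measured spoiling curves
  (`afisim.fitting`);
* **spectroscopy conversions** (`afisim.spectro`): Lorentzian
  FWHM → T2*, inversion-recovery zero crossing → T1, ppm ↔ Hz;
* a **synthetic measurement generator** (`afisim.synthetic`) with the
  phantom tube catalog and Rician ROI noise, so the whole pipeline is
  testable without scanner data;
* a **CLI** (`afisim`) with `simulate-curve`, `te-sweep`, `fit`,
  `synth` and `catalog` subcommands.

## Worked example

```python
import numpy as np
from afisim import *

# Water tube W1 at 3 T, moment set I (A_G1/A_G2 = 117.5/587.5 mT·ms/m),
# TR1/TR2 = 25/125 ms, TE = 1.9 ms, true flip angle 60°, Φ0 = 120°.
w1 = tissue_for("W1", "3T")
prot = AFIProtocol(te_ms=1.9, phi0_deg=120.0)
sig = simulate_afi(prot, w1, alpha_true_deg=60.0)
est = afi_flip_angle(sig, prot.n)
print(f"|S1| = {abs(sig.s1):.4f}, |S2| = {abs(sig.s2):.4f}")
print(f"water flip-angle estimate: {est:.1f} deg "
      f"({percent_deviation(est, 60.0):+.1f}% vs reference)")

# PVP5 at 3 T with the fitted interference parameters
# (w = 0.136, φ = −0.18π, Δν = 320 Hz).
system = TwoComponentSystem.build(tissue_for("PVP5", "3T"), 320.0)
params = InterferenceParams.from_pi_units(0.136, -0.18, 320.0)
curve = spoiling_curve(prot, lambda p: simulate_afi_two_component(
    p, system, params, alpha_true_deg=60.0))
phi_min, alpha_min = curve_minimum(curve)
print("PVP5 two-frequency curve:",
      np.array2string(curve.alpha_deg, precision=1))
print(f"minimum {alpha_min:.1f} deg at phi0 = {phi_min:.0f} deg, "
      f"asymmetry = {asymmetry(curve):+.1f} deg")
```

prints

```
|S1| = 0.0994, |S2| = 0.0740
water flip-angle estimate: 50.2 deg (-16.3% vs reference)
PVP5 two-frequency curve: [81.2 49.1 24.2 20.3 40.  51.9 63.  71.3 79.4 80.9]
minimum 20.3 deg at phi0 = 60 deg, asymmetry = +42.6 deg
```

The water estimate is moderately biased by incomplete spoiling at this
moment set but its spoiling curve stays symmetric (Δα ≈ 0). The PVP
curve is grossly asymmetric: the interference term drives the estimate
down to 20° at Φ0 = 60° (a −66% error against the 60° reference) while
Φ0 = 120° reads 63° — the single-frequency model cannot produce this.

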
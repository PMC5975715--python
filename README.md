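# hemobc

Boundary-condition synthesis and sensitivity toolkit for image-based
cardiovascular CFD.

Patient-specific simulations of aortic flow almost never have measured
velocity profiles at the inlet or measured pressures at the outlets, so
every study must *assume* boundary conditions — and the choice matters.
`hemobc` provides the building blocks for studying that sensitivity:

* **Inlet velocity profiles** on arbitrary triangulated planar patches:
  plug, parabolic (Poiseuille), two linear-shear and two skewed-cubic
  variants, and full Womersley pulsatile flow, all *exactly* normalized
  to a prescribed flow waveform Q(t) at every instant — the profile
  shape is the experimental variable, the flow rate the controlled one.
* **Secondary flow**: a counter-rotating vortex pair superposed on the
  axial profile, with a 15%-of-radius core cutoff to suppress the
  kernel singularity and an amplitude K(t) calibrated so the
  area-weighted mean in-plane speed is 24% of the mean axial speed
  during systole.
* **Windkessel outlet models**: two-element (RC) and three-element
  (RCR) lumped-parameter pressure models, integrated implicitly
  (backward Euler, unconditionally stable), plus a single-junction 0D
  network that couples several terminals to one inlet waveform, and
  prescribed-percentage outflow splits.
* **Comparison statistics**: NRMSD of axial velocity over
  cross-sectional slices, integrated wall-shear-stress difference at an
  instant, and time-averaged WSS (TAWSS) difference over a cycle, with
  area-weighted surface sums and composite-trapezoid time integration.
* **A pulsatile pipe-flow solver** (Crank–Nicolson / central
  differences) used as an independent numerical oracle for the
  Bessel-function Womersley formulation.

## The model in brief

A periodic flow waveform is represented by its truncated Fourier series
Q(t) = a₀ + Σₙ (aₙ cos nωt + bₙ sin nωt) (order 8 by default).  The
Womersley profile for harmonic n on a pipe of radius R is

    uₙ(ρ,t) = Re{ (Qₙ/πR²) · [1 − J₀(i^{3/2}αₙρ)/J₀(i^{3/2}αₙ)]
                 / [1 − 2J₁(i^{3/2}αₙ)/(i^{3/2}αₙJ₀(i^{3/2}αₙ))] · e^{inωt} },

with Womersley number αₙ = R√(nω/ν) and Qₙ = aₙ − i bₙ.  The
three-element Windkessel outlet obeys

    dp/dt + p/(C·R_d) = (Q/C)(1 + R_p/R_d) + R_p·dQ/dt,

with proximal resistance R_p, compliance C and distal resistance R_d
(R_p = 0 gives the two-element model).  Comparison metrics follow

    NRMSD  = sqrt(Σᵢ(U_ref,i − U_case,i)²/n) / mean(U_ref),
    WSS%   = |100·∫(τ_case − τ_ref)dA / ∫τ_ref dA|,
    TAWSS% = the same with an additional ∫dt over the cardiac cycle.

## Worked example

```python
import numpy as np
from hemobc import fixtures as fx
from hemobc.inlet_profiles import (ProfileSpec, SecondaryFlowSpec,
                                   generate_profile, systole_window)
from hemobc.waveform import fit_fourier

waveform = fx.make_waveform()            # synthetic aortic cycle, 25 L/min peak
fourier = fit_fourier(waveform, 8)       # 8th-order Fourier series
patch = fx.make_patch(fx.FixtureConfig(radius=0.01))   # 1 cm inlet disk

spec = ProfileSpec("parabolic", secondary=SecondaryFlowSpec())
t_sys = 0.5 * sum(systole_window(fourier))             # mid-systole
field = generate_profile(patch, spec, fourier, [t_sys])

print("flow rate  Q(t) =", fourier.evaluate(t_sys), "m^3/s")
print("patch flux      =", field.flux()[0], "m^3/s")
print("in-plane/axial  =", field.mean_in_plane_speed()[0]
                           / field.mean_axial_speed()[0])
```

prints

```
flow rate  Q(t) = 0.00041436777626560427 m^3/s
patch flux      = 0.00041436777626560427 m^3/s
in-plane/axial  = 0.24000000000000002
```

— the discrete flux through the patch equals the prescribed waveform
value exactly, and the calibrated vortex pair delivers a mean secondary
speed of 24% of the mean axial speed at the systolic instant.

The same operations are reachable from the shell:

```
hemobc fixtures --out inputs/
hemobc gen-inlet --shape womersley --waveform inputs/waveform.csv \
       --patch inputs/patch_nodes.csv --facets inputs/patch_facets.csv \
       --secondary inputs/vortex.json --out profile.csv
hemobc windkessel --params inputs/windkessel_descending_aorta.json \
       --waveform inputs/waveform.csv --dt 0.01 --cycles 5 --out p.csv
hemobc compare --ref a.csv --case b.csv --metric tawss --upto-d 1.0
```

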
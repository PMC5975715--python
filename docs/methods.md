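# Methods

This note records the models implemented in `hemobc`, the assumptions
behind them, the numerical choices, and what the synthetic test inputs
do and do not demonstrate about real data.

## Flow waveforms and Fourier representation

A cardiac flow waveform is one period of samples (t, Q), internally in
m³/s (readers accept L/min; 1 L/min = 1/60000 m³/s).  Downstream
consumers use the truncated Fourier series of order N (default 8,
adequate to capture the systolic peak and valve-closure dip of an
aortic waveform without amplifying digitization noise).

The fit is performed by least squares on the given sample times rather
than by FFT, because digitized clinical waveforms are rarely uniformly
sampled.  The constant term is pinned to the periodic trapezoidal time
average of the samples and the harmonics are fitted to the residual.
On a uniform grid the constant column is orthogonal to every harmonic,
so this constrained fit coincides with the joint least-squares solution
and with the DFT; on non-uniform grids it guarantees that the series'
mean flow is the trapezoidal average of the data, which is the quantity
the rest of the toolkit treats as the cardiac output.  Orders above the
Nyquist limit of the sampling (2N + 1 > n) are rejected.

## Inlet patch geometry

An inlet patch is a planar triangulation in a local frame: origin at
the area centroid, ê₁ the in-plane shear axis (anatomically the
inner-to-outer arch direction), n̂ the flow-positive normal.  Nodal
quadrature weights are one third of each incident triangle's area
(vertex-lumped rule, second-order accurate for smooth integrands).
The effective radius is that of the area-equivalent circle, R = √(A/π),
and D = 2R.

Non-circular cross-sections are handled through the normalized boundary
distance ρ(x, y) = r/R(θ), where R(θ) is the radius of the boundary
polygon along the ray through the point.  This maps any star-shaped
patch onto the unit disk, so the analytic profile shapes evaluate
naturally on ellipses and mildly irregular inlets.  The construction
assumes the patch is star-shaped about its centroid — true for convex
cross-sections, which covers realistic vessel inlets.

## Axial profile families

With s the coordinate along ê₁ and σ = ±1 selecting the variant:

| family        | shape                          |
|---------------|--------------------------------|
| plug          | 1                              |
| parabolic     | 2(1 − ρ²)                      |
| linear shear  | 1 + σ·s/R                      |
| cubic shear   | 1 + σ·(s/R)³                   |

Each has unit area-mean over the exact unit disk (the odd shear moments
vanish on a disk): the shear profiles are zero at one wall and twice
the mean at the opposite wall.  The linear/cubic functional forms are
this package's concrete realization of "skewed" profiles — schematic
descriptions of such profiles do not pin down a formula, so the
simplest polynomial family with the correct wall values was chosen.

**Exact flow-rate normalization.**  At every time step the nodal axial
velocities are rescaled so the discrete flux Σᵢ uᵢaᵢ equals Q(t).
Discrete flux is computed with exactly-rounded summation
(`math.fsum`): near flow reversal the Womersley profile's positive and
negative regions nearly cancel, and a naive dot product then carries a
relative error far above machine epsilon with respect to the small net
flux.  After the scalar rescale, the remaining per-product rounding
residual (order 1e-11 relative at worst) is absorbed into the
largest-area node, so the measured discrete flux reproduces Q(t) at
machine precision at every instant, for every family.  The single-node
adjustment perturbs that node's velocity by a relative amount below
1e-10 and has no physical significance.

At negative-flow instants (the post-systolic dip) the spatial shape is
kept fixed and the sign is carried by the normalization factor, i.e.
the whole profile reverses rather than the skew direction flipping.

## Womersley profile

The steady Fourier component is carried by a Poiseuille profile; each
harmonic n adds the classical rigid-pipe solution

    Re{ (Qₙ/πR²)·[1 − J₀(i^{3/2}αₙρ)/J₀(i^{3/2}αₙ)]
        / [1 − 2J₁(i^{3/2}αₙ)/(i^{3/2}αₙJ₀(i^{3/2}αₙ))] · e^{inωt} },

αₙ = R√(nω/ν), Qₙ = aₙ − i·bₙ, evaluated with scipy's complex-argument
Bessel functions.  The bracketed ratio integrates to 1 over the cross
section, so the analytic flux is Q(t) already; the generator's
renormalization only removes the triangulation quadrature error
(≈3×10⁻⁴ at default density).  For blood (ν = 0.004 Pa·s / 1060 kg·m⁻³)
on a 1 cm aortic root at 1 Hz, α₁ ≈ 13.  Extreme αₙ (several hundred)
overflow the Bessel evaluation; this raises a numerical error with
guidance to reduce the order, rather than returning garbage.

As α → 0 the harmonic shape degenerates to quasi-steady Poiseuille,
which is verified in the tests both as a limit and exactly for a
mean-only waveform.

## Secondary flow: counter-rotating vortex pair

The in-plane field for unit amplitude is

    v(x,y) = [−(y−y₁), (x−x₁)]/d₁² + [(y−y₂), −(x−x₂)]/d₂²,

two opposite-signed vortices at (x₁,y₁), (x₂,y₂) (default ±0.4R on the
shear axis).  Two kernel readings are implemented:

* `point_distance` (default): dᵢ is the Euclidean node–center
  distance.  The kernel is then singular exactly at the vortex centers,
  which is what the core cutoff exists to suppress, so this reading is
  taken as the physically intended one.
* `literal_radial`: dᵢ = r − rᵢ with r, rᵢ radial distances from the
  patch origin — the formula exactly as often typeset; retained as an
  option.

In both modes the velocity is set to the zero vector at every node
within 15% of the effective radius of either center
(`core_cutoff_fraction = 0.15`).

**Amplitude calibration.**  K(t) is chosen so that the area-weighted
mean in-plane speed is `target_speed_ratio` (default 0.24) times the
area-weighted mean axial speed.  Because both means are homogeneous of
degree one in their fields, K(t) = ratio · mean_axial_speed(t) /
mean_unit_secondary_speed holds with one proportionality constant: the
systolic calibration instant fixes the entire series, and outside
systole K(t) simply scales with the axial speed.  Whether the ratio
should instead decay in diastole is physiologically open; the
proportional choice is the simplest defensible one and is configurable
through the systole window.  Area-weighted (rather than unweighted)
node means are used throughout, consistent with the surface-integral
conventions of the WSS metrics.  The systole window defaults to the
contiguous interval where Q(t) exceeds 10% of its peak.

## Windkessel models

The RCR outlet ODE dp/dt + p/(CR_d) = (Q/C)(1 + R_p/R_d) + R_p·dQ/dt is
integrated by backward Euler with dQ/dt ≈ (Qₙ₊₁ − Qₙ)/dt — fully
implicit, first order, unconditionally stable, matching the implicit
first-order time stepping conventional in this setting.  Default
dt = 0.01 s and 5 cardiac cycles.  The initial pressure defaults to the
steady state at the mean flow, Q̄(R_p + R_d), the fastest approach to
the periodic regime; the per-cycle periodicity residual
max|p(t) − p(t−T)| is reported so the cycle count can be judged.  The
closed-form impedance Z(ω) = R_p + R_d/(1 + iωCR_d) serves as the test
oracle.  Parameters are accepted in CGS (dyn·s/cm⁵, cm⁵/dyn) or SI with
exact conversion (1 dyn·s/cm⁵ = 10⁵ Pa·s/m³).

The two-element model is R_p = 0 in the same code path, so RC and
RCR(R_p=0) trajectories are bitwise identical by construction.

## 0D network

One inlet, N terminal branches, one junction pressure — the minimal
analogue of a branching-vessel outlet set that still exercises the
Windkessel coupling.  Per implicit step the unknowns (P_j, {p_c,i},
{Q_i}) solve the exact linear system of junction balance, terminal
resistance drops, and backward-Euler compliance updates, monolithically
(one `solve` per step); R_p = 0 rows degenerate gracefully to P_j =
p_c,i.  The first reported sample is itself a consistency step from the
steady-state initialization, so mass conservation Σ Qᵢ = Q_in holds at
machine precision at every reported sample.  A single junction cannot
reproduce the flow division of a real 3D vessel tree, where the split
emerges from the geometry; it is a testbed for the terminal models, not
a surrogate for the 3D solution.

## Pipe-flow oracle

The axisymmetric momentum equation du/dt = G(t)/ρ + ν(1/r)∂/∂r(r∂u/∂r)
with no slip at r = R and a ghost-node symmetry condition at the axis
(the axis Laplacian limit 4(u₁−u₀)/Δr²) is marched by Crank–Nicolson
with second-order central differences — deliberately higher-order than
a production CFD scheme because an oracle should converge faster than
what it checks.  Second-order convergence to the closed-form Womersley
solution is verified (error ratio ≈ 4 on doubling N_r and 1/dt).

The generator-vs-oracle comparison feeds both codes the *same* physics
through different inputs: a single pressure-gradient harmonic drives
the finite-difference solver, its analytic flow-rate amplitude
Qₙ = (Gₙ/iρnω)·πR²·[1 − 2J₁/(i^{3/2}αJ₀)] is handed to the generator as
a one-term waveform, and the two velocity fields are compared as
functions of the normalized coordinate ρ.  Comparing in ρ (rather than
physical radius against the patch's polygonal boundary) keeps the
patch's O(3×10⁻⁴) geometric discretization out of the comparison, so
the measured error reflects the finite-difference discretization alone
and shows clean 4× decay under refinement.  Starting the march on the
closed-form solution removes the viscous start-up transient, whose
decay time grows as α²/ (j₀₁² ω) and would otherwise dominate the run
time at high α; the march itself still validates the discrete operator,
since any inconsistency would drift the solution off the analytic orbit
within the simulated cycles.

## Comparison statistics

* NRMSD uses the plain unweighted mean over the n slice samples, both
  in the RMS numerator and the reference-mean denominator — the /n
  convention as typeset in the statistic's definition.
* Integrated WSS and TAWSS differences use facet-area-weighted sums
  (the dA convention), TAWSS adding composite-trapezoid integration
  over the cycle time grid.
* The statistics act on axial-velocity and WSS *magnitudes* (scalars).
* Near-inlet restriction keeps samples with streamwise station ≤ the
  cutoff, in multiples of the inlet diameter D.

Zero-reference denominators raise errors rather than returning NaN.

## Synthetic inputs: what they do and do not show

The fixture waveform is parametric and clearly synthetic: a sin²
systolic ejection peak (default period 1 s, peak 25 L/min, systole
fraction 0.35 — resting adult aortic values), a brief sin² backflow dip
(10% of peak) for valve closure, and zero diastolic flow, with the
exact peak instant inserted into the sample grid.  It emulates the
qualitative anatomy of an aortic flow curve — single peak, undershoot,
quiescent diastole — but no patient's waveform; passing tests
demonstrate correct *mechanics* (decomposition, normalization,
calibration), not physiological fidelity.  Likewise the structured
disk/ellipse patches exercise the geometry pipeline but not the
irregular, slightly non-planar inlets of segmented medical images, and
the toy wall fields (per-facet sinusoids with brute-force-computed
reference statistics) validate the metric implementations, not any CFD
solution.  Quantities that depend on a specific patient geometry and a
full 3D solve — actual WSS differences between boundary conditions,
NRMSD decay along a real aorta — are outside what this package can
reproduce and are deliberately not asserted anywhere.

Windkessel element values and outflow splits for the bundled aorta
configuration are conventional literature values for an adult thoracic
aorta with four supra-aortic branches; they are inputs, not results.

## Numerical defaults

| parameter | default | note |
|---|---|---|
| Fourier order | 8 | captures systolic peak + dip |
| time step dt | 0.01 s | Windkessel / network integration |
| cardiac cycles | 5 | periodicity residual reported |
| core cutoff | 0.15·R | vortex kernel singularity guard |
| speed ratio | 0.24 | secondary/primary calibration |
| vortex centers | (±0.4R, 0) | on the shear axis, inside the cutoff-free region |
| systole window | Q > 10% peak | contiguous interval |
| mesh density | 24 rings (fixtures) | area error ≈ 3×10⁻⁴ |
| pipe solver | N_r = 128, dt = T/512 | oracle resolution |
| blood | ρ = 1060 kg/m³, μ = 0.004 Pa·s | Newtonian |

Problem sizes in the test and acceptance runs (≈2–3×10³ patch nodes,
≤10³ time steps per simulation) were chosen so every verification
closes its error budget comfortably; all checks complete in seconds.

## Known limitations

* Profiles are generated on planar patches only; mapping onto curved
  inlet caps is not supported.
* The Womersley formulation assumes a rigid circular pipe; on
  non-circular patches it is applied through the ρ-mapping as a
  controlled approximation, not an exact solution.
* The 0D network is single-junction; arterial trees and 1D wave
  propagation are out of scope.
* Bessel evaluation overflows for Womersley numbers of several hundred
  (very high harmonics); the error message suggests reducing the
  order.
* All models are Newtonian and rigid-walled by construction of their
  inputs.
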
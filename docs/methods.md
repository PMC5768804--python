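# Methods

This note documents the models, numerical schemes, default parameters and
design choices behind `rfasim`, and what the synthetic-phantom test bed
does and does not establish about real treatments.

## Synthetic patient models

A phantom is a regular voxel grid (world coordinates in mm, axis order
x, y, z, identity orientation) carrying boolean masks — liver ROI, tumor,
large vessels — and per-voxel fields of the Pennes parameters. Voxel
membership follows a center-in-shape rule: a voxel belongs to a sphere or
capped cylinder iff its center does. This makes brute-force voxel-center
scans *exact* oracles for every mask builder, at the cost of ignoring
partial-volume effects. Where shapes overlap, precedence is
vessel > tumor > healthy: vessels are heat sinks and must never be
overwritten; the tumor is clipped to the liver ROI.

The simulation domain is restricted to a sphere of radius 60 mm around the
tumor centroid. Standard liver RFA protocols produce coagulation diameters
of at most ~5 cm, so tissue beyond that border does not measurably
influence the temperature field; the restriction caps the linear-system
size accordingly.

### Default tissue properties

The literature value ranges for perfused liver are wide; the defaults
below are mid-range textbook values and every one is overridable per
phantom spec (the CLI rejects values outside documented plausibility
windows rather than silently accepting them).

| class   | ρ (kg/m³) | c (J/kg·K) | k (W/m·K) | ω_b (kg/m³·s) |
|---------|-----------|------------|-----------|----------------|
| healthy liver | 1060 | 3600 | 0.512 | 2.0 |
| tumor   | 1045 | 3760 | 0.552 | 1.0 |
| vessel (blood) | 1060 | 3617 | 0.52 | — (Dirichlet) |

Blood heat capacity c_b = 3600 J/(kg·K), arterial temperature
T_b = 37 °C. Healthy-liver perfusion is taken from the commonly used
0.6–6 kg/(m³·s) window; tumors are modelled hypo-perfused relative to
parenchyma. These magnitudes cannot be validated against a single
authoritative source — they are the knobs the uncertainty ensemble exists
to sweep.

## Bioheat solver

Temperature obeys the Pennes equation

    ρc ∂T/∂t = ∇·(k ∇T) − ω_b c_b (T − T_b) + q .

Discretization is a 7-point finite-difference Laplacian with
harmonic-mean face conductivities (continuous flux across tissue
interfaces) on the regular grid. Unknowns are the ROI voxels outside the
vessel mask. Two kinds of boundary handling:

- **Dirichlet voxels** — vessel voxels and voxels outside the liver ROI
  are held at their state temperature, which initialization sets to T_b.
  Large vessels therefore act as perfect local heat sinks, distinct from
  the distributed capillary perfusion term. Holding *state values* rather
  than hard-coding T_b also admits test configurations with arbitrary
  fixed boundary temperatures (the 1-D two-ends-fixed conduction oracle).
- **Outer grid faces** are no-flux; in practice the ROI sphere is interior
  to the grid, so the ROI boundary is a T_b Dirichlet shell.

Time integration is backward Euler by default. The linear systems are
strongly diagonally dominant at ablation time steps (ρc/Δt dominates the
conduction couplings), so each step is solved with Jacobi-preconditioned
conjugate gradients warm-started from the previous field (rtol 1e-12);
this outperforms direct factorization by orders of magnitude at these
sizes and keeps runs bit-reproducible. A forward-Euler explicit scheme is
retained for testing; it checks Δt against the stability bound
min ρc / (Σ k_face/h² + ω_b c_b) and raises an error naming the bound.
With q ≥ 0 and T ≥ T_b initially, the implicit scheme satisfies the
discrete maximum principle; in the insulated, perfusion-free
configuration the heat content grows by exactly the deposited energy each
step (verified to ~1e-13 relative).

### Power deposition

The probe deposits power as an isotropic 3-D Gaussian around each source
point: the tip for simple probes, tip plus prong tips (equal weights) for
umbrella probes. Vendor per-prong power splits are not public; the equal
split is the symmetric default and configurable. The summed kernel is
renormalized over the ROI so the voxel sum of q·vol equals the delivered
wattage exactly, regardless of truncation. Default σ = 2 mm (3 mm in the
bundled protocol), configurable per protocol.

### Protocol engine

A protocol is an ordered list of phases, each with a duration, a control
mode and an umbrella extension fraction. Modes: `constant_power`;
`temperature_controlled`, the proportional law
clamp(P_max·(1 − (T_probe − T_target)/band), 0, P_max) with a 5 °C default
band, where T_probe is the maximum temperature over the source-point
voxels (the sensing location is not standardized across devices; the
probe maximum is the conservative choice); and `cooldown` (power off).
Each phase is stepped with a uniform Δt dividing its duration (nearest to
the requested splitting step, default 1 s). Source points are re-derived
per phase from the phase's extension fraction. A previous simulation
result can seed the next run, so multi-cycle treatments with repositioned
needles chain; chaining with an unchanged needle is field-wise identical
to running the concatenated phase list.

## Cell-death model

Each voxel carries fractions of Alive, Vulnerable and Dead cells:

    dA/dt = −k_f A + k_b V
    dV/dt =  k_f A − k_b V − k_f V
    dD/dt =  k_f V,    k_f = k̄_f · e^{T/T_k} · (1 − A)

Defaults k̄_f = 3.33e-3 s⁻¹, k_b = 7.77e-3 s⁻¹, T_k = 40.5 °C follow the
published parameterization of this three-state model. The (1 − A) factor
makes damage self-catalysing — and makes A = 1 a fixed point, so the
baseline state seeds a small vulnerable fraction (A = 0.99, V = 0.01), as
in the original model. Dead is absorbing: D is non-decreasing in time, so
the predicted lesion only grows within a treatment.

Integration is classical RK4, operator-split against the bioheat step at
the same Δt, internally sub-stepped so that the fastest local rate times
the sub-step stays ≤ 0.1 (the forward rate grows exponentially with
temperature and can exceed 1 s⁻¹ near the probe). States are clamped to
[0, 1] and renormalized each sub-step; a numerical max() guards the
monotonicity of D against rounding. Against an adaptive reference
integration (DOP853, rtol 1e-12) the voxel ODE agrees to ~1e-13 at
Δt = 1 s.

The lesion is {D ≥ 0.8} within the ROI; 0.8 is a documented, configurable
choice (extraction rules in the literature vary). The lesion surface is
the marching-cubes iso-surface of D at the threshold.

## Uncertainty ensembles

Up to two parameters vary simultaneously: tissue perfusion, tumor
perfusion, heat capacity, thermal conductivity, or the needle geometry.
Scalar parameters take linear (endpoints included; n = 1 → midpoint) or
seeded-uniform samples over a range; needle variation draws placements
uniformly within a ball of radius r around each defining point. Two specs
with it_p1 and it_p2 iterations yield exactly it_p1·it_p2 configurations,
each simulated independently; scalar overrides rewrite the corresponding
property field classwise (healthy parenchyma for tissue perfusion, tumor
voxels for tumor perfusion, all non-vessel ROI voxels for conductivity and
heat capacity).

The lesion ensemble is summarized by contour band depth: the depth of
member c is the fraction of unordered pairs (i, j), both ≠ c, with
lesion_i ∩ lesion_j ⊆ lesion_c ⊆ lesion_i ∪ lesion_j (the j = 2
subset-size convention; the member under evaluation is excluded from the
pairs). The median is the deepest member (ties → lowest index, for
deterministic reporting); members with depth < 0.1 (configurable) are
outliers; the 50 % band is the (intersection, union) of the deepest half
of the non-outlier members and the envelope that of all non-outlier
members. For five strictly nested masks the middle member attains the
maximum depth 4/6 and the extremes 0 — a useful closed-form check.

## Registration

Landmark-based rigid registration uses the closed-form Kabsch/Procrustes
solution: SVD of the centered cross-covariance, with the sign of the
smallest singular vector flipped when det < 0 so a proper rotation is
always returned (no scaling, no reflection). Fewer than three pairs or
collinear source landmarks are rejected as under-determined. Noiseless
random transforms are recovered to < 1e-9 mm RMS; residuals agree with an
independent quaternion (Horn) closed form. Deformable registration is out
of scope — phantoms are generated directly in the model frame.

## Validation metrics

With voxel counts a = |test|, b = |reference|, i = |test ∩ reference|:
DSC = 200·i/(a+b), SN = 100·i/b, PPV = 100·i/a, RVD = 100·|a−b|/b
(absolute by default; a directional variant would drop the modulus).
Surface distances are symmetric vertex-to-nearest-triangle: distances
from every test vertex to the reference mesh and vice versa are pooled;
AAE is the pooled mean, min/max the pooled extremes. Exact point-triangle
distances are evaluated on KD-tree candidate triangles (nearest
centroids), which is exact for the near-uniform tessellations marching
cubes produces. A one-sided variant is available; the symmetric form is
the default since the convention is not standardized.

The success rule is strict on all three thresholds:
RVD < 20 % and SN > 80 % and AAE < 3 mm; boundary values fail.

Safety-margin classification measures, for each lesion-surface point, the
exact distance to the tumor's half-way iso-boundary (signed negative
inside the tumor) and bands it: failed < 4.5 mm ≤ critical ≤ 5.5 mm <
safe. The band edges map to "critical" — the strict published
inequalities leave the boundary values unassigned, and the closed
critical band is the conservative completion. Every surface point
receives a label; results are exported as a per-point CSV.

## Problem sizes and reproducibility

The bundled configurations run at 16³–64³ voxels with 1.5–4 mm spacing
and protocols of minutes of simulated time at Δt of 1–3 s: large enough
for the analytic oracles to hold to their stated tolerances, small enough
for interactive turnaround on one CPU (a full 25-member ensemble at 32³
takes tens of seconds). All stochastic inputs — landmark noise, needle
perturbation, random sampling — flow from explicit integer seeds; a fixed
seed makes phantoms, simulations and whole ensembles bit-reproducible.

## What the phantom test bed does not show

Synthetic phantoms have exactly spherical tumors, straight vessels,
piecewise-constant properties and perfectly known geometry. Passing tests
therefore validate the *numerics and logic* of the pipeline — not
predictive accuracy on patients, which additionally depends on
segmentation, registration and deformation errors and on
temperature-dependent tissue behavior. Known model limitations:

- no vaporization, carbonization or impedance roll-off, so near-probe
  temperatures in constant-power mode can exceed physical values
  (temperature-controlled protocols keep them realistic);
- tissue properties are temperature-independent;
- vessels are perfect (Dirichlet) heat sinks regardless of flow rate;
- power deposition along prong *shafts* is not modelled (sources sit at
  tip and prong tips);
- regular-grid finite differences in place of boundary-conforming
  adaptive meshes: geometric accuracy at tissue interfaces is
  first-order, compensated by fine spacing at desk scales.
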
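# Methods

`retinox` implements a hybrid model of a retinal arteriolar branch and its
downstream microcirculation: a heterogeneous arteriolar tree solved
vessel-by-vessel, coupled to lumped compartments for capillaries and
venules. This note records the model equations as implemented, the
parameter choices and their provenance, the numerical methods, and the
limitations a user should know before trusting a result.

## Model overview

A simulation proceeds in five coupled stages:

1. **Geometry.** A seeded generator grows an arteriolar tree of 4–5
   branching orders with fixed per-order diameters
   (117/73/44/32/22 µm) and stochastic per-order lengths. Each terminal
   arteriole feeds a chain of three compartments — capillaries (C), small
   venules (SV), large venules (LV) — each a group of identical parallel
   vessels.
2. **Hemodynamics.** Poiseuille flow, Q = ΔP·πD⁴/(128 µL), with mass
   conservation at nodes, fixed inlet pressure (40 mmHg) and fixed
   terminal-outlet pressure (24 mmHg), iterated with discharge-hematocrit
   propagation and an empirical apparent-viscosity law µ(D, H_D).
3. **Flow regulation.** Each arteriole's diameter D and smooth-muscle
   activation A follow wall-mechanics ODEs: the Laplace tension
   T = (P − IOP)·D/2 relaxes toward the passive+active wall tension
   T_total(D, A), and A relaxes toward a sigmoid of the tone stimulus
   S_tone = C_myo·T − C_shear·τ_wall − C_meta·S_meta + C″_tone.
4. **Oxygen transport.** In the arterioles and their tissue, a
   Green's-function method: vessels are line sources, tissue consumes
   oxygen at the Michaelis–Menten rate M0·P/(P0 + P). In each capillary, a
   Krogh cylinder: a tissue sleeve of width d consuming at constant M0,
   with the closed-form radial profile and exact convective bookkeeping
   f(P_b) = Q(H_D·C0·S(P_b) + α_b·P_b), S the Hill curve
   (P50 = 26 mmHg, n = 2.7). Venule compartments exchange no oxygen.
5. **Metrics.** Oxygen extraction fraction
   OEF = Σ Q_i (SaO2 − SvO2,i) / (Q_total·SaO2) over terminal pathways,
   hypoxic-fraction curves over the arteriolar tissue, pathway-averaged
   Krogh radial profiles, and capillary-count distributions.

## Synthetic networks: what they emulate and what they do not

The two reference branch geometries this model family was built around
were digitized from experimental images and are not publicly deposited,
so this package generates statistically similar trees instead. The
generator is quota-driven: each subtree must deliver an exact number of
terminals, while the branching motif at each step is random — a symmetric
bifurcation (both children one order deeper) or an asymmetric side branch
(child one order deeper, parent continues at its own order, probability
`asymmetry`). The feeding artery and first-order arterioles always grow as
arcades shedding side branches, which mirrors retinal anatomy and keeps
the network resistance stable across seeds. Single-terminal side branches
off the arcades take anatomically short pathways (`short_path_scale`);
these proximal shortcuts carry the high-flow tail of the capillary-count
distribution.

Capillary counts follow the flow partition rule n_C,i =
max(1, round(Q_TA,i / Q_C)), with the single-capillary reference flow
Q_C ≈ 0.211 nl/min obtained from an assumed 6 µm capillary diameter,
15 dyn/cm² wall shear, and 9.05 cP viscosity.

Per-order **lengths are calibration choices, not measured values** — no
per-order length statistics were reported for the reference branches.
Defaults (means 700/550/450/350/300 µm for orders 1–5, lognormal,
CV 0.3–0.4, truncated to [0.2, 5]× the mean) give desk-scale trees;
the full-scale presets `branch1_like_config` / `branch2_like_config`
(280 and 170 terminals, means 1700/1400/1300/1100/850 µm) were calibrated
once so that downstream capillary totals land near 7×10⁴ and 6×10⁴ with
per-compartment medians of a few hundred and tails of a few thousand,
matching the reference branches' published statistics in scale and shape.
Emulation means *statistical* similarity: per-seed totals vary by roughly
±10%, and no seed reproduces the reference geometries' exact numbers.
Passing tests therefore certify the model machinery and the direction and
scale of its predictions, not patient-specific values.

The embedding is quasi-planar (z-jitter ~15 µm) with collision avoidance:
candidate segments are retried until they clear existing vessels by
> 4 µm surface-to-surface (bounded retries). Without this, crossing
vessels create ill-conditioned source systems in the oxygen solver.

## Hemodynamics

Internally all quantities are CGS (cm, s, dyn, poise); interfaces use
mmHg, µm, nl/min, cP (conversions centralized in `units.py`).

*Pressure solve.* Conservation of flow at interior nodes gives a linear
system with Dirichlet values at the inlet node and every terminal outlet
node; by construction every root-to-terminal pathway drops exactly
16 mmHg. The solver is successive over-relaxation (ω = 1.5, residual
tolerance 1e-13 mmHg-equivalent per node), implemented as sparse
triangular sweeps; a sparse direct solve is available behind the same
interface and is used inside the regulation time-stepping loop for speed.
Both agree to better than 1e-9 relative.

*Hematocrit.* On a tree, the default proportional split (children inherit
the parent's discharge hematocrit) satisfies red-cell flux conservation
exactly and makes H_D uniform at the 0.4 inflow value. An empirical
phase-separation rule is available behind the same interface for
sensitivity studies; it conserves RBC flux by giving the second daughter
the complement of the first.

*Viscosity.* Three laws: `constant` (9.05 cP, the capillary reference),
`in_vitro` (the glass-tube fit with the Fåhræus–Lindqvist minimum near
7 µm), and `in_vivo` (default), which adds the endothelial-surface-layer
correction observed in living microvessels. The in-vivo law is the
default because (a) the flow-solver lineage this model derives from uses
it, and (b) at D = 6 µm, H_D = 0.4 it evaluates to ≈ 10.9 cP, consistent
with the 9.05 cP single-capillary value, whereas the in-vitro law gives
≈ 2.7 cP. Apparent viscosity = relative viscosity × plasma viscosity
(1.2 cP).

*Outer iteration.* Pressure/flow solves alternate with
hematocrit/viscosity updates until the relative change is below 1e-10.
With the proportional split on a tree this converges in one outer cycle.

## Flow regulation

Wall-mechanics coefficients are derived per vessel from the passive
reference diameter D0: C_pass = 1.67·D0, C′_pass = −0.027·D0 + 12.52,
C_act = 1.30·D0^1.48, C′_act = −0.00146·D0 + 1.13,
C″_act = −0.00146·D0 + 0.308, C_myo = 1.37/D0; C_shear = 0.0258 cm²/dyn,
C_meta = 1000 (µM·cm)⁻¹, τ_d = 1 s, τ_a = 20 s, IOP = 15 mmHg (the
Laplace balance needs an extraocular pressure; 15 mmHg is a normal value
and is configurable).

*D0.* Defining D0 as "the passive diameter at 40 mmHg" is degenerate once
C_pass = 1.67·D0 is adopted: with IOP = 15 mmHg the Laplace tension at
40 mmHg is 1.6665·D0 dyn/cm for *any* D0, so the implied root equation is
an identity rather than a constraint. Instead D0 = 1.3·Dc per vessel,
which reproduces the published calculated ranges (D0 = 29–151 µm against
control diameters Dc = 22–117 µm at both ends of the hierarchy).

*Calibration of the control state.* With converged control flows, each
vessel's control tension is Tc = (P_mid − IOP)·Dc/2; the control
activation A_c = (Tc − T_pass(Dc))/T_act^max(Dc) follows from tension
balance, and C″_tone = logit(A_c) − C_myo·Tc + C_shear·τ_c + C_meta·S_meta,c
makes the control state an exact equilibrium of the ODEs (verified to
1e-12). Calibrated C″_tone values land at 50–90 on desk-scale trees,
inside the published 52–205 range.

*The conducted metabolic signal* S_meta is not specified in the wall-
mechanics literature the model draws on (its units, µM·cm, suggest a
conducted metabolite concentration integrated along vessel length). The
reconstruction implemented here: for vessel i, S_meta,i = c_sig ·
Σ_{terminals t downstream} (Q_t/Q_i)·(1 − S_out,t)·L_C,t·exp(−d_it/λ),
i.e. flow-weighted capillary-bed hemoglobin desaturation times capillary
length, decaying upstream with length constant λ = 1 cm. The
concentration scale c_sig = 5 µM makes the metabolic term comparable to
the calibrated C″_tone range at baseline. Because C″_tone is calibrated
*around* this signal, c_sig affects only the feedback gain, not the
control equilibrium. **This is a model reconstruction**, exposed behind
`metabolic_signal` so alternative formulations can be swapped in; results
that depend on the magnitude (not direction) of metabolic dilation should
be read with that in mind.

*Time integration* is explicit Euler with flows re-solved every step and
the metabolic signal refreshed every 10 steps (and once more at
convergence, as a self-consistency check). The nominal step is 0.1 s, but
the diameter equation is stiff for the largest vessels (the active-tension
Gaussian is narrow: C″_act ≈ 0.09 at D0 ≈ 150 µm), so the step is capped
at 1/λ_max, with λ_max the numerically estimated local rate constant
(recomputed every 50 steps); a step that would drive any diameter
non-positive is rejected and halved. Steady state is declared when
max |dD/dt|·τ_d/Dc and max |dA/dt|·τ_a fall below 1e-6. During the inner
loop, S_meta uses a fast convective chain model with the inlet saturation
at terminal entry (arteriolar desaturation neglected there); the full
Green's solve supplies terminal blood PO2 for the reported metrics.

"Regulation off" means diameters frozen at the control state — the model
analog of impaired autoregulation.

## Oxygen transport

### Arterioles: Green's-function method

Vessel segments are split into line-source elements of length ≤ 2
diameters. The tissue PO2 at x is

P(x) = Σ_e G(x, e)·q_e − Σ_t G(x, x_t)·m_t·V_t + c,

with the free-space kernel G = 1/(4πK|x−x′|) (analytically integrated
over each line element; the element's own surface is the evaluation
offset), K = D_diff·α = 6e-10 cm³O2/cm/s/mmHg, and m_t = M0·P_t/(P0+P_t)
the Michaelis–Menten consumption (P0 = 10 mmHg; negative P enters the
consumption as zero). The additive constant c is the free-space kernel's
gauge freedom; it is fixed each iteration by *exact* global balance
Σ q_e = Σ m_t V_t (a scalar root solve, since q is affine in c). Source
strengths solve the surface condition P(surface of e) = P_b,e
(intravascular resistance neglected); elements whose unconstrained
strength would be negative are pinned to zero by an active set, i.e.
vessel walls are sources only. This keeps blood saturation non-increasing
along flow, at the cost of letting tissue locally exceed blood PO2 in
crowded regions (with collision-free geometry the pinned set is small).

Blood PO2 is marched down the tree by the convective law
df/ds = −q_v with f = Q(H_D·C0·S + α_b·P_b), C0 = 0.5 cm³O2/cm³,
α_b = 3.1e-5 cm³O2/cm³/mmHg, inlet saturation 0.92 (P_b ≈ 64 mmHg), and
element effluxes subtracted in order; P_b is recovered by safeguarded
Newton inversion of the strictly monotone f.

The nonlinear consumption field is solved by damped Newton iteration with
a matrix-free Jacobian: tissue–tissue kernel products are FFT convolutions
on the regular grid (kernel transform cached), the vessel-source feedback
is a low-rank correction through the factorized surface system, and the
balance constant contributes a rank-one term; the linearized system is
solved by GMRES (tol 1e-3) with backtracking on the residual. Convergence
is max |ΔP| < 0.01 mmHg; typically 6–10 Newton iterations, plus 2–4 outer
passes for the blood march (tol 0.05 mmHg). Naive Picard iteration fails
here: coherent modes over hypoxic transition shells have feedback gains
≫ 1.

*Tissue domain.* The "arteriolar tissue" is the set of grid cells nearest
the vessel network, clipped so the selected volume equals the prescribed
arteriolar vessel+tissue volume VOL_A = 0.00115 cm³ (each cell carries
equal volume weight). At the default 40–60 µm spacing this is a sleeve of
roughly ±100 µm around the tree — consistent with VOL_A divided by
network length — leaving the remaining tissue to the capillary
compartments. Grid spacing is the main resolution knob; the hypoxic
fraction at M0 = 3 shifts by a few points between 40 and 60 µm spacing.

*Known biases.* The free-space kernel omits domain-boundary reflections
(quantified against the finite-difference oracle: mean interior
discrepancy < 1%, worst ~3–5% of the vessel–tissue PO2 difference);
tissue cells adjacent to strong sources can overshoot blood PO2 (a
near-field discretization artifact affecting a small volume fraction).

### Finite-difference oracle

An independent cross-check solves the same conservation law on a regular
grid: 7-point Laplacian, zero-flux (or fixed-PO2) box boundary, vessels
rasterized as Dirichlet cells filling the vessel radius, Michaelis–Menten
consumption handled by damped Newton with conjugate-gradient inner solves.
It is meant for single- or few-vessel instances; with the vessel diameter
below the grid spacing the Dirichlet line under-represents the vessel
surface (a warning is emitted) and near-field comparisons are not
meaningful.

### Capillary compartments: Krogh cylinders

Every capillary in a compartment is identical: radius r_c = 3 µm, length
L_C drawn per chain (lognormal; mean 400 µm by default — a calibration
choice), sleeve width d shared by all chains. d solves the volume
partition CD = Σ n_C L_C / (VOL_A + Σ[n_C L_C π(r_C+d)² + SV + LV
volumes]) by bracketed bisection (tolerance 1e-4 µm); at the reference
CD = 500 mm⁻² with ~7×10⁴ capillaries of ~400 µm this yields d ≈ 22 µm.
A CD target above the d→0 supremum raises an infeasibility error.

The radial profile uses the closed form
P(r) = P_wall + (M0/4K)(r²−r_c²) − (M0·r_t²/2K)·ln(r/r_c) with zero flux
at r_t, clamped at zero with a hypoxic-annulus flag. Consumption in the
sleeve is constant at M0 (not Michaelis–Menten) — the standard Krogh
assumption — so the convective efflux per unit length is exactly
q_v = M0·π(r_t²−r_c²) and f_out = f_in − q_v·L_C in closed form; blood
that would be driven below f = 0 is reported as depleted (P_b = 0). The
wall PO2 at each axial station equals the local blood PO2, and reported
profiles are evaluated at the downstream end s = L_C. Venule stages set
d = 0 and pass saturation through unchanged.

## Metrics and sweeps

OEF uses the saturations at the downstream end of the capillaries along
each pathway, flow-weighted as in its definition. The arterio-venous
saturation difference is SaO2 minus the flow-weighted mean SvO2 — a model
quantity, *not* the instrument-derived clinical optical-density ratio.
Threshold curves are volume-weighted hypoxic fractions on a 0–60 mmHg
grid (1 mmHg steps). Radial profiles are averaged over pathways both
unweighted (the headline curve; pathway averaging weights were never
specified, so the neutral choice is primary) and flow-weighted (for
sensitivity); network comparisons report curve separations at both r_c
and r_t, absolute and relative. Sweeps re-run the full pipeline per
condition; with regulation on, the tone is calibrated at the baseline
condition (M0 = 2, CD = 500) and the diameters re-equilibrate at the
perturbed condition. Capillary counts are assigned once from the
control-state flows and then held fixed; per-capillary flows track the
regulated terminal flows.

## Problem sizes

Oxygen-transport experiments run on desk-scale trees (12–24 terminals,
≤ ~100 segments, 5–20 k tissue cells at 60–90 µm spacing); a single
Green's solve takes seconds to tens of seconds on one CPU. The
capillary-distribution statistics use the full-scale presets (600–760
segments) through the flow stage only, which costs well under a minute.
These sizes are the package's supported regime; the Green's solver's
dense kernel matrices grow as (tissue cells × elements) and become the
memory bottleneck well before 10⁵ cells.

## Known limitations

- Synthetic geometry only; no image-derived networks, and generator
  length statistics are calibration choices.
- The conducted metabolic signal is a reconstruction (above).
- Free-space Green's kernel: no boundary reflections; near-source tissue
  cells can overshoot.
- Venous side is lumped; no venous networks, no venous oxygen uptake, no
  venous collapse, no IOP variation, no pulsatility.
- Capillary compartments are identical parallel vessels — no capillary
  network topology.
- Regulation is arteriolar only; capillaries and venules are fixed
  resistances.
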
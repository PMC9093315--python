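# Methods

`headeit` implements desk-scale electrical impedance tomography (EIT) of the
head: a complete-electrode-model finite-element forward solver on layered
phantoms, adjoint sensitivity matrices, nominal-conductivity calibration, and
difference imaging of conductivity change with both a one-step linearized
("traditional") solver and a nonlinear scheme solved by a regularised
Newton-Krylov GMRES method. This note records the models, the parameters
that matter, and the design decisions taken where the problem was genuinely
open.

## Phantom geometry and meshing

The phantom is a convex head-like solid: a hemisphere of outer radius R
(default 80 mm) on a cylindrical base of depth 0.35 R. Five concentric
shells — white matter, grey matter, CSF, skull, scalp, with default outer
radii 60/65/70/75/80 mm — are defined through the generalized radius
rho(p) = |p| above the equator and hypot(x, y) below it, and elements are
labelled by the shell containing their centroid. Meshing is Delaunay
tetrahedralization of a seeded point cloud (structured surface sampling plus
a jittered interior grid); because the solid is convex the Delaunay hull
fills it exactly up to surface facet chords. Meshes are deterministic per
seed, hit the requested element count within roughly ±30 %, and conserve the
analytic solid volume to better than 1 % at 20k elements.

Two consequences of desk scale are worth stating plainly. First, 5 mm
shells are thinner than the 8–19 mm mesh spacing of 5k–20k-element meshes,
so the skull and CSF layers are aliased: they form jagged,
single-element-thick shells rather than clean barriers. Second, electrode
patches consist of only one to a few boundary faces, so patch geometry
fluctuates between meshes. Both effects are treated as (realistic,
deliberate) modelling error: forward frames computed on differently meshed
instances of the same geometry disagree by a relative error of 0.1–0.35,
converging roughly linearly in mesh spacing. The nonlinear difference
method is designed precisely to survive this class of error, and the
localization study below exploits it by using different forward and inverse
meshes.

## Electrode model and layout

Electrodes are complete-electrode-model boundary patches with contact
impedance (default 1e-3 ohm.m^2, motivated by low-impedance scalp
electrodes; configurable). The 32-electrode layout is a shipped table of
unit directions approximating an extended 10–20-style arrangement: the
published array gives no coordinates, so the table was constructed once, by
constrained optimization, to satisfy the two properties the instrument
documentation states — all 20 injection pairs subtend more than 120 degrees
at the head centre ("nearly diametrically opposed"), and electrodes are
mutually separated by at least 16 degrees. Electrode 32 sits at the vertex.

The measurement frame is 20 current patterns (1 mA peak-to-peak, dwell
500 us, hence 100 frames/s) with voltages acquired between all numerically
adjacent non-injecting pairs (k, k+1), k = 1..31, without wrap-around —
the unique convention under which the shipped patterns yield exactly 546
measurements. The rejection of adjacent-but-not-neighbouring pairs is a
configuration file, not a derivation; under the shipped layout the
numbering discontinuities fall at pairs (17,18) and (31,32), whose
appearances across the patterns total exactly 37 measurements, leaving 509.

Simulation noise is zero-mean Gaussian per measurement with standard
deviation |v_i| x 10^(-SNR/20) (channel-referenced, matching how instrument
channel SNRs are quoted); full-scale-referenced noise is available as an
option.

## Forward model and sensitivities

Potentials use P1 tetrahedra with piecewise-constant conductivity; the
coupled node/electrode system is grounded by pinning one interior node
(measured voltage differences are invariant to the choice, and this is
asserted by test). One sparse LU factorization per conductivity field is
shared by all injection and adjoint solves of a frame. Voltages are rms
values of the sinusoidal drive: pk-pk amplitude divided by 2*sqrt(2).

The element Jacobian uses the adjoint formula J[m,e] = -int_e grad(u_drive)
. grad(u_meas) dx, costing one solve per pattern plus one per distinct
measurement pair; it is verified against central finite differences to
better than 1e-4. A subtlety: with fixed contact impedance the complete
electrode model is *not* homogeneous of degree -1 in the tissue
conductivities alone — scaling sigma by a does not scale U by 1/a, because
the contact admittances stay fixed. At the default contact impedance the
contact term carries roughly 7 % of the total sensitivity. The exact Euler
identity is J.sigma + J_kappa.kappa = -U(sigma), where J_kappa is the
contact-admittance sensitivity (also provided); this identity holds to
machine precision and is the form asserted in the acceptance suite. The
element-only identity J.sigma = -U is recovered in the shunt limit of
near-ideal electrodes.

## Calibration

Scalp and skull are the only tissues whose conductivity the boundary data
constrain well, so the calibration estimates those two grouped values by
Gauss-Newton on the per-tissue column-summed Jacobian, holding CSF, grey
and white matter fixed at literature values, with a near-zero identity
Tikhonov term (1e-10 of tr(J'J); the published procedure does not state its
regularisation) and a positivity projection (negative iterates are halved
toward zero). Noise-free closed-loop recovery is exact to machine
precision within ~5 iterations; the suite asserts 5 % in 15.

The per-volume scalp/skull sensitivity dominance over the brain (order
10x and more) emerges only when the shells are thick enough for the mesh to
resolve: on a thick-shell phantom (40/52/62/71/80 mm) the measured
dominance is ~11x (scalp) and ~44x (skull); on the thin default shells at
desk resolution it shrinks to ~3x because the aliased skull leaks.

## Difference imaging

Given a reference frame and a data frame, the traditional method solves
one linearized Tikhonov step dsigma = (J'J + lam R'R)^-1 J' dV at the
nominal conductivity sigma_N. The nonlinear method instead forms the
surrogate absolute target V~ = U(sigma_N) + dV and solves an absolute-style
problem for sigma~ by outer Gauss-Newton iterations started at sigma_N,
returning dsigma = sigma~ - sigma_N. Because the nominal prediction enters
both the target and the model side, the (large, unknowable) modelling error
of the head model largely cancels; the residual error term is ignored, as
it must be.

Numerical choices:

* R is the unnormalized first-difference operator over interior faces
  (+1/-1 per face); constant fields are in its null space.
* lam defaults to 1e-7 against this unnormalized prior ("absolute"
  scaling). With voltages in volts and desk-scale Jacobians this sits in a
  strongly smoothing regime (equivalent to a relative data/prior trace
  ratio of ~6), which is also where localization is best across a wide
  sweep; a "relative" scaling mode (lam x tr(J'J)/tr(R'R)) and an L-curve
  helper are provided for re-selection on other problems.
* Each Gauss-Newton step is solved by GMRES with Arnoldi (classical
  Gram-Schmidt with reorthogonalization, Givens-rotation least squares) on
  the operator v -> J'Jv + lam R'Rv; J'J is never materialized. Default
  subspace dimension 200, capped at the unknown count. Arnoldi breakdown
  returns the current best iterate with a flag.
* Skull elements are excluded from the update (their conductivity is held
  at the nominal value); scalp elements are updated, and scalp removal is a
  display/metrics step only.
* The Jacobian is refreshed at every outer iterate by default (a frozen
  mode exists). A backtracking step-length rule (scales 1, 1/2, ... 1/32)
  accepts the first non-increasing residual and flags floor exhaustion.
* Iterates are clipped at a 1e-4 S/m conductivity floor. Convergence is
  declared by iteration count (default 15); at desk scale the residual
  plateaus after ~4 outer iterations, so the shipped localization study
  stops at 6 and the synthetic-hemodynamics pipelines at 8.

## Localization study and metrics

The sphere-inclusion study embeds a 20 mm sphere of 0.65 S/m (blood) at
four intracranial locations (middle, front, left, right; ±35 mm offsets) in
a 12k-element forward phantom whose grey-matter and CSF conductivities are
set to the white-matter value (three-tissue simulation truth), simulates
509-measurement frames at SNR infinity, 70 dB and 50 dB (10 repeats each,
fixed seeds, noise independent in the inclusion and reference frames), and
reconstructs on a deliberately different 5k-element inverse phantom at the
five-value nominal conductivities. Reconstructions have the scalp removed,
are voxelized (default 3 mm for studies; 1.5 mm supported), and are scored
by the centre of gravity (CoG) of the positive part of dsigma — the
conductive-inclusion convention; absolute-value weighting is an option —
against the true centre.

Outcome at desk scale: the nonlinear method localizes all four inclusions
(no-noise errors 2–15 mm; 70 dB nearly identical; 50 dB roughly 2–6x worse
with much larger scatter between repeats), and all pairwise CoG separations
exceed 20 mm. The traditional method is consistently *worse* (no-noise
errors 5–17 mm) but does not collapse into indistinguishable images at this
scale: its published failure mode requires the nominal model's resolved
CSF/skull layers to suppress intracranial sensitivity in J(sigma_N), and a
desk-scale mesh cannot resolve those layers (see above). Passing the
nonlinear checks therefore demonstrates robustness to desk-scale mesh
mismatch, not the full-scale contrast between the methods.

## Synthetic hemodynamics

The REG (rheoencephalography) generator modulates three anterior
grey/white territories with a cardiac-like waveform — a Gaussian systolic
pulse with a quiescent diastole, normalized to zero mean over the cycle and
unit peak — at 1 % peak amplitude and 1 s period, forward-solving every
frame. The reference rule follows the measurement convention: the average
of the two frames ending 60 ms before the onset of the rapid voltage fall
(the onset, not the trough bottom — a reference at the trough would already
contain most of the modulation). Subsequent frame pairs are averaged to
halve the rate. On matched meshes the reconstructed peak grey/white change
recovers the injected 1 % almost exactly.

The THR (transient hyperemic response) generator superimposes a lateralized
slow change — default -20 % on the occluded side of the grey/white matter
and +5 % contralaterally, ramped over 0.5 s — on the cardiac modulation.
Difference images reconstructed from complete-cycle averages show
opposite-signed hemisphere means during occlusion, and the lateral contrast
collapses after release. Trough/fall instants are taken from generator
annotations; a minimum-finder convenience is deliberately not used for
scoring, since the underlying criterion is not algorithmically specified.

## What the synthetic studies do and do not show

The generators emulate the geometry of the measurement (frame structure,
channel-referenced noise, reference-frame rules) and first-order
physiology (conductivity rises with blood volume; occlusion lateralizes
the change). They do not emulate real electrode-skin behaviour, anisotropy,
subject anatomy, frequency-dependent admittivity, or physiological
variability between cycles; passing tests therefore validates the numerics
and the relative behaviour of the two reconstruction methods under
controlled modelling error, not clinical performance.

## Known limitations

* Shell aliasing at desk scale (discussed above) weakens the skull barrier
  and with it the full-scale traditional-method failure mode.
* Electrode patches of a few faces make per-measurement forward values
  converge slowly (linearly) under refinement.
* The voxelizer assigns voxel centres by exact containment per element;
  voxels whose centre falls in the negligible gaps left by surface sliver
  removal are zero.
* The L-curve corner picker uses a simple maximum-curvature rule and is a
  helper, not a robust selector.
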
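# Methods

`gmmrefine` implements single-particle cryo-EM pose refinement against
Gaussian-mixture references, together with focused refinement by Gaussian
width masking, patch-by-patch refinement with composite-map assembly, and
conformation-to-pose conversion for continuously moving domains.  This note
describes the model, the numerical choices, what the synthetic data
emulates, and the limits of what the tests show.

## Structure model and projection

A structure is a sum of N isotropic 3D Gaussians,

    M(x) = Σ_j A_j exp(−|x − c_j|² / 2σ_j²),

with centers `c_j` (Å, origin at the box center), amplitudes `A_j ≥ 0` and
widths `σ_j > 0` (Å).  Because the Fourier transform of a Gaussian is a
Gaussian, a 2D projection at pose (R, s) is available in closed form: in
units of pixels and cycles/pixel,

    F(k) = Σ_j A_j (2π)^{3/2} σ_j³ · exp(−2π²σ_j²|k|²) · exp(−2πi k·(b_j + s)),

where `b_j` is the in-plane part of `R c_j`.  No gridding interpolation is
used anywhere in alignment.  The factorization over kx/ky makes both the
projection and all of its parameter gradients dense matrix products, so the
whole optimization runs as exact closed-form gradients — the objective and
optimizer (Adam) match what an autodiff implementation would compute, to
floating-point precision (verified against central finite differences at
1e-4 relative tolerance).

Conventions: Euler angles are intrinsic ZYZ in degrees (`R = Rz(φ) Ry(θ)
Rz(ψ)`), shifts are in pixels and applied in Fourier space; Fourier images
are DC-centered with no 1/N normalization on the forward transform;
volumes are cubic with the real-space origin at voxel `n // 2`.

## The FRC objective

Alignment quality is the Fourier ring correlation between the analytic
projection and the (phase-flipped) particle image: per ring of width one
Fourier pixel, the normalized real part of the cross-correlation.  The loss
is the negative *unweighted* mean over rings in a band (DC excluded) —
rings are not weighted by their pixel population.  Ring-wise normalization
makes the score invariant to any ring-wise filtering of either image, which
is why CTF amplitude effects can be ignored once phases are flipped.
Zero-power rings are reported as 0, flagged, and excluded from the mean so
they cannot produce NaN gradients.

The band runs from ring 1 up to the ring of the previous iteration's
measured resolution, never beyond 0.9× Nyquist.  Internally the computation
is restricted to the centered Fourier sub-grid that contains the band
(exact, and roughly halves the cost at typical bands).

## Optimization and normalized coordinates

All searches use Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8).  Because Adam's
per-parameter step size equals the learning rate in the parameter's own
units, parameters are expressed in normalized coordinates before
optimization:

* rotations: a camera-frame *delta rotation vector* composed with the
  input pose, in units of full turns (1e-3 ≈ 0.36° per step).  The delta
  parameterization makes parameter distance equal to geodesic rotation
  angle; direct Euler optimization measurably under-recovers because Euler
  distance can be much larger than the true rotation (gimbal
  amplification).  Poses are converted back to ZYZ Euler angles for
  storage and STAR round-trips.
* shifts and Gaussian centers: fractions of the box size;
* amplitudes and widths: relative to their initial scale.

Per-particle pose refinement runs 10 Adam steps at learning rate 1e-3 per
outer iteration, with an accept-if-better safeguard (the best pose seen
along the trajectory, input included, is returned, so the loss never
increases).  A single 10-step pass covers roughly 1–2° and a quarter of a
pixel; full convergence is reached over the outer iterations of the
protocol (typically ≤ 5), which matches how the procedure is designed to
be run.  The conformation-to-pose conversion uses 30 steps at 1e-3 by
default; its optimum is reached to < 0.01° with ~100 steps.

GMM fitting to a map runs 40 epochs over 64 quasi-uniform orientations
(Fibonacci sphere with golden-ratio in-plane angles), minibatch 8, at
learning rate 1e-3 in the normalized coordinates above, with amplitudes
clipped to ≥ 0 and widths floored at 0.5 pixel after every step.  Width
masking or any other mask never enters the fit.  Reference projections of
the voxel map are central sections of a 2× padded FFT with cubic-spline
interpolation, accurate enough that a correct initialization is a fixed
point of the fit to well below a pixel.  (Adam drifts on the order of one
step size even at an optimum — it has no notion of convergence — so
"fixed point" means sub-pixel parameter movement, not bitwise stasis.)
The fit aborts with a diagnostic if the epoch loss increases five epochs
in a row.  Fit quality contract: average map-vs-rendered-model FSC > 0.9
over shells up to the target resolution.

## Seeding and N estimation

Map seeding clusters above-threshold voxels with value-weighted K-means;
atom seeding places one Gaussian per non-H atom, displaced by an isotropic
Gaussian with standard deviation = (gold-standard resolution)/3 — the
displacement law is a package choice, configurable, since only "randomized
at the determined resolution" is specified by the protocol.  Initial
amplitudes and widths are constants (width 1.5 pixel for map seeding, 1 Å
for atoms); a global least-squares amplitude scale against the map is
applied before fitting.  N is estimated by searching a geometric grid of
candidate N for the one whose seeded centers have mean nearest-neighbor
distance closest to the target resolution.

## Reconstruction and FSC

Direct Fourier inversion: each (phase-flipped) particle image is padded
2×, transformed, its in-plane shift removed, weighted by |CTF|, and
inserted as a central section into a 2× oversampled Fourier volume with
trilinear gridding; the accumulated weights use a Wiener-style denominator
Σ CTF² + ε with ε = 0.01 × the mean positive weight.  The oversampled grid
is then decimated back to the original Fourier grid (exact — equivalent to
folding the padded real-space box, whose out-of-box content is negligible
gridding residue; a hard real-space crop instead leaks low-frequency
gridding error into the weak high shells through the Dirichlet side lobes
of the crop window, which measurably corrupts high-resolution FSC).

Resolution is the gold-standard FSC between half maps at the 0.143
threshold (community standard; linearly interpolated crossing).  Shells
whose power is numerical dust (< 1e-24 of the maximum shell power) count
as empty.  Low-pass filtering uses a raised-cosine edge (half-width 2
shells; 0 gives a brick wall); sharpening rescales each shell's mean
amplitude to a reference radial profile, leaving zero-power shells
untouched with a warning.  Cyclic symmetry expansion multiplies the
particle table by N with `ψ → ψ + 360 m/N` (verified against rotation
matrix composition); reimposition averages z-rotated copies of the map,
optionally weighted by a rotated mask volume.

## Focused and patch-by-patch refinement

A region mask M ∈ [0, 1] broadens reference Gaussians whose centers fall
outside the mask (mask value < 0.999 at the center, trilinearly sampled):

    σ' = σ / (0.25 + 0.75 M)

— up to 4× at M = 0.  Centers and amplitudes are never modified: width
encodes local resolvability, not density.  The mask is applied to the GMM
*after* it is fitted to its half map, every iteration, and the same mask
is used for both half sets so patch FSC curves remain valid gold-standard
measures.  Global refinement is literally the focused loop without a mask,
so the K = 1 patch path is bitwise identical to global refinement at the
same seed.

Patches come from (unweighted) K-means on the Gaussian centers, K = 8 by
default; each patch gets a soft spherical mask centered on the cluster
centroid with radius = distance to the farthest member center (+1 voxel of
rasterization pad so that center still samples mask value 1), with a
5-pixel raised-cosine falloff.  A warning is issued for patches smaller
than 10 Å (below secondary-structure size).  Per patch, 3 focused
iterations; the per-patch half maps are merged voxel-wise as

    Map_composite = Σ_i Mask_i · Map_i / Σ_i Mask_i,

with voxels outside every mask set to 0 (warned).

## Conformation to pose conversion

A `ConformationSource` maps latent coordinates to a GaussianMixture, with
the latent origin decoding to the neutral model exactly.  The packaged
source is a parametric rigid-hinge decoder (latent z ∈ [−1, 1] rotates a
masked subset of Gaussians by z·max_angle about a hinge axis); any
external per-particle source with the same contract plugs in — training
such a source from images is out of scope here.  One independent source
per half set is enforced.

For each particle the conversion finds the pose θ_new minimizing the
masked RMSD between *projected Gaussian center coordinates* — the region
mask is per-Gaussian, so the center-coordinate reading is the one that
type-checks; an image-space variant is not needed for any result here.
Under this package's pose convention (image = projection of R·c) the
moving term must be the *neutral* model: minimize

    RMSD( (Project(conf, θ_init) − Project(neutral, θ_new)) · mask ),

which for a rigid region motion H yields R_new = R_init·H and immobilizes
the region at reconstruction.  The opposite assignment (neutral at
θ_init, conformed at θ_new) yields R_init·H⁻¹ and *doubles* the apparent
motion — easy to verify end-to-end and easy to get wrong, since which
reading is correct flips with the pose convention.  θ_new includes the
in-plane translation as free parameters (the in-plane part of the hinge's
translation component is exactly compensable; the beam-axis component is
not, leaving a small residual blur for hinges far from the origin).  The
objective at the returned pose never exceeds the objective at θ_init.

After conversion, focused refinement runs under the same region mask and
the result is treated as one patch for compositing.  Local-FSC
comparisons of converted reconstructions must use metric masks that do not
overlap the rest of the structure: the formerly rigid remainder moves in
the new frame, and its smearing contaminates any overlapping mask.

## Synthetic data

The simulator projects a known phantom at uniform (or listed) poses,
applies the CTF, and adds white Gaussian noise.  Defaults define the study
conditions:

* Phantoms are one or two ellipsoidal clusters of Gaussians.  For
  refinement studies at 1 Å/pixel, widths are atom-like (0.7–1.0 Å) so the
  Fourier signal extends toward Nyquist as it does for a real protein;
  with smooth (~2 Å) widths the outer rings of the FRC band are pure
  noise, and the mean-ring-FRC estimator cannot improve poses at any box
  size — ring count with signal is the quantity desk-scaling must
  preserve.
* CTF: standard phase-contrast formula (astigmatic defocus, Cs,
  relativistic wavelength, amplitude contrast 0.07, 300 kV).  The CTF is
  applied on a 2× padded grid and the image then cropped, so delocalized
  fringes genuinely leave the box instead of wrapping around
  (multiplication on the particle-size DFT grid is a circular convolution
  and corrupts the import-side resampling).  The default per-particle
  defocus range, 0.05–0.15 µm, is scaled down with the small box so that
  delocalization (≈ λ·Δz·k) stays inside it while still putting ~3 CTF
  zeros in band; phase flipping multiplies by sign(CTF) only and is
  guarded by an idempotence flag.
* SNR for particle images = (variance of the recorded, CTF-modulated
  image over its molecular support — |value| above 10% of the image
  maximum) / (noise variance); empirically recovered to within a few
  percent.  Half maps in the flexibility experiment instead use
  *whole-map* variance: their "average SNR" is a map-level statement, and
  the intensity-weighting effect that experiment exposes runs exactly
  through the smeared variant's lower map variance.
* The even/odd split is assigned alternately at simulation time and
  frozen; all randomness derives from one recorded seed, and reruns are
  bit-identical.

The flexibility/FSC-interpretation experiment renders, per half set, the
average of 10 structures in which every "atom" of a region is displaced in
a uniformly random direction by an exact distance d (Gaussian-magnitude
alternative available), adds noise at SNR 0.5, and compares unmasked FSC
curves between two displacement settings.  Distances are calibrated
through the attenuation of the exact-magnitude displacement model (first
sinc zero ⇒ local resolution ≈ 2d): core 1.5 Å (~3 Å), flexible 7.5 Å
(~15 Å) versus 3.5 Å (~7 Å).  The packaged test phantom keeps the two
domains fully separated (radius 7 Å, 24 Å apart, 60-pixel box) so the
flexible-region metric mask contains only the flexible domain.  The
exact-magnitude law produces sinc side lobes, so the "strictly worse local
FSC" comparison is made over the main-lobe shells.

What the synthetic data does not emulate: ice/solvent background,
beam-induced motion, amplitude falloff (B-factors), per-particle
magnification or defocus error, and non-rigid conformational change
beyond the rigid-hinge stand-in.  Passing tests therefore demonstrate the
correctness and qualitative behavior of the algorithms, not performance
on real micrograph-derived data.

## Problem sizes used by the packaged tests

Desk-scale runs were sized for a single CPU: the fit-quality contract uses
a 500-Gaussian phantom in a 96-pixel box; the pose-recovery study uses
4,000 particles (SNR 0.3, σ = 4°/1 px perturbations) of a 300-Gaussian
two-domain phantom in an 80-pixel box for 3 iterations; hinge-motion
studies use 600 particles at 64 pixels; identity checks run on 100–200
particles at 32–48 pixels.

## Known limitations

* The per-particle mean-ring-FRC estimator has a noise floor of a couple
  of degrees at SNR 0.3 on desk-scale boxes; refinement converges to that
  floor, not to zero error.
* Gimbal-degenerate poses (tilt near 0/180°) are handled by the delta
  parameterization during optimization but Euler round-trips at exact
  degeneracy collapse ψ into φ (the rotation itself is preserved).
* The reconstructor's gridding kernel (trilinear on a 2× grid) and CTF
  weighting are reasonable defaults, not matched to any particular
  external package.
* Only cyclic point groups are supported for symmetry operations.
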
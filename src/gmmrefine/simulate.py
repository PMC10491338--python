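"""Synthetic cryo-EM data: GMM phantoms, particle stacks with CTF and
noise, pose perturbations, and the flexibility/FSC illustration.

The particle simulator projects a known phantom at sampled poses, applies
the CTF by multiplication in Fourier space, and adds white Gaussian noise
calibrated so that

    SNR = (signal variance within the molecular support) / (noise variance)

where the molecular support of a particle is the set of pixels whose clean
(CTF-free) projection exceeds 10% of its maximum.  The even/odd half-set
split is assigned alternately and ground-truth poses are returned
separately.  All randomness flows from the single recorded seed.

The flexibility experiment reproduces a counter-intuitive property of
global FSC curves: each half map is the average of 10 renderings in which
every "atom" of a flexible region is displaced in a uniformly random
direction by a fixed distance (the distance controls local resolution),
plus noise at SNR 0.5; the *more* flexible variant can show an equal or
better unmasked global FSC because its smeared region carries less Fourier
weight, even though its local FSC in that region is strictly worse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .core import GaussianMixture, DensityMap, Pose, project, render_volume, freq_grid_1d
from .particles import ParticleSet, default_ctf_frame
from .reconstruct import FSCCurve, fsc
from . import io as fio


# ---------------------------------------------------------------------------
# phantoms


def random_phantom(n_gaussians: int = 300, seed: int = 0, n_domains: int = 2,
                   domain_radius: float = 11.0, separation: float = 13.0,
                   width_range: tuple = (1.6, 2.2),
                   amp_range: tuple = (0.7, 1.3)):
    """Protein-like phantom: ``n_domains`` ellipsoidal clusters of Gaussians.

    Returns ``(GaussianMixture, domain_labels)``.  Default geometry (two
    ~22 A domains separated along x) fits comfortably in a 64-pixel box at
    1 A/pixel.
    """
    rng = np.random.default_rng(seed)
    per = np.full(n_domains, n_gaussians // n_domains)
    per[: n_gaussians - per.sum()] += 1
    centers = []
    labels = []
    offs = (np.arange(n_domains) - (n_domains - 1) / 2.0) * separation
    for d in range(n_domains):
        c = rng.normal(0.0, domain_radius / 2.2, (per[d], 3))
        keep = np.linalg.norm(c, axis=1) < domain_radius
        while keep.sum() < per[d]:
            extra = rng.normal(0.0, domain_radius / 2.2, (per[d], 3))
            c = np.vstack([c[keep], extra])
            keep = np.linalg.norm(c, axis=1) < domain_radius
        c = c[keep][: per[d]]
        c[:, 0] += offs[d]
        centers.append(c)
        labels.append(np.full(per[d], d))
    centers = np.vstack(centers)
    labels = np.concatenate(labels)
    widths = rng.uniform(*width_range, n_gaussians)
    amps = rng.uniform(*amp_range, n_gaussians)
    return GaussianMixture(centers, amps, widths), labels


def two_domain_phantom(n_gaussians: int = 300, seed: int = 0):
    return random_phantom(n_gaussians=n_gaussians, seed=seed, n_domains=2)


def random_eulers(num: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform orientations on SO(3), as ZYZ Euler angles in degrees."""
    return Rotation.random(num, random_state=rng).as_euler("ZYZ", degrees=True)


def perturb_poses(eulers: np.ndarray, shifts: np.ndarray, angle: float,
                  shift: float, rng: np.random.Generator,
                  mode: str = "gaussian"):
    """Perturb poses by a random-axis rotation and a random-direction shift.

    mode="gaussian": rotation angle ~ N(0, angle) deg, shift components
    ~ N(0, shift/sqrt(2)) px (so the expected magnitude scale is ``shift``);
    mode="fixed": rotation angle = ``angle`` exactly, shift magnitude =
    ``shift`` exactly (random directions).
    """
    P = len(eulers)
    axes = rng.normal(size=(P, 3))
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    if mode == "gaussian":
        angs = rng.normal(0.0, angle, P)
        ds = rng.normal(0.0, shift / np.sqrt(2.0), (P, 2))
    elif mode == "fixed":
        angs = np.full(P, angle)
        phi = rng.uniform(0, 2 * np.pi, P)
        ds = shift * np.stack([np.cos(phi), np.sin(phi)], axis=1)
    else:
        raise ValueError(f"unknown perturbation mode {mode!r}")
    Rp = Rotation.from_rotvec(np.deg2rad(angs)[:, None] * axes)
    R0 = Rotation.from_euler("ZYZ", eulers, degrees=True)
    new_e = (Rp * R0).as_euler("ZYZ", degrees=True)
    return new_e, shifts + ds


def angular_error(eulers_a: np.ndarray, eulers_b: np.ndarray) -> np.ndarray:
    """Geodesic rotation distance (degrees) between two Euler sets."""
    Ra = Rotation.from_euler("ZYZ", np.atleast_2d(eulers_a), degrees=True)
    Rb = Rotation.from_euler("ZYZ", np.atleast_2d(eulers_b), degrees=True)
    return np.degrees((Ra * Rb.inv()).magnitude())


# ---------------------------------------------------------------------------
# particle simulation


@dataclass
class SimSpec:
    """Conditions for a simulated particle stack.

    phantom : the ground-truth GaussianMixture
    n_particles : stack size
    n / apix : box size (pixels) and pixel size (A/px)
    snr : signal-variance-over-support / noise-variance; np.inf disables noise
    pose_mode : "uniform" or "listed" (then ``eulers``/``shifts`` given)
    ctf : overrides for the default CTF parameter set
    defocus_range : per-particle defocus (A) drawn uniformly from this
        interval (zeros of the CTF then differ across particles, as in a
        real defocus series); the default is scaled down with the desk-
        scale box so CTF delocalization stays inside the particle box
        (delocalization ~ lambda * defocus * k must be << box radius)
    seed : master seed, recorded in the output
    """

    phantom: GaussianMixture
    n_particles: int = 1000
    n: int = 64
    apix: float = 1.0
    snr: float = 0.3
    pose_mode: str = "uniform"
    eulers: np.ndarray | None = None
    shifts: np.ndarray | None = None
    ctf: dict = field(default_factory=dict)
    defocus_range: tuple = (500.0, 1500.0)
    apply_ctf: bool = True
    support_frac: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.snr <= 0:
            raise ValueError("SNR must be positive")
        if self.n_particles < 1:
            raise ValueError("need at least one particle")


def simulate_particles(spec: SimSpec):
    """Simulate a particle stack; returns ``(ParticleSet, true_eulers,
    true_shifts)``.  The ParticleSet's pose columns hold the ground truth
    (callers typically perturb them before refining); images are *not*
    phase flipped."""
    rng = np.random.default_rng(spec.seed)
    n, apix, P = spec.n, spec.apix, spec.n_particles
    half_span = (n // 2 - 1) * apix
    if np.any(np.abs(spec.phantom.centers) > half_span):
        raise ValueError("box too small for the phantom")
    if spec.pose_mode == "uniform":
        eulers = random_eulers(P, rng)
        shifts = np.zeros((P, 2))
    elif spec.pose_mode == "listed":
        eulers = np.array(spec.eulers, dtype=np.float64)
        shifts = (np.zeros((P, 2)) if spec.shifts is None
                  else np.array(spec.shifts, dtype=np.float64))
    else:
        raise ValueError(f"unknown pose mode {spec.pose_mode!r}")

    ctf_frame = default_ctf_frame(P, **spec.ctf)
    if "defocus_u" not in spec.ctf:
        dz = rng.uniform(*spec.defocus_range, P)
        ctf_frame["defocus_u"] = dz
        ctf_frame["defocus_v"] = dz
    # CTF is applied on a 2x padded grid so delocalized fringes genuinely
    # leave (and are truncated by) the particle box instead of wrapping
    # around; small boxes therefore pair with small defocus defaults.
    npad = 2 * n
    pad_lo = npad // 2 - n // 2
    images = np.empty((P, n, n), dtype=np.float32)
    sig_vars = np.empty(P)
    for i in range(P):
        F = project(spec.phantom, Pose(eulers[i], shifts[i]), n, apix,
                    cdtype=np.complex128).data
        clean = np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(F))).real
        if spec.apply_ctf:
            Fp = project(spec.phantom, Pose(eulers[i], shifts[i]), npad, apix,
                         cdtype=np.complex128).data
            Fp *= fio.ctf_for_particle(npad, apix, ctf_frame.iloc[i])
            big = np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(Fp))).real
            images[i] = big[pad_lo:pad_lo + n, pad_lo:pad_lo + n]
        else:
            images[i] = clean
        # the signal whose variance defines the SNR is the recorded (CTF-
        # modulated) image, over its molecular support (|value| above a
        # fraction of the image maximum — same rule as measure_snr)
        img_sig = images[i]
        support = np.abs(img_sig) > spec.support_frac * np.abs(img_sig).max()
        sig_vars[i] = img_sig[support].var() if support.any() else img_sig.var()
    if np.isfinite(spec.snr):
        sigma = float(np.sqrt(sig_vars.mean() / spec.snr))
        images += rng.normal(0.0, sigma, images.shape).astype(np.float32)
    half = (np.arange(P) % 2).astype(np.int8)
    # without a CTF there is nothing to flip; mark the stack ready for FRC
    ps = ParticleSet(images, apix, eulers.copy(), shifts.copy(), ctf_frame,
                     half, phase_flipped=not spec.apply_ctf)
    return ps, eulers, shifts


def measure_snr(images: np.ndarray, clean: np.ndarray,
                support_frac: float = 0.1) -> float:
    """Empirical SNR of a noisy stack given the clean (CTF-modulated)
    images: mean support signal variance over residual noise variance."""
    noise = images - clean
    sig = []
    for i in range(len(clean)):
        s = np.abs(clean[i]) > support_frac * np.abs(clean[i]).max()
        sig.append(clean[i][s].var())
    return float(np.mean(sig) / noise.var())


def simulate_conformal_particles(source, latents: np.ndarray, spec: SimSpec):
    """Heterogeneous stack: particle i is a projection of ``source.decode
    (latents[i])`` instead of a single rigid phantom.

    ``spec.phantom`` provides the neutral structure for box checks; poses,
    CTF and noise follow the same conventions as
    :func:`simulate_particles`.  Returns ``(ParticleSet, eulers, shifts)``.
    """
    zs = np.asarray(latents, dtype=np.float64)
    if len(zs) != spec.n_particles:
        raise ValueError("one latent per particle required")
    base = spec.phantom
    out_imgs = None
    rng = np.random.default_rng(spec.seed)
    n, apix, P = spec.n, spec.apix, spec.n_particles
    eulers = random_eulers(P, rng) if spec.pose_mode == "uniform" \
        else np.array(spec.eulers, dtype=np.float64)
    shifts = np.zeros((P, 2)) if spec.shifts is None \
        else np.array(spec.shifts, dtype=np.float64)
    ctf_frame = default_ctf_frame(P, **spec.ctf)
    if "defocus_u" not in spec.ctf:
        dz = rng.uniform(*spec.defocus_range, P)
        ctf_frame["defocus_u"] = dz
        ctf_frame["defocus_v"] = dz
    npad = 2 * n
    pad_lo = npad // 2 - n // 2
    images = np.empty((P, n, n), dtype=np.float32)
    sig_vars = np.empty(P)
    for i in range(P):
        gmm_i = source.decode(zs[i])
        if spec.apply_ctf:
            Fp = project(gmm_i, Pose(eulers[i], shifts[i]), npad, apix).data
            Fp *= fio.ctf_for_particle(npad, apix, ctf_frame.iloc[i])
            big = np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(Fp))).real
            images[i] = big[pad_lo:pad_lo + n, pad_lo:pad_lo + n]
        else:
            F = project(gmm_i, Pose(eulers[i], shifts[i]), n, apix).data
            images[i] = np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(F))).real
        img = images[i]
        support = np.abs(img) > spec.support_frac * np.abs(img).max()
        sig_vars[i] = img[support].var() if support.any() else img.var()
    if np.isfinite(spec.snr):
        sigma = float(np.sqrt(sig_vars.mean() / spec.snr))
        images += rng.normal(0.0, sigma, images.shape).astype(np.float32)
    half = (np.arange(P) % 2).astype(np.int8)
    ps = ParticleSet(images, apix, eulers.copy(), shifts.copy(), ctf_frame,
                     half, phase_flipped=not spec.apply_ctf)
    return ps, eulers, shifts


# ---------------------------------------------------------------------------
# the flexibility / FSC interpretation experiment


@dataclass
class FlexSpec:
    """One flexibility setting for the FSC-interpretation experiment.

    coords : (M, 3) "atom" positions (e.g. phantom Gaussian centers)
    region_labels : (M,) integer region id per atom
    displacement : {region id: distance in Angstrom}; each realization
        shifts every atom of the region in a uniformly random direction by
        exactly that distance
    maps_per_half : renderings averaged per half map (10)
    snr : noise level of the half maps (0.5)
    width / amplitude : rendering Gaussian parameters
    """

    coords: np.ndarray
    region_labels: np.ndarray
    displacement: dict
    n: int = 64
    apix: float = 1.0
    maps_per_half: int = 10
    snr: float = 0.5
    width: float = 1.5
    amplitude: float = 1.0
    support_frac: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if any(d < 0 for d in self.displacement.values()):
            raise ValueError("displacements must be >= 0")


def _random_unit_vectors(num: int, rng) -> np.ndarray:
    v = rng.normal(size=(num, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def flexibility_half_maps(spec: FlexSpec) -> tuple[DensityMap, DensityMap]:
    """Averaged, noisy half maps under the displacement model."""
    rng = np.random.default_rng(spec.seed)
    coords = np.asarray(spec.coords, dtype=np.float64)
    labels = np.asarray(spec.region_labels)
    M = len(coords)
    halves = []
    for h in range(2):
        acc = np.zeros((spec.n,) * 3)
        for _ in range(spec.maps_per_half):
            shifted = coords.copy()
            for region, dist in spec.displacement.items():
                sel = labels == region
                if dist > 0 and sel.any():
                    shifted[sel] += dist * _random_unit_vectors(sel.sum(), rng)
            g = GaussianMixture(shifted, np.full(M, spec.amplitude),
                                np.full(M, spec.width))
            acc += render_volume(g, spec.n, spec.apix, dtype=np.float32).data
        acc /= spec.maps_per_half
        # half-map noise is calibrated against the *whole-map* variance:
        # a variant whose flexible density is smeared out has genuinely
        # lower signal variance and therefore receives less noise at the
        # same average SNR — the intensity-weighting effect the experiment
        # is designed to expose
        sigma = np.sqrt(acc.var() / spec.snr)
        acc = acc + rng.normal(0.0, sigma, acc.shape)
        halves.append(DensityMap(acc, spec.apix))
    return halves[0], halves[1]


def flexibility_fsc_experiment(spec_a: FlexSpec, spec_b: FlexSpec):
    """Unmasked gold-standard FSC curves for two flexibility settings.

    Returns ``(curve_a, curve_b, (maps_a, maps_b))`` — the two-sided
    comparison the experiment is about (e.g. large vs moderate flexible-
    region displacement)."""
    maps_a = flexibility_half_maps(spec_a)
    maps_b = flexibility_half_maps(spec_b)
    return fsc(*maps_a), fsc(*maps_b), (maps_a, maps_b)
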
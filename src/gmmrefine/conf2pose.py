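"""Convert per-particle conformational states into pose changes.

Within a small enough region a conformational change looks like a rigid
motion, so instead of deforming the map we can change the frame of
reference: for each particle we find the pose theta_new at which the
*conformed* GMM's target region projects onto the same 2D positions as the
neutral GMM's region at the particle's original pose, by minimizing the
masked RMSD between the projected Gaussian center coordinates

    RMSD( (Project(GMM_neutral, theta_init) - Project(GMM_conf, theta_new)) * mask )

over 30 Adam iterations at learning rate 1e-3 (normalized pose
coordinates), starting from theta_new = theta_init.  Reconstructing all
particles at their new poses immobilizes the target region (and smears the
rest), after which focused refinement under the same region mask sharpens
it further.

The per-particle conformations come from a decoder satisfying the
ConformationSource contract: latent coordinates -> GaussianMixture, with
the latent origin decoding to the neutral GMM exactly.  A rigid-hinge
stand-in decoder is provided; any external source (e.g. a trained neural
decoder) with the same contract plugs in.  One independent source per half
set keeps the gold standard intact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .core import GaussianMixture, DensityMap, Pose, _dR_deuler
from .optim import Adam
from .particles import ParticleSet, EVEN, ODD


def _check_gaussian_mask(mask: np.ndarray, n: int) -> np.ndarray:
    m = np.asarray(mask, dtype=bool).ravel()
    if m.shape != (n,):
        raise ValueError("mask length must equal the number of Gaussians")
    if not m.any():
        raise ValueError("Gaussian mask selects no Gaussians")
    return m


@dataclass
class StandinDecoder:
    """Parametric conformation source: a rigid hinge rotation of the masked
    region.

    Latent scalar z in [-1, 1] maps to a rotation of the masked Gaussians
    by ``z * max_angle`` degrees about the axis through ``hinge_point``
    along ``hinge_axis``; z = 0 returns the neutral GMM exactly, and
    unmasked Gaussians never move.
    """

    neutral: GaussianMixture
    region: np.ndarray
    hinge_point: np.ndarray
    hinge_axis: np.ndarray
    max_angle: float
    half: int | None = None

    def __post_init__(self):
        self.region = _check_gaussian_mask(self.region, len(self.neutral))
        self.hinge_point = np.asarray(self.hinge_point, dtype=np.float64)
        axis = np.asarray(self.hinge_axis, dtype=np.float64)
        nrm = np.linalg.norm(axis)
        if nrm == 0 or not np.all(np.isfinite(axis)):
            raise ValueError("invalid hinge axis")
        self.hinge_axis = axis / nrm

    def decode(self, z: float) -> GaussianMixture:
        z = float(np.atleast_1d(z)[0])
        out = self.neutral.copy()
        if z == 0.0:
            return out
        R = Rotation.from_rotvec(np.deg2rad(z * self.max_angle) * self.hinge_axis)
        sel = self.region
        out.centers[sel] = self.hinge_point + R.apply(out.centers[sel] - self.hinge_point)
        return out


def projected_region_rmsd(neutral: GaussianMixture, conf: GaussianMixture,
                          theta_init: Pose, theta_new: Pose,
                          mask: np.ndarray, apix: float = 1.0) -> float:
    """Masked projected-center RMSD (pixels): the conformed region at
    theta_init versus the neutral region at theta_new — the quantity the
    conversion minimizes."""
    m = _check_gaussian_mask(mask, len(neutral))
    u = (conf.centers[m] / apix) @ theta_init.rotation_matrix().T
    u = u[:, :2] + theta_init.shift
    v = (neutral.centers[m] / apix) @ theta_new.rotation_matrix().T
    v = v[:, :2] + theta_new.shift
    return float(np.sqrt(np.mean(np.sum((u - v) ** 2, axis=1))))


def convert_conformation_to_pose(neutral: GaussianMixture, conf: GaussianMixture,
                                 theta_init: Pose, mask: np.ndarray,
                                 iterations: int = 30, learning_rate: float = 1e-3,
                                 apix: float = 1.0, box_size: int | None = None,
                                 optimize_shift: bool = True) -> Pose:
    """Pose minimizing the masked projected-center RMSD (see module doc).

    Gradients of the mean squared deviation are analytic (the projection of
    a center is linear in the rotation matrix); Adam runs in normalized
    pose coordinates starting at theta_init.  The returned pose never has a
    higher objective than theta_init.
    """
    if len(neutral) != len(conf):
        raise ValueError("neutral and conformed GMM must share N (Gaussian correspondence)")
    m = _check_gaussian_mask(mask, len(neutral))
    n_box = box_size if box_size is not None else 100
    # The particle's image shows the *conformed* region at theta_init; the
    # new pose makes the *neutral* region project onto those positions, so
    # reconstructing at theta_new immobilizes the region in the neutral
    # frame.  (Which of the two GMMs moves in the objective is fixed by the
    # pose convention: here image = projection of R c.)
    u = (conf.centers[m] / apix) @ theta_init.rotation_matrix().T
    u = u[:, :2] + theta_init.shift  # target 2D coords, pixels
    c = neutral.centers[m] / apix
    M = len(c)

    # camera-frame delta rotation vector (turns) composed with theta_init,
    # shift in box fractions — same normalized coordinates as pose refinement
    R0 = theta_init.rotation_matrix()
    rv = np.zeros(3)
    ps = theta_init.shift.copy() / n_box
    opt = Adam(lr=learning_rate)
    best = (np.inf, R0.copy(), theta_init.shift.copy())
    two_pi = 2.0 * np.pi
    for it in range(iterations + 1):
        R = Rotation.from_rotvec(rv * two_pi).as_matrix() @ R0
        sh = ps * n_box
        a = c @ R.T  # rotated conf centers (M, 3)
        v = a[:, :2] + sh
        d = v - u  # (M, 2)
        mse = float(np.mean(np.sum(d ** 2, axis=1)))
        if mse < best[0]:
            best = (mse, R.copy(), sh.copy())
        if it == iterations:
            break
        # d(v)/d(delta rotation about camera axes): cross-product rows
        grv = np.array([
            -np.sum(d[:, 1] * a[:, 2]),
            np.sum(d[:, 0] * a[:, 2]),
            np.sum(-d[:, 0] * a[:, 1] + d[:, 1] * a[:, 0]),
        ]) * (2.0 / M)
        gs = 2.0 * d.mean(axis=0)
        grads = {"rv": grv * two_pi}
        params = {"rv": rv}
        if optimize_shift:
            grads["shift"] = gs * n_box
            params["shift"] = ps
        opt.step(params, grads)
    eul = Rotation.from_matrix(best[1]).as_euler("ZYZ", degrees=True)
    return Pose(eul, best[2])


def hetero_to_pose_pipeline(even: ParticleSet, odd: ParticleSet,
                            sources: dict, latents: dict, mask: np.ndarray,
                            region_mask_volume: DensityMap, n_gaussians: int,
                            focused_iterations: int = 3, seed: int = 0,
                            audit=None, conf_iterations: int = 30,
                            learning_rate: float = 1e-3, **kwargs):
    """Decode each particle's conformation, convert it to a pose, then run
    focused refinement on the target region.

    sources: {half: ConformationSource}; latents: {half: (P_half,) array}.
    Each half only ever sees its own decoder (enforced).
    Returns the focused RefinementState (its half_maps are the output).
    """
    from .focused import run_focused_refinement

    halves = {EVEN: even, ODD: odd}
    converted = {}
    for h in sorted(halves):
        src = sources[h]
        if getattr(src, "half", None) is not None and src.half != h:
            raise ValueError("gold-standard violation: decoder from the wrong half set")
        if audit is not None:
            audit.record_alignment(getattr(src, "half", h) if getattr(src, "half", None)
                                   is not None else h, h)
        ps = halves[h]
        zs = np.asarray(latents[h], dtype=np.float64)
        if len(zs) != len(ps):
            raise ValueError("one latent per particle required")
        neutral = src.decode(0.0)
        eulers = np.empty_like(ps.eulers)
        shifts = np.empty_like(ps.shifts)
        for i in range(len(ps)):
            conf = src.decode(zs[i])
            pose = convert_conformation_to_pose(
                neutral, conf, Pose(ps.eulers[i], ps.shifts[i]), mask,
                iterations=conf_iterations, learning_rate=learning_rate,
                apix=ps.apix, box_size=ps.n)
            eulers[i] = pose.euler
            shifts[i] = pose.shift
        converted[h] = ps.with_poses(eulers, shifts)
    state = run_focused_refinement(converted[EVEN], converted[ODD], n_gaussians,
                                   iterations=focused_iterations,
                                   mask=region_mask_volume, seed=seed,
                                   audit=audit, **kwargs)
    state.converted_poses = {h: (converted[h].eulers, converted[h].shifts)
                             for h in converted}
    return state
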
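"""Focused refinement via Gaussian-width masking, K-means patch
segmentation, spherical soft masks and composite-map assembly.

Focusing works by *broadening* reference Gaussians outside a region mask:
for mask value M at a Gaussian's center, the width becomes

    sigma' = sigma / (0.25 + 0.75 M)

(up to 4x at M = 0), which lowers the effective local resolution of the
reference outside the region so the alignment is driven by the features
inside it, while amplitudes — hence low-resolution constraints — are kept.
The broadening is applied only to Gaussians whose centers fall outside the
mask (mask value < 0.999), so the reference keeps soft boundaries even
under a sharp mask.

Patch-by-patch refinement segments the GMM into K patches (K-means on the
centers, K = 8 by default), focus-refines each patch for 3 iterations under
its spherical mask (radius = farthest member Gaussian, 5-pixel raised-
cosine falloff; the same mask for both half sets), and merges the per-patch
reconstructions by mask-weighted averaging:

    Map_composite = sum_i Mask_i * Map_i / sum_i Mask_i .
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.cluster import KMeans

from .core import GaussianMixture, DensityMap
from .particles import ParticleSet, EVEN, ODD
from .reconstruct import backproject, fsc, resolution_at, lowpass, fft2_centered_stack


def _check_mask(mask: np.ndarray) -> None:
    if mask.min() < 0.0 or mask.max() > 1.0 + 1e-9:
        raise ValueError("mask values must lie in [0, 1]")


def sample_mask_at(mask: DensityMap, points: np.ndarray) -> np.ndarray:
    """Trilinear mask value at physical points (Angstrom, box-center origin)."""
    half = mask.n // 2
    vox = np.asarray(points) / mask.apix + half  # (N, 3) in (x, y, z) voxels
    coords = vox[:, ::-1].T  # array axes are [z, y, x]
    return ndimage.map_coordinates(mask.data.astype(np.float64), coords,
                                   order=1, mode="constant")


def apply_width_mask(gmm: GaussianMixture, mask: DensityMap,
                     inside_level: float = 0.999) -> GaussianMixture:
    """Broaden Gaussians outside the mask: sigma' = sigma/(0.25 + 0.75 M).

    Centers and amplitudes are never modified (broadening encodes lower
    local resolution, not lower density); Gaussians whose centers lie
    inside the mask (M >= ``inside_level``) keep their width exactly.
    """
    _check_mask(mask.data)
    m = sample_mask_at(mask, gmm.centers)
    outside = m < inside_level
    widths = gmm.widths.copy()
    widths[outside] = gmm.widths[outside] / (0.25 + 0.75 * m[outside])
    return GaussianMixture(gmm.centers.copy(), gmm.amplitudes.copy(), widths)


def spherical_mask(n: int, apix: float, center: np.ndarray, radius: float,
                   falloff_px: float = 5.0) -> DensityMap:
    """Soft sphere: 1 inside ``radius``, raised-cosine falloff over
    ``falloff_px`` pixels, 0 beyond."""
    half = n // 2
    ax = (np.arange(n) - half) * apix
    cz, cy, cx = center[2], center[1], center[0]
    r = np.sqrt((ax[:, None, None] - cz) ** 2 + (ax[None, :, None] - cy) ** 2 +
                (ax[None, None, :] - cx) ** 2)
    fall = falloff_px * apix
    m = np.zeros((n, n, n))
    m[r <= radius] = 1.0
    edge = (r > radius) & (r < radius + fall)
    m[edge] = 0.5 * (1.0 + np.cos(np.pi * (r[edge] - radius) / fall))
    return DensityMap(m, apix)


@dataclass
class PatchSet:
    """K-means segmentation of a GMM with per-patch spherical soft masks."""
    labels: np.ndarray                 # (N,) patch index per Gaussian
    masks: list                        # per-patch DensityMap
    centers: np.ndarray                # (K, 3) patch centers, Angstrom
    radii: np.ndarray                  # (K,) Angstrom (pre-falloff)

    @property
    def k(self) -> int:
        return len(self.masks)


def segment_patches(gmm: GaussianMixture, n: int, apix: float, k: int = 8,
                    seed: int = 0, falloff_px: float = 5.0,
                    min_radius_warn: float = 10.0) -> PatchSet:
    """K-means on the Gaussian centers (unweighted); one spherical mask per
    patch covering all its member centers."""
    if k > len(gmm):
        raise ValueError("more patches than Gaussians")
    if k == 1:
        labels = np.zeros(len(gmm), dtype=int)
        centers = gmm.centers.mean(axis=0, keepdims=True)
    else:
        for attempt in range(2):
            km = KMeans(n_clusters=k, n_init=1, random_state=seed + attempt)
            labels = km.fit_predict(gmm.centers)
            if len(np.unique(labels)) == k:
                centers = km.cluster_centers_
                break
        else:
            raise RuntimeError("empty patch after K-means re-seed")
    radii = np.empty(k)
    masks = []
    for i in range(k):
        pts = gmm.centers[labels == i]
        radii[i] = float(np.linalg.norm(pts - centers[i], axis=1).max())
        if radii[i] < min_radius_warn:
            warnings.warn(f"patch {i} radius {radii[i]:.1f} A is smaller than a "
                          "single secondary-structure element; alignment may be noisy")
        # one-voxel rasterization pad so the farthest member center still
        # samples mask value 1 under trilinear interpolation
        masks.append(spherical_mask(n, apix, centers[i], radii[i] + apix,
                                    falloff_px))
    return PatchSet(labels, masks, np.atleast_2d(centers), radii)


def composite(maps: list, patch_masks: PatchSet | list) -> DensityMap:
    """Voxel-wise mask-weighted average of per-patch maps; voxels outside
    every mask are set to 0 (with a warning)."""
    masks = patch_masks.masks if isinstance(patch_masks, PatchSet) else patch_masks
    if len(maps) != len(masks):
        raise ValueError("one map per patch mask required")
    ref = maps[0]
    num = np.zeros_like(ref.data, dtype=np.float64)
    den = np.zeros_like(ref.data, dtype=np.float64)
    for m, msk in zip(maps, masks):
        if m.data.shape != ref.data.shape or msk.data.shape != ref.data.shape:
            raise ValueError("grid mismatch between maps/masks")
        num += msk.data * m.data
        den += msk.data
    uncovered = den <= 0
    if np.any(uncovered):
        warnings.warn("composite: voxels outside all patch masks set to 0")
    out = np.where(uncovered, 0.0, num / np.where(uncovered, 1.0, den))
    return DensityMap(out, ref.apix)


# ---------------------------------------------------------------------------
# the focused refinement loop (also the engine behind global refinement)


def run_focused_refinement(even: ParticleSet, odd: ParticleSet, n_gaussians: int,
                           iterations: int = 3, mask: DensityMap | None = None,
                           seed: int = 0, audit=None, fit_epochs: int = 40,
                           n_projections: int = 64,
                           iterations_per_particle: int = 10,
                           learning_rate: float = 1e-3,
                           stop_on_convergence: bool = False,
                           chunk: int = 256,
                           initial_state=None):
    """Iterative gold-standard refinement; ``mask=None`` is global
    refinement, otherwise the width mask is applied to each half's GMM
    after it is fitted to its half map.

    Returns a RefinementState whose ``half_maps`` are the final unmasked,
    unfiltered reconstructions.
    """
    from .refine import (RefinementState, build_half_gmm, refine_poses_batch,
                         HalfReference)
    from .core import default_band

    if not even.phase_flipped or not odd.phase_flipped:
        raise ValueError("particles must be phase flipped before FRC alignment")
    halves = {EVEN: even, ODD: odd}
    for h, ps in halves.items():
        lbl = np.unique(np.asarray(ps.half))
        if len(lbl) != 1 or lbl[0] != h:
            raise ValueError("gold-standard violation: half-set argument mismatch")
    if mask is not None:
        _check_mask(mask.data)
    n = even.n
    apix = even.apix

    state = RefinementState() if initial_state is None else initial_state
    poses = {h: (halves[h].eulers.copy(), halves[h].shifts.copy()) for h in halves}
    part_F = {h: fft2_centered_stack(halves[h].images.astype(np.float64)).astype(np.complex64)
              for h in halves}

    # iteration 0: reconstruct at input poses, measure starting resolution
    maps = {}
    for h in sorted(halves):
        if audit is not None:
            audit.record_alignment(h, h)
        maps[h] = backproject(halves[h], poses[h][0], poses[h][1])
    curve = fsc(maps[EVEN], maps[ODD])
    res = resolution_at(curve)
    state.fsc_history.append(curve)
    state.resolutions.append(res)
    state.half_maps = maps

    for it in range(1, iterations + 1):
        band_hi = min(int(round(n * apix / res)), int(0.9 * (n // 2)))
        band = default_band(n, max(band_hi, 2))
        new_maps = {}
        for h in sorted(halves):
            lp = lowpass(maps[h], max(res, 2.0 * apix + 1e-9))
            gmm = build_half_gmm(lp, n_gaussians, h, it, seed,
                                 fit_epochs=fit_epochs, n_projections=n_projections,
                                 audit=audit)
            state.gmms[h] = gmm
            ref = gmm if mask is None else apply_width_mask(gmm, mask)
            if audit is not None:
                audit.record_alignment(h, h)
            e, s, l0, l1 = refine_poses_batch(ref, part_F[h], poses[h][0],
                                              poses[h][1], apix,
                                              iterations=iterations_per_particle,
                                              learning_rate=learning_rate,
                                              band=band, chunk=chunk)
            poses[h] = (e, s)
            new_maps[h] = backproject(halves[h], e, s)
        maps = new_maps
        curve = fsc(maps[EVEN], maps[ODD])
        new_res = resolution_at(curve)
        state.iteration = it
        state.fsc_history.append(curve)
        state.resolutions.append(new_res)
        state.half_maps = maps
        state.poses = poses
        if stop_on_convergence and new_res >= res:
            res = new_res
            break
        res = new_res
    state.poses = poses
    return state


def run_patch_refinement(even: ParticleSet, odd: ParticleSet, gmm: GaussianMixture,
                         n_gaussians: int, k: int = 8, iterations: int = 3,
                         seed: int = 0, audit=None, **kwargs):
    """Patch-by-patch refinement: segment ``gmm`` into K patches, run the
    focused loop per patch (same mask for both halves), composite per half.

    Returns ``(composite_even, composite_odd, patches, states)``.
    """
    n, apix = even.n, even.apix
    patches = segment_patches(gmm, n, apix, k=k, seed=seed)
    states = []
    maps_e, maps_o = [], []
    for i, msk in enumerate(patches.masks):
        st = run_focused_refinement(even, odd, n_gaussians, iterations=iterations,
                                    mask=msk, seed=seed, audit=audit, **kwargs)
        states.append(st)
        maps_e.append(st.half_maps[EVEN])
        maps_o.append(st.half_maps[ODD])
    comp_e = composite(maps_e, patches)
    comp_o = composite(maps_o, patches)
    return comp_e, comp_o, patches, states
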
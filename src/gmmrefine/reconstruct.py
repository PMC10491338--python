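"""Voxel-space reconstruction by direct Fourier inversion, FSC measurement,
filtering, sharpening and cyclic symmetry operations.

Each particle's 2D Fourier transform is a central section of the 3D
transform of the structure (projection-slice theorem).  Reconstruction
inserts every section into the 3D Fourier volume with trilinear gridding
and per-voxel weight accumulation; phase-flipped particles are inserted
with |CTF| weighting and a Wiener-style denominator sum(CTF^2) + eps.

Resolution is the "gold-standard" Fourier shell correlation between two
independently refined half maps, read off at the 0.143 threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .core import (DensityMap, FourierImage, Pose, freq_grid_1d, shell_indices)
from .particles import ParticleSet
from . import io as fio


@dataclass
class FSCCurve:
    values: np.ndarray
    apix: float
    n: int

    @property
    def freq(self) -> np.ndarray:
        return np.arange(len(self.values)) / (self.n * self.apix)


# ---------------------------------------------------------------------------
# Fourier helpers


def fft3_centered(vol: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(vol)))


def ifft3_centered(F: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(F))).real


def fft2_centered_stack(imgs: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(imgs, axes=(-2, -1))), axes=(-2, -1))


def map_slice(F3: np.ndarray, R: np.ndarray, n: int | None = None,
              order: int = 1, prefiltered: bool = False) -> np.ndarray:
    """Central section of a DC-centered 3D Fourier volume at rotation R
    (trilinear interpolation); the section matches the analytic projection
    convention of :func:`gmmrefine.core.project`.

    ``F3`` may be the transform of a padded (oversampled) copy of the map;
    pass the original box size as ``n`` and the interpolation error drops
    quadratically with the padding factor.
    """
    no = F3.shape[0]
    if n is None:
        n = no
    k = freq_grid_1d(n)
    kx, ky = np.meshgrid(k, k)
    k3 = np.stack([kx.ravel(), ky.ravel(), np.zeros(kx.size)])  # (3, npix)
    q = R.T @ k3  # object-frame frequency, cycles per original pixel
    coords = q[::-1] * no + no // 2  # array axes are [z, y, x]
    re = ndimage.map_coordinates(F3.real, coords, order=order,
                                 prefilter=not prefiltered, mode="constant")
    im = ndimage.map_coordinates(F3.imag, coords, order=order,
                                 prefilter=not prefiltered, mode="constant")
    return (re + 1j * im).reshape(n, n)


def padded_fft3(vol: np.ndarray, oversample: int = 2) -> np.ndarray:
    """DC-centered 3D FFT of the volume zero-padded by ``oversample``."""
    n = vol.shape[0]
    no = n * oversample
    big = np.zeros((no, no, no), dtype=np.float64)
    lo = no // 2 - n // 2
    big[lo:lo + n, lo:lo + n, lo:lo + n] = vol
    return fft3_centered(big)


# ---------------------------------------------------------------------------
# backprojection


def backproject(particles: ParticleSet, eulers: np.ndarray | None = None,
                shifts: np.ndarray | None = None, ctf_weighting: bool = True,
                chunk: int = 128, eps_frac: float = 0.01,
                oversample: int = 2) -> DensityMap:
    """Direct Fourier inversion of a (single-half-set) particle stack.

    Slices are inserted with trilinear gridding into an ``oversample``-times
    finer Fourier grid (i.e. a padded box) to keep interpolation error low,
    then cropped back to the original box in real space.

    Raises if the stack mixes half-set labels — reconstructing across the
    gold-standard split is never allowed.
    """
    halves = np.unique(np.asarray(particles.half))
    if len(halves) > 1:
        raise ValueError("gold-standard violation: backproject received particles "
                         "from both half sets")
    n = particles.n
    P = len(particles)
    eulers = particles.eulers if eulers is None else np.asarray(eulers)
    shifts = particles.shifts if shifts is None else np.asarray(shifts)
    if len(eulers) != P or len(shifts) != P:
        raise ValueError("pose arrays must match the number of particles")

    no = n * oversample
    # pad images so the 2D Fourier sampling matches the oversampled 3D grid
    k = freq_grid_1d(no)  # cycles per (original-size) pixel
    kx, ky = np.meshgrid(k, k)
    keep = (kx ** 2 + ky ** 2) <= 0.25  # Nyquist disk
    k3 = np.stack([kx[keep], ky[keep], np.zeros(np.count_nonzero(keep))])  # (3, M)
    M = k3.shape[1]
    num_re = np.zeros(no ** 3)
    num_im = np.zeros(no ** 3)
    den = np.zeros(no ** 3)
    pad_lo = no // 2 - n // 2

    for lo in range(0, P, chunk):
        hi = min(lo + chunk, P)
        B = hi - lo
        imgs = np.zeros((B, no, no))
        imgs[:, pad_lo:pad_lo + n, pad_lo:pad_lo + n] = \
            particles.images[lo:hi].astype(np.float64)
        F2 = fft2_centered_stack(imgs)
        # undo the in-plane shift so every section is centered
        ph = np.exp((2j * np.pi) * (kx[None] * shifts[lo:hi, 0, None, None] +
                                    ky[None] * shifts[lo:hi, 1, None, None]))
        F2 = F2 * ph
        vals = F2.reshape(B, -1)[:, keep.ravel()]
        if ctf_weighting:
            cw = fio.ctf_stack(no, particles.apix, particles.ctf,
                               np.arange(lo, hi)).astype(np.float64)
            cw = cw.reshape(B, -1)[:, keep.ravel()]
            vals = vals * np.abs(cw)
            wts = cw ** 2
        else:
            wts = np.ones((B, M))
        Rs = Rotation.from_euler("ZYZ", eulers[lo:hi], degrees=True).as_matrix()
        q = np.einsum("bji,jm->bim", Rs, k3)  # R^T k3 -> (B, 3, M)
        _scatter_trilinear(q, vals, wts, no, num_re, num_im, den)

    den_pos = den[den > 0]
    eps = eps_frac * (den_pos.mean() if den_pos.size else 1.0)
    F3 = ((num_re + 1j * num_im) / (den + eps)).reshape(no, no, no)
    if oversample > 1:
        # decimate back to the original Fourier grid (exact; equivalent to
        # folding the padded real-space box, whose out-of-box content is
        # negligible gridding residue)
        start = (no // 2) % oversample
        F3 = F3[start::oversample, start::oversample, start::oversample]
    vol = ifft3_centered(np.ascontiguousarray(F3))
    return DensityMap(vol, particles.apix)


@njit(cache=True, fastmath=True)
def _scatter_kernel(gx, gy, gz, vre, vim, wt, n, num_re, num_im, den):
    for i in range(gx.size):
        x0 = int(np.floor(gx[i]))
        y0 = int(np.floor(gy[i]))
        z0 = int(np.floor(gz[i]))
        fx = gx[i] - x0
        fy = gy[i] - y0
        fz = gz[i] - z0
        for dz in range(2):
            z = z0 + dz
            if z < 0 or z >= n:
                continue
            wz = fz if dz else 1.0 - fz
            for dy in range(2):
                y = y0 + dy
                if y < 0 or y >= n:
                    continue
                wy = fy if dy else 1.0 - fy
                for dx in range(2):
                    x = x0 + dx
                    if x < 0 or x >= n:
                        continue
                    w = (fx if dx else 1.0 - fx) * wy * wz
                    flat = (z * n + y) * n + x
                    num_re[flat] += w * vre[i]
                    num_im[flat] += w * vim[i]
                    den[flat] += w * wt[i]


def _scatter_trilinear(q: np.ndarray, vals: np.ndarray, wts: np.ndarray,
                       n: int, num_re: np.ndarray, num_im: np.ndarray,
                       den: np.ndarray) -> None:
    """Accumulate complex slice values into the flat 3D accumulators.

    q: (B, 3, M) object-frame frequencies in cycles/pixel (order x, y, z);
    array layout is [z, y, x] with DC at n//2 on each axis.
    """
    g = q * n + n // 2  # voxel coordinates (x, y, z)
    _scatter_kernel(np.ascontiguousarray(g[:, 0]).ravel(),
                    np.ascontiguousarray(g[:, 1]).ravel(),
                    np.ascontiguousarray(g[:, 2]).ravel(),
                    np.ascontiguousarray(vals.real).ravel(),
                    np.ascontiguousarray(vals.imag).ravel(),
                    np.ascontiguousarray(wts, dtype=np.float64).ravel(),
                    n, num_re, num_im, den)


# ---------------------------------------------------------------------------
# FSC


def fsc(a: DensityMap, b: DensityMap, mask: np.ndarray | None = None) -> FSCCurve:
    """Per-shell normalized correlation between two maps (optionally under a
    real-space mask)."""
    if a.data.shape != b.data.shape:
        raise ValueError("mismatched map shapes")
    da, db = a.data, b.data
    if mask is not None:
        da = da * mask
        db = db * mask
    n = a.n
    Fa = fft3_centered(da)
    Fb = fft3_centered(db)
    sidx, nshells = shell_indices(n)
    sf = sidx.ravel()
    keep = sf >= 0
    sk = sf[keep]
    cross = np.bincount(sk, weights=(Fa * np.conj(Fb)).real.ravel()[keep], minlength=nshells)
    pa = np.bincount(sk, weights=(np.abs(Fa) ** 2).ravel()[keep], minlength=nshells)
    pb = np.bincount(sk, weights=(np.abs(Fb) ** 2).ravel()[keep], minlength=nshells)
    # shells whose power is numerical dust count as empty; the floor sits
    # far below any real signal tail but far above float64 roundoff
    good = (pa > 1e-24 * pa.max()) & (pb > 1e-24 * pb.max())
    vals = np.zeros(nshells)
    vals[good] = np.clip(cross[good] / np.sqrt(pa[good] * pb[good]), -1.0, 1.0)
    return FSCCurve(vals, a.apix, n)


def resolution_at(curve: FSCCurve, threshold: float = 0.143) -> float:
    """Resolution (Angstrom) at the first crossing below ``threshold``,
    linearly interpolated; Nyquist (2*apix) if the curve never crosses."""
    v = curve.values
    f = curve.freq
    for i in range(1, len(v)):
        if v[i] < threshold:
            f0, f1 = f[i - 1], f[i]
            v0, v1 = v[i - 1], v[i]
            fc = f0 + (v0 - threshold) / (v0 - v1) * (f1 - f0) if v0 != v1 else f1
            return float(1.0 / fc) if fc > 0 else float("inf")
    return 2.0 * curve.apix


def average_fsc(curve: FSCCurve, max_resolution: float) -> float:
    """Mean FSC over shells up to (and including) the target resolution,
    DC shell excluded."""
    fmax = 1.0 / max_resolution
    sel = (curve.freq > 0) & (curve.freq <= fmax + 1e-12)
    return float(curve.values[sel].mean())


# ---------------------------------------------------------------------------
# filtering / sharpening


def _radial_filter(n: int, apix: float, transfer) -> np.ndarray:
    k = freq_grid_1d(n) / apix
    kr = np.sqrt(k[:, None, None] ** 2 + k[None, :, None] ** 2 + k[None, None, :] ** 2)
    return transfer(kr)


def lowpass(m: DensityMap, resolution: float, edge_shells: float = 2.0) -> DensityMap:
    """Cosine-edge low-pass at 1/resolution; edge half-width = ``edge_shells``
    Fourier shells."""
    if resolution < 2.0 * m.apix:
        raise ValueError("resolution finer than Nyquist")
    fc = 1.0 / resolution
    dw = edge_shells / (m.n * m.apix)

    def transfer(kr):
        h = np.ones_like(kr)
        h[kr >= fc + dw] = 0.0
        if dw > 0:
            edge = (kr > fc - dw) & (kr < fc + dw)
            h[edge] = 0.5 * (1.0 + np.cos(np.pi * (kr[edge] - (fc - dw)) / (2 * dw)))
        return h

    F = fft3_centered(m.data) * _radial_filter(m.n, m.apix, transfer)
    return DensityMap(ifft3_centered(F), m.apix)


def radial_profile(m: DensityMap) -> np.ndarray:
    """Mean Fourier amplitude per shell."""
    F = fft3_centered(m.data)
    sidx, nshells = shell_indices(m.n)
    sf = sidx.ravel()
    keep = sf >= 0
    amp = np.bincount(sf[keep], weights=np.abs(F).ravel()[keep], minlength=nshells)
    cnt = np.bincount(sf[keep], minlength=nshells)
    return amp / np.maximum(cnt, 1)


def sharpen_by_profile(m: DensityMap, profile: np.ndarray) -> DensityMap:
    """Rescale each Fourier shell's amplitude to match a reference radial
    profile (model-based sharpening).  Zero-power shells are left unscaled."""
    import warnings
    cur = radial_profile(m)
    nshells = len(cur)
    if len(profile) != nshells:
        raise ValueError("profile length must equal number of shells")
    scale = np.ones(nshells)
    good = cur > 0
    if not np.all(good[profile > 0]):
        warnings.warn("zero-power shell during sharpening; left unscaled")
    scale[good] = profile[good] / cur[good]
    F = fft3_centered(m.data)
    sidx, _ = shell_indices(m.n)
    mult = np.ones_like(F, dtype=np.float64)
    inside = sidx >= 0
    mult[inside] = scale[sidx[inside]]
    return DensityMap(ifft3_centered(F * mult), m.apix)


# ---------------------------------------------------------------------------
# symmetry


def _parse_cyclic(group: str) -> int:
    g = group.strip().lower()
    if not g.startswith("c") or not g[1:].isdigit() or int(g[1:]) < 1:
        raise ValueError(f"only cyclic symmetry groups cN are supported, got {group!r}")
    return int(g[1:])


def symmetry_expand(particles: ParticleSet, group: str) -> ParticleSet:
    """Duplicate each particle at its N symmetry-related orientations.

    For a cyclic group about z, the m-th copy's rotation is R @ Rz(360 m/N),
    which in ZYZ Euler terms adds 360 m/N to the in-plane angle psi.
    """
    N = _parse_cyclic(group)
    if N == 1:
        return particles
    P = len(particles)
    idx = np.repeat(np.arange(P), N)
    base = particles.subset(idx)
    Rs = Rotation.from_euler("ZYZ", particles.eulers, degrees=True).as_matrix()
    eulers = np.empty((P * N, 3))
    for m in range(N):
        Sz = Rotation.from_euler("z", 360.0 * m / N, degrees=True).as_matrix()
        Rm = np.einsum("pij,jk->pik", Rs, Sz)
        eulers[m::N] = Rotation.from_matrix(Rm).as_euler("ZYZ", degrees=True)
    order = np.argsort(np.repeat(np.arange(P), N), kind="stable")  # already ordered
    return base.with_poses(eulers, base.shifts)


def rotate_map_z(m: DensityMap, angle_deg: float) -> DensityMap:
    """Rotate a map about the z axis through the box center (trilinear)."""
    n = m.n
    c = n // 2
    ax = np.arange(n) - c
    z, y, x = np.meshgrid(ax, ax, ax, indexing="ij")
    a = np.deg2rad(angle_deg)
    ca, sa = np.cos(a), np.sin(a)
    # inverse rotation of output coords
    xs = ca * x + sa * y
    ys = -sa * x + ca * y
    coords = np.stack([z + c, ys + c, xs + c])
    out = ndimage.map_coordinates(m.data.astype(np.float64), coords.reshape(3, -1),
                                  order=1, mode="constant").reshape(n, n, n)
    return DensityMap(out, m.apix)


def symmetry_reimpose(m: DensityMap, group: str,
                      weight: np.ndarray | None = None) -> DensityMap:
    """Weighted average of the N z-rotated copies of a map.

    ``weight`` (optional, same grid) is rotated along with the map; without
    it the plain N-fold average is returned.
    """
    N = _parse_cyclic(group)
    if N == 1:
        return m.copy()
    num = np.zeros_like(m.data, dtype=np.float64)
    den = np.zeros_like(m.data, dtype=np.float64)
    for mth in range(N):
        ang = 360.0 * mth / N
        rm = rotate_map_z(m, ang)
        if weight is not None:
            rw = rotate_map_z(DensityMap(weight, m.apix), ang).data
        else:
            rw = np.ones_like(num)
        num += rw * rm.data
        den += rw
    out = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return DensityMap(out, m.apix)
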
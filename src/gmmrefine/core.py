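"""Gaussian-mixture structure representation and the FRC alignment objective.

A macromolecule is represented as a sum of isotropic 3D Gaussians,

    M(x) = sum_j A_j exp(-|x - c_j|^2 / (2 sigma_j^2)),

with centers ``c_j`` (Angstrom, origin at the box center), nonnegative
amplitudes ``A_j`` and positive widths ``sigma_j`` (Angstrom).  A 2D
projection at a pose is generated *analytically in Fourier space*: rotating
the centers and projecting along the beam axis turns each Gaussian into a
Gaussian-shaped Fourier envelope times a phase ramp, so no gridding
interpolation is ever needed.  Alignment quality is scored by the Fourier
ring correlation (FRC) between the projection and a particle image; because
every ring is independently normalized the score is insensitive to
ring-wise filtering of either image, and CTF amplitude effects drop out
once particle phases are flipped.

Conventions (used across the whole package):

* images/volumes are cubic, pixel size ``apix`` in Angstrom/pixel, the
  real-space origin sits at voxel index ``n // 2``;
* Fourier images are DC-centered; the forward transform carries no 1/N
  normalization; frequencies are in cycles/pixel;
* Euler angles are intrinsic ZYZ in degrees (``R = Rz(phi) Ry(theta)
  Rz(psi)``), matching the common cryo-EM STAR convention; in-plane
  translations are in pixels and applied in Fourier space.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

TWO_PI = 2.0 * np.pi
# prefactor for the Fourier-space amplitude of one projected unit Gaussian
# of width sigma (pixels): A * (2 pi)^{3/2} sigma^3
_W3 = (2.0 * np.pi) ** 1.5


# ---------------------------------------------------------------------------
# domain types


@dataclass
class GaussianMixture:
    """Sum-of-Gaussians structure model.

    centers : (N, 3) float array, Angstrom, box-centered origin
    amplitudes : (N,) nonnegative
    widths : (N,) positive, Angstrom
    """

    centers: np.ndarray
    amplitudes: np.ndarray
    widths: np.ndarray

    def __post_init__(self):
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=np.float64))
        self.amplitudes = np.asarray(self.amplitudes, dtype=np.float64).ravel()
        self.widths = np.asarray(self.widths, dtype=np.float64).ravel()
        if self.centers.shape[0] < 1 or self.centers.shape[1] != 3:
            raise ValueError("centers must be a non-empty (N, 3) array")
        if len(self.amplitudes) != len(self.centers) or len(self.widths) != len(self.centers):
            raise ValueError("amplitudes/widths length must match centers")
        if not np.all(np.isfinite(self.centers)):
            raise ValueError("centers must be finite")
        if np.any(self.widths <= 0):
            raise ValueError("all widths must be > 0")
        if np.any(self.amplitudes < 0):
            raise ValueError("all amplitudes must be >= 0")

    def __len__(self) -> int:
        return self.centers.shape[0]

    def copy(self) -> "GaussianMixture":
        return GaussianMixture(self.centers.copy(), self.amplitudes.copy(), self.widths.copy())

    # plain-text serialization: one row per Gaussian (index x y z amp width)
    def to_text(self, path) -> None:
        n = len(self)
        arr = np.column_stack([np.arange(n), self.centers, self.amplitudes, self.widths])
        header = "index x y z amplitude width (Angstrom; origin at box center)"
        np.savetxt(path, arr, header=header, fmt="%d %.17g %.17g %.17g %.17g %.17g")

    @classmethod
    def from_text(cls, path) -> "GaussianMixture":
        arr = np.atleast_2d(np.loadtxt(path))
        return cls(arr[:, 1:4], arr[:, 4], arr[:, 5])


@dataclass
class Pose:
    """Rigid-body pose: intrinsic ZYZ Euler angles (degrees) + 2D shift (pixels)."""

    euler: np.ndarray
    shift: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self):
        self.euler = np.asarray(self.euler, dtype=np.float64).ravel()
        self.shift = np.asarray(self.shift, dtype=np.float64).ravel()
        if self.euler.shape != (3,) or self.shift.shape != (2,):
            raise ValueError("euler must have 3 entries, shift 2")

    def rotation_matrix(self) -> np.ndarray:
        return Rotation.from_euler("ZYZ", self.euler, degrees=True).as_matrix()

    @classmethod
    def from_matrix(cls, R: np.ndarray, shift=(0.0, 0.0)) -> "Pose":
        eul = Rotation.from_matrix(R).as_euler("ZYZ", degrees=True)
        return cls(eul, np.asarray(shift, dtype=np.float64))

    def compose(self, other: "Pose") -> "Pose":
        """Pose applying ``other`` first, then ``self`` (shifts add)."""
        R = self.rotation_matrix() @ other.rotation_matrix()
        return Pose.from_matrix(R, self.shift + other.shift)

    def inverse(self) -> "Pose":
        return Pose.from_matrix(self.rotation_matrix().T, -self.shift)


@dataclass
class FourierImage:
    """DC-centered complex 2D Fourier image."""

    data: np.ndarray
    apix: float
    dc_centered: bool = True

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 2 or self.data.shape[0] != self.data.shape[1]:
            raise ValueError("FourierImage must be square 2D")
        if self.apix <= 0:
            raise ValueError("pixel size must be positive")

    @property
    def n(self) -> int:
        return self.data.shape[0]

    def to_real(self) -> np.ndarray:
        return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(self.data))).real

    @classmethod
    def from_real(cls, img: np.ndarray, apix: float) -> "FourierImage":
        F = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(np.asarray(img))))
        return cls(F, apix)


@dataclass
class FRCRings:
    """Per-ring Fourier ring correlation (ring width = 1 Fourier pixel)."""

    values: np.ndarray          # correlation per ring, clipped to [-1, 1]
    counts: np.ndarray          # pixels per ring
    valid: np.ndarray           # False where a ring had zero power (value forced to 0)
    apix: float
    n: int                      # box size the rings came from

    @property
    def freq(self) -> np.ndarray:
        """Ring center spatial frequency in 1/Angstrom."""
        return np.arange(len(self.values)) / (self.n * self.apix)


@dataclass
class DensityMap:
    """Cubic voxel map; origin at voxel n//2 along each axis."""

    data: np.ndarray
    apix: float

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or len(set(self.data.shape)) != 1:
            raise ValueError("DensityMap must be a cubic 3D array")
        if self.apix <= 0:
            raise ValueError("pixel size must be positive")

    @property
    def n(self) -> int:
        return self.data.shape[0]

    def copy(self) -> "DensityMap":
        return DensityMap(self.data.copy(), self.apix)


# ---------------------------------------------------------------------------
# frequency / ring helpers


def freq_grid_1d(n: int) -> np.ndarray:
    """DC-centered 1D frequency axis in cycles/pixel."""
    return np.fft.fftshift(np.fft.fftfreq(n))


_RING_ONEHOT_CACHE: dict = {}


def _ring_onehot_from(rk: np.ndarray, nrings: int, dtype, key) -> np.ndarray:
    """Membership matrix (kept pixels x rings) for fast batched ring sums."""
    full_key = key + (np.dtype(dtype).name,)
    if full_key not in _RING_ONEHOT_CACHE:
        oh = np.zeros((rk.size, nrings), dtype=dtype)
        oh[np.arange(rk.size), rk] = 1.0
        _RING_ONEHOT_CACHE[full_key] = oh
    return _RING_ONEHOT_CACHE[full_key]


def ring_indices(n: int) -> tuple[np.ndarray, int]:
    """Integer ring index per 2D Fourier pixel (DC-centered); rings beyond
    Nyquist (index > n//2) are marked with -1 and excluded everywhere."""
    k = freq_grid_1d(n) * n  # Fourier-pixel units
    r = np.sqrt(k[:, None] ** 2 + k[None, :] ** 2)
    idx = np.rint(r).astype(np.int64)
    nrings = n // 2 + 1
    idx[idx >= nrings] = -1
    return idx, nrings


def shell_indices(n: int) -> tuple[np.ndarray, int]:
    """3D analogue of :func:`ring_indices`."""
    k = freq_grid_1d(n) * n
    r = np.sqrt(k[:, None, None] ** 2 + k[None, :, None] ** 2 + k[None, None, :] ** 2)
    idx = np.rint(r).astype(np.int64)
    nshells = n // 2 + 1
    idx[idx >= nshells] = -1
    return idx, nshells


# ---------------------------------------------------------------------------
# rendering and projection


def render_volume(gmm: GaussianMixture, n: int, apix: float,
                  dtype=np.float64) -> DensityMap:
    """Evaluate the GMM on an ``n^3`` voxel grid (value at voxel centers).

    Raises if any center falls outside the box, naming the offending
    Gaussian.  Separable evaluation: each Gaussian factorizes over x/y/z.
    """
    half = n // 2
    ax = (np.arange(n) - half) * apix  # physical coordinate of voxel centers
    tol = 0.5 * apix  # half-voxel slack for edge-voxel centroids
    lo, hi = ax[0] - tol, ax[-1] + tol
    bad = np.where(np.any((gmm.centers < lo) | (gmm.centers > hi), axis=1))[0]
    if bad.size:
        raise ValueError(f"Gaussian {bad[0]} center {gmm.centers[bad[0]]} lies outside the box")
    inv2s2 = 1.0 / (2.0 * gmm.widths ** 2)
    # (N, n) factors per axis
    dx2 = (ax[None, :] - gmm.centers[:, 0:1]) ** 2
    dy2 = (ax[None, :] - gmm.centers[:, 1:2]) ** 2
    dz2 = (ax[None, :] - gmm.centers[:, 2:3]) ** 2
    ex = np.exp(-dx2 * inv2s2[:, None]).astype(dtype)
    ey = np.exp(-dy2 * inv2s2[:, None]).astype(dtype)
    ez = np.exp(-dz2 * inv2s2[:, None]).astype(dtype)
    ez = ez * gmm.amplitudes[:, None].astype(dtype)
    # volume[z, y, x] = sum_j ez[j,z] ey[j,y] ex[j,x]
    zy = np.einsum("jz,jy->jzy", ez, ey).reshape(len(gmm), -1)
    vol = (zy.T @ ex).reshape(n, n, n)
    return DensityMap(vol, apix)


def _projection_factors(gmm: GaussianMixture, R: np.ndarray, shift_px: np.ndarray,
                        n: int, apix: float, cdtype=np.complex128):
    """Separable per-Gaussian Fourier factors of the analytic projection.

    Returns (Gx, Gy, w, bx, by, sig_px) where the projection Fourier image is
    ``F[y, x] = sum_j w_j Gy[j, y] Gx[j, x]`` with frequencies in
    cycles/pixel and all lengths in pixels.
    """
    k = freq_grid_1d(n)
    c_px = gmm.centers / apix
    sig = gmm.widths / apix
    b = c_px @ R.T  # rotated centers; image-plane coords = first two comps
    bx = b[:, 0] + shift_px[0]
    by = b[:, 1] + shift_px[1]
    env = -2.0 * np.pi ** 2 * (sig ** 2)[:, None] * (k ** 2)[None, :]
    phx = (-TWO_PI * 1j) * bx[:, None] * k[None, :]
    phy = (-TWO_PI * 1j) * by[:, None] * k[None, :]
    Gx = np.exp(env + phx).astype(cdtype)
    Gy = np.exp(env + phy).astype(cdtype)
    w = (gmm.amplitudes * _W3 * sig ** 3).astype(cdtype)
    return Gx, Gy, w, b, sig


def project(gmm: GaussianMixture, pose: Pose, n: int, apix: float,
            cdtype=np.complex128) -> FourierImage:
    """Analytic Fourier-space projection of the GMM at ``pose``.

    Equals the (DC-centered, unnormalized) 2D DFT of the beam-axis line
    integral of the posed GMM sampled on the image grid, up to sampling
    error which is negligible for widths >= ~1.5 pixels.
    """
    if n < 2:
        raise ValueError("degenerate image grid (size < 2)")
    R = pose.rotation_matrix()
    Gx, Gy, w, _, _ = _projection_factors(gmm, R, pose.shift, n, apix, cdtype)
    F = (w[:, None] * Gy).T @ Gx
    return FourierImage(F, apix)


# ---------------------------------------------------------------------------
# FRC


def _ring_means(flat_vals: np.ndarray, ridx_flat: np.ndarray, nrings: int) -> np.ndarray:
    keep = ridx_flat >= 0
    return np.bincount(ridx_flat[keep], weights=flat_vals[keep], minlength=nrings)


def frc(a: FourierImage, b: FourierImage) -> FRCRings:
    """Fourier ring correlation, ring width 1 Fourier pixel.

    Per ring: Re<a conj(b)> / sqrt(<|a|^2><|b|^2>).  Rings with zero power
    in either image get value 0 and ``valid=False``.
    """
    if a.data.shape != b.data.shape:
        raise ValueError("mismatched Fourier image shapes")
    n = a.n
    ridx, nrings = ring_indices(n)
    rf = ridx.ravel()
    cross = (a.data * np.conj(b.data)).real.ravel()
    pa = (np.abs(a.data) ** 2).ravel()
    pb = (np.abs(b.data) ** 2).ravel()
    s_ab = _ring_means(cross, rf, nrings)
    s_aa = _ring_means(pa, rf, nrings)
    s_bb = _ring_means(pb, rf, nrings)
    counts = np.bincount(rf[rf >= 0], minlength=nrings)
    valid = (s_aa > 0) & (s_bb > 0) & (counts > 0)
    vals = np.zeros(nrings)
    denom = np.sqrt(s_aa[valid] * s_bb[valid])
    vals[valid] = np.clip(s_ab[valid] / denom, -1.0, 1.0)
    return FRCRings(vals, counts, valid, a.apix, n)


def default_band(n: int, rmax: int | None = None) -> tuple[int, int]:
    """Loss band in ring indices: DC excluded, capped at Nyquist."""
    hi = n // 2 if rmax is None else min(int(rmax), n // 2)
    return (1, hi)


def frc_loss(gmm: GaussianMixture, pose: Pose, particle: FourierImage,
             band: tuple[int, int] | None = None) -> float:
    """Negative mean FRC over rings in ``band`` (inclusive), DC excluded."""
    loss, _ = frc_loss_and_grad(gmm, pose, particle, band, want_grad=False)
    return loss


def frc_loss_and_grad(gmm: GaussianMixture, pose: Pose, particle: FourierImage,
                      band: tuple[int, int] | None = None, want_grad: bool = True,
                      want_gaussian_grads: bool = False, cdtype=np.complex128):
    """FRC loss and its analytic gradients.

    Returns ``(loss, grads)`` where ``grads`` (None unless requested) maps
    ``euler`` -> (3,) d(loss)/d(degrees), ``shift`` -> (2,) per pixel, and,
    when ``want_gaussian_grads``, ``centers`` -> (N, 3) per Angstrom,
    ``amplitudes`` -> (N,), ``widths`` -> (N,) per Angstrom.
    """
    n = particle.n
    band = default_band(n) if band is None else band
    if band[1] < band[0]:
        raise ValueError("empty FRC loss band")
    R = pose.rotation_matrix()
    out = _batch_frc_loss_grads(
        gmm, R[None], pose.shift[None], particle.data[None], n, particle.apix,
        band, want_grad=want_grad, want_gaussian_grads=want_gaussian_grads,
        cdtype=cdtype)
    loss = float(out["loss"][0])
    if not want_grad:
        return loss, None
    grads = {"shift": out["shift"][0]}
    grads["euler"] = _chain_euler_grads(out["db"][0], pose.euler, gmm.centers / particle.apix)
    if want_gaussian_grads:
        db = out["db"][0]  # (N, 2) dL/d(projected center, pixels)
        apix = particle.apix
        grads["centers"] = (db[:, 0:1] * R[0][None, :] + db[:, 1:2] * R[1][None, :]) / apix
        grads["amplitudes"] = out["damp"][0]
        grads["widths"] = out["dsig"][0] / apix
    return loss, grads


def _dR_deuler(euler_deg: np.ndarray):
    """Derivatives of R = Rz(a)Ry(b)Rz(c) wrt each angle, per *degree*."""
    a, b, c = np.deg2rad(euler_deg)
    ca, sa, cb, sb, cc, sc = np.cos(a), np.sin(a), np.cos(b), np.sin(b), np.cos(c), np.sin(c)
    Rza = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1]])
    Ryb = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
    Rzc = np.array([[cc, -sc, 0], [sc, cc, 0], [0, 0, 1]])
    dRza = np.array([[-sa, -ca, 0], [ca, -sa, 0], [0, 0, 0]])
    dRyb = np.array([[-sb, 0, cb], [0, 0, 0], [-cb, 0, -sb]])
    dRzc = np.array([[-sc, -cc, 0], [cc, -sc, 0], [0, 0, 0]])
    scale = np.pi / 180.0
    return [scale * (dRza @ Ryb @ Rzc),
            scale * (Rza @ dRyb @ Rzc),
            scale * (Rza @ Ryb @ dRzc)]


def _chain_euler_grads(db: np.ndarray, euler_deg: np.ndarray, centers_px: np.ndarray) -> np.ndarray:
    """Chain dL/d(projected center) through dR/d(euler)."""
    dRs = _dR_deuler(euler_deg)
    g = np.empty(3)
    for m, dR in enumerate(dRs):
        dbm = centers_px @ dR.T  # (N, 3); image-plane comps 0,1
        g[m] = float(np.sum(db[:, 0] * dbm[:, 0] + db[:, 1] * dbm[:, 1]))
    return g


def _batch_frc_loss_grads(gmm: GaussianMixture, Rs: np.ndarray, shifts_px: np.ndarray,
                          particles_F: np.ndarray, n: int, apix: float,
                          band: tuple[int, int], want_grad: bool = True,
                          want_gaussian_grads: bool = False,
                          sum_gaussian_grads: bool = False,
                          cdtype=np.complex128):
    """Batched FRC loss + gradients for one GMM against B particles/poses.

    Rs: (B, 3, 3); shifts_px: (B, 2); particles_F: (B, n, n) DC-centered.
    The adjoint of the ring-normalized correlation is assembled per ring and
    pulled back through the separable projection factors as matrix products.
    """
    B = Rs.shape[0]
    N = len(gmm)
    k = freq_grid_1d(n)
    sig = gmm.widths / apix
    c_px = gmm.centers / apix
    rdtype = np.float64 if cdtype == np.complex128 else np.float32

    # all rings the loss can use fit inside a centered sub-grid of
    # half-width band_hi + 1; cropping there is exact and much cheaper
    m = n
    if band[1] < n // 2 - 1:
        m = min(n, 2 * (band[1] + 2))
        lo_i = n // 2 - m // 2
        k = k[lo_i:lo_i + m]
        particles_F = particles_F[:, lo_i:lo_i + m, lo_i:lo_i + m]
    k = k.astype(rdtype)

    b3 = np.einsum("bij,nj->bni", Rs, c_px)  # rotated centers (B, N, 3)
    b = b3[:, :, :2]
    bx = b[..., 0] + shifts_px[:, 0:1]
    by = b[..., 1] + shifts_px[:, 1:2]
    # separable factors: real Gaussian envelope (independent of pose) times
    # a unit phase ramp; real exp + sincos is much cheaper than complex exp
    env = np.exp((-2.0 * np.pi ** 2) * (sig.astype(rdtype) ** 2)[:, None]
                 * (k ** 2)[None, :])  # (N, n)
    phx = (-TWO_PI) * bx[..., None].astype(rdtype) * k[None, None, :]
    phy = (-TWO_PI) * by[..., None].astype(rdtype) * k[None, None, :]
    Gx = (env[None] * (np.cos(phx) + 1j * np.sin(phx))).astype(cdtype)
    Gy = (env[None] * (np.cos(phy) + 1j * np.sin(phy))).astype(cdtype)
    w = (gmm.amplitudes * _W3 * sig ** 3).astype(cdtype)

    F = np.matmul(np.swapaxes(w[None, :, None] * Gy, 1, 2), Gx)  # (B, m, m)

    kr = np.sqrt(k[:, None] ** 2 + k[None, :] ** 2)
    ridx = np.rint(kr * n).astype(np.int64)
    nrings = n // 2 + 1
    ridx[ridx >= nrings] = -1
    rf = ridx.ravel()
    keep = rf >= 0
    rk = rf[keep]
    G = particles_F.astype(cdtype)
    cross = (F * np.conj(G)).reshape(B, -1)[:, keep]
    pa = (np.abs(F) ** 2).reshape(B, -1)[:, keep]
    pb = (np.abs(G) ** 2).reshape(B, -1)[:, keep]

    onehot = _ring_onehot_from(rk, nrings, rdtype, key=(n, m))

    def rsum(v):
        return (np.ascontiguousarray(v.real).astype(rdtype, copy=False)
                @ onehot).astype(np.float64)

    s_ab = rsum(cross)
    s_aa = rsum(pa)
    s_bb = rsum(pb)
    in_band = np.zeros(nrings, dtype=bool)
    in_band[band[0]:band[1] + 1] = True
    valid = (s_aa > 1e-300) & (s_bb > 1e-300) & in_band[None, :]
    denom = np.sqrt(np.where(valid, s_aa * s_bb, 1.0))
    C = np.where(valid, s_ab / denom, 0.0)
    nvalid = np.maximum(valid.sum(axis=1), 1)
    loss = -C.sum(axis=1) / nvalid

    result = {"loss": loss}
    if not want_grad:
        return result

    # per-ring adjoint coefficients -> per-pixel fields
    alpha = np.where(valid, 1.0 / denom, 0.0) / nvalid[:, None]          # times G
    beta = np.where(valid, C / np.where(valid, s_aa, 1.0), 0.0) / nvalid[:, None]  # times F
    al_pix = np.zeros((B, m * m), dtype=np.float64)
    be_pix = np.zeros((B, m * m), dtype=np.float64)
    al_pix[:, keep] = alpha[:, rk]
    be_pix[:, keep] = beta[:, rk]
    # dL/dp = Re <dF/dp, Z>,  Z = -(alpha G - beta F)  (already /nvalid)
    Z = (-(al_pix.reshape(B, m, m) * G - be_pix.reshape(B, m, m) * F)).astype(cdtype)
    Zb = np.conj(Z)

    mikx = ((-TWO_PI * 1j) * k).astype(cdtype)
    # shift gradient, elementwise: Re[F (-2pi i k) Zb] = 2pi k Im[F Zb]
    FZ = (F * Zb).imag
    gsx = TWO_PI * np.sum(FZ * k[None, None, :], axis=(1, 2))
    gsy = TWO_PI * np.sum(FZ * k[None, :, None], axis=(1, 2))
    result["shift"] = np.stack([gsx, gsy], axis=1)

    # per-Gaussian projected-center gradients via Gy @ M @ Gx contractions
    def contract(M):
        # returns (B, N): sum_{y,x} Gy[b,j,y] M[b,y,x] Gx[b,j,x]
        t = np.matmul(Gy, M)          # (B, N, n)
        return np.sum(t * Gx, axis=2)  # (B, N)

    Zkx = Zb * mikx[None, None, :]
    Zky = Zb * mikx[None, :, None]
    Tx = contract(Zkx)
    Ty = contract(Zky)
    db = np.stack([(w[None, :] * Tx).real, (w[None, :] * Ty).real], axis=2)  # (B,N,2) per pixel
    result["db"] = db
    result["rot_centers"] = b3  # for tangent-space (delta-rotation) chains

    if want_gaussian_grads:
        T0 = contract(Zb)
        k2 = (k ** 2).astype(cdtype)
        Tx2 = contract(Zb * k2[None, None, :])
        Ty2 = contract(Zb * k2[None, :, None])
        w_over_A = (_W3 * sig ** 3).astype(cdtype)
        damp = (w_over_A[None, :] * T0).real
        dsig = ((w * (3.0 / sig))[None, :] * T0
                - (w * (4.0 * np.pi ** 2 * sig))[None, :] * (Tx2 + Ty2)).real
        if sum_gaussian_grads:
            damp = damp.sum(axis=0)
            dsig = dsig.sum(axis=0)
        result["damp"] = damp
        result["dsig"] = dsig  # per pixel of width
    return result
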
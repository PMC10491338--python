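"""Readers/writers for MRC maps/stacks and STAR metadata, plus CTF phase
flipping.

Conventions
-----------
* Volumes and stacks are MRC mode 2 (float32); the header pixel size is
  honored on read and written on write.  Stack axis 0 indexes particles.
* STAR: both the legacy single-table dialect and the versioned
  (``data_optics`` + ``data_particles``) dialect are read.  Shifts are
  stored internally in **pixels**; ``_rlnOriginXAngst/YAngst`` are divided
  by the optics-group pixel size on import.  All columns are preserved
  verbatim for round-tripping.
* The half-set split comes from ``_rlnRandomSubset`` (1 -> even, 2 -> odd)
  and is never invented unless ``assign_split=True`` is passed explicitly.
* CTF: standard phase-contrast transfer function with astigmatic defocus,
  spherical aberration, relativistic wavelength and amplitude contrast.
  Phase flipping multiplies Fourier coefficients by sign(CTF) only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import gemmi
import mrcfile

from .core import DensityMap, FourierImage, freq_grid_1d
from .particles import ParticleSet, default_ctf_frame, CTF_COLUMNS


# ---------------------------------------------------------------------------
# MRC


def write_mrc(path, data: np.ndarray | DensityMap, apix: float | None = None) -> None:
    if isinstance(data, DensityMap):
        apix = data.apix
        data = data.data
    if apix is None or apix <= 0:
        raise ValueError("pixel size must be positive")
    with mrcfile.new(str(path), overwrite=True) as f:
        f.set_data(np.asarray(data, dtype=np.float32))
        f.voxel_size = apix


def read_mrc(path):
    """Read an MRC file; returns ``(data float32, apix)``.

    3D data is a volume (or a stack — the caller knows which); the stack
    convention is axis 0 = particle index.
    """
    with mrcfile.open(str(path), permissive=True) as f:
        data = np.asarray(f.data, dtype=np.float32)
        apix = float(f.voxel_size.x)
    if apix <= 0:
        raise ValueError(f"{path}: non-positive pixel size in header")
    return data, apix


def read_map(path) -> DensityMap:
    data, apix = read_mrc(path)
    return DensityMap(data, apix)


# ---------------------------------------------------------------------------
# STAR

_REQUIRED = ["rlnAngleRot", "rlnAngleTilt", "rlnAnglePsi",
             "rlnDefocusU", "rlnDefocusV", "rlnDefocusAngle"]


def read_star(path) -> dict[str, pd.DataFrame]:
    """Parse a STAR file into one DataFrame per data block.

    Numeric columns are converted where possible; everything else stays as
    strings so unknown columns round-trip verbatim.
    """
    doc = gemmi.cif.read_file(str(path))
    blocks: dict[str, pd.DataFrame] = {}
    for block in doc:
        tags = [item.loop.tags for item in block if item.loop is not None]
        if not tags:
            continue
        loop = next(item.loop for item in block if item.loop is not None)
        cols = {}
        for tag in loop.tags:
            name = tag.lstrip("_")
            vals = np.array(block.find_loop(tag))
            try:
                vals = vals.astype(np.float64)
            except ValueError:
                pass
            cols[name] = vals
        blocks[block.name] = pd.DataFrame(cols)
    return blocks


def write_star(blocks: dict[str, pd.DataFrame], path) -> None:
    with open(path, "w") as f:
        f.write("\n# written by gmmrefine\n\n")
        for name, df in blocks.items():
            if len(df) == 0 or len(df.columns) == 0:
                f.write(f"data_{name}\n\n")
                continue
            f.write(f"data_{name}\n\nloop_\n")
            for i, col in enumerate(df.columns):
                f.write(f"_{col} #{i + 1}\n")
            for _, row in df.iterrows():
                f.write(" ".join(_star_fmt(v) for v in row.values) + "\n")
            f.write("\n")


def _star_fmt(v) -> str:
    if isinstance(v, (float, np.floating)):
        return f"{v:.6f}"
    return str(v)


def particles_from_star(path, images: np.ndarray | None = None,
                        apix: float | None = None,
                        assign_split: bool = False,
                        seed: int = 0) -> ParticleSet:
    """Build a :class:`ParticleSet` skeleton from STAR metadata.

    ``images`` may be omitted (zero-size placeholder stack) when only the
    metadata is needed.  Raises on any missing required column, and on a
    missing ``_rlnRandomSubset`` unless ``assign_split`` is set.
    """
    blocks = read_star(path)
    if "particles" in blocks:       # versioned dialect
        df = blocks["particles"]
        optics = blocks.get("optics")
    else:                           # legacy: single block
        df = next(iter(blocks.values())) if blocks else pd.DataFrame()
        optics = None
    if len(df) == 0:
        raise ValueError(f"{path}: no particles in STAR file")
    for col in _REQUIRED:
        if col not in df.columns:
            raise KeyError(f"{path}: missing required STAR column _{col}")

    if apix is None:
        if optics is not None and "rlnImagePixelSize" in optics.columns:
            apix = float(optics["rlnImagePixelSize"].iloc[0])
        elif "rlnImagePixelSize" in df.columns:
            apix = float(df["rlnImagePixelSize"].iloc[0])
        else:
            raise ValueError("pixel size not found in STAR; pass apix=")

    eulers = df[["rlnAngleRot", "rlnAngleTilt", "rlnAnglePsi"]].to_numpy(dtype=np.float64)
    if "rlnOriginXAngst" in df.columns:
        shifts = df[["rlnOriginXAngst", "rlnOriginYAngst"]].to_numpy(dtype=np.float64) / apix
    elif "rlnOriginX" in df.columns:
        shifts = df[["rlnOriginX", "rlnOriginY"]].to_numpy(dtype=np.float64)
    else:
        shifts = np.zeros((len(df), 2))

    if "rlnRandomSubset" in df.columns:
        half = (df["rlnRandomSubset"].to_numpy(dtype=np.float64).astype(int) - 1) % 2
    elif assign_split:
        half = np.arange(len(df)) % 2
    else:
        raise ValueError(f"{path}: no _rlnRandomSubset column; a half-set split is "
                         "never invented (pass assign_split=True to alternate)")

    ctf = default_ctf_frame(len(df))
    ctf["defocus_u"] = df["rlnDefocusU"].to_numpy(dtype=np.float64)
    ctf["defocus_v"] = df["rlnDefocusV"].to_numpy(dtype=np.float64)
    ctf["astig_angle"] = df["rlnDefocusAngle"].to_numpy(dtype=np.float64)
    src = optics if optics is not None else df
    for col, tag in [("voltage", "rlnVoltage"), ("cs", "rlnSphericalAberration"),
                     ("amp_contrast", "rlnAmplitudeContrast")]:
        if tag in src.columns:
            ctf[col] = float(src[tag].iloc[0]) if optics is not None else \
                src[tag].to_numpy(dtype=np.float64)

    if images is None:
        images = np.zeros((len(df), 0, 0), dtype=np.float32)
    return ParticleSet(images, apix, eulers, shifts, ctf, half,
                       phase_flipped=False, extra=df)


def particles_to_star(particles: ParticleSet, path, angst_shifts: bool = False) -> None:
    """Write particle poses/CTF/half-set to a legacy-dialect STAR file.

    If the particle set carries an ``extra`` table (from an earlier import)
    its unrecognized columns are written back verbatim; recognized pose
    columns are overwritten with the current values.
    """
    df = particles.extra.copy() if particles.extra is not None else pd.DataFrame()
    df["rlnAngleRot"] = particles.eulers[:, 0]
    df["rlnAngleTilt"] = particles.eulers[:, 1]
    df["rlnAnglePsi"] = particles.eulers[:, 2]
    if angst_shifts:
        df["rlnOriginXAngst"] = particles.shifts[:, 0] * particles.apix
        df["rlnOriginYAngst"] = particles.shifts[:, 1] * particles.apix
        df.drop(columns=[c for c in ("rlnOriginX", "rlnOriginY") if c in df], inplace=True)
    else:
        df["rlnOriginX"] = particles.shifts[:, 0]
        df["rlnOriginY"] = particles.shifts[:, 1]
    df["rlnDefocusU"] = particles.ctf["defocus_u"].to_numpy()
    df["rlnDefocusV"] = particles.ctf["defocus_v"].to_numpy()
    df["rlnDefocusAngle"] = particles.ctf["astig_angle"].to_numpy()
    df["rlnVoltage"] = particles.ctf["voltage"].to_numpy()
    df["rlnSphericalAberration"] = particles.ctf["cs"].to_numpy()
    df["rlnAmplitudeContrast"] = particles.ctf["amp_contrast"].to_numpy()
    df["rlnRandomSubset"] = np.asarray(particles.half, dtype=int) + 1
    if "rlnImagePixelSize" not in df.columns:
        df["rlnImagePixelSize"] = particles.apix
    write_star({"particles": df}, path)


# ---------------------------------------------------------------------------
# CTF


def electron_wavelength(voltage_kv: float) -> float:
    """Relativistic electron wavelength in Angstrom."""
    if voltage_kv <= 0:
        raise ValueError("voltage must be positive")
    v = voltage_kv * 1e3
    return 12.2639 / np.sqrt(v + 0.97845e-6 * v * v)


def ctf_2d(n: int, apix: float, defocus_u: float, defocus_v: float | None = None,
           astig_angle: float = 0.0, voltage: float = 300.0, cs: float = 2.7,
           amp_contrast: float = 0.07, phase_shift: float = 0.0) -> np.ndarray:
    """DC-centered 2D CTF. Defocus in Angstrom (underfocus positive), cs in
    mm, voltage in kV, angles in degrees."""
    if apix <= 0:
        raise ValueError("pixel size must be positive")
    lam = electron_wavelength(voltage)
    if defocus_v is None:
        defocus_v = defocus_u
    k = freq_grid_1d(n) / apix  # 1/Angstrom
    kx, ky = np.meshgrid(k, k)  # kx varies along axis 1 to match image [y, x]
    k2 = kx ** 2 + ky ** 2
    ang = np.arctan2(ky, kx)
    dz = 0.5 * (defocus_u + defocus_v) + 0.5 * (defocus_u - defocus_v) * \
        np.cos(2.0 * (ang - np.deg2rad(astig_angle)))
    gamma = (np.pi * lam * dz * k2
             - 0.5 * np.pi * (cs * 1e7) * lam ** 3 * k2 ** 2
             - np.deg2rad(phase_shift))
    w = amp_contrast
    return -(np.sqrt(1.0 - w * w) * np.sin(gamma) + w * np.cos(gamma))


def ctf_for_particle(n: int, apix: float, ctf_row) -> np.ndarray:
    return ctf_2d(n, apix, ctf_row["defocus_u"], ctf_row["defocus_v"],
                  ctf_row["astig_angle"], ctf_row["voltage"], ctf_row["cs"],
                  ctf_row["amp_contrast"], ctf_row["phase_shift"])


def ctf_stack(n: int, apix: float, ctf: pd.DataFrame,
              rows: np.ndarray | None = None) -> np.ndarray:
    """Vectorized CTF grids for many particles: (P, n, n) float32."""
    if apix <= 0:
        raise ValueError("pixel size must be positive")
    sub = ctf if rows is None else ctf.iloc[rows]
    volt = sub["voltage"].to_numpy()
    if np.any(volt <= 0):
        raise ValueError("voltage must be positive")
    lam = 12.2639 / np.sqrt(volt * 1e3 + 0.97845e-6 * (volt * 1e3) ** 2)
    k = freq_grid_1d(n) / apix
    kx, ky = np.meshgrid(k, k)
    k2 = (kx ** 2 + ky ** 2)[None]
    ang = np.arctan2(ky, kx)[None]
    du = sub["defocus_u"].to_numpy()[:, None, None]
    dv = sub["defocus_v"].to_numpy()[:, None, None]
    aa = np.deg2rad(sub["astig_angle"].to_numpy())[:, None, None]
    dz = 0.5 * (du + dv) + 0.5 * (du - dv) * np.cos(2.0 * (ang - aa))
    lam3 = lam[:, None, None]
    cs = sub["cs"].to_numpy()[:, None, None] * 1e7
    gamma = (np.pi * lam3 * dz * k2 - 0.5 * np.pi * cs * lam3 ** 3 * k2 ** 2
             - np.deg2rad(sub["phase_shift"].to_numpy())[:, None, None])
    w = sub["amp_contrast"].to_numpy()[:, None, None]
    out = -(np.sqrt(1.0 - w * w) * np.sin(gamma) + w * np.cos(gamma))
    return out.astype(np.float32)


def phase_flip(image: FourierImage, ctf: np.ndarray) -> FourierImage:
    """Multiply each Fourier coefficient by sign(CTF); amplitudes untouched."""
    if ctf.shape != image.data.shape:
        raise ValueError("CTF grid does not match image")
    sign = np.where(ctf < 0, -1.0, 1.0)
    return FourierImage(image.data * sign, image.apix)


def phase_flip_stack(particles: ParticleSet) -> ParticleSet:
    """Return a copy of the particle set with CTF phases flipped (no-op if
    already flipped; the flag prevents double application)."""
    if particles.phase_flipped:
        return particles
    n = particles.n
    out = np.empty_like(particles.images)
    chunk = 256
    for lo in range(0, len(particles), chunk):
        hi = min(lo + chunk, len(particles))
        ctfs = ctf_stack(n, particles.apix, particles.ctf, np.arange(lo, hi))
        F = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(
            particles.images[lo:hi].astype(np.float64), axes=(-2, -1))), axes=(-2, -1))
        F *= np.where(ctfs < 0, -1.0, 1.0)
        out[lo:hi] = np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(
            F, axes=(-2, -1))), axes=(-2, -1)).real.astype(particles.images.dtype)
    ps = ParticleSet(out, particles.apix, particles.eulers, particles.shifts,
                     particles.ctf, np.asarray(particles.half), True, particles.extra)
    return ps


def read_pdb_coords(path, exclude_hydrogen: bool = True) -> np.ndarray:
    """Non-H atom coordinates (Angstrom) from a PDB/mmCIF file."""
    st = gemmi.read_structure(str(path))
    coords = []
    for model in st:
        for chain in model:
            for res in chain:
                for atom in res:
                    if exclude_hydrogen and atom.element.is_hydrogen:
                        continue
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
        break
    if not coords:
        raise ValueError(f"{path}: no atoms read")
    return np.asarray(coords)


def write_fsc_text(curve, path) -> None:
    """FSC curve as two-column text: spatial frequency (1/Angstrom), correlation."""
    np.savetxt(path, np.column_stack([curve.freq, curve.values]),
               header="freq(1/A) correlation", fmt="%.8g")
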
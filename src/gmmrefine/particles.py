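"""Particle stacks with poses, CTF parameters and immutable half-set labels.

The even/odd ("gold-standard") split is assigned once — on import or on
simulation — and is frozen afterwards: the label array is write-protected
and every refinement entry point checks that a particle is only ever paired
with the reference of its own half set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EVEN, ODD = 0, 1

CTF_COLUMNS = ["defocus_u", "defocus_v", "astig_angle", "voltage", "cs",
               "amp_contrast", "phase_shift"]

CTF_DEFAULTS = {"defocus_u": 15000.0, "defocus_v": 15000.0, "astig_angle": 0.0,
                "voltage": 300.0, "cs": 2.7, "amp_contrast": 0.07,
                "phase_shift": 0.0}


def default_ctf_frame(n_particles: int, **overrides) -> pd.DataFrame:
    vals = dict(CTF_DEFAULTS)
    vals.update(overrides)
    return pd.DataFrame({c: np.full(n_particles, vals[c]) for c in CTF_COLUMNS})


@dataclass
class ParticleSet:
    """Image stack + per-particle metadata.

    images : (P, n, n) real-space images
    apix : pixel size, Angstrom/pixel
    eulers : (P, 3) ZYZ Euler angles, degrees
    shifts : (P, 2) in-plane translations, pixels
    ctf : DataFrame with columns ``CTF_COLUMNS`` (defocus in Angstrom,
        cs in mm, voltage in kV, angles in degrees)
    half : (P,) labels in {0 (even), 1 (odd)}; write-protected
    phase_flipped : whether image phases have been CTF-sign corrected
    extra : passthrough metadata (e.g. unrecognized STAR columns)
    """

    images: np.ndarray
    apix: float
    eulers: np.ndarray
    shifts: np.ndarray
    ctf: pd.DataFrame
    half: np.ndarray
    phase_flipped: bool = False
    extra: pd.DataFrame | None = None

    def __post_init__(self):
        self.images = np.asarray(self.images)
        self.eulers = np.array(self.eulers, dtype=np.float64)
        self.shifts = np.array(self.shifts, dtype=np.float64)
        half = np.array(self.half, dtype=np.int8)
        half.setflags(write=False)
        self.half = half
        P = len(self.images)
        if self.images.ndim != 3 or self.images.shape[1] != self.images.shape[2]:
            raise ValueError("images must be a (P, n, n) stack")
        if not (len(self.eulers) == len(self.shifts) == len(self.ctf) == len(half) == P):
            raise ValueError("per-particle arrays must share length")
        if P and not np.all(np.isin(half, [EVEN, ODD])):
            raise ValueError("half labels must be 0 (even) or 1 (odd)")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def n(self) -> int:
        return self.images.shape[1]

    def subset(self, index: np.ndarray) -> "ParticleSet":
        extra = self.extra.iloc[index].reset_index(drop=True) if self.extra is not None else None
        return ParticleSet(self.images[index], self.apix, self.eulers[index],
                           self.shifts[index], self.ctf.iloc[index].reset_index(drop=True),
                           np.asarray(self.half)[index], self.phase_flipped, extra)

    def half_set(self, half: int) -> "ParticleSet":
        return self.subset(np.where(np.asarray(self.half) == half)[0])

    def with_poses(self, eulers: np.ndarray, shifts: np.ndarray) -> "ParticleSet":
        return ParticleSet(self.images, self.apix, eulers, shifts, self.ctf,
                           np.asarray(self.half), self.phase_flipped, self.extra)
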
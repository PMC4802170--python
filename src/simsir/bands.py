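"""Band separation: demixing phase-shifted raw frames into frequency bands.

Under sinusoidal illumination with ``B`` bands the spectrum of the ``p``-th
raw frame of one pattern orientation is a phase-weighted sum of ``2B - 1``
information components,

    D_p(k) = sum_m  C_m(k) * exp(i * m * phi_p),      m = -(B-1) .. +(B-1),

where ``phi_p`` is the pattern phase of that frame (the phase of the first
harmonic) and ``C_m`` holds the sample spectrum shifted by ``m`` times the
pattern step frequency, multiplied by the detection OTF.  Separation
inverts this linear mixing pixel-wise with the Moore-Penrose pseudo-inverse
of the mixing matrix, so any number of phases ``P >= 2B - 1`` is accepted
(redundant phases are combined in the least-squares sense).

Only the ``m >= 0`` components are kept: for real-valued raw data the
negative orders are the Hermitian mirrors of the positive ones.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .fourier import Domain, Field2D, edge_window, forward_transform

__all__ = [
    "Ordering",
    "StackError",
    "SeparationError",
    "RawStack",
    "SeparatedBands",
    "build_mixing_matrix",
    "reorder",
    "separate",
    "exposure_factors",
]


class Ordering(enum.Enum):
    """Frame order of a raw acquisition sequence."""

    PHASE_INNER_ANGLE_OUTER = "paz"  # frame index = angle * P + phase
    ANGLE_INNER_PHASE_OUTER = "apz"  # frame index = phase * A + angle


class StackError(ValueError):
    pass


class SeparationError(ValueError):
    pass


@dataclass
class RawStack:
    """Ordered raw SIM frames with acquisition metadata."""

    frames: list[Field2D]
    n_angles: int
    n_phases: int
    n_bands: int
    ordering: Ordering = Ordering.PHASE_INNER_ANGLE_OUTER
    pixel_size_nm: float = 80.0

    def __post_init__(self) -> None:
        if self.n_angles < 1:
            raise StackError("need at least one pattern orientation")
        if self.n_bands not in (2, 3):
            raise StackError("n_bands must be 2 (two-beam) or 3 (three-beam)")
        if self.n_phases < 2 * self.n_bands - 1:
            raise StackError(
                f"{self.n_phases} phases cannot separate {2 * self.n_bands - 1} "
                f"components; need n_phases >= {2 * self.n_bands - 1}"
            )
        expected = self.n_angles * self.n_phases
        if len(self.frames) != expected:
            raise StackError(f"expected {expected} frames, found {len(self.frames)}")
        sizes = {f.size_px for f in self.frames}
        pix = {f.pixel_size_nm for f in self.frames}
        if len(sizes) != 1 or len(pix) != 1:
            raise StackError("all frames must share size and pixel size")
        for f in self.frames:
            f.require(Domain.REAL)

    @property
    def size_px(self) -> int:
        return self.frames[0].size_px

    def frame(self, angle: int, phase: int) -> Field2D:
        grid = reorder(self.frames, self.ordering, self.n_angles, self.n_phases)
        return grid[angle][phase]


@dataclass
class SeparatedBands:
    """Separated frequency components of one pattern orientation.

    ``components[m]`` houses the ``+m`` order (``m = 0 .. n_bands-1``); the
    ``-m`` orders are the Hermitian mirrors and are not stored.  Component 0
    equals the mean (widefield) spectrum of the orientation's frames.
    """

    components: list[Field2D]
    orientation: int
    phases: np.ndarray

    @property
    def n_bands(self) -> int:
        return len(self.components)


def reorder(
    frames: Sequence, ordering: Ordering, n_angles: int, n_phases: int
) -> list[list]:
    """Group a flat frame sequence as ``grid[angle][phase]``."""
    expected = n_angles * n_phases
    if len(frames) != expected:
        raise StackError(f"expected {expected} frames, found {len(frames)}")
    grid: list[list] = [[None] * n_phases for _ in range(n_angles)]
    for idx, fr in enumerate(frames):
        if ordering is Ordering.PHASE_INNER_ANGLE_OUTER:
            a, p = divmod(idx, n_phases)
        else:
            p, a = divmod(idx, n_angles)
        grid[a][p] = fr
    return grid


def build_mixing_matrix(phases: Sequence[float], n_bands: int) -> np.ndarray:
    """Phase-mixing matrix ``M[p, j] = exp(i*m*phi_p)``.

    Columns are ordered ``m = -(B-1), ..., 0, ..., +(B-1)`` so column
    ``j`` corresponds to order ``m = j - (B - 1)``.  For ``P`` equidistant
    phases the columns are orthogonal and ``M^H M = P * I``.
    """
    phases = np.asarray(phases, dtype=float)
    p, ncomp = phases.size, 2 * n_bands - 1
    if p < ncomp:
        raise SeparationError(
            f"{p} phases under-determine {ncomp} components (need >= {ncomp})"
        )
    m_orders = np.arange(-(n_bands - 1), n_bands)
    mat = np.exp(1j * np.outer(phases, m_orders))
    if np.linalg.matrix_rank(mat, tol=1e-8) < ncomp:
        coll = _colliding_phases(phases, n_bands)
        raise SeparationError(f"mixing matrix is rank-deficient; colliding phases: {coll}")
    return mat


def _colliding_phases(phases: np.ndarray, n_bands: int) -> list[tuple[int, int]]:
    pairs = []
    for i in range(len(phases)):
        for j in range(i + 1, len(phases)):
            if abs((phases[i] - phases[j] + np.pi) % (2 * np.pi) - np.pi) < 1e-9:
                pairs.append((i, j))
    return pairs


def exposure_factors(stack: RawStack) -> np.ndarray:
    """Per-frame rescale factors equalizing mean intensity to the stack median.

    Compensates bleaching / exposure drift which would otherwise leak
    between components through the mixing matrix.
    """
    means = np.array([float(np.real(f.values).mean()) for f in stack.frames])
    if np.any(means <= 0):
        return np.ones_like(means)
    return np.median(means) / means


def separate(
    stack: RawStack,
    orientation: int,
    phases: Optional[Sequence[float]] = None,
    fade_px: Optional[int] = None,
    normalize_exposure: bool = False,
) -> SeparatedBands:
    """Separate the frequency components of one pattern orientation.

    Frames are (optionally) exposure-normalized, edge-windowed, Fourier
    transformed and demixed with the pseudo-inverse of the mixing matrix.
    ``phases`` defaults to ``P`` equidistant steps over 2*pi; a global
    pattern phase offset is *not* part of the matrix -- it stays attached
    to the components and is estimated afterwards.
    """
    if not 0 <= orientation < stack.n_angles:
        raise StackError(f"orientation {orientation} out of range")
    p = stack.n_phases
    if phases is None:
        phases = 2.0 * np.pi * np.arange(p) / p
    phases = np.asarray(phases, dtype=float)
    if phases.size != p:
        raise SeparationError(f"expected {p} phases, got {phases.size}")
    mat = build_mixing_matrix(phases, stack.n_bands)
    pinv = np.linalg.pinv(mat)

    grid = reorder(stack.frames, stack.ordering, stack.n_angles, stack.n_phases)
    factors = exposure_factors(stack) if normalize_exposure else np.ones(len(stack.frames))
    fgrid = reorder(factors, stack.ordering, stack.n_angles, stack.n_phases)
    if fade_px is None:
        fade_px = stack.size_px // 16

    spectra = []
    for ph in range(p):
        fr = grid[orientation][ph]
        scaled = Field2D(fr.values * fgrid[orientation][ph], fr.pixel_size_nm, Domain.REAL)
        spectra.append(forward_transform(edge_window(scaled, fade_px)).values)
    spectra = np.stack(spectra)  # (P, N, N)

    comps = np.einsum("mp,pij->mij", pinv, spectra)
    # keep m = 0 .. B-1 (rows B-1 .. 2B-2 of the solution vector)
    out = [
        Field2D(comps[stack.n_bands - 1 + m], stack.pixel_size_nm, Domain.FREQ)
        for m in range(stack.n_bands)
    ]
    return SeparatedBands(components=out, orientation=orientation, phases=phases)
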
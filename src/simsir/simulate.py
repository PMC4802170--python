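"""Forward simulation of SIM acquisitions with known ground truth.

Emulates the standard fluorescent-bead test sample and the image-formation
chain of a structured-illumination microscope: a nonnegative object is
multiplied by a sinusoidal illumination pattern, blurred with the detection
OTF, scaled to a photon budget and corrupted with Poisson shot noise plus
Gaussian read noise.  Every stochastic choice flows from one explicit seed,
so a stack is bit-reproducible from its ground-truth record.

Pattern conventions
-------------------
``phase`` always denotes the total phase of the *first harmonic* (band 1),
referenced to the field centre ``r0 = (N/2, N/2)``.

* two-beam:    I(r) = 1 + m * cos(2*pi*k.(r-r0)/N + phase)
* three-beam:  I(r) = 1 + m1 * cos(2*pi*(k/2).(r-r0)/N + phase)
                       + m2 * cos(2*pi*k.(r-r0)/N + 2*phase)

so a physical translation of the pattern advances the band-2 harmonic by
exactly twice the band-1 phase.  ``k`` is the full pattern frequency in
cycles/image; the per-order step frequency (the ``k_vector`` stored in
:class:`~simsir.estimate.SimParams`) is ``k`` for two-beam and ``k/2`` for
three-beam data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .bands import Ordering, RawStack
from .fourier import Domain, Field2D, forward_transform, inverse_transform
from .otf import OtfSpec

__all__ = [
    "GroundTruth",
    "make_bead_surface",
    "make_point_pair",
    "illumination_pattern",
    "simulate_stack",
    "default_k_vectors",
]

DEFAULT_ANGLES_DEG = (0.0, 60.0, 120.0)


@dataclass
class GroundTruth:
    """A known object plus everything needed to regenerate its stack."""

    object_image: Field2D
    scene: dict
    seed: int = 0

    def __post_init__(self) -> None:
        self.object_image.require(Domain.REAL)
        if np.any(np.real(self.object_image.values) < -1e-12):
            raise ValueError("ground-truth object must be nonnegative")


def _render_disks(
    n: int, pixel_size_nm: float, centers_px: np.ndarray, radius_px: float
) -> np.ndarray:
    """Anti-aliased disks: per-pixel coverage via a 1-px linear edge ramp."""
    img = np.zeros((n, n))
    y, x = np.mgrid[0:n, 0:n]
    for cx, cy in centers_px:
        r = np.hypot(x - cx, y - cy)
        img += np.clip(radius_px - r + 0.5, 0.0, 1.0)
    return np.clip(img, 0.0, None)


def _splat_point(img: np.ndarray, cx: float, cy: float, amp: float = 1.0) -> None:
    """Bilinear sub-pixel splat of a point emitter (flat spectrum)."""
    x0, y0 = int(np.floor(cx)), int(np.floor(cy))
    fx, fy = cx - x0, cy - y0
    for dy, wy in ((0, 1 - fy), (1, fy)):
        for dx, wx in ((0, 1 - fx), (1, fx)):
            img[y0 + dy, x0 + dx] += amp * wx * wy


def make_bead_surface(
    n_beads: int,
    size_px: int,
    pixel_size_nm: float = 80.0,
    diameter_nm: float = 200.0,
    min_distance_nm: Optional[float] = None,
    margin_px: int = 12,
    seed: int = 0,
    max_tries: int = 10_000,
) -> GroundTruth:
    """Randomly placed, non-overlapping fluorescent beads on a dark field.

    Beads are rendered as anti-aliased disks of the given diameter.
    Placement is rejection sampling with a configurable minimum
    centre-to-centre distance (default: one diameter).
    """
    rng = np.random.default_rng(seed)
    radius_px = 0.5 * diameter_nm / pixel_size_nm
    min_d_px = (min_distance_nm or diameter_nm) / pixel_size_nm
    lo, hi = margin_px, size_px - margin_px
    if hi <= lo:
        raise ValueError("margin leaves no room for beads")
    centers: list[tuple[float, float]] = []
    tries = 0
    while len(centers) < n_beads:
        if tries >= max_tries:
            raise ValueError(
                f"could not place {n_beads} beads after {max_tries} tries; lower the density"
            )
        tries += 1
        c = rng.uniform(lo, hi, size=2)
        if all(np.hypot(c[0] - px, c[1] - py) >= min_d_px for px, py in centers):
            centers.append((float(c[0]), float(c[1])))
    img = _render_disks(size_px, pixel_size_nm, np.asarray(centers), radius_px)
    obj = Field2D(img, pixel_size_nm, Domain.REAL)
    scene = {
        "kind": "bead_surface",
        "n_beads": n_beads,
        "diameter_nm": diameter_nm,
        "centers_px": centers,
        "seed": seed,
    }
    return GroundTruth(obj, scene, seed)


def make_point_pair(
    separation_nm: float,
    size_px: int,
    pixel_size_nm: float = 80.0,
    orientation_deg: float = 0.0,
    amplitude: float = 1.0,
) -> GroundTruth:
    """Deterministic two-point scene for resolution (two-point dip) tests.

    Two unit point emitters, splat with bilinear sub-pixel weights, placed
    symmetrically about the field centre along the given direction.
    """
    img = np.zeros((size_px, size_px))
    half = 0.5 * separation_nm / pixel_size_nm
    th = np.deg2rad(orientation_deg)
    cx, cy = size_px / 2.0, size_px / 2.0
    dx, dy = half * np.cos(th), half * np.sin(th)
    _splat_point(img, cx - dx, cy - dy, amplitude)
    _splat_point(img, cx + dx, cy + dy, amplitude)
    obj = Field2D(img, pixel_size_nm, Domain.REAL)
    scene = {
        "kind": "point_pair",
        "separation_nm": separation_nm,
        "orientation_deg": orientation_deg,
    }
    return GroundTruth(obj, scene, 0)


def illumination_pattern(
    kind: str,
    k_cyc_img: tuple[float, float],
    phase: float,
    modulation: float | tuple[float, float],
    n: int,
) -> np.ndarray:
    """Sinusoidal illumination intensity on an ``n x n`` grid, mean 1.

    ``kind`` is ``"two_beam"`` (one harmonic at ``k``) or ``"three_beam"``
    (harmonics at ``k/2`` and ``k``); ``phase`` is the first-harmonic phase.
    For three-beam, ``modulation`` may be a pair ``(m1, m2)`` of harmonic
    amplitudes (defaults to ``(m, m/2)`` when a scalar is given).
    """
    kx, ky = k_cyc_img
    if np.hypot(kx, ky) > n / 2:
        raise ValueError("pattern frequency beyond the grid Nyquist limit")
    # phases are referenced to the field centre (where the object lives),
    # which decouples the phase estimate from small k-vector errors
    x = np.arange(n) - n // 2
    arg = 2.0 * np.pi * (kx * x[None, :] + ky * x[:, None]) / n
    if kind == "two_beam":
        m = float(np.squeeze(modulation))
        if m < 0 or m > 1:
            raise ValueError(f"two-beam modulation must lie in [0, 1], got {m}")
        return 1.0 + m * np.cos(arg + phase)
    if kind == "three_beam":
        if np.isscalar(modulation):
            m1, m2 = float(modulation), float(modulation) / 2.0
        else:
            m1, m2 = (float(v) for v in modulation)
        return 1.0 + m1 * np.cos(0.5 * arg + phase) + m2 * np.cos(arg + 2.0 * phase)
    raise ValueError(f"unknown pattern kind {kind!r}")


def default_k_vectors(
    n_angles: int,
    k_mag_cyc_img: float,
    angles_deg: Sequence[float] = DEFAULT_ANGLES_DEG,
) -> list[tuple[float, float]]:
    """Pattern k-vectors (full pattern frequency) for each orientation."""
    if len(angles_deg) < n_angles:
        angles_deg = tuple(180.0 * a / n_angles for a in range(n_angles))
    return [
        (
            k_mag_cyc_img * float(np.cos(np.deg2rad(th))),
            k_mag_cyc_img * float(np.sin(np.deg2rad(th))),
        )
        for th in list(angles_deg)[:n_angles]
    ]


def simulate_stack(
    gt: GroundTruth,
    otf: OtfSpec,
    n_angles: int = 3,
    n_phases: int = 3,
    n_bands: int = 2,
    k_vectors: Optional[Sequence[tuple[float, float]]] = None,
    k_frac_of_cutoff: float = 0.9,
    phase_offsets: Optional[Sequence[float]] = None,
    modulation: float | tuple[float, float] = 0.8,
    photons: Optional[float] = 500.0,
    read_noise_e: float = 2.0,
    background: float = 0.0,
    background_sigma_px: float = 20.0,
    ordering: Ordering = Ordering.PHASE_INNER_ANGLE_OUTER,
    seed: int = 0,
    quantize: bool = True,
) -> tuple[RawStack, list[dict]]:
    """Simulate a raw SIM stack; returns the stack and per-orientation truth.

    Each frame is ``OTF_blur(object * pattern) + background`` scaled so the
    brightest pixel of the stack receives ``photons`` expected photons, then
    Poisson shot noise and Gaussian read noise (sigma ``read_noise_e``) are
    applied and the frame is quantized to 16-bit integers.  ``photons=None``
    disables noise and quantization entirely (float frames).

    ``background`` adds an unmodulated, heavily defocus-blurred copy of the
    object (relative amplitude) to every frame, emulating out-of-focus
    light; it exercises the OTF-attenuation path of the reconstruction.

    The truth records store, per orientation, the per-order step frequency
    ``k_vector`` (cycles/image), the first-harmonic ``phase`` and the
    harmonic ``modulations`` -- directly comparable to estimated values.
    """
    obj = gt.object_image
    n = obj.size_px
    if photons is not None and photons <= 0:
        raise ValueError("photon budget must be positive (or None for noise-free)")
    kind = "two_beam" if n_bands == 2 else "three_beam"
    if k_vectors is None:
        kc_um = otf.cutoff_cyc_per_um
        k_mag = k_frac_of_cutoff * kc_um * (n * obj.pixel_size_nm * 1e-3)
        k_vectors = default_k_vectors(n_angles, k_mag)
    k_vectors = [tuple(map(float, kv)) for kv in k_vectors]
    if len(k_vectors) != n_angles:
        raise ValueError("need one pattern k-vector per orientation")
    if phase_offsets is None:
        phase_offsets = [0.0] * n_angles
    rng = np.random.default_rng(seed)
    otf_grid = otf.grid(n, obj.pixel_size_nm)

    bg = 0.0
    if background > 0:
        # unmodulated defocus haze: object blurred by a wide Gaussian
        sig = forward_transform(obj).values
        u = np.arange(n) - n // 2
        f_cyc_px = np.hypot(u[None, :], u[:, None]) / n
        g = np.exp(-2.0 * np.pi**2 * background_sigma_px**2 * f_cyc_px**2)
        blurred = np.fft.ifft2(np.fft.ifftshift(sig * g)).real
        bg = background * np.clip(blurred, 0.0, None)

    expected = []
    for a in range(n_angles):
        for p in range(n_phases):
            phi = phase_offsets[a] + 2.0 * np.pi * p / n_phases
            pat = illumination_pattern(kind, k_vectors[a], phi, modulation, n)
            spec = np.fft.fftshift(np.fft.fft2(np.real(obj.values) * pat))
            frame = np.fft.ifft2(np.fft.ifftshift(spec * otf_grid)).real
            expected.append(np.clip(frame, 0.0, None) + bg)

    peak = max(float(e.max()) for e in expected)
    if peak <= 0:
        raise ValueError("object produces no signal")
    frames_pa: list[list[np.ndarray]] = [[None] * n_phases for _ in range(n_angles)]
    idx = 0
    for a in range(n_angles):
        for p in range(n_phases):
            e = expected[idx]
            idx += 1
            if photons is None:
                out = e
            else:
                scaled = e * (photons / peak)
                noisy = rng.poisson(scaled).astype(float)
                if read_noise_e > 0:
                    noisy += rng.normal(0.0, read_noise_e, size=noisy.shape)
                out = np.clip(noisy, 0.0, 65535.0)
                if quantize:
                    out = np.round(out)
            frames_pa[a][p] = out

    flat: list[Field2D] = []
    total = n_angles * n_phases
    for i in range(total):
        if ordering is Ordering.PHASE_INNER_ANGLE_OUTER:
            a, p = divmod(i, n_phases)
        else:
            p, a = divmod(i, n_angles)
        flat.append(Field2D(frames_pa[a][p], obj.pixel_size_nm, Domain.REAL))

    stack = RawStack(
        frames=flat,
        n_angles=n_angles,
        n_phases=n_phases,
        n_bands=n_bands,
        ordering=ordering,
        pixel_size_nm=obj.pixel_size_nm,
    )
    step = 1.0 if n_bands == 2 else 0.5  # per-order step relative to pattern k
    if np.isscalar(modulation):
        mods = (float(modulation),) if n_bands == 2 else (float(modulation), float(modulation) / 2.0)
    else:
        mods = tuple(float(v) for v in modulation)
    truth = [
        {
            "k_vector": [k_vectors[a][0] * step, k_vectors[a][1] * step],
            "phase": float(phase_offsets[a]),
            "modulations": list(mods[: n_bands - 1]),
            "seed": seed,
        }
        for a in range(n_angles)
    ]
    return stack, truth


def write_truth_json(path: str | Path, truth: list[dict], extra: dict | None = None) -> None:
    obj = {"orientations": truth}
    if extra:
        obj.update(extra)
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
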
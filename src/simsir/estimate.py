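"""Automatic estimation of illumination-pattern parameters.

Per pattern orientation the reconstruction needs the pattern k-vector to
sub-pixel precision, the global pattern phase and the modulation depth.
All three are recovered from the separated bands themselves by weighted
cross-correlation in the spectral overlap region: band ``m`` carries the
object spectrum shifted by ``m`` times the pattern step frequency, so
correlating it against band 0 over all relative shifts peaks exactly at
that shift.  The search runs in two stages:

1. a coarse integer-pixel correlation map (one FFT), with a low-frequency
   disk excluded from the fit -- the widefield overlap always dominates
   there and would otherwise always win;
2. iterative sub-pixel grid refinement: an 11 x 11 grid of candidate
   shifts, shrunk by a zoom factor each iteration, evaluated through
   closed-form fractional-frequency sums (no interpolation).

The complex correlation value at the optimum then yields the pattern phase
(its argument) and the modulation depth (its magnitude, normalized by the
band-0 overlap energy).

Weighting: both bands are divided by the OTF (with a small floor to avoid
amplifying the support edge) and the correlation is restricted to -- and
weighted by -- the product of the two OTFs over the overlap region; under
that weight the compensation cancels algebraically, so the correlation is
computed on the raw masked bands.  The search maximizes the
Cauchy-Schwarz-normalized correlation coefficient rather than the raw
magnitude, which keeps the peak position unbiased when the object's
spectral energy drifts under the moving overlap weight (see
:class:`_CorrelationEngine`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np

from .bands import RawStack, SeparatedBands, reorder, separate, exposure_factors
from .fourier import Domain, Field2D, edge_window, forward_transform, hermitian_mirror
from .otf import OTF_FLOOR, OtfSpec

__all__ = [
    "EstimationError",
    "EstimationOptions",
    "SimParams",
    "common_region_weight",
    "coarse_k_search",
    "refine_k_subpixel",
    "band_correlation",
    "phase_and_modulation",
    "estimate_orientation",
    "estimate_parameters",
    "wicker_phase_refinement",
]


class EstimationError(RuntimeError):
    pass


@dataclass
class EstimationOptions:
    """Tunable knobs of the parameter search.

    ``exclusion_radius_factor`` scales the OTF cutoff to give the radius of
    the low-frequency disk excluded from the coarse fit.  ``iterations``
    and ``zoom`` set the sub-pixel refinement schedule (3 x 10 reaches
    1/1000 px).  ``fade_px`` is the edge-window apron used before
    estimation (default: size/16).
    """

    exclusion_radius_factor: float = 0.4
    iterations: int = 3
    zoom: float = 10.0
    fade_px: Optional[int] = None
    otf_floor: float = OTF_FLOOR
    wicker: bool = False
    normalize_exposure: bool = False


@dataclass
class SimParams:
    """Estimated illumination parameters of one pattern orientation.

    ``k_vector`` is the per-order step frequency in cycles/image: component
    ``m`` of the separated data sits at ``m * k_vector``.  ``phases[m-1]``
    and ``modulations[m-1]`` are the measured global phase and modulation
    depth of band ``m``; phases are referenced to the field centre (for an
    ideal acquisition ``phases[m-1]`` equals ``m`` times the pattern's
    first-harmonic phase offset, modulo 2*pi).
    """

    k_vector: tuple[float, float]
    phases: tuple[float, ...]
    modulations: tuple[float, ...]
    fit_quality: float = 0.0
    flags: list[str] = dc_field(default_factory=list)
    fit_trace: list[dict] = dc_field(default_factory=list, repr=False)

    @property
    def phase_offset(self) -> float:
        """Global pattern phase (band-1 phase), radians in (-pi, pi]."""
        return self.phases[0]

    @property
    def modulation_depth(self) -> float:
        return self.modulations[0]

    @property
    def n_bands(self) -> int:
        return len(self.phases) + 1

    def to_dict(self) -> dict:
        return {
            "k_vector": [float(v) for v in self.k_vector],
            "phases": [float(v) for v in self.phases],
            "modulations": [float(v) for v in self.modulations],
            "fit_quality": float(self.fit_quality),
            "flags": list(self.flags),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimParams":
        return cls(
            k_vector=tuple(d["k_vector"]),
            phases=tuple(d["phases"]),
            modulations=tuple(d["modulations"]),
            fit_quality=float(d.get("fit_quality", 0.0)),
            flags=list(d.get("flags", [])),
        )


# ---------------------------------------------------------------------------
# weighting helpers

def _kc_px(otf: OtfSpec, n: int, pixel_size_nm: float) -> float:
    """OTF cutoff expressed in frequency pixels (= cycles/image)."""
    return otf.cutoff_cyc_per_um * n * pixel_size_nm * 1e-3


def common_region_weight(
    band_index: int,
    k_shift_cyc_img: tuple[float, float],
    otf: OtfSpec,
    n: int,
    pixel_size_nm: float,
    floor: float = OTF_FLOOR,
) -> np.ndarray:
    """Overlap weight ``OTF(k) * OTF(|k - m*k_shift|)`` on the centred grid.

    Zero wherever either factor drops below the OTF floor; raises if the
    two supports are disjoint (shift too large for any overlap).
    """
    o0 = otf.grid(n, pixel_size_nm)
    sx, sy = k_shift_cyc_img
    om = otf.grid(n, pixel_size_nm, (band_index * sx, band_index * sy))
    w = o0 * om
    w[(o0 <= floor) | (om <= floor)] = 0.0
    if not np.any(w > 0):
        raise EstimationError("no spectral overlap between band 0 and the shifted band")
    return w


# ---------------------------------------------------------------------------
# correlation machinery

def _grid_eval(prod: np.ndarray, sx: np.ndarray, sy: np.ndarray) -> np.ndarray:
    """Evaluate ``N^2 * sum_r prod(r) * exp(-2j*pi*s.r/N)`` on an s-grid.

    Exact fractional-frequency DFT samples via two thin matrix products;
    returns ``c[iy, ix]`` for every combination of the candidate shifts.
    """
    n = prod.shape[0]
    x = np.arange(n)
    vx = np.exp(-2j * np.pi * np.outer(x, sx) / n)  # (n, Sx)
    vy = np.exp(-2j * np.pi * np.outer(x, sy) / n)  # (n, Sy)
    return (vy.T @ (prod @ vx)) * n * n  # (Sy, Sx)


def _noise_floor(power: np.ndarray, support_mask: np.ndarray) -> float:
    """Median per-pixel spectral power outside the OTF support.

    For white (shot/read) noise the spectrum is flat, so the out-of-support
    level estimates the noise contribution to every in-support pixel.
    """
    outside = power[~support_mask]
    if outside.size < 16:
        return 0.0
    return float(np.median(outside))


def _center_phase(phase_at_origin: float, shift: tuple[float, float]) -> float:
    """Re-reference a correlation phase from pixel (0, 0) to the field centre.

    The correlation argument carries the pattern phase as seen from the
    array origin; adding ``2*pi*(s . r0)/N = pi*(sx + sy)`` moves the
    reference to the centre pixel, where the imaged structures live.
    """
    ph = phase_at_origin + np.pi * (shift[0] + shift[1])
    return float((ph + np.pi) % (2.0 * np.pi) - np.pi)


class _CorrelationEngine:
    """Normalized weighted cross-correlation of two bands over shifts.

    Under the overlap weight ``w_s(k) = OTF(k) * OTF(k+s)`` the OTF
    compensation of the two bands cancels algebraically,

        c(s) = sum_k w_s(k) comp0*(k) compm(k+s)
             = sum_k [mask*band0]*(k) [mask*bandm](k+s),

    so the correlation is evaluated on the raw masked bands -- exact for
    every fractional ``s`` at once and free of noise amplification at the
    support edge.  The normalization energies

        e0(s) = sum_k w_s |comp0(k)|^2  = corr(|band0|^2/OTF, OTF)(s)
        em(s) = sum_k w_s |compm(k+s)|^2 = corr(OTF, |bandm|^2/OTF)(s)

    are correlations of real fields and share the same fractional-DFT
    evaluation.  The fit maximizes the Cauchy-Schwarz-normalized magnitude
    ``|c| / sqrt(e0 * em)``, which (unlike raw ``|c|``) is unbiased against
    the object's spectral energy distribution drifting under the moving
    weight.
    """

    def __init__(self, band0: Field2D, bandm: Field2D, otf: OtfSpec, floor: float):
        n = band0.size_px
        o = otf.grid(n, band0.pixel_size_nm)
        mask = o > floor
        o_floor = np.maximum(o, floor)
        self.n = n
        ishift = np.fft.ifftshift
        self._a = np.fft.ifft2(ishift(band0.values * mask))
        self._b = np.fft.ifft2(ishift(bandm.values * mask))
        # sparse per-pixel energy densities inside the support; the flat
        # noise floor measured outside the support is subtracted so the
        # normalization energies are unbiased under shot/read noise
        u = np.arange(n) - n // 2
        kxg, kyg = np.meshgrid(u.astype(float), u.astype(float))
        sel = mask.ravel()
        self._kx = kxg.ravel()[sel]
        self._ky = kyg.ravel()[sel]
        p0 = np.abs(band0.values) ** 2
        pm = np.abs(bandm.values) ** 2
        self._p0 = (np.clip(p0 - _noise_floor(p0, mask), 0.0, None) / o_floor).ravel()[sel]
        self._pm = (np.clip(pm - _noise_floor(pm, mask), 0.0, None) / o_floor).ravel()[sel]
        # dense radial OTF lookup table in frequency pixels
        self._rtab = np.linspace(0.0, 1.5 * n, int(np.ceil(6 * n)) + 1)
        fov_um = n * band0.pixel_size_nm * 1e-3
        vtab = otf.value(self._rtab / fov_um)
        self._vtab = np.where(vtab > floor, vtab, 0.0)

    def _otf_at(self, r_px: np.ndarray) -> np.ndarray:
        return np.interp(r_px, self._rtab, self._vtab, right=0.0)

    def energies(self, shift: tuple[float, float]) -> tuple[float, float]:
        """Exact (e0, em) at one shift: OTF weight evaluated analytically."""
        sx, sy = shift
        e0 = float(self._p0 @ self._otf_at(np.hypot(self._kx + sx, self._ky + sy)))
        em = float(self._pm @ self._otf_at(np.hypot(self._kx - sx, self._ky - sy)))
        return e0, em

    def grids(self, sx: np.ndarray, sy: np.ndarray):
        """(c, e0, em) on the shift grid ``sy x sx``.

        ``c`` comes from the exact fractional-DFT identity; the smooth
        energy surfaces are evaluated point-wise through the radial table.
        """
        c = _grid_eval(np.conj(self._a) * self._b, sx, sy)
        e0 = np.empty((sy.size, sx.size))
        em = np.empty((sy.size, sx.size))
        for iy, vy in enumerate(sy):
            for ix, vx in enumerate(sx):
                e0[iy, ix], em[iy, ix] = self.energies((vx, vy))
        return c, e0, em

    def at(self, shift: tuple[float, float]):
        """Exact (c, e0, em, quality) at a single shift."""
        c = complex(_grid_eval(np.conj(self._a) * self._b,
                               np.array([shift[0]]), np.array([shift[1]]))[0, 0])
        e0, em = self.energies(shift)
        q = abs(c) / np.sqrt(e0 * em) if e0 > 0 and em > 0 else 0.0
        return c, e0, em, float(q)


def _argmax_tiebreak(mag: np.ndarray, sx: np.ndarray, sy: np.ndarray) -> tuple[int, int]:
    """Index of the magnitude argmax; ties go to smallest |k|, then lexicographic."""
    best = mag.max()
    iy, ix = np.nonzero(mag >= best * (1.0 - 1e-12))
    if len(iy) == 1:
        return int(iy[0]), int(ix[0])
    kx, ky = sx[ix], sy[iy]
    order = np.lexsort((ky, kx, np.hypot(kx, ky)))
    return int(iy[order[0]]), int(ix[order[0]])


def coarse_k_search(
    band0: Field2D,
    band1: Field2D,
    otf: OtfSpec,
    exclusion_radius_px: Optional[float] = None,
    floor: float = OTF_FLOOR,
) -> tuple[tuple[int, int], np.ndarray]:
    """Integer-pixel pattern-shift candidate from a full correlation map.

    Returns the argmax shift ``(kx, ky)`` in frequency pixels and the
    correlation-magnitude map (centred layout) for diagnostics.  The disk
    ``|k| <= exclusion_radius`` is excluded from the fit: band overlap at
    small shifts is dominated by low-frequency content regardless of the
    pattern, which is exactly the failure the exclusion region prevents.
    A peak touching the exclusion (or outer) boundary triggers a warning.
    """
    band0.require(Domain.FREQ)
    band1.require(Domain.FREQ)
    n = band0.size_px
    if not np.any(band0.values) or not np.any(band1.values):
        raise EstimationError("all-zero band; nothing to correlate")
    kc = _kc_px(otf, n, band0.pixel_size_nm)
    if exclusion_radius_px is None:
        exclusion_radius_px = 0.4 * kc
    o = otf.grid(n, band0.pixel_size_nm)
    mask = o > floor
    ofl = np.maximum(o, floor)
    fft2, fshift, ishift = np.fft.fft2, np.fft.fftshift, np.fft.ifftshift
    a = np.fft.ifft2(ishift(band0.values * mask))
    b = np.fft.ifft2(ishift(band1.values * mask))
    pow0 = np.abs(band0.values) ** 2
    powm = np.abs(band1.values) ** 2
    pow0 = np.clip(pow0 - _noise_floor(pow0, mask), 0.0, None)
    powm = np.clip(powm - _noise_floor(powm, mask), 0.0, None)
    p0 = np.fft.ifft2(ishift(pow0 / ofl * mask))
    pm = np.fft.ifft2(ishift(powm / ofl * mask))
    q = np.fft.ifft2(ishift(o * mask))
    # integer-shift correlation and energy maps (exact at integer shifts)
    cmap = fshift(fft2(np.conj(a) * b)) * n * n
    e0map = fshift(fft2(np.conj(p0) * q)).real * n * n
    emmap = fshift(fft2(np.conj(q) * pm)).real * n * n
    # normalized correlation coefficient; guard against empty-overlap cells
    denom = np.sqrt(np.clip(e0map, 0.0, None) * np.clip(emmap, 0.0, None))
    floor_e = 1e-9 * max(denom.max(), 1e-300)
    mag = np.abs(cmap) / np.maximum(denom, floor_e)
    mag[denom <= floor_e] = 0.0
    u = np.arange(n) - n // 2
    r = np.hypot(u[None, :], u[:, None])
    outer = min(1.9 * kc, n / 2 - 1)
    valid = (r > exclusion_radius_px) & (r <= outer)
    if not valid.any():
        raise EstimationError("exclusion radius leaves no search region")
    mag_masked = np.where(valid, mag, -np.inf)
    iy, ix = np.unravel_index(int(np.argmax(mag_masked)), mag.shape)
    k = (int(ix - n // 2), int(iy - n // 2))
    peak_r = float(np.hypot(*k))
    if peak_r <= exclusion_radius_px + 1.5 or peak_r >= outer - 1.5:
        warnings.warn(
            "correlation peak lies on the search-region boundary; "
            "the parameter fit likely failed (check the exclusion radius)",
            stacklevel=2,
        )
    elif mag[iy, ix] < 0.45:
        warnings.warn(
            f"weak correlation peak (normalized height {mag[iy, ix]:.2f}); "
            "the parameter fit likely failed (check the exclusion radius and "
            "the pattern modulation)",
            stacklevel=2,
        )
    return k, mag


def refine_k_subpixel(
    band0: Field2D,
    bandm: Field2D,
    otf: OtfSpec,
    k0: tuple[float, float],
    iterations: int = 3,
    zoom: float = 10.0,
    floor: float = OTF_FLOOR,
) -> tuple[tuple[float, float], complex, float, list[dict]]:
    """Iterative sub-pixel refinement of the correlation peak.

    Starting from the coarse candidate ``k0`` (within one pixel of the true
    peak), evaluates the weighted complex correlation on an 11 x 11 grid of
    spacing ``zoom**-i`` pixels around the current best at iteration ``i``,
    keeping the magnitude argmax.  After the final iteration the
    correlation is re-evaluated exactly at the optimum.

    Returns ``(k, c, band0_overlap_energy, trace)`` where ``c`` is the
    complex correlation at the optimum and the trace holds one magnitude
    panel per iteration for diagnostics.
    """
    band0.require(Domain.FREQ)
    bandm.require(Domain.FREQ)
    engine = _CorrelationEngine(band0, bandm, otf, floor)
    center = (float(k0[0]), float(k0[1]))
    offsets = np.arange(-5, 6, dtype=float)
    best_q = -np.inf
    trace: list[dict] = []
    for i in range(1, iterations + 1):
        step = zoom ** (-i)
        sx = center[0] + offsets * step
        sy = center[1] + offsets * step
        c, e0, em = engine.grids(sx, sy)
        denom = np.sqrt(e0 * em)
        guard = 1e-9 * max(float(denom.max()), 1e-300)
        mag = np.abs(c) / np.maximum(denom, guard)
        mag[denom <= guard] = 0.0
        iy, ix = _argmax_tiebreak(mag, sx, sy)
        trace.append({"center": center, "step": step, "magnitude": mag})
        if mag[iy, ix] < best_q * (1.0 - 1e-12):
            warnings.warn(
                "correlation magnitude did not improve during sub-pixel "
                "refinement; returning best-so-far",
                stacklevel=2,
            )
            break
        best_q = mag[iy, ix]
        center = (float(sx[ix]), float(sy[iy]))
    c_opt, energy0, _, _ = engine.at(center)
    return center, c_opt, energy0, trace


def band_correlation(
    band0: Field2D,
    bandm: Field2D,
    otf: OtfSpec,
    shift_cyc_img: tuple[float, float],
    floor: float = OTF_FLOOR,
) -> tuple[complex, float, float]:
    """Weighted correlation of two bands at a fixed relative shift.

    Returns ``(c, band0_overlap_energy, quality)`` where quality is the
    Cauchy-Schwarz-normalized correlation peak height in [0, 1].
    """
    band0.require(Domain.FREQ)
    bandm.require(Domain.FREQ)
    c, e0, _, quality = _CorrelationEngine(band0, bandm, otf, floor).at(shift_cyc_img)
    return c, e0, quality


def phase_and_modulation(
    c: complex,
    band0_energy: float,
    shift_cyc_img: Optional[tuple[float, float]] = None,
) -> tuple[float, float, list[str]]:
    """Pattern phase and modulation depth from the correlation optimum.

    The correlation of the OTF-compensated bands equals
    ``(m/2) * exp(i*phase) * sum_overlap w |O|^2`` for a perfect forward
    model, so ``phase = arg(c)`` and ``m = 2|c| / sum_overlap w |band0|^2``.
    When the band shift is given, the phase is re-referenced to the field
    centre (the convention used throughout).  Modulation values outside
    (0, 1.5] are clamped and flagged; values outside (0.3, 1.1) are flagged
    as suspicious but kept.
    """
    flags: list[str] = []
    if band0_energy <= 0:
        raise EstimationError("band-0 overlap energy is zero; cannot normalize")
    phase = float(np.angle(c))
    if shift_cyc_img is not None:
        phase = _center_phase(phase, shift_cyc_img)
    mod = 2.0 * abs(c) / band0_energy
    if mod <= 0.0 or mod > 1.5:
        flags.append("modulation_out_of_range")
        mod = min(max(mod, 1e-6), 1.5)
    elif not 0.3 < mod < 1.1:
        flags.append("modulation_suspicious")
    return phase, float(mod), flags


# ---------------------------------------------------------------------------
# per-orientation driver

def estimate_orientation(
    stack: RawStack,
    orientation: int,
    otf: OtfSpec,
    opts: Optional[EstimationOptions] = None,
) -> SimParams:
    """Recover k-vector, per-band phases and modulation depths for one orientation.

    The highest band anchors the k fit (largest lever arm: its correlation
    peak sits at ``(B-1) * k``); lower bands are then fitted for phase and
    modulation at their derived shifts.  With ``opts.wicker`` enabled the
    per-frame pattern phases are measured individually afterwards and the
    separation repeated with the measured (possibly non-equidistant) phases.
    """
    opts = opts or EstimationOptions()
    sep = separate(
        stack,
        orientation,
        fade_px=opts.fade_px,
        normalize_exposure=opts.normalize_exposure,
    )
    b0 = sep.components[0]
    anchor = stack.n_bands - 1
    kc = _kc_px(otf, stack.size_px, stack.pixel_size_nm)
    excl = opts.exclusion_radius_factor * kc
    k_coarse, _ = coarse_k_search(b0, sep.components[anchor], otf, excl, opts.otf_floor)
    k_anchor, c_anchor, e0_anchor, trace = refine_k_subpixel(
        b0,
        sep.components[anchor],
        otf,
        k_coarse,
        iterations=opts.iterations,
        zoom=opts.zoom,
        floor=opts.otf_floor,
    )
    k1 = (k_anchor[0] / anchor, k_anchor[1] / anchor)

    if opts.wicker:
        try:
            phases = wicker_phase_refinement(stack, orientation, k1, otf, opts)
            sep = separate(
                stack,
                orientation,
                phases=phases,
                fade_px=opts.fade_px,
                normalize_exposure=opts.normalize_exposure,
            )
            b0 = sep.components[0]
        except EstimationError as exc:
            warnings.warn(f"per-frame phase refinement failed ({exc}); "
                          "keeping equidistant phases", stacklevel=2)

    flags: list[str] = []
    phases_out: list[float] = []
    mods_out: list[float] = []
    quality = 0.0
    for m in range(1, stack.n_bands):
        shift = (m * k1[0], m * k1[1])
        c_m, e0, q = band_correlation(b0, sep.components[m], otf, shift, opts.otf_floor)
        ph, mod, fl = phase_and_modulation(c_m, e0, shift)
        phases_out.append(ph)
        mods_out.append(mod)
        flags.extend(f"band{m}:{f}" for f in fl)
        if m == anchor:
            quality = q

    k_mag = float(np.hypot(*k_anchor))
    if not excl < k_mag <= 1.2 * kc * anchor:
        flags.append("k_outside_expected_range")
    return SimParams(
        k_vector=k1,
        phases=tuple(phases_out),
        modulations=tuple(mods_out),
        fit_quality=quality,
        flags=flags,
        fit_trace=trace,
    )


def estimate_parameters(
    stack: RawStack,
    otf: OtfSpec,
    opts: Optional[EstimationOptions] = None,
) -> list[SimParams]:
    """Estimate illumination parameters for every pattern orientation."""
    return [estimate_orientation(stack, a, otf, opts) for a in range(stack.n_angles)]


def wicker_phase_refinement(
    stack: RawStack,
    orientation: int,
    k1_cyc_img: tuple[float, float],
    otf: OtfSpec,
    opts: Optional[EstimationOptions] = None,
) -> np.ndarray:
    """Measure each frame's absolute pattern phase individually.

    Each frame's spectrum, with the orientation's widefield (zero-order)
    spectrum removed, is correlated against the widefield at the pattern
    shift; the argument of that correlation is the frame's first-harmonic
    phase.  Like all single-stack per-frame phase estimators, the result
    carries an object-dependent bias from the spectral self-overlap of the
    remaining orders (chiefly the mirror order) -- of the order of a tenth
    of a radian for sparse objects, smaller for dense samples.  With the
    minimal number of phases (P = 2B-1) this bias is not removable from
    the data alone: any phase guess reproduces the frames exactly through
    the pseudo-inverse, so no internal criterion can discriminate further.

    Raises :class:`EstimationError` when the pattern signal is too weak to
    trust (e.g. zero modulation); callers fall back to equidistant phases.
    """
    opts = opts or EstimationOptions()
    fade = opts.fade_px if opts.fade_px is not None else stack.size_px // 16
    grid = reorder(stack.frames, stack.ordering, stack.n_angles, stack.n_phases)
    factors = (
        exposure_factors(stack) if opts.normalize_exposure else np.ones(len(stack.frames))
    )
    fgrid = reorder(factors, stack.ordering, stack.n_angles, stack.n_phases)
    n = stack.size_px
    o = otf.grid(n, stack.pixel_size_nm)
    mask = o > opts.otf_floor
    spectra = []
    for p in range(stack.n_phases):
        fr = grid[orientation][p]
        scaled = Field2D(fr.values * fgrid[orientation][p], fr.pixel_size_nm, Domain.REAL)
        spectra.append(forward_transform(edge_window(scaled, fade)).values * mask)

    c0 = Field2D(np.mean(spectra, axis=0), stack.pixel_size_nm, Domain.FREQ)
    phases, qualities = [], []
    for sp in spectra:
        resid = Field2D(sp - c0.values, stack.pixel_size_nm, Domain.FREQ)
        c, _, q = band_correlation(c0, resid, otf, k1_cyc_img, opts.otf_floor)
        phases.append(_center_phase(float(np.angle(c)), k1_cyc_img))
        qualities.append(q)
    if min(qualities) < 0.1:
        raise EstimationError(
            f"per-frame phase correlation too weak (min quality {min(qualities):.3g})"
        )
    return np.asarray(phases)
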
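"""Complex 2-D field container and the Fourier primitives used throughout.

Conventions
-----------
* The forward DFT is unnormalized (``numpy.fft.fft2``); the inverse carries
  the full ``1/N**2`` factor.  All filter formulas elsewhere are written to
  be invariant under this choice.
* Spectra are stored with the zero frequency at the array *centre*
  (``fftshift`` layout).  Frequency pixel ``u`` along an axis corresponds to
  ``u - N/2`` cycles per image.
* Pixel indices are 0-based; arrays are indexed ``[y, x]`` while vectors
  (shifts, k-vectors) are ordered ``(kx, ky)``.
* ``subpixel_shift(f, s)`` multiplies the real-space field by
  ``exp(+2j*pi*(sx*x + sy*y)/N)``, which translates the spectrum by ``+s``
  frequency pixels: content at frequency ``k`` moves to ``k + s``.  For
  integer ``s`` this is an exact circular roll of the spectrum.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Domain",
    "DomainError",
    "Field2D",
    "forward_transform",
    "inverse_transform",
    "subpixel_shift",
    "translate_spectrum",
    "paste_double",
    "edge_window",
    "power_spectrum",
    "hermitian_mirror",
    "freq_radii_cyc_per_img",
    "cyc_img_to_cyc_um",
    "radial_profile",
    "support_radius",
]


class Domain(enum.Enum):
    """Domain tag of a :class:`Field2D`: real space or frequency space."""

    REAL = "real"
    FREQ = "freq"


class DomainError(ValueError):
    """An operation received a field in the wrong domain."""


@dataclass
class Field2D:
    """A square complex 2-D image or spectrum with sampling metadata.

    Parameters
    ----------
    values : ndarray
        ``(N, N)`` complex samples, indexed ``[y, x]``.
    pixel_size_nm : float
        Real-space sampling in nanometres (of the real-space image this
        field, or its inverse transform, represents).
    domain : Domain
        Whether ``values`` live in real or frequency space.
    """

    values: np.ndarray
    pixel_size_nm: float
    domain: Domain = Domain.REAL

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError(f"field must be square 2-D, got shape {self.values.shape}")
        n = self.values.shape[0]
        if n < 16 or n % 2:
            raise ValueError(f"edge length must be even and >= 16, got {n}")
        if not self.pixel_size_nm > 0:
            raise ValueError(f"pixel_size_nm must be positive, got {self.pixel_size_nm}")

    @property
    def size_px(self) -> int:
        return self.values.shape[0]

    @property
    def field_of_view_um(self) -> float:
        """Real-space extent of one edge, in micrometres."""
        return self.size_px * self.pixel_size_nm * 1e-3

    def require(self, domain: Domain) -> None:
        if self.domain is not domain:
            raise DomainError(f"expected {domain.name} field, got {self.domain.name}")

    def copy(self) -> "Field2D":
        return replace(self, values=self.values.copy())


def forward_transform(f: Field2D) -> Field2D:
    """Unnormalized forward DFT, zero frequency moved to the array centre."""
    f.require(Domain.REAL)
    spec = np.fft.fftshift(np.fft.fft2(f.values))
    return Field2D(spec, f.pixel_size_nm, Domain.FREQ)


def inverse_transform(f: Field2D) -> Field2D:
    """Inverse DFT (carries the 1/N^2 normalization)."""
    f.require(Domain.FREQ)
    img = np.fft.ifft2(np.fft.ifftshift(f.values))
    return Field2D(img, f.pixel_size_nm, Domain.REAL)


def _phase_ramp(n: int, shift: tuple[float, float]) -> np.ndarray:
    sx, sy = shift
    x = np.arange(n)
    rx = np.exp(2j * np.pi * sx * x / n)
    ry = np.exp(2j * np.pi * sy * x / n)
    return np.outer(ry, rx)  # [y, x]


def subpixel_shift(f: Field2D, shift: tuple[float, float]) -> Field2D:
    """Translate the field's spectrum by ``shift`` frequency pixels.

    The shift may be fractional.  Implemented as multiplication of the
    real-space field by a complex linear phase; spectrum content at ``k``
    moves to ``k + shift``.
    """
    f.require(Domain.REAL)
    return Field2D(f.values * _phase_ramp(f.size_px, shift), f.pixel_size_nm, Domain.REAL)


def translate_spectrum(f: Field2D, shift: tuple[float, float]) -> Field2D:
    """Same translation as :func:`subpixel_shift` but applied to a spectrum."""
    f.require(Domain.FREQ)
    return forward_transform(subpixel_shift(inverse_transform(f), shift))


def paste_double(f: Field2D, target_size: int) -> Field2D:
    """Embed an ``N x N`` spectrum centred into a ``2N x 2N`` zero spectrum.

    The field of view is unchanged, so the frequency sampling in cycles per
    image is unchanged; the corresponding real-space pixel size halves.
    """
    f.require(Domain.FREQ)
    n = f.size_px
    if target_size != 2 * n:
        raise ValueError(f"target_size must be 2*{n}, got {target_size}")
    out = np.zeros((target_size, target_size), dtype=np.complex128)
    lo = n // 2
    out[lo : lo + n, lo : lo + n] = f.values
    return Field2D(out, f.pixel_size_nm / 2.0, Domain.FREQ)


def _window_1d(n: int, fade_px: int) -> np.ndarray:
    d = np.minimum(np.arange(n), n - 1 - np.arange(n)).astype(float)
    w = np.ones(n)
    apron = d < fade_px
    w[apron] = 0.5 * (1.0 - np.cos(np.pi * d[apron] / fade_px))
    return w


def edge_window(f: Field2D, fade_px: int) -> Field2D:
    """Raised-cosine apron of width ``fade_px`` at every border.

    Suppresses wrap-around discontinuities before FFT-based processing.
    ``fade_px = 0`` is the identity; border pixels go to exactly zero for
    any positive fade.
    """
    f.require(Domain.REAL)
    if fade_px < 0 or fade_px > f.size_px // 4:
        raise ValueError(f"fade_px must be in [0, {f.size_px // 4}], got {fade_px}")
    if fade_px == 0:
        return f.copy()
    w = _window_1d(f.size_px, fade_px)
    return Field2D(f.values * np.outer(w, w), f.pixel_size_nm, Domain.REAL)


def power_spectrum(f: Field2D, transform: str = "log") -> np.ndarray:
    """``|F(k)|^2`` mapped through a display transform, for diagnostics.

    ``transform`` is ``"log"`` (``log(1+x)``, default), ``"sqrt"`` (gamma
    0.5) or ``"none"``.  Axis calibration: one frequency pixel equals
    ``1/(N * pixel_size)`` cycles/nm.
    """
    f.require(Domain.FREQ)
    p = np.abs(f.values) ** 2
    if transform == "log":
        return np.log1p(p)
    if transform == "sqrt":
        return np.sqrt(p)
    if transform == "none":
        return p
    raise ValueError(f"unknown display transform {transform!r}")


def hermitian_mirror(f: Field2D) -> Field2D:
    """Return ``conj(F(-k))`` on the centred grid.

    The spectrum of a real image is invariant under this map.  On an even
    grid the mirror is a flip followed by a one-pixel roll along each axis
    (the Nyquist row/column map to themselves).
    """
    f.require(Domain.FREQ)
    v = np.conj(np.roll(np.flip(f.values), 1, axis=(0, 1)))
    return Field2D(v, f.pixel_size_nm, Domain.FREQ)


def freq_radii_cyc_per_img(n: int) -> np.ndarray:
    """Radial frequency magnitude |k| in cycles/image on the centred grid."""
    u = np.arange(n) - n // 2
    return np.hypot(u[None, :], u[:, None])


def cyc_img_to_cyc_um(k_cyc_img: float | np.ndarray, n: int, pixel_size_nm: float):
    """Convert cycles/image to cycles/micrometre for an ``n``-pixel field."""
    return np.asarray(k_cyc_img) / (n * pixel_size_nm * 1e-3)


def radial_profile(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Azimuthal mean of ``arr`` over integer-radius bins around the centre.

    Returns ``(radii, mean)`` with radii in frequency pixels (= cycles per
    image for a centred spectrum).
    """
    n = arr.shape[0]
    r = freq_radii_cyc_per_img(n)
    bins = np.round(r).astype(int).ravel()
    sums = np.bincount(bins, weights=np.abs(arr).ravel())
    counts = np.bincount(bins)
    radii = np.arange(len(sums))
    return radii, sums / np.maximum(counts, 1)


def support_radius(
    f: Field2D,
    threshold: float = 1e-3,
    inband_cyc_img: tuple[float, float] = (5.0, 20.0),
) -> float:
    """Radius (cycles/image) where azimuthal power falls below threshold.

    The reference "in-band" level is the mean azimuthal power over the
    given radius window; the support is the largest radius whose azimuthal
    mean power still reaches ``threshold`` times that level.  Measured in
    cycles/image it is directly comparable between a raw-size spectrum and
    the doubled reconstruction grid (same field of view).
    """
    f.require(Domain.FREQ)
    radii, prof = radial_profile(np.abs(f.values) ** 2)
    lo, hi = inband_cyc_img
    sel = (radii >= lo) & (radii <= hi)
    if not sel.any():
        raise ValueError("in-band radius window is empty")
    ref = float(prof[sel].mean())
    above = np.nonzero(prof >= threshold * ref)[0]
    return float(radii[above[-1]]) if above.size else 0.0
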
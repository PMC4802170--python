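"""Optical transfer function models.

The in-focus, incoherent 2-D OTF of a circular pupil is the normalized
autocorrelation of the pupil disk,

    OTF(nu) = (2/pi) * (arccos(nu) - nu*sqrt(1 - nu**2)),   nu = k/kc,

cutting off at ``kc = 2*NA/lambda_em``.  This closed form is used whenever
no measured OTF is supplied.  Measured OTFs are read from a plain
two-column text table or a small JSON dialect and interpolated with a
monotone cubic (PCHIP).

For single-slice reconstructions an *attenuated* OTF damps the frequencies
near zero with an inverted Gaussian notch,

    att(k) = 1 - a * exp(-k**2 / (2*sigma**2)),

suppressing out-of-focus background and restoring a degree of optical
sectioning.  The notch parameters (strength ``a``, FWHM) are heuristic and
exposed as configuration.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.interpolate import PchipInterpolator

from .fourier import Domain, Field2D, freq_radii_cyc_per_img

__all__ = [
    "OtfError",
    "OtfFormatError",
    "OtfSpec",
    "otf_cutoff",
    "ideal_otf",
    "attenuation_factor",
    "apply_otf",
    "read_otf_file",
]

#: Lower bound used wherever a spectrum is divided by the OTF
#: (parameter-estimation weighting); avoids amplifying noise at the
#: support edge.
OTF_FLOOR = 1e-4


class OtfError(ValueError):
    pass


class OtfFormatError(OtfError):
    """A tabulated OTF file violates the expected format."""


def otf_cutoff(na: float, lambda_em_nm: float) -> float:
    """Incoherent lateral cutoff ``kc = 2*NA/lambda`` in cycles/micrometre.

    ``lambda_em_nm`` is the *emission* wavelength of the fluorophore, not
    the excitation line.
    """
    if na <= 0 or lambda_em_nm <= 0:
        raise OtfError("numerical aperture and emission wavelength must be positive")
    return 2.0 * na / (lambda_em_nm * 1e-3)


@dataclass
class OtfSpec:
    """Radially symmetric OTF with optional tabulated profile.

    Attributes
    ----------
    na, lambda_em_nm :
        Objective numerical aperture and fluorophore emission wavelength.
    source :
        ``"ideal"`` (pupil-autocorrelation closed form) or ``"from_file"``.
    profile :
        Interpolator ``k [cyc/um] -> value`` when ``source == "from_file"``.
    attenuation_strength, attenuation_fwhm_cyc_per_um :
        Parameters of the low-frequency attenuation notch.
    """

    na: float
    lambda_em_nm: float
    source: str = "ideal"
    profile: Optional[PchipInterpolator] = field(default=None, repr=False)
    profile_max_k: float = 0.0
    attenuation_strength: float = 0.99
    attenuation_fwhm_cyc_per_um: float = 1.2

    def __post_init__(self) -> None:
        if self.na <= 0 or self.lambda_em_nm <= 0:
            raise OtfError("numerical aperture and emission wavelength must be positive")
        if not 0.0 <= self.attenuation_strength <= 1.0:
            raise OtfError("attenuation strength must lie in [0, 1]")
        if self.attenuation_fwhm_cyc_per_um <= 0:
            raise OtfError("attenuation FWHM must be positive")
        if self.source not in ("ideal", "from_file"):
            raise OtfError(f"unknown OTF source {self.source!r}")
        if self.source == "from_file" and self.profile is None:
            raise OtfError("source 'from_file' requires a tabulated profile")

    @property
    def cutoff_cyc_per_um(self) -> float:
        return otf_cutoff(self.na, self.lambda_em_nm)

    def value(self, k_cyc_per_um) -> np.ndarray:
        """OTF value at radial frequency ``k`` (cycles/um); vectorized."""
        k = np.asarray(k_cyc_per_um, dtype=float)
        if np.any(k < 0):
            raise OtfError("radial frequency must be non-negative")
        if self.source == "ideal":
            return ideal_otf(self, k)
        out = np.clip(self.profile(np.clip(k, 0.0, self.profile_max_k)), 0.0, 1.0)
        return np.where(k > self.profile_max_k, 0.0, out)

    def attenuation(self, k_cyc_per_um) -> np.ndarray:
        return attenuation_factor(self, k_cyc_per_um)

    def grid(
        self,
        n: int,
        pixel_size_nm: float,
        center_cyc_img: tuple[float, float] = (0.0, 0.0),
        attenuated: bool = False,
    ) -> np.ndarray:
        """Sample the (optionally attenuated) OTF on an ``n x n`` centred grid.

        ``center_cyc_img`` places the OTF origin at that frequency-pixel
        offset from the array centre (used for shifted band weights).
        """
        fov_um = n * pixel_size_nm * 1e-3
        u = np.arange(n) - n // 2
        kx = (u[None, :] - center_cyc_img[0]) / fov_um
        ky = (u[:, None] - center_cyc_img[1]) / fov_um
        k = np.hypot(kx, ky)
        v = self.value(k)
        if attenuated:
            v = v * self.attenuation(k)
        return v


def ideal_otf(spec: OtfSpec, k_cyc_per_um) -> np.ndarray:
    """Closed-form incoherent 2-D OTF (normalized pupil autocorrelation)."""
    k = np.asarray(k_cyc_per_um, dtype=float)
    if np.any(k < 0):
        raise OtfError("radial frequency must be non-negative")
    nu = np.clip(k / spec.cutoff_cyc_per_um, 0.0, 1.0)
    val = (2.0 / np.pi) * (np.arccos(nu) - nu * np.sqrt(1.0 - nu * nu))
    return np.where(np.asarray(k_cyc_per_um) >= spec.cutoff_cyc_per_um, 0.0, val)


def attenuation_factor(spec: OtfSpec, k_cyc_per_um) -> np.ndarray:
    """Inverted-Gaussian notch ``1 - a*exp(-k^2/(2 sigma^2))``.

    ``sigma`` derives from the configured FWHM; ``a = 0`` disables the
    attenuation (returns 1 everywhere).
    """
    k = np.asarray(k_cyc_per_um, dtype=float)
    sigma = spec.attenuation_fwhm_cyc_per_um / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    return 1.0 - spec.attenuation_strength * np.exp(-(k * k) / (2.0 * sigma * sigma))


def apply_otf(
    spectrum: Field2D,
    spec: OtfSpec,
    band_shift_cyc_img: tuple[float, float] = (0.0, 0.0),
    attenuated: bool = False,
) -> Field2D:
    """Multiply a spectrum by the OTF centred at ``band_shift`` (cyc/image)."""
    spectrum.require(Domain.FREQ)
    g = spec.grid(spectrum.size_px, spectrum.pixel_size_nm, band_shift_cyc_img, attenuated)
    return Field2D(spectrum.values * g, spectrum.pixel_size_nm, Domain.FREQ)


def _spec_from_samples(
    k: np.ndarray, v: np.ndarray, na: float, lambda_em_nm: float, origin: str
) -> OtfSpec:
    if k.size < 2:
        raise OtfFormatError(f"{origin}: need at least two (k, value) rows, got {k.size}")
    if np.any(np.diff(k) <= 0):
        row = int(np.nonzero(np.diff(k) <= 0)[0][0]) + 2
        raise OtfFormatError(f"{origin}: k values must be strictly increasing (row {row})")
    bad = np.nonzero((v > 1.05) | (v < -0.05))[0]
    if bad.size:
        raise OtfFormatError(
            f"{origin}: OTF value {v[bad[0]]:g} out of range [-0.05, 1.05] (row {bad[0] + 1})"
        )
    if k[0] > 1e-9:
        raise OtfFormatError(f"{origin}: table must start at k = 0 (first k is {k[0]:g})")
    kc = otf_cutoff(na, lambda_em_nm)
    if k[-1] < kc:
        raise OtfFormatError(
            f"{origin}: table covers k up to {k[-1]:g} but must reach the cutoff {kc:g} cyc/um"
        )
    gaps = np.diff(k)
    if np.any(gaps[k[:-1] < kc] > kc / 2):
        raise OtfFormatError(f"{origin}: sampling gap larger than kc/2 below the cutoff")
    v = np.clip(v, 0.0, 1.0)
    if v[0] <= 0:
        raise OtfFormatError(f"{origin}: value at k = 0 must be positive")
    v = v / v[0]  # renormalize so OTF(0) = 1
    interp = PchipInterpolator(k, v, extrapolate=False)
    return OtfSpec(
        na=na,
        lambda_em_nm=lambda_em_nm,
        source="from_file",
        profile=interp,
        profile_max_k=float(k[-1]),
    )


def read_otf_file(
    path: str | Path,
    na: float | None = None,
    lambda_em_nm: float | None = None,
) -> OtfSpec:
    """Read a tabulated OTF.

    Two formats are accepted:

    * whitespace-separated two-column text (``k [cyc/um]  value``), ``#``
      comments allowed; ``na`` and ``lambda_em_nm`` must then be supplied;
    * a JSON object ``{"na": .., "lambda_em_nm": .., "samples": [[k, v], ..]}``.

    The profile is clamped to [0, 1], renormalized so value(0) = 1, and
    interpolated with a monotone cubic.
    """
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith("{"):
        obj = json.loads(text)
        try:
            samples = np.asarray(obj["samples"], dtype=float)
            na_f, lam_f = float(obj["na"]), float(obj["lambda_em_nm"])
        except (KeyError, TypeError, ValueError) as exc:
            raise OtfFormatError(f"{path}: malformed JSON OTF ({exc})") from None
        if samples.ndim != 2 or samples.shape[1] != 2:
            raise OtfFormatError(f"{path}: 'samples' must be a list of [k, value] pairs")
        return _spec_from_samples(samples[:, 0], samples[:, 1], na_f, lam_f, str(path))
    if na is None or lambda_em_nm is None:
        raise OtfError("text-format OTF tables require na and lambda_em_nm")
    rows = []
    for i, line in enumerate(text.splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise OtfFormatError(f"{path}: expected two columns on line {i}")
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except ValueError:
            raise OtfFormatError(f"{path}: non-numeric entry on line {i}") from None
    arr = np.asarray(rows, dtype=float).reshape(-1, 2)
    return _spec_from_samples(arr[:, 0], arr[:, 1], na, lambda_em_nm, str(path))
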
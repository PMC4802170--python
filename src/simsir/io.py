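"""File I/O: multi-page TIFF stacks, parameter JSON, diagnostic exports.

Raw input is grayscale multi-page TIFF (16-bit unsigned or 32-bit float);
anything the pipeline writes is 32-bit float TIFF plus JSON sidecars.
Non-square pages are centre-cropped (with a logged warning) since the
Fourier pipeline operates on square, even-sized fields.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

from .bands import RawStack
from .config import ReconConfig
from .estimate import SimParams
from .fourier import Domain, Field2D, power_spectrum

__all__ = [
    "StackIOError",
    "load_stacks",
    "load_stack",
    "write_stack_tiff",
    "write_image_tiff",
    "write_params_json",
    "read_params_json",
]

log = logging.getLogger("simsir")


class StackIOError(ValueError):
    pass


def _crop_square_even(page: np.ndarray, origin: str) -> np.ndarray:
    h, w = page.shape
    edge = min(h, w)
    edge -= edge % 2
    if (h, w) != (edge, edge):
        log.warning("%s: page %dx%d centre-cropped to %dx%d", origin, w, h, edge, edge)
        y0, x0 = (h - edge) // 2, (w - edge) // 2
        page = page[y0 : y0 + edge, x0 : x0 + edge]
    return page


def load_stacks(path: str | Path, config: ReconConfig) -> list[RawStack]:
    """Read one or more raw stacks from a multi-page TIFF.

    The page count must be ``n_angles * n_phases`` or an integer multiple of
    it (a time series, split sequentially into per-timepoint stacks).
    """
    config.validate()
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise StackIOError(f"{path}: expected a stack of 2-D grayscale pages")
    per = config.frames_per_reconstruction
    if data.shape[0] % per:
        raise StackIOError(
            f"{path}: {data.shape[0]} pages is not a multiple of "
            f"{config.acquisition.n_angles} angles x {config.acquisition.n_phases} "
            f"phases = {per} frames"
        )
    shapes = {data[i].shape for i in range(data.shape[0])}
    if len(shapes) != 1:
        raise StackIOError(f"{path}: mixed page sizes {sorted(shapes)}")
    pix = config.acquisition.pixel_size_nm
    stacks = []
    for t in range(data.shape[0] // per):
        frames = [
            Field2D(
                _crop_square_even(np.asarray(data[t * per + i], dtype=float), str(path)),
                pix,
                Domain.REAL,
            )
            for i in range(per)
        ]
        stacks.append(
            RawStack(
                frames=frames,
                n_angles=config.acquisition.n_angles,
                n_phases=config.acquisition.n_phases,
                n_bands=config.acquisition.n_bands,
                ordering=config.ordering,
                pixel_size_nm=pix,
            )
        )
    return stacks


def load_stack(path: str | Path, config: ReconConfig) -> RawStack:
    """Read exactly one raw stack (error on time series)."""
    stacks = load_stacks(path, config)
    if len(stacks) != 1:
        raise StackIOError(f"{path}: contains {len(stacks)} timepoints, expected one")
    return stacks[0]


def write_stack_tiff(path: str | Path, stack: RawStack) -> None:
    pages = np.stack([np.real(f.values).astype(np.float32) for f in stack.frames])
    tifffile.imwrite(path, pages)


def write_image_tiff(
    path: str | Path, field: Field2D, clip_zero: bool = False, as_power_spectrum: bool = False
) -> None:
    """Export a field as 32-bit float TIFF.

    Real-space fields are written as-is (negatives preserved unless
    ``clip_zero``); frequency-space fields are written as log-scaled power
    spectra when requested.
    """
    if as_power_spectrum:
        img = power_spectrum(field, "log")
    else:
        img = np.real(field.values)
        if clip_zero:
            img = np.clip(img, 0.0, None)
    tifffile.imwrite(path, img.astype(np.float32))


def write_params_json(path: str | Path, params: Sequence[SimParams], meta: dict | None = None) -> None:
    obj = {"orientations": [p.to_dict() for p in params]}
    if meta:
        obj["meta"] = meta
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_params_json(path: str | Path) -> list[SimParams]:
    obj = json.loads(Path(path).read_text())
    return [SimParams.from_dict(d) for d in obj["orientations"]]
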
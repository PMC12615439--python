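"""Reading and writing the package's on-disk formats.

* Lambda stacks and two-channel images: multi-page TIFF (page k = channel k,
  pages in ascending wavelength order; for two-channel files page 0 is SHG,
  page 1 TPEF) with a JSON sidecar carrying the acquisition metadata
  ``{start_nm, step_nm, n_channels, excitation_nm, shg_band, tpef_band}``.
* Spectra: two-column CSV ``wavelength_nm,intensity``.
* Renders: 8-bit RGB PNG.

Integer pixel data round-trips bit-exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError
from .spectral import (
    AcquisitionMeta,
    EmissionSpectrum,
    LambdaStack,
    TwoChannelImage,
    WavelengthGrid,
)

__all__ = [
    "sidecar_path",
    "write_stack",
    "read_stack",
    "write_spectrum_csv",
    "read_spectrum_csv",
    "write_png",
    "write_mask",
    "read_mask",
]


def sidecar_path(path: str | Path) -> Path:
    return Path(path).with_suffix(".json")


def _meta_dict(meta: AcquisitionMeta, grid: WavelengthGrid | None, n_channels: int) -> dict:
    d = {
        "n_channels": n_channels,
        "excitation_nm": meta.excitation_nm,
        "shg_band": list(meta.shg_band),
        "tpef_band": list(meta.tpef_band),
    }
    if grid is not None:
        d["start_nm"] = grid.start_nm
        d["step_nm"] = grid.step_nm
    return d


def write_stack(obj: LambdaStack | TwoChannelImage, path: str | Path) -> Path:
    """Write a stack/two-channel image as multi-page TIFF + JSON sidecar."""
    path = Path(path)
    if isinstance(obj, LambdaStack):
        pages = np.moveaxis(obj.pixels, 2, 0)
        meta = _meta_dict(obj.meta, obj.grid, obj.grid.n_channels)
    elif isinstance(obj, TwoChannelImage):
        pages = np.stack([obj.shg, obj.tpef])
        meta = _meta_dict(obj.meta, None, 2)
    else:
        raise FormatError(f"cannot write object of type {type(obj).__name__}")
    tifffile.imwrite(path, pages, photometric="minisblack")
    sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_stack(path: str | Path) -> LambdaStack | TwoChannelImage:
    """Read a multi-page TIFF plus its JSON sidecar.

    Files whose sidecar declares ``n_channels == 2`` come back as
    :class:`TwoChannelImage`; anything else as :class:`LambdaStack` with the
    declared wavelength grid.  A page count that disagrees with the sidecar
    is a format error.
    """
    path = Path(path)
    side = sidecar_path(path)
    if not side.exists():
        raise FormatError(f"missing metadata sidecar {side}")
    try:
        meta_d = json.loads(side.read_text())
    except json.JSONDecodeError as e:
        raise FormatError(f"unreadable sidecar {side}: {e}") from e
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    declared = int(meta_d.get("n_channels", pages.shape[0]))
    if pages.shape[0] != declared:
        raise FormatError(
            f"{path.name}: {pages.shape[0]} TIFF pages but sidecar declares "
            f"{declared} channels"
        )
    meta = AcquisitionMeta(
        excitation_nm=float(meta_d.get("excitation_nm", 810.0)),
        shg_band=tuple(meta_d.get("shg_band", (389.0, 419.0))),
        tpef_band=tuple(meta_d.get("tpef_band", (430.0, 716.0))),
    )
    if declared == 2:
        return TwoChannelImage(pages[0], pages[1], meta=meta)
    grid = WavelengthGrid(
        start_nm=float(meta_d.get("start_nm", 382.0)),
        step_nm=float(meta_d.get("step_nm", 11.0)),
        n_channels=declared,
    )
    return LambdaStack(np.moveaxis(pages, 0, 2), grid=grid, meta=meta)


def write_spectrum_csv(s: EmissionSpectrum, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"wavelength_nm": s.wavelengths_nm, "intensity": s.intensities}
    ).to_csv(path, index=False, float_format="%.12g")
    return path


def read_spectrum_csv(path: str | Path) -> EmissionSpectrum:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as e:  # empty / unparseable file
        raise FormatError(f"cannot parse spectrum CSV {path}: {e}") from e
    for col in ("wavelength_nm", "intensity"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    if len(df) == 0:
        raise FormatError(f"{path}: spectrum has no rows")
    return EmissionSpectrum(df["wavelength_nm"].to_numpy(), df["intensity"].to_numpy())


def write_png(rgb: np.ndarray, path: str | Path) -> Path:
    """Write a float RGB image in [0, 1] as 8-bit PNG."""
    path = Path(path)
    img8 = np.clip(np.asarray(rgb) * 255.0 + 0.5, 0, 255).astype(np.uint8)
    iio.imwrite(path, img8)
    return path


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    """Binary mask as an 8-bit PNG (255 = foreground)."""
    path = Path(path)
    iio.imwrite(path, (np.asarray(mask, dtype=bool) * np.uint8(255)))
    return path


def read_mask(path: str | Path) -> np.ndarray:
    return np.asarray(iio.imread(path)) > 127
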
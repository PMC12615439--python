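"""Core data model for multiphoton spectral imaging.

Two acquisition modes are represented:

* **lambda mode** — every pixel carries a full emission spectrum sampled on a
  uniform wavelength grid (by default 32 channels, 382 nm start, 11-nm step,
  nominally covering 382-714 nm).  Stored as a :class:`LambdaStack`.
* **multichannel mode** — two broad detector bands, one for second-harmonic
  generation (SHG, 389-419 nm by default) and one for two-photon excited
  fluorescence (TPEF, 430-716 nm).  Stored as a :class:`TwoChannelImage`.

SHG is coherent scattering at exactly half the excitation wavelength, so with
810-nm excitation the collagen signal appears at 405 nm and lands in the
404-nm lambda channel.  TPEF comes from endogenous fluorophores (NADH, FAD,
lipopigments, porphyrins, structural proteins) and is spectrally broad.

Channel labels are the lower edges of the 382 + 11k nm grid; the nominal
382-714 nm range is treated as descriptive (the last label is 723 nm).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DegenerateInputError, SpecError

__all__ = [
    "WavelengthGrid",
    "AcquisitionMeta",
    "LambdaStack",
    "TwoChannelImage",
    "EmissionSpectrum",
    "ROI",
    "channel_labels",
    "shg_wavelength",
    "nearest_channel",
    "roi_mean_spectrum",
    "normalize_spectrum",
    "band_integrate",
    "combine_spectral_image",
    "overlay_tpef_shg",
]


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength grid of a lambda-mode acquisition.

    ``label(k) = start_nm + k * step_nm`` for k in [0, n_channels).
    """

    start_nm: float = 382.0
    step_nm: float = 11.0
    n_channels: int = 32

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise SpecError("n_channels must be >= 1")
        if self.step_nm <= 0:
            raise SpecError("step_nm must be positive (labels strictly increasing)")

    @property
    def labels(self) -> np.ndarray:
        return self.start_nm + self.step_nm * np.arange(self.n_channels)

    def label(self, k: int) -> float:
        if not 0 <= k < self.n_channels:
            raise IndexError(f"channel index {k} out of range [0, {self.n_channels})")
        return self.start_nm + k * self.step_nm


@dataclass(frozen=True)
class AcquisitionMeta:
    """Excitation wavelength and the two multichannel detector bands (nm)."""

    excitation_nm: float = 810.0
    shg_band: tuple[float, float] = (389.0, 419.0)
    tpef_band: tuple[float, float] = (430.0, 716.0)

    def __post_init__(self) -> None:
        if self.excitation_nm <= 0:
            raise SpecError("excitation_nm must be positive")
        for name, (lo, hi) in (("shg_band", self.shg_band), ("tpef_band", self.tpef_band)):
            if not (300.0 <= lo < hi <= 800.0):
                raise SpecError(f"{name} must satisfy 300 <= lo < hi <= 800, got ({lo}, {hi})")
        s, t = sorted([self.shg_band, self.tpef_band])
        if s[1] >= t[0]:
            raise SpecError("shg_band and tpef_band must not overlap")


def channel_labels(grid: WavelengthGrid) -> np.ndarray:
    """Wavelength label (nm) of every channel, in channel order."""
    return grid.labels


def shg_wavelength(meta: AcquisitionMeta | float) -> float:
    """SHG emission wavelength: exactly half the excitation wavelength.

    Accepts either an :class:`AcquisitionMeta` or a bare excitation
    wavelength in nm.
    """
    exc = meta.excitation_nm if isinstance(meta, AcquisitionMeta) else float(meta)
    if exc <= 0:
        raise SpecError("excitation wavelength must be positive")
    return exc / 2.0


def nearest_channel(grid: WavelengthGrid, target_nm: float) -> tuple[int, float]:
    """Index and label of the channel nearest ``target_nm``.

    Ties are broken toward the lower index (``np.argmin`` keeps the first
    minimum), so the rule is deterministic.
    """
    labels = grid.labels
    k = int(np.argmin(np.abs(labels - target_nm)))
    return k, float(labels[k])


def _as_pixels(pixels: np.ndarray, ndim: int, name: str) -> np.ndarray:
    # dtype is preserved (integer TIFF data must round-trip bit-exactly)
    arr = np.asarray(pixels)
    if arr.dtype.kind not in "uif":
        raise SpecError(f"{name} must be numeric, got dtype {arr.dtype}")
    if arr.ndim != ndim:
        raise SpecError(f"{name} must be {ndim}-dimensional, got shape {arr.shape}")
    if arr.dtype.kind != "u" and np.any(arr < 0):
        raise SpecError(f"{name} intensities must be nonnegative")
    return arr


@dataclass
class LambdaStack:
    """An H x W x n_channels spectral image with its wavelength grid."""

    pixels: np.ndarray
    grid: WavelengthGrid = field(default_factory=WavelengthGrid)
    meta: AcquisitionMeta = field(default_factory=AcquisitionMeta)

    def __post_init__(self) -> None:
        self.pixels = _as_pixels(self.pixels, 3, "lambda-stack pixels")
        if self.pixels.shape[2] != self.grid.n_channels:
            raise SpecError(
                f"stack has {self.pixels.shape[2]} channels but grid declares "
                f"{self.grid.n_channels}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape


@dataclass
class TwoChannelImage:
    """Paired SHG and TPEF detector-band images of the same field."""

    shg: np.ndarray
    tpef: np.ndarray
    meta: AcquisitionMeta = field(default_factory=AcquisitionMeta)

    def __post_init__(self) -> None:
        self.shg = _as_pixels(self.shg, 2, "SHG image")
        self.tpef = _as_pixels(self.tpef, 2, "TPEF image")
        if self.shg.shape != self.tpef.shape:
            raise SpecError("SHG and TPEF images must share shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.shg.shape


@dataclass
class EmissionSpectrum:
    """A (wavelength, intensity) curve, e.g. a ROI-averaged emission spectrum."""

    wavelengths_nm: np.ndarray
    intensities: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths_nm.ndim != 1 or self.intensities.ndim != 1:
            raise SpecError("spectrum vectors must be one-dimensional")
        if self.wavelengths_nm.size != self.intensities.size:
            raise SpecError("wavelength and intensity vectors must have equal length")
        if self.wavelengths_nm.size and np.any(np.diff(self.wavelengths_nm) <= 0):
            raise SpecError("wavelengths must be strictly increasing")
        if np.any(self.intensities < 0):
            raise SpecError("spectrum intensities must be nonnegative")
        if self.normalized and abs(self.intensities.max(initial=0.0) - 1.0) > 1e-9:
            raise SpecError("normalized spectrum must have unit maximum")

    def __len__(self) -> int:
        return self.wavelengths_nm.size


class ROI:
    """Region of interest over an H x W field: a rectangle or a boolean mask."""

    def __init__(self, mask: np.ndarray):
        mask = np.asarray(mask, dtype=bool)
        if mask.ndim != 2:
            raise SpecError("ROI mask must be two-dimensional")
        if not mask.any():
            raise SpecError("ROI is empty")
        self.mask = mask

    @classmethod
    def from_mask(cls, mask: np.ndarray) -> "ROI":
        return cls(mask)

    @classmethod
    def from_bounds(cls, shape: tuple[int, int], r0: int, r1: int, c0: int, c1: int) -> "ROI":
        """Half-open rectangle rows [r0, r1), cols [c0, c1) on a ``shape`` field."""
        h, w = shape
        if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
            raise SpecError(f"ROI bounds ({r0},{r1},{c0},{c1}) outside image {shape}")
        mask = np.zeros(shape, dtype=bool)
        mask[r0:r1, c0:c1] = True
        return cls(mask)

    @classmethod
    def full(cls, shape: tuple[int, int]) -> "ROI":
        return cls(np.ones(shape, dtype=bool))

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def roi_mean_spectrum(stack: LambdaStack, roi: ROI) -> EmissionSpectrum:
    """Mean emission spectrum over a region of interest.

    Channel k of the result is the arithmetic mean of the stack over the ROI
    pixels at channel k.  The result is not normalized.
    """
    if roi.mask.shape != stack.pixels.shape[:2]:
        raise SpecError(
            f"ROI shape {roi.mask.shape} does not match image {stack.pixels.shape[:2]}"
        )
    mean = stack.pixels[roi.mask].mean(axis=0)
    return EmissionSpectrum(stack.grid.labels, mean, normalized=False)


def normalize_spectrum(s: EmissionSpectrum) -> EmissionSpectrum:
    """Rescale a spectrum to unit maximum (the convention used for reporting
    relative component ratios).  Idempotent; all-zero input is degenerate."""
    peak = s.intensities.max(initial=0.0)
    if peak <= 0:
        raise DegenerateInputError("cannot normalize an all-zero spectrum")
    return EmissionSpectrum(s.wavelengths_nm, s.intensities / peak, normalized=True)


def band_integrate(stack: LambdaStack, band: tuple[float, float]) -> np.ndarray:
    """Per-pixel sum over channels whose label falls inside the closed band.

    This is how the broadband multichannel-mode images are emulated from a
    lambda stack: the SHG-band integral of the default grid sums the 393, 404
    and 415-nm channels.
    """
    lo, hi = band
    if hi < lo:
        raise SpecError(f"band upper edge below lower edge: ({lo}, {hi})")
    labels = stack.grid.labels
    inside = (labels >= lo) & (labels <= hi)
    if not inside.any():
        raise SpecError(f"band ({lo}, {hi}) contains no grid channel")
    return stack.pixels[:, :, inside].sum(axis=2)


def _rescale_unit(img: np.ndarray) -> np.ndarray:
    peak = img.max(initial=0.0)
    return img / peak if peak > 0 else np.zeros_like(img, dtype=float)


def combine_spectral_image(stack: LambdaStack) -> np.ndarray:
    """Render the combined-spectral two-color composite of a lambda stack.

    The SHG-band integral is mapped to purple (equal red + blue) and the
    TPEF-band integral to blue, each band rescaled to [0, 1] by its own
    maximum so weak fluorescence stays visible next to the strong coherent
    SHG.  Returns an H x W x 3 float RGB image in [0, 1]; an all-zero stack
    renders black.
    """
    try:
        shg = _rescale_unit(band_integrate(stack, stack.meta.shg_band))
    except SpecError:
        shg = np.zeros(stack.pixels.shape[:2])
    try:
        tpef = _rescale_unit(band_integrate(stack, stack.meta.tpef_band))
    except SpecError:
        tpef = np.zeros(stack.pixels.shape[:2])
    rgb = np.zeros(stack.pixels.shape[:2] + (3,), dtype=float)
    rgb[:, :, 0] = shg
    rgb[:, :, 2] = shg + tpef
    return np.clip(rgb, 0.0, 1.0)


def overlay_tpef_shg(img: TwoChannelImage) -> np.ndarray:
    """Render the classic TPEF/SHG overlay: SHG green, TPEF red.

    Each channel is rescaled by its own maximum, so pixels strong in both
    (collagen that also fluoresces) appear yellow.  Blue stays zero.
    """
    rgb = np.zeros(img.shape + (3,), dtype=float)
    rgb[:, :, 0] = _rescale_unit(img.tpef)
    rgb[:, :, 1] = _rescale_unit(img.shg)
    return np.clip(rgb, 0.0, 1.0)
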
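"""Automatic collagen-content quantification.

Pipeline (fixed order): contrast enhancement by percentile stretch, Otsu
thresholding on the enhanced image, binary morphological opening then
closing, and finally the pixel fraction

    collagen_content = (# collagen pixels) / (# pixels).

The same pipeline runs on two modalities: the SHG detector-band image
(collagen is the dominant SHG source) and the SHG-band integral of a
32-channel combined spectral image.  Every intermediate stage image is kept
on the result so that each step can be inspected or asserted.

Otsu's threshold is computed from a histogram of the enhanced image:
among all bin-edge splits it maximizes the between-class variance
``w0 * w1 * (mu0 - mu1)**2``; ties go to the lowest qualifying edge and the
returned threshold is the lower edge of the upper class (pixels >= threshold
are collagen).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.morphology import closing, disk, footprint_rectangle, opening

from .errors import DegenerateInputError, SpecError
from .spectral import LambdaStack, TwoChannelImage, band_integrate

__all__ = [
    "SegmentationParams",
    "SegmentationResult",
    "enhance",
    "otsu_threshold",
    "morph_clean",
    "collagen_content",
    "quantify_shg",
    "quantify_combined",
    "batch_report",
    "dice_coefficient",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable knobs of the collagen pipeline.

    Percentiles control the linear contrast stretch; ``hist_bins`` sets the
    Otsu histogram resolution (256 matches the classical 8-bit formulation);
    the structuring element drives the morphological cleanup (radius 0 is the
    identity).
    """

    enhance_low_pct: float = 1.0
    enhance_high_pct: float = 99.0
    hist_bins: int = 256
    selem_radius: int = 1
    selem_shape: str = "disk"

    def __post_init__(self) -> None:
        if not (0.0 <= self.enhance_low_pct < self.enhance_high_pct <= 100.0):
            raise SpecError("percentiles must satisfy 0 <= low < high <= 100")
        if self.hist_bins < 2:
            raise SpecError("hist_bins must be >= 2")
        if self.selem_radius < 0:
            raise SpecError("selem_radius must be >= 0")
        if self.selem_shape not in ("disk", "square"):
            raise SpecError("selem_shape must be 'disk' or 'square'")

    def footprint(self) -> np.ndarray | None:
        if self.selem_radius == 0:
            return None
        if self.selem_shape == "disk":
            return disk(self.selem_radius)
        side = 2 * self.selem_radius + 1
        return footprint_rectangle((side, side))


@dataclass
class SegmentationResult:
    """Binary collagen mask, the Otsu threshold that produced it, the pixel
    fraction, and every intermediate stage image."""

    mask: np.ndarray
    threshold: float
    collagen_content: float
    stage_images: dict = field(default_factory=dict)


def enhance(img: np.ndarray, p: SegmentationParams | None = None) -> np.ndarray:
    """Linear percentile contrast stretch onto [0, 1].

    The low percentile maps to 0 and the high percentile to 1; values outside
    are clipped.  A constant image maps to all zeros.
    """
    p = p or SegmentationParams()
    img = np.asarray(img, dtype=float)
    if img.size == 0:
        raise SpecError("cannot enhance an empty image")
    lo = np.percentile(img, p.enhance_low_pct)
    hi = np.percentile(img, p.enhance_high_pct)
    if hi <= lo:
        return np.zeros_like(img)
    return np.clip((img - lo) / (hi - lo), 0.0, 1.0)


def otsu_threshold(img: np.ndarray, bins: int = 256) -> float:
    """Histogram-based Otsu threshold.

    Builds a ``bins``-bin histogram over the image's value range and returns
    the interior bin edge maximizing the between-class variance
    ``w0 * w1 * (mu0 - mu1)**2``.  Pixels >= the returned edge form the
    foreground class.  Ties are broken by the lowest qualifying edge.
    """
    img = np.asarray(img, dtype=float)
    vmin, vmax = float(img.min()), float(img.max())
    if vmin == vmax:
        raise DegenerateInputError("constant image: no threshold separates two classes")
    counts, edges = np.histogram(img, bins=bins, range=(vmin, vmax))
    counts = counts.astype(float)
    total = counts.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])

    # cumulative weight/mean of the lower class for every interior split i
    w0 = np.cumsum(counts)[:-1] / total
    w1 = 1.0 - w0
    cum_mass = np.cumsum(counts * centers)
    mu0 = np.divide(cum_mass[:-1], np.cumsum(counts)[:-1] * 1.0,
                    out=np.zeros(bins - 1), where=np.cumsum(counts)[:-1] > 0)
    mu1 = np.divide(cum_mass[-1] - cum_mass[:-1], (total - np.cumsum(counts)[:-1]),
                    out=np.zeros(bins - 1), where=(total - np.cumsum(counts)[:-1]) > 0)
    between = w0 * w1 * (mu0 - mu1) ** 2
    # candidate splits: the edge must follow a nonempty bin and leave a
    # nonempty upper class.  Splits inside runs of empty bins produce the
    # same partition as the run's first edge, so dropping them both keeps
    # the "lowest qualifying edge" tie rule and avoids floating-point
    # near-ties between mathematically identical splits.
    valid = (counts[:-1] > 0) & (w1 > 0)
    if not valid.any():
        raise DegenerateInputError("image histogram occupies a single bin")
    between[~valid] = -np.inf
    best = int(np.argmax(between))  # first maximum = lowest qualifying edge
    return float(edges[best + 1])


def morph_clean(mask: np.ndarray, p: SegmentationParams | None = None) -> np.ndarray:
    """Binary opening (removes speckle) then closing (fills small holes)
    with the configured structuring element.  Radius 0 is the identity."""
    p = p or SegmentationParams()
    mask = np.asarray(mask, dtype=bool)
    fp = p.footprint()
    if fp is None:
        return mask.copy()
    return closing(opening(mask, fp), fp)


def collagen_content(mask: np.ndarray) -> float:
    """Fraction of pixels flagged as collagen: exact count ratio in [0, 1]."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        raise SpecError("empty mask")
    return float(mask.sum()) / mask.size


def _run_pipeline(gray: np.ndarray, p: SegmentationParams) -> SegmentationResult:
    enhanced = enhance(gray, p)
    thr = otsu_threshold(enhanced, bins=p.hist_bins)
    raw_mask = enhanced >= thr
    cleaned = morph_clean(raw_mask, p)
    return SegmentationResult(
        mask=cleaned,
        threshold=thr,
        collagen_content=collagen_content(cleaned),
        stage_images={
            "original": np.asarray(gray, dtype=float),
            "enhanced": enhanced,
            "thresholded": raw_mask,
            "cleaned": cleaned,
        },
    )


def quantify_shg(
    img: TwoChannelImage | np.ndarray, p: SegmentationParams | None = None
) -> SegmentationResult:
    """Collagen content from an SHG image (the SHG channel of a two-channel
    acquisition, or a bare H x W intensity image)."""
    p = p or SegmentationParams()
    gray = img.shg if isinstance(img, TwoChannelImage) else np.asarray(img, dtype=float)
    if gray.ndim != 2:
        raise SpecError(f"SHG image must be 2-D, got shape {gray.shape}")
    return _run_pipeline(gray, p)


def quantify_combined(stack: LambdaStack, p: SegmentationParams | None = None) -> SegmentationResult:
    """Collagen content from a 32-channel combined spectral image.

    The collagen-bearing grayscale is the SHG-band integral of the stack
    (sum of the channels inside ``meta.shg_band``); the segmentation pipeline
    is then identical to :func:`quantify_shg`.
    """
    p = p or SegmentationParams()
    gray = band_integrate(stack, stack.meta.shg_band)
    return _run_pipeline(gray, p)


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom


def batch_report(entries: list[dict]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble a per-image table and a per-modality mean +/- SD summary.

    ``entries`` are dicts with keys ``file``, ``modality``, ``threshold`` and
    ``collagen_content`` (the shape produced by the CLI or by running the
    quantify functions yourself).  The SD is the sample standard deviation
    (ddof=1); for a single image it is reported as NaN.
    """
    if not entries:
        raise SpecError("batch_report needs at least one entry")
    table = pd.DataFrame(entries, columns=["file", "modality", "threshold", "collagen_content"])
    summary = (
        table.groupby("modality", sort=False)["collagen_content"]
        .agg(n="count", mean="mean", sd=lambda s: s.std(ddof=1))
        .reset_index()
    )
    return table, summary
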
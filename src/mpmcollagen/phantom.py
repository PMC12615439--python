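"""Synthetic fibrous-tissue phantoms with known ground truth.

The generator emulates the appearance of collagen-rich fibrous tumor tissue
under label-free multiphoton imaging:

* **Collagen fiber bundles** — curvilinear strokes (random-walk polylines
  dilated to a fiber width) carrying a narrow SHG emission component at
  405 nm plus a small broadband TPEF share (real collagen fluoresces
  weakly, which is what makes it appear yellow in TPEF/SHG overlays).
* **Cells** — disks scattered preferentially in the non-collagen matrix.
  The cytoplasm annulus fluoresces through NADH, FAD and lipopigment
  components; the nucleus interior carries no signal at all and renders as
  a dark spot, as nuclei do in autofluorescence imaging.
* **Detection noise** — Poisson shot noise (scaled so that the configured
  ``poisson_scale`` acts as the expected photon count per unit intensity)
  plus additive Gaussian read noise, clipped at zero.

Per-pixel spectra are nonnegative mixtures of the same eight Gaussian
component bases used by the fitting module, sampled at the 32 lambda-mode
channel labels, so fit round-trips are closed-form consistent.

Every phantom is fully determined by its :class:`PhantomSpec` (including the
seed): the same spec yields bit-identical images, masks and abundance maps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line
from skimage.morphology import dilation, disk as disk_footprint

from .errors import SpecError
from .multipeak import ComponentSet, component_model, default_components
from .spectral import (
    AcquisitionMeta,
    EmissionSpectrum,
    LambdaStack,
    TwoChannelImage,
    WavelengthGrid,
    band_integrate,
)

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "draw_fibers",
    "draw_cells",
    "build_ground_truth",
    "render_lambda_stack",
    "render_two_channel",
    "reference_spectrum",
]

#: Mask fraction must land within this distance of the target.
FRACTION_TOL = 0.02


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic tissue field.

    Amplitudes are on the arbitrary pre-noise intensity scale; the relative
    SHG-vs-TPEF scale is a free choice of the phantom, not a tissue claim.
    """

    height: int = 256
    width: int = 256
    n_fibers: int = 40
    fiber_width_px: float = 3.0
    fiber_width_jitter_px: float = 1.0
    fiber_orientation_range: tuple[float, float] = (0.0, math.pi)
    fiber_intensity: float = 1.0
    n_cells: int = 25
    cell_radius_px: float = 9.0
    nucleus_radius_px: float = 4.0
    cytoplasm_amplitudes: dict = field(
        default_factory=lambda: {
            "NADH_free": 0.35,
            "NADH_bound": 0.10,
            "FAD": 0.18,
            "lipopigment": 0.12,
        }
    )
    collagen_tpef_fraction: float = 0.15
    target_collagen_fraction: float = 0.5
    poisson_scale: float = 200.0
    gaussian_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 8 or self.width < 8:
            raise SpecError("phantom must be at least 8 x 8 pixels")
        if self.n_fibers < 0 or self.n_cells < 0:
            raise SpecError("counts must be nonnegative")
        if self.fiber_width_px <= 0 or self.cell_radius_px <= 0 or self.nucleus_radius_px <= 0:
            raise SpecError("widths and radii must be positive")
        if self.nucleus_radius_px >= self.cell_radius_px:
            raise SpecError("nucleus radius must be smaller than cell radius")
        if not (0.0 <= self.target_collagen_fraction <= 0.95):
            raise SpecError(
                "target_collagen_fraction must lie in [0, 0.95]; denser fields are "
                "unreachable with fiber strokes"
            )
        if self.target_collagen_fraction > 0 and self.n_fibers == 0:
            raise SpecError("cannot reach a positive collagen fraction with n_fibers = 0")
        if self.collagen_tpef_fraction < 0 or self.fiber_intensity < 0:
            raise SpecError("intensities must be nonnegative")
        if self.poisson_scale < 0 or self.gaussian_sd < 0:
            raise SpecError("noise parameters must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)


@dataclass
class GroundTruth:
    """True masks and per-component abundance maps of a phantom."""

    collagen_mask: np.ndarray
    nucleus_mask: np.ndarray
    abundance_maps: dict[str, np.ndarray]

    @property
    def collagen_fraction(self) -> float:
        return float(self.collagen_mask.mean())


def _random_fiber(
    rng: np.random.Generator, spec: PhantomSpec, length_px: float, forbidden: np.ndarray | None
) -> np.ndarray:
    """One dilated random-walk stroke as a boolean mask."""
    h, w = spec.shape
    r = rng.uniform(0, h)
    c = rng.uniform(0, w)
    theta = rng.uniform(*spec.fiber_orientation_range)
    if rng.random() < 0.5:
        theta += math.pi  # orientation is undirected; walk either way
    width = max(1.0, rng.normal(spec.fiber_width_px, spec.fiber_width_jitter_px))
    step = 3.0
    n_steps = max(2, int(length_px / step))
    canvas = np.zeros(spec.shape, dtype=bool)
    pr = int(np.clip(round(r), 0, h - 1))
    pc = int(np.clip(round(c), 0, w - 1))
    for _ in range(n_steps):
        theta += rng.normal(0.0, 0.15)  # gentle curvature
        r += step * math.sin(theta)
        c += step * math.cos(theta)
        qr = int(np.clip(round(r), 0, h - 1))
        qc = int(np.clip(round(c), 0, w - 1))
        rr, cc = draw_line(pr, pc, qr, qc)
        canvas[rr, cc] = True
        pr, pc = qr, qc
        if not (0 <= r < h and 0 <= c < w):
            break
    radius = max(0, int(round((width - 1) / 2)))
    if radius > 0:
        canvas = dilation(canvas, disk_footprint(radius))
    if forbidden is not None:
        canvas &= ~forbidden
    return canvas


def _fill_fibers(
    rng: np.random.Generator,
    spec: PhantomSpec,
    mask: np.ndarray,
    target: float,
    forbidden: np.ndarray | None = None,
) -> np.ndarray:
    """Add strokes to ``mask`` until its fraction is within the target band."""
    if target <= 0:
        return mask
    area = spec.height * spec.width
    # nominal length so that n_fibers straight fibers would tile the target
    length = max(12.0, target * area / (max(spec.n_fibers, 1) * spec.fiber_width_px))
    attempts = 0
    max_attempts = 80 * max(spec.n_fibers, 1)
    while mask.mean() < target - 0.005 and attempts < max_attempts:
        attempts += 1
        fiber = _random_fiber(rng, spec, length, forbidden)
        candidate = mask | fiber
        if candidate.mean() > target + FRACTION_TOL:
            length *= 0.6  # overshoot: retry with shorter strokes
            if length < 6.0:
                break
            continue
        mask = candidate
    if abs(mask.mean() - target) > FRACTION_TOL:
        raise SpecError(
            f"could not reach collagen fraction {target:.3f} "
            f"(achieved {mask.mean():.3f}); spec is too constrained"
        )
    return mask


def draw_fibers(spec: PhantomSpec, rng: np.random.Generator | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Collagen fiber mask and its SHG abundance map.

    Strokes are added (shrinking their length on overshoot) until the mask
    fraction lies within +/-0.02 of ``target_collagen_fraction``.  The
    abundance map is ``fiber_intensity`` modulated by a smooth multiplicative
    texture, so bundles are not perfectly flat.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    mask = np.zeros(spec.shape, dtype=bool)
    if spec.target_collagen_fraction > 0 and spec.n_fibers > 0:
        mask = _fill_fibers(rng, spec, mask, spec.target_collagen_fraction)
    texture = 1.0 + 0.15 * gaussian_filter(rng.standard_normal(spec.shape), sigma=6.0)
    abundance = np.where(mask, spec.fiber_intensity * np.clip(texture, 0.4, None), 0.0)
    return mask, abundance


def draw_cells(
    spec: PhantomSpec,
    collagen_mask: np.ndarray,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Nucleus mask and cytoplasm abundance maps.

    Cells are placed by rejection sampling: first trying centers whose
    nucleus avoids collagen entirely, then (if the field is crowded) only
    requiring nuclei to stay disjoint from each other.  Overcrowding degrades
    gracefully — fewer cells are placed, never an error.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    h, w = spec.shape
    nucleus_mask = np.zeros(spec.shape, dtype=bool)
    cyto_maps = {name: np.zeros(spec.shape) for name in spec.cytoplasm_amplitudes}
    margin = int(math.ceil(spec.cell_radius_px))
    if h - 2 * margin <= 0 or w - 2 * margin <= 0:
        return nucleus_mask, cyto_maps
    for _ in range(spec.n_cells):
        placed = False
        for attempt in range(60):
            cr = rng.integers(margin, h - margin)
            cc = rng.integers(margin, w - margin)
            nrr, ncc = draw_disk((cr, cc), spec.nucleus_radius_px, shape=spec.shape)
            if nucleus_mask[nrr, ncc].any():
                continue  # nuclei must stay pairwise disjoint
            if attempt < 40 and collagen_mask[nrr, ncc].any():
                continue  # prefer the non-collagen matrix while space remains
            crr, ccc = draw_disk((cr, cc), spec.cell_radius_px, shape=spec.shape)
            cell = np.zeros(spec.shape, dtype=bool)
            cell[crr, ccc] = True
            nucleus = np.zeros(spec.shape, dtype=bool)
            nucleus[nrr, ncc] = True
            annulus = cell & ~nucleus
            jitter = rng.uniform(0.8, 1.2)
            for name, amp in spec.cytoplasm_amplitudes.items():
                cyto_maps[name][annulus] += amp * jitter
            nucleus_mask |= nucleus
            placed = True
            break
        if not placed:
            continue
    return nucleus_mask, cyto_maps


def build_ground_truth(
    spec: PhantomSpec, cs: ComponentSet | None = None
) -> GroundTruth:
    """Assemble the full abundance model of a phantom.

    Order of construction: fibers to the target fraction, then cells, then
    nuclei are carved out of every map (nuclei are fluorescence-dark), and
    finally short fibers are topped up away from nuclei if the carving pushed
    the collagen fraction below its tolerance band.
    """
    cs = cs if cs is not None else default_components()
    rng = np.random.default_rng(spec.seed)
    collagen_mask, shg_abundance = draw_fibers(spec, rng)
    nucleus_mask, cyto_maps = draw_cells(spec, collagen_mask, rng)

    # nuclei are dark: zero every abundance and remove them from the mask
    collagen_mask &= ~nucleus_mask
    shg_abundance[nucleus_mask] = 0.0
    target = spec.target_collagen_fraction
    if target > 0 and collagen_mask.mean() < target - FRACTION_TOL + 0.005:
        forbidden = dilation(nucleus_mask, disk_footprint(1))
        collagen_mask = _fill_fibers(rng, spec, collagen_mask, target, forbidden=forbidden)
        new = collagen_mask & (shg_abundance == 0)
        shg_abundance[new] = spec.fiber_intensity

    maps = {name: np.zeros(spec.shape) for name in cs.names}
    maps["collagen_SHG"] = shg_abundance
    # collagen's weak broadband fluorescence, carried by the structural-protein band
    maps["structural_protein"] = maps["structural_protein"] + spec.collagen_tpef_fraction * shg_abundance
    for name, m in cyto_maps.items():
        if name not in maps:
            raise SpecError(f"cytoplasm component {name!r} not in the component set")
        maps[name] = maps[name] + m
        maps[name][nucleus_mask] = 0.0
    return GroundTruth(collagen_mask, nucleus_mask, maps)


def _clean_stack(truth: GroundTruth, grid: WavelengthGrid, cs: ComponentSet) -> np.ndarray:
    labels = grid.labels
    h, w = truth.collagen_mask.shape
    basis = np.stack(
        [
            component_model(labels, 1.0, c.center_nm, c.sigma_init_nm)
            for c in cs
        ]
    )  # (n_components, n_channels)
    abundances = np.stack([truth.abundance_maps[n] for n in cs.names])  # (n, H, W)
    return np.tensordot(abundances, basis, axes=(0, 0))  # (H, W, n_channels)


def _apply_noise(clean: np.ndarray, spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    noisy = clean
    if spec.poisson_scale > 0:
        noisy = rng.poisson(clean * spec.poisson_scale) / spec.poisson_scale
    if spec.gaussian_sd > 0:
        noisy = noisy + rng.normal(0.0, spec.gaussian_sd, size=clean.shape)
    return np.clip(noisy, 0.0, None)


def render_lambda_stack(
    spec: PhantomSpec,
    grid: WavelengthGrid | None = None,
    meta: AcquisitionMeta | None = None,
    cs: ComponentSet | None = None,
) -> tuple[LambdaStack, GroundTruth]:
    """Render the phantom as a noisy 32-channel lambda stack.

    Per-pixel spectra are the abundance-weighted sums of the component bases
    sampled at the channel labels; Poisson then Gaussian noise is applied and
    the result clipped at zero.
    """
    grid = grid if grid is not None else WavelengthGrid()
    meta = meta if meta is not None else AcquisitionMeta()
    cs = cs if cs is not None else default_components()
    truth = build_ground_truth(spec, cs)
    clean = _clean_stack(truth, grid, cs)
    noise_rng = np.random.default_rng([spec.seed, 1])
    noisy = _apply_noise(clean, spec, noise_rng)
    return LambdaStack(noisy, grid=grid, meta=meta), truth


def render_two_channel(
    spec: PhantomSpec,
    grid: WavelengthGrid | None = None,
    meta: AcquisitionMeta | None = None,
    cs: ComponentSet | None = None,
) -> tuple[TwoChannelImage, GroundTruth]:
    """Render the phantom as a two-channel (SHG + TPEF band) image.

    The pre-noise channels are exactly the band integrals of the matched
    noiseless lambda stack; noise is applied after integration.  The ground
    truth is identical to the one :func:`render_lambda_stack` returns for the
    same spec.
    """
    grid = grid if grid is not None else WavelengthGrid()
    meta = meta if meta is not None else AcquisitionMeta()
    cs = cs if cs is not None else default_components()
    truth = build_ground_truth(spec, cs)
    clean = _clean_stack(truth, grid, cs)
    clean_stack = LambdaStack(clean, grid=grid, meta=meta)
    shg = band_integrate(clean_stack, meta.shg_band)
    tpef = band_integrate(clean_stack, meta.tpef_band)
    noise_rng = np.random.default_rng([spec.seed, 2])
    shg = _apply_noise(shg, spec, noise_rng)
    tpef = _apply_noise(tpef, spec, noise_rng)
    return TwoChannelImage(shg, tpef, meta=meta), truth


def reference_spectrum(
    ratio_vector: np.ndarray,
    cs: ComponentSet | None = None,
    step_nm: float = 1.0,
) -> EmissionSpectrum:
    """Noiseless model spectrum with the given component amplitudes.

    Evaluated on a fine (default 1-nm) grid over 382-714 nm with the default
    component centers and widths; not normalized.  Useful for fit round-trip
    tests and for synthesizing literature ratio tables.
    """
    cs = cs if cs is not None else default_components()
    amps = np.asarray(ratio_vector, dtype=float)
    if amps.shape != (len(cs),):
        raise SpecError(f"expected {len(cs)} amplitudes, got shape {amps.shape}")
    if np.any(amps < 0):
        raise SpecError("amplitudes must be nonnegative")
    lam = np.arange(382.0, 714.0 + 0.5 * step_nm, step_nm)
    centers = cs.centers_nm
    sigmas = np.array([c.sigma_init_nm for c in cs])
    y = component_model(lam, amps, centers, sigmas)
    return EmissionSpectrum(lam, y, normalized=False)
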
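# Methods

`mpmcollagen` analyzes label-free multiphoton microscopy (MPM) data of
fibrous, collagen-rich tissue — the setting is the dense extracellular
matrix of fibrous meningioma, but nothing in the code is specific to that
tumor. This note documents the models, the parameters that matter, the
synthetic phantom used for validation, and the numerical choices made where
the design was genuinely open.

## Imaging model

Two MPM acquisition modes are represented.

**Lambda mode.** Each pixel carries an emission spectrum sampled on a
uniform wavelength grid; the default is 32 channels starting at 382 nm with
an 11-nm step. Channel labels are the lower edges of that grid,
`label(k) = 382 + 11k` nm. The nominal detection range 382–714 nm is
treated as descriptive: the last label is arithmetically 723 nm, and
whether the quoted range refers to channel centers or edges is not
determinable from typical instrument descriptions. The lower-edge
convention is the one that puts the second-harmonic line of an 810-nm
excitation (405 nm) into a channel labelled 404 nm, which matches how these
channels are referred to in practice.

**Multichannel mode.** Two broad detector bands: SHG at 389–419 nm and
TPEF (two-photon excited fluorescence) at 430–716 nm. Band membership of a
lambda channel is decided by its label lying in the closed interval; with
the default grid the SHG band integrates channels 393, 404 and 415 nm.

Renders follow the field's color conventions: the TPEF/SHG overlay codes
SHG green and TPEF red (collagen that also fluoresces shows yellow); the
combined-spectral composite codes the SHG-band integral purple and the
TPEF-band integral blue. Each band is rescaled by its own maximum before
coloring, so renders are invariant under global intensity scaling and weak
fluorescence remains visible next to the (much stronger) coherent SHG.

## Spectral decomposition

A ROI-averaged, unit-peak-normalized emission spectrum is modelled as a
nonnegative sum of eight Gaussian components in wavelength,

    S(λ) = Σ_j A_j exp(−(λ − μ_j)² / (2σ_j²)),

with nominal centers 405 (collagen SHG), 425 (protein-bound NADH), 475
(free NADH), 510 (structural proteins), 545 (FAD), 575 (lipopigments), 630
and 690 nm (porphyrin derivatives I/II). The Gaussian line shape is a
modelling choice — the bands of endogenous fluorophores are smooth and
approximately symmetric on this grid — and the SHG line is given a narrow
width prior (σ init 10 nm, bounds 4–15 nm) because its linewidth tracks
the laser bandwidth, while fluorophores are broad (σ init 20 nm, bounds
8–60 nm).

**Ratios are amplitudes, not areas.** The per-component "relative ratio"
reported is the fitted peak amplitude on the normalized-intensity scale.
On a normalized spectrum the dominant component's amplitude sits just below
one (neighboring tails contribute the rest of the unit peak), which is how
the conventional ratio tables in the MPM literature read; area ratios would
not naturally be ≤ 1.

**Identifiability and the tied-width default.** With eight overlapping
bands on a ~330-point spectrum, letting every component drift its center
(±5 nm) and width (8–60 nm) independently makes the least-squares problem
statistically unidentifiable: the linearized (Cramér–Rao) amplitude
standard deviation under 1% additive noise ranges from 0.9 to ~100 — i.e.
neighboring components can trade amplitude almost freely along near-null
directions of the design matrix. The default fit therefore uses the
*tied* parameterization: centers fixed at their nominal assignments, and
one shared width per group of components with identical width bounds (the
narrow SHG line and the seven broad fluorophores form two groups). Under
this model, noiseless synthetic spectra are recovered exactly and 1% noise
perturbs amplitudes by at most ~0.02. The fully free per-component model
remains available (`width_mode="free"`) for spectra whose bands genuinely
deviate from the nominal positions; it should only be trusted on noiseless
or heavily averaged input.

**Solver.** Bounded trust-region-reflective least squares
(`scipy.optimize.least_squares`) with an analytic Jacobian, swept over a
fixed grid of width starts (12, 16, 20, 25, 30 nm plus the per-group
initial widths); the start with the lowest residual wins. Starting
amplitudes at each width start are solved exactly by bounded linear least
squares (BVLS) against the initial Gaussian basis. The procedure is fully
deterministic — no random restarts — and a fit that converges from no
start raises an error rather than returning silently. Amplitudes are
bounded to [0, 1.5] on the normalized scale; the fit window is 382–714 nm.
The normalization precondition is enforced softly (peak within [0.5, 1.5]):
spectra synthesized from near-unit amplitude lists legitimately peak
slightly above 1 because neighboring tails add.

## Collagen quantification

The pipeline is fixed in this order (each intermediate is retained on the
result object):

1. **Enhancement** — linear percentile stretch onto [0, 1]; defaults map the
   1st percentile to 0 and the 99th to 1, clipping outside. A constant
   image maps to zero.
2. **Otsu threshold** — computed from scratch on a 256-bin histogram of the
   enhanced image: the interior bin edge maximizing the between-class
   variance ω₀ω₁(μ₀−μ₁)². The returned threshold is the lower edge of the
   upper class (pixels ≥ threshold are collagen). Candidate edges are
   restricted to those following a nonempty bin — edges inside runs of
   empty bins describe the same partition, so this both implements the
   "lowest qualifying edge" tie rule and avoids floating-point near-ties
   between mathematically identical splits.
3. **Morphological cleanup** — binary opening (removes speckle) then
   closing (fills small holes) with a disk structuring element of radius 1
   by default; radius 0 disables the step.
4. **Pixel fraction** — collagen content = (collagen pixels)/(all pixels),
   an exact count ratio.

Two modality entry points share this pipeline: `quantify_shg` runs it on an
SHG detector image, and `quantify_combined` first reduces a 32-channel
stack to the SHG-band channel sum (the collagen-specific reduction; other
reductions such as the full-grid integral would mix in cytoplasmic
fluorescence). Batch reports give the per-modality mean and sample
standard deviation (ddof = 1; undefined for a single image).

## Synthetic phantom

Real patient imagery for this tissue type is not publicly distributable,
so validation runs on a generator whose ground truth is known exactly.

The phantom emulates: curvilinear collagen fiber bundles (random-walk
polylines dilated to a 3 ± 1 px width) carrying SHG abundance with a smooth
multiplicative texture; a weak broadband fluorescence share on collagen
(15% of the SHG abundance, carried by the structural-protein component)
so fibers appear yellow in overlays; cells as disks (radius 9 px) with
fluorescence-dark nuclei (radius 4 px) and cytoplasm carrying free NADH
(0.35), FAD (0.18), lipopigment (0.12) and bound NADH (0.10) abundances;
and detection noise as Poisson shot noise (expected 200 photons per unit
intensity — peak-signal SNR ≈ 14) plus additive Gaussian read noise
(σ = 0.01), clipped at zero. Amplitude choices are plausible for
NAD(P)H/flavin-dominated cytoplasm against strong fibrillar SHG but are
free parameters of the phantom, not claims about tissue.

Fibers are added — shrinking the stroke length on overshoot — until the
collagen mask fraction is within ±0.02 of the target; nuclei are carved out
of every abundance map afterwards (nuclei are dark in autofluorescence
imaging) and fibers are topped up away from nuclei if the carving dropped
the fraction below band. Per-pixel spectra are the abundance-weighted sums
of the same Gaussian bases the fitting module uses, sampled at the channel
labels, so fit round-trips are closed-form consistent. Identical specs
(including the seed) produce bit-identical phantoms; the two-channel render
of a spec equals the band integrals of its noiseless lambda stack, with
noise applied after integration.

**What the phantom does not model:** optical point-spread functions, depth
attenuation and scattering, detector spectral response, fiber crimp or
sub-resolution texture, spatially varying background, and real nuclear
pleomorphism. Passing recovery tests therefore demonstrates correctness of
the algorithm chain under a controlled forward model, not clinical-grade
accuracy on tissue.

## Problem sizes and defaults

Phantoms default to 256 × 256 px (most unit tests use 96–128 px), chosen
as a representative desk-scale field that keeps a full suite run under ten
seconds. Recovery acceptance sweeps target fractions 0.2–0.65 at 256 × 256
with the default noise model; the cohort-style check runs 14 phantoms at
128 × 128 with true fractions drawn from a truncated Normal(0.53, 0.13).
Spectral fits use a 1-nm synthesis grid (333 points) for reference spectra
and the native 32-channel grid for ROI spectra.

## Known limitations

- The tied-width spectral model assumes a common bandwidth for the broad
  fluorophores; genuinely heterogeneous bandwidths will be absorbed into
  amplitude biases (the free mode exposes, but cannot stabilize, that
  degeneracy on noisy data).
- The Otsu pipeline assumes a bimodal-enough enhanced histogram; on images
  that are nearly all background or all collagen the threshold becomes
  arbitrary within the dominant mode (the degenerate all-constant case
  raises an error instead of guessing).
- Channel labels above 714 nm (the last grid label is 723 nm) are retained
  in full-grid integrals; band-limited operations never touch them with the
  default bands.
- Collagen content is a pixel fraction of the imaged field; it is not a
  volume fraction and depends on the segmentation scale like any
  threshold-based measure.
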
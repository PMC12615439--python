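# mpmcollagen

Label-free multiphoton microscopy (MPM) analysis of fibrous, collagen-rich
tissue: spectral (lambda-mode) image handling, eight-component multi-peak
decomposition of emission spectra, and automatic collagen-content
quantification — validated end to end on synthetic tissue phantoms with
known ground truth.

## Who this is for

MPM of unstained tissue derives contrast from endogenous signals: fibrillar
collagen produces second-harmonic generation (SHG) at exactly half the
excitation wavelength, while NADH, FAD, lipopigments, porphyrins and
structural proteins emit two-photon excited fluorescence (TPEF). For
collagen-dense tumors such as fibrous meningioma this makes MPM a
label-free window on the extracellular matrix. This package implements the
desk-side analysis around such acquisitions for anyone working with
32-channel lambda stacks or two-channel TPEF/SHG images: microscopists,
image analysts, and methods developers who need a tested, scriptable
pipeline rather than one-off vendor macros.

## What it computes

**Spectral decomposition.** A ROI-averaged, unit-normalized emission
spectrum is fitted as a nonnegative sum of eight Gaussian components

    S(λ) = Σ_j A_j exp(−(λ − μ_j)² / (2σ_j²))

at centers 405 (collagen SHG), 425 (bound NADH), 475 (free NADH), 510
(structural proteins), 545 (FAD), 575 (lipopigments), 630 and 690 nm
(porphyrins I/II), by bounded deterministic least squares. The fitted
amplitudes are the relative component ratios.

**Collagen content.** SHG images (or the SHG-band integral of a 32-channel
stack) pass through a fixed pipeline — percentile contrast stretch, Otsu
thresholding implemented from the histogram (maximizing the between-class
variance ω₀ω₁(μ₀−μ₁)²), binary opening + closing — and collagen content is
the resulting pixel fraction, collagen pixels / all pixels.

**Phantoms.** A seeded generator renders fibrous-tissue fields (collagen
fiber bundles, cells with dark nuclei and fluorescent cytoplasm, Poisson +
Gaussian detection noise) as lambda stacks and two-channel images together
with their exact ground-truth masks and per-component abundance maps.

See `docs/methods.md` for the models, assumptions and parameter choices.

## Worked example

```python
import numpy as np
from mpmcollagen import (
    PhantomSpec, ROI, dice_coefficient, fit_components, normalize_spectrum,
    quantify_combined, quantify_shg, ratio_report, render_lambda_stack,
    render_two_channel, roi_mean_spectrum,
)

spec = PhantomSpec(seed=7, target_collagen_fraction=0.5)   # 256x256 field
stack, truth = render_lambda_stack(spec)                   # 32-channel stack
two, _ = render_two_channel(spec)                          # SHG + TPEF bands

print("true collagen fraction:", round(truth.collagen_fraction, 3))
res = quantify_shg(two)
print("SHG-image content:", round(res.collagen_content, 3),
      " threshold:", round(res.threshold, 3))
print("combined-image content:",
      round(quantify_combined(stack).collagen_content, 3))
print("Dice vs truth:", round(dice_coefficient(res.mask, truth.collagen_mask), 3))

s = normalize_spectrum(roi_mean_spectrum(stack, ROI.full(spec.shape)))
print(ratio_report(fit_components(s)).head(3).to_string(index=False))
```

prints

```
true collagen fraction: 0.495
SHG-image content: 0.51  threshold: 0.262
combined-image content: 0.51
Dice vs truth: 0.951
              name    ratio
      collagen_SHG 0.992981
structural_protein 0.149628
         NADH_free 0.050899
```

The phantom was built to hold 49.5% collagen; both modalities read it back
as 0.510 (within the pipeline's ±0.05 validation band) with a mask overlap
(Dice) of 0.95. The full-field mean spectrum is dominated by the 405-nm
collagen SHG component, as expected for a fiber-dense field; the
structural-protein ratio includes the weak broadband fluorescence the
phantom assigns to collagen itself.

The same workflow is available from the shell:

```bash
mpmcollagen simulate --seed 7 --target-fraction 0.5 --out phantom/
mpmcollagen collagen phantom/two_channel.tif --modality shg --out quant/
# -> shg: collagen content 0.510 +/- n/a over 1 image(s)
mpmcollagen fit-spectrum --stack phantom/lambda_stack.tif --out fit/
# -> dominant component: collagen_SHG (ratio 0.993)
mpmcollagen render phantom/lambda_stack.tif --out combined.png
```

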
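# renalswin

Kidney CT lesion segmentation and classification that couples explicit
intensity statistics with attention-based networks, for researchers who
need every stage of such a pipeline — phantom data, preprocessing,
statistical segmentation, network training, evaluation, saliency — testable
on one CPU.

Renal lesions (cysts, stones, tumors) differ from surrounding parenchyma
mostly through intensity distribution and shape, and the hard cases are
small or low-contrast.  `renalswin` addresses this with two coupled ideas:

1. **A three-parameter Gamma mixture over pixel intensities.**  Each tissue
   region follows a location-shifted Gamma law with shape α, scale β and
   location γ (support y > γ, mean μ = γ + αβ, variance σ² = αβ²); an image
   is a K-component mixture with weights w_i.  The component count and
   initial parameters come from hierarchical clustering of an intensity
   subsample; an EM-style loop with a moment-matching M-step (β = V/Ȳ,
   α = Ȳ²/V under posterior responsibilities, locations fixed) refines the
   fit.  Posterior argmax segments the image; a peak-normalized density
   "atypicality" map (1 − max_i f_i(y)/f_i(mode_i)) highlights pixels no
   tissue law explains and rides along as an extra network input channel.
2. **A windowed-attention encoder–decoder with Gamma-gated channels.**  A
   four-stage hierarchical encoder (shifted-window self-attention, patch
   merging, features at 1/4…1/32 resolution) feeds a decoder whose skip
   connections are cross-attention — F_fused = softmax(Q_dec K_encᵀ/√d)
   V_enc + F_dec — with deep supervision and a dilated-convolution boundary
   branch.  Channel gating estimates per-channel Gamma parameters (k, θ)
   from pooled activations and rescales channels by
   sigmoid(u·μ̂ + v·σ̂² + b), where μ = kθ and σ² = kθ².  A pyramid
   classifier with a class token and attention-based scale fusion labels
   lesion crops (normal/cyst/stone/tumor).

Everything runs on a small NumPy reverse-mode autodiff core included in the
package, so the full pipeline trains and evaluates on a single CPU at
phantom scale.  Synthetic kidney phantoms with known Gamma tissue laws make
every stage verifiable against exact oracles; see `docs/methods.md` for the
models, defaults and limitations.

## Worked example

Fit a Gamma mixture to a lesion-free kidney phantom and segment it
(`examples/01_gamma_mixture_fit.py`):

```python
from renalswin.gamma import em_fit, hierarchical_init, segment_by_mixture
from renalswin.phantom import PhantomSpec, generate_phantom

img, mask, _ = generate_phantom(PhantomSpec(class_label="normal", seed=3))
init = hierarchical_init(img.pixels.ravel(), max_k=4, seed=0)
state = em_fit(img.pixels.ravel(), init, max_iter=30)
seg = segment_by_mixture(img, state.mixture)
```

Output of the example script:

```
true tissue means: background 20.0, parenchyma 140.0
recovered K = 2, component means = [ 20.1 140. ], weights = [0.729 0.271]
mixture mean intensity = 52.5 (empirical image mean = 52.6)
mixture segmentation pixel accuracy vs ground truth: 1.0000
```

The clustering found the right number of tissue regions, the EM refinement
recovered the true region means (20 and 140) to within 0.1 intensity units,
the mixture weights match the background/parenchyma area fractions, and
classifying each pixel by its posterior separates kidney from background
perfectly — on a clear-contrast phantom, intensity alone suffices, which is
exactly what the known tissue laws predict.

The other examples cover the atypicality map (`02`), dataset generation and
manifest validation (`03`), a one-minute segmentation training run (`04`),
and crop classification with Grad-CAM saliency (`05`).  Each prints what it
computes and says what the numbers mean.

A thin CLI mirrors the pipeline order for shell use:

```bash
renalswin --seed 3 phantoms --n-per-class 10 --image-size 64 --out data/
renalswin fit-gamma --in data/normal_0000.png --max-k 4 --out params.json
renalswin segment-gamma --in data/normal_0000.png --params params.json --out seg.png
renalswin train-seg --data data/ --out runs/seg
renalswin evaluate --pred data/ --truth data/ --manifest data/manifest.csv --out report.json
```

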
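# drseg

Domain-randomised synthetic training for 3D segmentation that is robust to
contrast and resolution — without ever training on an acquired image.

## The problem

Supervised segmentation networks work well on the domain they were trained on
and degrade sharply on scans of a different MRI contrast, modality, or slice
spacing; clinical archives are full of exactly such heterogeneous 2D
acquisitions with thick slices and heavy partial voluming. `drseg` implements
the *domain randomisation* answer: train on synthetic images sampled on the
fly from a generative model conditioned only on anatomical **label maps**,
with every generation parameter drawn fresh from wide uniform priors at each
example. Real scans of any contrast and resolution then lie inside the
support of the training distribution, and a single trained network segments
them all at a crisp high working resolution `r_HR`.

For each training pair {I, T}, given a label map S:

- spatial: `L = S ∘ φ_aff ∘ φ_nonlin`, with a random affine and a
  diffeomorphic warp (scaling-and-squaring exponential of a coarse Gaussian
  stationary velocity field), nearest-neighbour resampled in one pass;
- contrast: `G(x) ~ N(μ_{L(x)}, σ²_{L(x)})` with per-label μ ~ U(0, 255),
  σ ~ U(0, 35) redrawn every example;
- artefacts: multiplicative bias `G·exp(B)` from an upsampled 4³ Gaussian
  grid; min–max rescaling to [0, 1]; gamma transform `I^exp(γ)`,
  γ ~ N(0, σ_γ²);
- resolution: slice axis ~ U{0,1,2}, spacing r_spac ~ U(r_HR, b_res),
  thickness r_thick ~ U(r_HR, r_spac), Gaussian slice-profile blur of width
  `2α·ln(10)/(2π)·r_thick/r_HR` voxels, downsampling to r_spac and
  resampling back to the r_HR grid;
- target: T is the same deformed label map with non-segmented labels reset
  to background — image and target are perfectly aligned by construction.

The network (3D U-Net with instance normalisation, ELU, soft Dice loss,
Adam, batch size 1) and the test-time pipeline (resample
to r_HR, 1st/99th-percentile rescaling, left/right flip-averaged prediction,
largest-component filtering) are included, as are the evaluation statistics
used to validate such a model: Dice, 95th-percentile surface distance, soft
volumes with OLS covariate correction and Cohen's d effect sizes, and an EM
intensity-clustering label subdivision for anatomies whose label maps do not
describe all visible tissue.

No external data are needed anywhere: a phantom module generates label-map
corpora with the structural features the pipeline relies on (lateral
structure pairs, an extra-cerebral shell, lesion hosts).

## Worked example

```python
import numpy as np
from drseg import phantoms
from drseg.estimator import DomainRandomizedSegmenter
from drseg.nn import ModelConfig

rng = np.random.default_rng(0)
corpus, pairs, roles = phantoms.make_phantom_corpus(4, (32, 32, 32), 2, rng)
cfg = phantoms.phantom_generation_config(2)           # labels 2,3,4 segmented
lesions = phantoms.make_lesion_blobs(6, rng)

est = DomainRandomizedSegmenter(gen_config=cfg, model_config=ModelConfig(),
                                n_steps=300, learning_rate=2e-3,
                                checkpoint_every=150, random_state=0)
est.fit(corpus, lesion_masks=lesions)                 # trains on synthetic stream
print(f"validation checkpoint: step {est.checkpoint_.step}")
print(f"final training loss:   {est.training_log_['loss'].iloc[-1]:.3f}")

from drseg.generator import sample_training_pair
test = sample_training_pair(corpus, cfg, np.random.default_rng(99),
                            lesion_masks=lesions)
print(f"held-out mean foreground Dice: {est.score([test.image], [test.target]):.3f}")
```

Output (300 steps is a demonstration, not a trained model):

```
validation checkpoint: step 300
final training loss:   0.327
held-out mean foreground Dice: 0.661
```

The training loss is the average soft Dice over the segmented channels
(0 = perfect overlap); the score is the hard Dice of the postprocessed
segmentation against the generator's own aligned target on a fresh draw. The
full desk-scale run in the test suite (4,500 steps with a step-decay
schedule and tail-averaged checkpoint retention, ~18 min on one CPU)
reaches mean foreground Dice ≥ 0.8 on unseen contrasts, with 5 mm slice
spacing within 0.15 Dice of isotropic input — the at-a-desk analogue of
contrast/resolution invariance.

The same pipeline is scriptable from the shell:

```bash
drseg phantom --n 4 --shape 32,32,32 --structures 2 --seed 0 --out labels/
drseg generate --labels labels/ --n 10 --seed 1 --out synth/
drseg train --labels labels/ --steps 4500 --seed 2 --out run/
drseg segment --model run/checkpoint_004500.npz --in scan.nii.gz \
              --pairs labels/lateral_pairs.csv --out seg.nii.gz
drseg eval --pred preds/ --ref refs/ --out metrics.csv
```

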
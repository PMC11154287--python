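# mpi-deblur

Simulation and deep-learning deblurring of magnetic particle imaging (MPI)
for tumor phantom quantification.

MPI images the spatial concentration ρ(r) of superparamagnetic nanoparticle
tracers.  X-space reconstruction — gridding the induced-voltage signal

    s(t) = d/dt ∫ σ_s ρ(r) m₀ L[k G (r_s(t) − r)] dr,   L(ξ) = coth ξ − 1/ξ,

by the instantaneous field-free-point position r_s(t) — yields the tracer
map convolved with the Langevin-derivative point-spread function
L'(ξ) = 1/ξ² − csch²ξ.  The resulting "native" images are blurry and noisy,
which defeats accurate lesion localization and concentration quantification.

This package provides, for researchers working on MPI reconstruction and
learned image restoration:

* a physics-based **forward simulator** (Langevin PSF, blur, SNR-exact
  spatially varying noise, 1-D signal synthesis) with the published
  simulation constants as defaults;
* a seeded **synthetic phantom corpus** generator (random tumor blobs,
  grayscale concentration levels, gradient variants, dihedral augmentation,
  leakage-safe train/test splits);
* a **dual-branch CNN + Transformer network** with channel-attention
  fusion, trained with the multi-supervised loss
  λ_a·MSE(x_a,y) + λ_b·MSE(x_b,y) + λ_f·MSE(x_f,y),
  implemented on a self-contained numpy autodiff engine (no GPU or deep
  learning framework required);
* classical **deconvolution baselines** (Wiener, Richardson–Lucy, blind)
  and **PSNR/SSIM** evaluation with mean ± std reports;
* **transfer learning** (freeze-and-fine-tune) and the two reproduction
  studies: two-target concentration ratios (1:0.2 … 1:1) and module
  ablations.

See `docs/methods.md` for the model, its assumptions and every default.

## Worked example

```python
import numpy as np
from mpi_deblur import SimulationParams, build_psf
from mpi_deblur.phantoms import build_dataset_arrays
from mpi_deblur.pipeline import ExperimentConfig, train, predict
from mpi_deblur.metrics import evaluate

# 440 phantom/native pairs at the published simulation constants (Langevin
# PSF at G = 6, additive noise at 5-15 dB SNR), 400 train / 40 test
data = build_dataset_arrays(440, (400, 40), rng_seed=7)
train_mask = data["split"] == "train"

cfg = ExperimentConfig(n_pairs=440, epochs=24, seed=7)
result = train(cfg, data["natives"][train_mask], data["phantoms"][train_mask])

test = ~train_mask
print("native :", evaluate(data["natives"][test], data["phantoms"][test]))
print("model  :", evaluate(predict(result.net, data["natives"][test]),
                           data["phantoms"][test]))
```

Output (≈4 min on one CPU core):

```
native : PSNR 18.0385 ± 1.8809  SSIM 0.5333 ± 0.0726  (n=40)
model  : PSNR 23.4683 ± 2.7891  SSIM 0.8917 ± 0.0412  (n=40)
```

The native X-space images sit at ~18 dB PSNR against the ground-truth
concentration maps; the trained network recovers ~5.4 dB and lifts SSIM
from 0.53 to 0.89, i.e. most of the structural degradation from the
Langevin blur and noise is removed.  The same protocol with the classical
baselines (`mpi_deblur.baselines`) shows Wiener/Richardson–Lucy/blind
deconvolution recovering substantially less (see the acceptance output
below for a full comparison).

The command line mirrors the library:

```bash
mpi-deblur dataset build --n 8000 --split 7000,1000 --out ds --seed 0
mpi-deblur train --data ds --out model.npz --epochs 24 --seed 0
mpi-deblur predict --ckpt model.npz --in ds/native_00000.tif --out restored.tif
mpi-deblur study concentration --ckpt model.npz --out ratios.json
mpi-deblur study ablation --data ds --out ablation.json
```

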
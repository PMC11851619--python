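# fdosr

Arbitrary-scale 3D super-resolution with frequency-domain regularization,
exercised end to end on synthetic cardiac-like phantoms.

## The problem

Isotropic 3D whole-heart MRI resolves small structures such as coronary
arteries, but ECG- and respiratory-triggered acquisitions are slow. A
super-resolution (SR) network lets a fast low-resolution scan stand in for
the long high-resolution one — provided it (a) works at *any* real scale
factor (a clinical scan is not degraded by a tidy integer), and (b) does
not blur away the fine detail that motivated the high resolution in the
first place.

`fdosr` addresses both with an encoder/decoder pair trained with a
spectral penalty:

* **Encoder f_θ** — a residual dense network on the low-resolution grid
  (8 residual dense blocks of 3 conv+ReLU layers each, dense
  concatenation, local and global feature fusion, global residual; no
  pooling, no normalization), ending in a 128-channel feature volume.
* **Arbitrary-scale upscale** — parameter-free trilinear resampling of the
  feature volume to the target grid, so one trained model serves any
  factor s ≥ 1 (2.5, 3.7, ... included).
* **Decoder g_φ** — an 8-layer per-voxel MLP with shared weights mapping
  each voxel's 128-vector to one intensity.

Training solves

    argmin_θ,φ  ||y − g_φ(f_θ(x))||₁  +  λ · ||mask ⊙ (FFT3D[y] − FFT3D[g_φ(f_θ(x))])||₁

where the binary mask keeps the high-spatial-frequency 70% band of the
spectrum (30% of the extent per axis is zeroed): the penalty pushes
training to preserve edges and thin vessels rather than just average
intensity. λ = 1e-3 by default. Scale factors are drawn uniformly from
[2, 4] during training, which is what teaches the network to be
scale-agnostic.

Because the clinical corpus is not redistributable, the package ships a
first-class synthetic-phantom module that reproduces the statistical
regime the method assumes — fine tubular structures (1–3 voxels across),
smooth ellipsoidal compartments, four contrast profiles standing in for
the four clinical sequences (REACT, NCSSFP, SSFP, IRSSFP), mild noise —
and every study in the test suite runs on those phantoms at desk scale.
See `docs/methods.md` for the full model description, parameter meanings,
and what the phantom studies do and do not demonstrate.

## Worked example

```python
import numpy as np
from fdosr import (PhantomSpec, generate_phantom, degrade, make_corpus,
                   EncoderConfig, DecoderConfig, super_resolve,
                   psnr, ssim3d, nearest_baseline)
from fdosr.training import desk_training_config, train

# 16 training phantoms (32³, four contrast profiles) and one test phantom
train_vols = [v for _, _, v in make_corpus(16, (32, 32, 32), base_seed=100)]
val_vols   = [v for _, _, v in make_corpus(4,  (32, 32, 32), base_seed=500)]
hr = generate_phantom(PhantomSpec(grid_size=(32, 32, 32), seed=901))

# tiny desk-scale model, 200 optimization steps, factors s ~ U[2, 4]
enc = EncoderConfig(n_rdb=2, layers_per_rdb=3, base_channels=32,
                    growth_channels=8, feature_dim=32)
dec = DecoderConfig(n_layers=4, hidden_width=32)
model, history = train(train_vols, desk_training_config(seed=0),
                       enc, dec, validation=val_vols)

lr = degrade(hr, 2.5)                       # 32³ -> 12³, non-integer factor
sr = super_resolve(lr, 2.5, model, target_dims=hr.shape)
nn = nearest_baseline(lr, 2.5, target_dims=hr.shape)
print(f"model   PSNR {psnr(sr, hr):5.2f} dB  SSIM {ssim3d(sr, hr):.3f}")
print(f"nearest PSNR {psnr(nn, hr):5.2f} dB  SSIM {ssim3d(nn, hr):.3f}")
```

Output from this exact script (seeds as shown):

```
model   PSNR 22.01 dB  SSIM 0.737
nearest PSNR 19.75 dB  SSIM 0.627
```

The trained tiny model recovers the phantom's tubes and shell borders
noticeably better than nearest-neighbor interpolation at a non-integer
factor it was never shown explicitly — the factor-agnostic behavior the
training regime is designed to produce. (At desk scale the absolute dB
values are far below what the full-size architecture reaches on clinical
volumes; the *ordering* is the point.)

The same pipeline is scriptable from the shell:

```sh
fdosr simulate --n 4 --size 32 --profile react --seed 0 --out phantoms/
fdosr degrade --in phantoms/phantom_000.nii.gz --factor 2.5 --out lr.nii.gz
fdosr pipeline --config run.yaml --seed 3     # simulate -> train -> evaluate
```

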
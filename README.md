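# dixonsep

Two-point Dixon water–fat separation for chemical-shift-encoded MRI:
the dual-echo signal model, field-map phasor selection as a binary
quadratic program solved by projected power iteration, a multiresolution
acceleration pipeline, seeded synthetic phantoms (including metal-like
B0 perturbations and multicoil simulation with SVD coil compression),
a hierarchical multi-output CNN trained on those phantoms, and pinned
image-quality metrics.  It is aimed at MR-physics and image-analysis
researchers who want a tested, reproducible desk-scale implementation
of dual-echo water–fat separation to study swap behavior, field-map
estimation, and learned separation — not a clinical tool.

## The problem

A dual-echo acquisition measures, per pixel,

```
S1 = (W + C1·F)·e^{iφ1},   S2 = (W + C2·F)·e^{iφ2},
Ck = exp(i·2π·Δf·TEk),     φk = φ0 + 2π·b0·TEk,
```

with water/fat amplitudes `W, F ≥ 0`, fat chemical-shift offset `Δf`
(≈ −447 Hz at 3 T for a single-peak −3.5 ppm model) and field-map
frequency `b0` (Hz).  The magnitudes determine `{W, F}` only up to a
swap; each of the two candidates implies a unit phasor
`P = e^{i·2π·b0·(TE2−TE1)}` candidate.  Choosing the wrong candidate
swaps water and fat exactly.  The package resolves the ambiguity by
minimizing

```
f(x) = Σ_{r,s∈N_r} V(r,s)(x_r, x_s),
V(r,s)(i,j) = min(|S1(r)|,|S1(s)|)/d(r,s) · |P_i(r) − P_j(s)|²,
```

a binary quadratic program over per-pixel candidate labels enforcing
field-map smoothness, solved by a projected power iteration (with a
brute-force oracle for tiny graphs), optionally at coarse resolution
with per-pixel re-selection after phasor upsampling.  A hierarchical
encoder–decoder CNN (3×3 conv + PReLU blocks with dense local
shortcuts, 2×2 stride-2 conv down/up, global shortcuts, two 1×1
heads; l1 loss, He init, Adam) learns the same mapping end-to-end
from synthetic phantoms.  See `docs/methods.md` for the full model
description and design decisions.

## Worked example

```python
import numpy as np, dixonsep as dx

truth = dx.generate_phantom(dx.smooth_spec(), seed=7)      # known W, F, b0
img   = dx.simulate_acquisition(truth, noise_sigma=0.0)    # dual-echo signals
res   = dx.separate_dual_echo(img)                         # classical pipeline

print(np.abs(res.water - truth.water).max())   # 8.3e-16
print(dx.evaluate_pair(res.water, truth.water).corr)  # 1.0000
```

On noiseless smooth-field phantoms the classical pipeline is exact to
machine precision.  The scripts in `examples/` walk through each
capability; `examples/02_swap_robustness.py` prints, for the
swap-inducing phantom preset,

```
swapped pixels, per-pixel baseline : 67.2 %
swapped pixels, full pipeline      : 0.00 %
```

i.e. a pixel-independent candidate choice swaps the entire fat rim
while the smoothness-regularized selection recovers the true
assignment.  The same comparison is the control for the trained
network, which reaches a validation l1 of ≈ 0.025 (in units of the
99th-percentile signal) and a mean per-image water correlation of
≈ 0.99 on held-out phantoms after the standard desk run
(`examples/05_train_network.py` is a faster miniature).

A thin CLI wraps the library for shell use:

```
dixonsep simulate --seed 7 --n 4 --out runs/sim
dixonsep separate --input runs/sim/case000.npz --output runs/sim/rec --downsample 4
dixonsep eval --pred runs/sim/rec --ref-truth runs/sim/case000_truth.npz --out runs/sim/metrics.json
dixonsep train --data runs/sim --net desk --epochs 20 --out runs/model
dixonsep predict --model runs/model --input runs/sim/case000.npz --output runs/sim/net
```

## Layout

```
src/dixonsep/
  core.py      signal model, candidate amplitudes/phasors, inversion
  selector.py  penalty graph, projected power + oracle, multiresolution
  phantom.py   seeded phantoms, metal dipole, multicoil + coil compression
  nn.py        NumPy conv/PReLU/Adam engine with manual backprop
  network.py   network presets, input normalization, training, inference
  metrics.py   pinned corr / l1 / SSIM / pSNR
  io.py        archives, NIfTI pairs, manifests, seed fan-out
  cli.py       umbrella CLI
examples/      one short narrative script per capability
docs/methods.md  model assumptions, parameters, design decisions
```
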
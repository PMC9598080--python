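"""The four pinned image-quality metrics on controlled degradations."""

import numpy as np

import dixonsep as dx

truth = dx.generate_phantom(dx.smooth_spec(), seed=2)
ref = truth.water
rng = np.random.default_rng(0)

cases = {
    "identical": ref,
    "plus noise (sigma 0.02)": ref + 0.02 * rng.standard_normal(ref.shape),
    "plus noise (sigma 0.10)": ref + 0.10 * rng.standard_normal(ref.shape),
    "smoothed (3x3 mean)": np.pad(ref, 1, mode="edge")[1:-1, 1:-1],
}
from scipy import ndimage
cases["smoothed (3x3 mean)"] = ndimage.uniform_filter(ref, 3)

print(f"{'case':26s} {'corr':>7s} {'l1':>8s} {'ssim':>7s} {'psnr':>7s}")
for name, pred in cases.items():
    r = dx.evaluate_pair(np.abs(pred), ref)
    print(f"{name:26s} {r.corr:7.4f} {r.l1:8.4f} {r.ssim:7.4f} {r.psnr:7.2f}")
print()
print("Identical images pin the identities corr=1, l1=0, ssim=1 and the")
print("capped 99 dB psnr; noise lowers ssim/psnr monotonically; all four")
print("metrics are invariant to a joint rescaling of both images.")
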
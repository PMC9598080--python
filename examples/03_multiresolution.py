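"""Multiresolution acceleration of the field-map estimation.

The phasor selection runs on block-mean downsampled echoes; the
selected phasor field is upsampled and amplitudes are re-solved at full
resolution.  The voxel-count ratio of the clinical resolutions
(~0.6 x 0.6 x 1 mm^3 -> 6 x 6 x 6 mm^3) shows the speed-up this buys.
"""

import numpy as np

import dixonsep as dx

ratio = dx.downsampling_voxel_ratio((0.6, 0.6, 1.0), (6.0, 6.0, 6.0))
print(f"clinical voxel-count reduction factor : {ratio:.0f}")

truth = dx.generate_phantom(dx.smooth_spec(), seed=3)
img = dx.simulate_acquisition(truth, noise_sigma=0.0)

for factor in (1, 2, 4):
    res = dx.separate_dual_echo(img, downsample_factor=factor)
    rel = np.abs(res.water - truth.water).sum() / truth.water.sum()
    print(f"factor {factor}: relative l1 water error {rel:.2e}, "
          f"{res.meta['iterations']} iterations")

print()
print("Coarse field-map estimation loses essentially nothing here because")
print("the candidate phasor is re-selected per pixel at full resolution")
print("before the exact amplitude solve.")
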
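"""Classical two-point Dixon separation of a synthetic phantom.

Generates a smooth-B0 phantom, simulates the dual-echo acquisition,
runs the projected-power separation pipeline and reports how well the
known water/fat maps are recovered.
"""

import numpy as np

import dixonsep as dx

truth = dx.generate_phantom(dx.smooth_spec(), seed=7)
img = dx.simulate_acquisition(truth, noise_sigma=0.0)

result = dx.separate_dual_echo(img)

err_w = np.abs(result.water - truth.water).max()
err_f = np.abs(result.fat - truth.fat).max()
rec = dx.evaluate_pair(result.water, truth.water)

print(f"selection energy        : {result.meta['energy']:.4g}")
print(f"power iterations        : {result.meta['iterations']}")
print(f"max abs error water/fat : {err_w:.2e} / {err_f:.2e}")
print(f"water corr / l1 / psnr  : {rec.corr:.4f} / {rec.l1:.2e} / {rec.psnr:.1f} dB")
print()
print("On noiseless data with a smooth field map the pipeline is exact:")
print("both maximum errors should be at numerical precision (~1e-14) and")
print("the correlation with ground truth should be 1.0000.")
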
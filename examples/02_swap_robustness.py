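"""Water/fat swap robustness of the smoothness-regularized selection.

Uses the swap-inducing phantom preset (wide fat rim, strong B0
gradient, metal-like dipole).  A per-pixel candidate choice with no
spatial coupling misassigns every fat-dominant pixel; the penalty-graph
selection recovers the correct assignment almost everywhere.
"""

import dixonsep as dx

truth = dx.generate_phantom(dx.swap_inducing_spec(), seed=1)
img = dx.simulate_acquisition(truth, noise_sigma=0.0)

baseline = dx.separate_no_smoothness(img)
pipeline = dx.separate_dual_echo(img)

sf_base = dx.swapped_fraction(baseline.water, baseline.fat, truth)
sf_pipe = dx.swapped_fraction(pipeline.water, pipeline.fat, truth)

print(f"swapped pixels, per-pixel baseline : {100 * sf_base:.1f} %")
print(f"swapped pixels, full pipeline      : {100 * sf_pipe:.2f} %")
print()
print("The baseline always picks the lower-fat candidate, so the whole fat")
print("rim comes out swapped (tens of percent).  The field-map smoothness")
print("penalty drives the swapped fraction to (near) zero.")
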
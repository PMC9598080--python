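"""SVD coil compression of a simulated multicoil acquisition.

Both echoes are stacked into one coils-by-pixels matrix and projected
onto the leading singular vectors, with the same matrix for both echoes
so that the inter-echo phase (which carries the field map) survives.
"""

import numpy as np

import dixonsep as dx

truth = dx.generate_phantom(dx.smooth_spec(), seed=5)
s1, s2, sens = dx.simulate_multicoil(truth, n_coils=16, noise_sigma=0.01, seed=5)

for n_virtual in (16, 6, 2, 1):
    v1, v2, retained = dx.compress_coils(s1, s2, n_virtual)
    print(f"{n_virtual:2d} virtual channels: retained signal energy {retained:.6f}")

v1, v2, _ = dx.compress_coils(s1, s2, 6)
phase_full = np.angle((s2 * np.conj(s1)).sum(axis=0))
phase_comp = np.angle((v2 * np.conj(v1)).sum(axis=0))
tissue = truth.tissue_mask > 0
dphi = np.abs(np.angle(np.exp(1j * (phase_comp - phase_full))))[tissue]
print(f"inter-echo phase deviation after 16->6 compression: "
      f"median {np.median(dphi):.2e} rad")
print()
print("Smooth coil sensitivities concentrate the energy in a few virtual")
print("channels, and the shared projection keeps the inter-echo phase.")
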
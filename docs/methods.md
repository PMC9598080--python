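# Methods

`dixonsep` implements two-point Dixon water–fat separation for
chemical-shift-encoded MRI, at two levels: a classical, physics-driven
pipeline (candidate phasors on a penalty graph, solved by projected
power iteration), and a convolutional network trained on synthetic
phantoms to map dual-echo images directly to water/fat images.  This
note records the models, the assumptions, the tunable parameters, and
the design choices made where the design was genuinely open.

## Signal model

Per pixel, the in-phase and out-of-phase complex signals are

    S1 = (W + C1 F) e^{i φ1},   S2 = (W + C2 F) e^{i φ2},

with `W, F ≥ 0` the water/fat amplitudes (arbitrary units),
`Ck = exp(i 2π Δf TEk)` the fat dephasing factor at echo time `TEk`,
and `φk = φ0 + 2π b0 TEk` collecting receive phase and B0-induced
phase.  Units are pinned: echo times in milliseconds in every
interface (converted to seconds only inside formulas), B0 maps in Hz,
phases in radians.

Assumptions and conventions:

- **Single-peak fat spectrum** at `fat_shift_ppm = −3.5` ppm
  (configurable).  Fat resonates below water, so Δf is negative and
  phase accrues as `exp(+i 2π Δf TE)`.  Multi-peak fat models, R2*
  decay and three-plus-echo acquisitions are out of scope.
- **2D slice processing** throughout; volumes are loops over slices.
- Default acquisition: 3 T, TE 2.23 ms (in-phase) / 1.26 ms
  (out-of-phase), giving Δf ≈ −447 Hz, `C1 ≈ +1`, `Re C2 ≈ −0.92`.
  Note the in-phase/out-of-phase TE pairs used clinically are not
  exactly consistent with a single shift value; the single-peak default
  is a documented assumption, and every formula takes `C1, C2` from the
  acquisition parameters rather than hard-coding ±1.

## Candidate ambiguity

The magnitude pair determines `p = W·F` and `q = W² + F²` in closed
form, hence `{W, F}` up to a swap:

    p = (|S1|² − |S2|²) / (2 (Re C1 − Re C2)),   q = |S1|² − 2 p Re C1,
    W + F = sqrt(q + 2p),   |W − F| = sqrt(q − 2p).

Candidate 1 assigns the larger root to water (an arbitrary but fixed
ordering; the selection stage, not the ordering, decides the output).
Under noise, negative products/discriminants are clamped to zero and
flagged in a degeneracy mask instead of raising.  Each candidate k
implies a unit phasor

    Pk = conj(S1) S2 / ((Wk + conj(C1) Fk)(Wk + C2 Fk)),

which for the candidate matching the truth equals the inter-echo B0
phasor `exp(i 2π b0 (TE2 − TE1))` exactly.  Both candidates fit the
measured magnitudes exactly, so picking the wrong one swaps water and
fat exactly — the swap artifact this package is about.

## Phasor selection as a binary quadratic program

Each pixel r picks candidate `x_r ∈ {1, 2}` to minimize
`f(x) = Σ_{r,s} V(r,s)(x_r, x_s)` with pairwise penalties

    V(r,s)(i,j) = min(|S1(r)|, |S1(s)|) / d(r,s) · |P_i(r) − P_j(s)|²

over a neighbor offset set.  Choices made here:

- **d(r, s) divides.**  The penalty line in the field-map-smoothness
  formulation is typographically ambiguous; physical smoothness
  weighting must decay with distance, so the distance divides.  The
  construction is isolated in `build_penalty_graph`, so the opposite
  reading is a one-line change for sensitivity experiments.
- **Neighbor set**: all integer offsets within Euclidean radius 4
  (48 offsets), configurable via `NeighborSpec`.  The clinical
  reference implementation uses 56 empirically selected pixels whose
  composition (and 2D/3D-ness) is unpublished; the radius-4 disk is the
  closest regular 2D analog.
- **Borders**: out-of-image neighbors are dropped (no padding, no
  wraparound).  The energy counts ordered pairs, so each unordered pair
  contributes twice, consistently in the solver and the brute-force
  oracle.

### Projected power solver

The one-hot relaxation iterates `v ← (λI − V) v` on the per-pixel
candidate 2-vector field, with `λ` the maximum total absolute row
weight of V.  That shift makes `λI − V` diagonally dominant, hence
positive semidefinite, so the power iteration converges toward the
smallest-penalty eigenmode of V.  Labels are read off each iteration by
projecting every pixel to the one-hot of its larger entry (ties keep
the current label).  Details that the problem statement leaves open,
fixed here:

- The continuous iterate is carried between multiplications.  A purely
  one-hot iteration with this λ provably freezes: flipping a label
  would need `M_cur − M_other > λ` while `M_cur ≤ λ` by construction.
- Label states are accepted only if they do not increase the energy, so
  the accepted-energy sequence is non-increasing by construction.
- The iteration runs from both canonical starts (all-candidate-1 and
  all-candidate-2) and returns the lower-energy result;
  `max_iter = 1000` per start — most instances converge within ~100
  multiplies, but strong-gradient instances can have a small eigengap
  and need several hundred; convergence when the normalized iterate
  stalls (max change < 1e−12) or the labels are stable for 10
  consecutive iterations.
- A greedy single-pixel descent pass follows (flip every pixel whose
  flip strictly lowers the energy; on conflict, flip the single best
  pixel).  The power iteration resolves the global structure but is
  insensitive to pixels whose two candidates nearly coincide
  (`W ≈ F`); the cleanup settles those at negligible cost and is
  strictly energy-decreasing and deterministic.
- The solver consumes no randomness; the `seed` argument exists for
  interface uniformity.

On 4×4 random graphs the solver matches exhaustive enumeration in
≥ 90 % of instances and never exceeds 1.1× the optimum in the test
suite; on noiseless smooth phantoms it recovers the true labeling
exactly.  These thresholds are this package's test choices, not claims
about the clinical implementation.

### Multiresolution pipeline

`separate_dual_echo` optionally block-mean-downsamples both echoes by
an integer factor (default 1; 4 is the coarse preset), solves the
selection at low resolution, bilinearly upsamples the selected phasor
field (renormalized to unit modulus; zero-magnitude interpolants fall
back to nearest neighbor), then **re-selects per pixel** the candidate
phasor closest in angle to the upsampled field and re-solves the 2×2
amplitude system at full resolution.  Recomputing amplitudes from the
re-selected candidate phasor — rather than upsampling water/fat images
directly — is exact in the noiseless limit, which is why it is the
default; the literal upsample-the-amplitudes ordering is available as
`upsample_mode="amplitude"` and is visibly blurrier at coarse factors.
The voxel-count ratio of the clinical resolutions (~0.6 × 0.6 × 1 mm³
to 6 × 6 × 6 mm³) is ~600, the speed-up the coarse field map buys.

### Global swap correction

Spatial smoothness cannot distinguish a globally swapped solution, so
`global_swap_correct` provides an explicit `swap`/`keep` flag plus an
`auto` heuristic standing in for the manual step used clinically: in
extremity imaging the tissue border should be fat-dominant
(subcutaneous fat), so the maps are swapped when the interior fat
fraction exceeds the border band's by a margin (default 0.2, band
width 3 px).  The heuristic is only meaningful for anatomies with a
fat rim; `keep` is the default everywhere.

## Synthetic phantoms

`generate_phantom` draws, from a seeded generator: a jittered body
ellipse with a water-dominant interior (W ≈ 0.9, F ≈ 0.08, modulated
by a smooth ±10 % polynomial), an optional fat rim (F ≈ 0.92) of
configurable width, marrow-like inclusions with fat fraction uniform
in [0.35, 0.65], a polynomial B0 field (order 2 by default) scaled to
`b0_amplitude_hz`, an optional dipole perturbation
`strength · (3cos²θ − 1) · a³ / max(r, a)³` mimicking a metallic
implant, and an order-1 polynomial receive phase.  Acquisition noise
is additive complex Gaussian; the default σ = 0.03 on unit-scale
tissue gives roughly 30 dB peak SNR.  Defaults are 64×64 images for
tests and training, 256×256 for demos.

Two presets define the study conditions: `smooth_spec` (B0 amplitude
40 Hz, no metal) — every such phantom separates exactly through the
noiseless classical pipeline — and `swap_inducing_spec` (wide rim,
120 Hz B0, 60 Hz dipole), on which a per-pixel lower-fat-candidate
baseline misassigns well over 10 % of decidable pixels, the fixture
that makes swap-robustness claims testable.

What the generator does **not** emulate: anatomical texture and
heterogeneity, k-space sampling and parallel-imaging artifacts,
multi-peak fat, R2* decay, motion, and the sheer variability of
clinical data.  Passing tests therefore demonstrate correctness of the
algorithms under the model's own assumptions, not clinical-grade
performance.

Multicoil simulation applies smooth random complex sensitivities per
coil; SVD coil compression stacks both echoes into one coils-by-pixels
matrix and projects both with the same leading-singular-vector matrix,
preserving inter-echo phase.  Compression operates in image space
(equivalent to k-space compression under linearity).

## Network

The network is a hierarchical encoder–decoder ("T-Net"-style):
per level, three 3×3 conv blocks with PReLU and densely connected
local shortcuts; 2×2 stride-2 convolutions down, 2×2 stride-2
transposed convolutions up; U-Net-style global shortcuts
(concatenation) between matching levels; two parallel linear 1×1 heads
for water and fat.  "Densely connected local shortcuts" is read as:
every block receives the concatenation of the level input and all
previous block outputs, and a final 1×1 projection fuses the level
back to its width — one concrete reading of an underdetermined wiring.
Output heads are linear with post-hoc clamping of negatives to zero
(magnitude images are predicted; whether complex outputs would be
preferable is untested here).

Inputs are six channels: `|S1|/m`, `|S2|/m`, `arg(S1)/π`, `arg(S2)/π`,
and two constant maps `TE1/10 ms`, `TE2/10 ms` so clinical echo times
land in ~[0.1, 0.5].  `m` is the 99th percentile of `|S1|` over the
training set, stored in a normalization record; the inverse transform
multiplies outputs by `m`.  Wrapped phase over π is the primary phase
encoding; a sin/cos encoding would avoid wrap discontinuities and is a
known alternative, but the wrapped encoding suffices on these phantoms.

Two presets share the topology: the full-scale configuration
(5 levels, 16/32/64/128/256 channels, ~7.3 M parameters) and the
desk-scale configuration used for all experiments here (3 levels,
8/16/32 channels, 110 866 parameters — the count is frozen in a
regression test from layer-by-layer hand accounting).

Training: l1 loss, He-normal initialization, Adam with lr 0.001,
β1 0.9, β2 0.999, ε 1e−8 (the optimizer's own adaptivity; no schedule,
no augmentation), batch size 16, fully seeded (init, data order,
noise).  The layers and backpropagation are implemented directly in
NumPy (`dixonsep.nn`): im2col convolutions, tile-based transposed
convolutions, per-channel PReLU, all float32.  Gradients are verified
against finite differences in the test suite's engine checks.

The standard desk run trains on 256 synthetic 64×64 smooth-B0
phantoms with 64 held out, 30 epochs (~12 min on one CPU).  Problem
sizes were chosen so the full suite runs on a laptop-class single
core; the full-scale preset builds and runs forward/backward but is
not trained in the tests.

## Metrics

`evaluate_pair` pins the four fidelity metrics so reported numbers are
reproducible: both images are scaled by the 99th percentile of the
reference (this exact normalization and the pSNR peak convention are
package choices — the common definitions leave them open, and they are
recorded in every `MetricsRecord`); Pearson correlation and mean
absolute error over all pixels (optional mask); SSIM with a Gaussian
window, σ 1.5, K1 0.01, K2 0.03, data range 1; pSNR = 20 log10(1/rmse)
with identical images capped at 99 dB.  Metrics are computed over the
whole image by default (no tissue masking).

## Numerical details and degenerate inputs

- Echo pairs with `Re C1 = Re C2` make the magnitude system ill-posed
  and are rejected.
- Background pixels (zero signal) get unit phasors, zero amplitudes,
  and are flagged degenerate; their graph weights vanish, so they do
  not influence selection.
- Pixels with `W = F` have coincident candidates; either label is
  accepted and the output is unaffected.
- Phasor upsampling renormalizes to unit modulus and falls back to
  nearest neighbor where opposed-phase neighbors cancel.
- All randomness flows through explicit integer seeds;
  `derive_seed(master, stage)` fans one master seed out to stages via
  SHA-256, keeping derived seeds below 2^31.

## Known limitations

- The classical solver is a heuristic for an NP-hard binary quadratic
  program; the brute-force oracle bounds it only on tiny graphs.
- The `auto` swap heuristic assumes a subcutaneous fat rim and a
  single connected object.
- The network is trained and evaluated purely on phantoms from this
  package's generator; no claim transfers to clinical data.
- 2D only; the clinical neighbor system may be 3D.
- The NumPy training loop is CPU-bound and desk-scale by design.
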